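"""Gene-order synteny: scaffold ordering by reference position, collinear
block detection, and displaced-segment flagging.

Positions are gene ranks, not base pairs, which makes the block logic
robust to indels; bp spans are reported alongside. A draft-genome target is
first laid out by sorting scaffolds on the median reference rank of their
orthologs — the practical stand-in for 'the order in which the majority of
their genes appear' in the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import AnnotatedGenome
from .orthology import OrthologMap

DEFAULT_DISPLACED_DISTANCE = 50


@dataclass
class SyntenyBlock:
    block_id: str
    pairs: list[tuple[str, str]]  # (reference locus, target locus)
    ref_interval: tuple[int, int]  # gene ranks, inclusive
    target_interval: tuple[int, int]
    orientation: str  # same | inverted
    displaced: bool = False
    scaffold_id: str = ""


def order_scaffolds_by_reference(
    target: AnnotatedGenome, map_: OrthologMap, reference: AnnotatedGenome
) -> list[str]:
    """Target scaffold IDs sorted by median reference rank of their
    orthologs; scaffolds with no orthologs go last, sorted by ID."""
    ref_rank = {f.locus_tag: i for i, f in enumerate(reference.gene_order())}
    by_b = map_.pair_by_b()
    keyed = []
    orphans = []
    for sid in target.scaffold_ids:
        ranks = [
            ref_rank[by_b[f.locus_tag].locus_a]
            for f in target.features
            if f.scaffold_id == sid and f.locus_tag in by_b
        ]
        if ranks:
            keyed.append((float(np.median(ranks)), sid))
        else:
            orphans.append(sid)
    return [sid for _, sid in sorted(keyed)] + sorted(orphans)


def synteny_blocks(
    map_: OrthologMap,
    target: AnnotatedGenome,
    reference: AnnotatedGenome,
    ordered_scaffolds: list[str] | None = None,
    max_target_gap: int = 1,
    max_ref_jump: int = 2,
    displaced_distance: int = DEFAULT_DISPLACED_DISTANCE,
) -> list[SyntenyBlock]:
    """Maximal within-scaffold runs of ortholog pairs with consecutive-
    monotone reference ranks.

    Up to ``max_target_gap`` unpaired target loci may sit between members,
    and the reference rank may skip up to ``max_ref_jump - 1`` loci per
    step (absorbing lineage-specific insertions on either side). Descending
    runs are inverted blocks. A block whose reference interval lies further
    than ``displaced_distance`` ranks from every neighbouring block (in
    target order) is flagged displaced.
    """
    ref_rank = {f.locus_tag: i for i, f in enumerate(reference.gene_order())}
    by_b = map_.pair_by_b()
    order = ordered_scaffolds or order_scaffolds_by_reference(
        target, map_, reference
    )
    feats_by_scaffold = {
        sid: [f for f in target.gene_order() if f.scaffold_id == sid]
        for sid in order
    }
    blocks: list[SyntenyBlock] = []
    trank = 0
    for sid in order:
        cur: list[tuple[int, int, str, str]] = []  # (trank, rrank, la, lb)
        direction = 0
        gap = 0

        def close():
            nonlocal cur, direction
            if cur:
                rr = [c[1] for c in cur]
                tt = [c[0] for c in cur]
                blocks.append(
                    SyntenyBlock(
                        block_id=f"block_{len(blocks) + 1}",
                        pairs=[(c[2], c[3]) for c in cur],
                        ref_interval=(min(rr), max(rr)),
                        target_interval=(min(tt), max(tt)),
                        orientation="inverted" if direction < 0 else "same",
                        scaffold_id=sid,
                    )
                )
            cur = []
            direction = 0

        for f in feats_by_scaffold[sid]:
            if f.locus_tag not in by_b:
                gap += 1
                if gap > max_target_gap:
                    close()
                trank += 1
                continue
            la = by_b[f.locus_tag].locus_a
            rr = ref_rank[la]
            if cur:
                delta = rr - cur[-1][1]
                ok = (
                    delta != 0
                    and abs(delta) <= max_ref_jump
                    and (direction == 0 or np.sign(delta) == direction)
                )
                if ok:
                    if direction == 0:
                        direction = int(np.sign(delta))
                else:
                    close()
            cur.append((trank, rr, la, f.locus_tag))
            gap = 0
            trank += 1
        close()
    # displaced flagging: a block is displaced when the reference rank jumps
    # by more than displaced_distance at every junction with its target-order
    # neighbours (block pairs are stored in target order, so the boundary
    # members are the first/last pairs regardless of orientation)
    def edge_rank(block: SyntenyBlock, first: bool) -> int:
        locus_a = block.pairs[0][0] if first else block.pairs[-1][0]
        return ref_rank[locus_a]

    for i, b in enumerate(blocks):
        jumps = []
        if i > 0:
            jumps.append(abs(edge_rank(blocks[i - 1], False) - edge_rank(b, True)))
        if i + 1 < len(blocks):
            jumps.append(abs(edge_rank(b, False) - edge_rank(blocks[i + 1], True)))
        b.displaced = bool(jumps) and all(j > displaced_distance for j in jumps)
    return blocks


def plot_synteny(
    target: AnnotatedGenome,
    map_: OrthologMap,
    reference: AnnotatedGenome,
    path: str,
    ordered_scaffolds: list[str] | None = None,
) -> None:
    """Synteny-gradient diagram: target genes as ticks coloured by the
    reference rank of their ortholog (gradient along the reference), with
    unpaired loci in grey."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref_rank = {f.locus_tag: i for i, f in enumerate(reference.gene_order())}
    n_ref = max(1, len(ref_rank) - 1)
    by_b = map_.pair_by_b()
    order = ordered_scaffolds or order_scaffolds_by_reference(
        target, map_, reference
    )
    cmap = plt.get_cmap("viridis")
    fig, ax = plt.subplots(figsize=(10, 2.2))
    for i in range(len(ref_rank)):
        ax.plot([i, i], [1.05, 1.45], color=cmap(i / n_ref), lw=0.8)
    x = 0
    for sid in order:
        for f in target.gene_order():
            if f.scaffold_id != sid:
                continue
            if f.locus_tag in by_b:
                c = cmap(ref_rank[by_b[f.locus_tag].locus_a] / n_ref)
            else:
                c = (0.7, 0.7, 0.7)
            ax.plot([x, x], [0.05, 0.45], color=c, lw=0.8)
            x += 1
        ax.axvline(x, ymin=0.02, ymax=0.32, color="k", lw=0.4, ls=":")
    ax.set_yticks([0.25, 1.25])
    ax.set_yticklabels([target.genome_id, reference.genome_id])
    ax.set_xlabel("gene rank")
    ax.set_ylim(0, 1.6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
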