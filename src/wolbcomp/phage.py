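"""Prophage-relic inventory: phage-homolog labelling, region delineation
tolerant of mobile-element interruptions and scaffold breaks, pseudogene
fragmentation detection, and the genome-reduction report.

Degrading prophages in endosymbiont genomes are not clean intervals: the
surviving gene runs are interrupted by freshly inserted transposases and
reverse transcriptases, split across scaffolds, and their genes decay into
premature-stop pseudogenes or multiple short annotations. The region logic
therefore works on gene order (not bp), tolerates a configurable number of
interleaved repeat-class loci, lets regions cross scaffold boundaries, and
counts genes at the ortholog level, merging fragments of one reference gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._codons import translate_cds
from .align import Scoring, glocal_align
from .genome import AnnotatedGenome
from .orthology import OrthologMap, _candidates

DEFAULT_GAP_TOLERANCE = 2


@dataclass
class PhageRegion:
    region_id: str
    members: list[str]  # ordered locus tags, interrupting repeats included
    gene_count: int  # ortholog-level, fragments merged
    interrupting_loci: list[str]
    span_bp: int
    scaffold_ids: list[str]
    reference_block: tuple[str, str] | None  # first/last matched ref locus


@dataclass
class FragmentationEvent:
    reference_locus: str
    fragments: list[str]
    cause: str  # premature_stop | split_annotation | truncation
    positions: list[tuple[int, int]] = field(default_factory=list)


def label_phage_homologs(
    target: AnnotatedGenome,
    phage_reference_loci: set[str],
    map_: OrthologMap,
    fragment_parents: dict[str, str] | None = None,
) -> dict[str, str | None]:
    """Per target locus: 'phage', 'repeat', or None.

    A locus is phage iff its ortholog — or, for annotation fragments, its
    fragment parent — is in the reference phage locus set. Repeat-class
    loci are flagged 'repeat' regardless (they interrupt, they do not
    belong), matching how mobile-element insertions inside relic regions
    are treated.
    """
    fragment_parents = fragment_parents or {}
    by_b = map_.pair_by_b()
    flags: dict[str, str | None] = {}
    for f in target.gene_order():
        if f.category == "repeat":
            flags[f.locus_tag] = "repeat"
            continue
        ref = None
        if f.locus_tag in by_b:
            ref = by_b[f.locus_tag].locus_a
        elif f.locus_tag in fragment_parents:
            ref = fragment_parents[f.locus_tag]
        flags[f.locus_tag] = "phage" if ref in phage_reference_loci else None
    return flags


def delineate_regions(
    target: AnnotatedGenome,
    flags: dict[str, str | None],
    map_: OrthologMap,
    gap_tolerance: int = DEFAULT_GAP_TOLERANCE,
    fragment_parents: dict[str, str] | None = None,
    reference: AnnotatedGenome | None = None,
) -> list[PhageRegion]:
    """Maximal runs of phage-flagged loci in genome order.

    Up to ``gap_tolerance`` consecutive interleaved repeat-class loci are
    absorbed (and reported as interrupting); any other locus, or a longer
    repeat run, breaks the region. Scaffold boundaries between consecutive
    members do not break a region. ``span_bp`` sums first-to-last extents
    per scaffold crossed.
    """
    fragment_parents = fragment_parents or {}
    by_b = map_.pair_by_b()
    ref_rank = (
        {f.locus_tag: i for i, f in enumerate(reference.gene_order())}
        if reference
        else {}
    )
    order = target.gene_order()
    regions: list[PhageRegion] = []
    cur: list = []
    pending_repeats: list = []
    interrupting: list[str] = []

    def close():
        nonlocal cur, pending_repeats, interrupting
        if cur:
            members = [f.locus_tag for f in cur]
            phage_members = [f for f in cur if flags[f.locus_tag] == "phage"]
            parents = set()
            for f in phage_members:
                if f.locus_tag in by_b:
                    parents.add(by_b[f.locus_tag].locus_a)
                elif f.locus_tag in fragment_parents:
                    parents.add(fragment_parents[f.locus_tag])
            span = 0
            sids: list[str] = []
            for f in cur:
                if f.scaffold_id not in sids:
                    sids.append(f.scaffold_id)
            for sid in sids:
                on = [f for f in cur if f.scaffold_id == sid]
                span += max(f.end for f in on) - min(f.start for f in on)
            ref_block = None
            if parents and ref_rank:
                ranked = sorted(parents, key=lambda t: ref_rank.get(t, -1))
                ref_block = (ranked[0], ranked[-1])
            regions.append(
                PhageRegion(
                    region_id=f"region_{len(regions) + 1}",
                    members=members,
                    gene_count=len(parents) if parents else len(phage_members),
                    interrupting_loci=list(interrupting),
                    span_bp=span,
                    scaffold_ids=sids,
                    reference_block=ref_block,
                )
            )
        cur = []
        pending_repeats = []
        interrupting = []

    for f in order:
        flag = flags.get(f.locus_tag)
        if flag == "phage":
            if cur and pending_repeats:
                cur.extend(pending_repeats)
                interrupting.extend(x.locus_tag for x in pending_repeats)
            pending_repeats = []
            cur.append(f)
        elif flag == "repeat" and cur:
            pending_repeats.append(f)
            if len(pending_repeats) > gap_tolerance:
                close()
        else:
            close()
    close()
    return regions


# ------------------------------------------------------------- fragmentation


def _internal_stops(cds: str) -> list[int]:
    """0-based codon indices of internal stops (final codon ignored)."""
    if len(cds) % 3:
        return []
    aa = translate_cds(cds)
    return [i for i, ch in enumerate(aa[:-1]) if ch == "*"]


def _ref_interval(fragment_cds: str, ref_cds: str, sc: Scoring) -> tuple[int, int]:
    """(start, end) 0-based half-open interval of the reference CDS covered
    by the fragment, from a glocal alignment."""
    aln = glocal_align(fragment_cds, ref_cds, sc, band=max(64, abs(len(ref_cds) - len(fragment_cds)) + 64))
    # count reference bases consumed before/inside the aligned stretch:
    # glocal output covers only the matched subject segment, so locate it
    start = ref_cds.find(aln.aligned_b.replace("-", ""))
    if start < 0:
        start = 0
    return start, start + len(aln.aligned_b.replace("-", ""))


def detect_fragmentation(
    map_: OrthologMap,
    target: AnnotatedGenome,
    reference: AnnotatedGenome,
    coverage_threshold: float = 0.9,
    min_fragment_identity: float = 60.0,
    scoring: Scoring | None = None,
) -> list[FragmentationEvent]:
    """Pseudogenization events of reference genes in the target.

    Three causes, in the order reported: a target CDS with a stop codon
    inside its reading frame where the reference has none
    (``premature_stop``, with 1-based nt positions of the stop codons);
    two or more target loci covering disjoint segments of one reference CDS
    (``split_annotation``); a paired target CDS covering less than
    ``coverage_threshold`` of its reference with flush scaffold sequence
    beyond the gene (``truncation``).
    """
    sc = scoring or Scoring()
    events: list[FragmentationEvent] = []
    by_b = {f.locus_tag: f for f in target.features}
    ref_by_tag = reference.features_by_tag()

    # (i) premature stops in paired genes
    for p in map_.pairs:
        tf = by_b.get(p.locus_b)
        rf = ref_by_tag.get(p.locus_a)
        if tf is None or rf is None or len(tf.cds_seq) % 3 or len(rf.cds_seq) % 3:
            continue
        stops = _internal_stops(tf.cds_seq)
        if stops and not _internal_stops(rf.cds_seq):
            events.append(
                FragmentationEvent(
                    reference_locus=p.locus_a,
                    fragments=[p.locus_b],
                    cause="premature_stop",
                    positions=[(3 * i + 1, 3 * i + 3) for i in stops],
                )
            )

    # (ii) split annotations: unpaired target loci that hit a reference CDS
    # on a segment disjoint from the paired fragment's segment
    ref_feats = reference.gene_order()
    ref_seqs = [f.cds_seq for f in ref_feats]
    unpaired = [by_b[t] for t in map_.unpaired_b if t in by_b]
    coverage_by_ref: dict[str, list[tuple[str, tuple[int, int]]]] = {}
    for p in map_.pairs:
        rf = ref_by_tag.get(p.locus_a)
        tf = by_b.get(p.locus_b)
        if rf is None or tf is None:
            continue
        coverage_by_ref.setdefault(p.locus_a, []).append(
            (p.locus_b, _ref_interval(tf.cds_seq, rf.cds_seq, sc))
        )
    if unpaired:
        cands = _candidates([f.cds_seq for f in unpaired], ref_seqs, k=12, min_seeds=2)
        for ui, ref_idxs in cands.items():
            uf = unpaired[ui]
            best = None
            for ri in ref_idxs:
                aln = glocal_align(uf.cds_seq, ref_seqs[ri], sc, band=256)
                matches = sum(
                    1
                    for x, y in zip(aln.aligned_a, aln.aligned_b)
                    if x == y and x in "ACGT"
                )
                ident = 100.0 * matches / aln.length
                if ident >= min_fragment_identity and (
                    best is None or aln.score > best[0]
                ):
                    best = (aln.score, ri)
            if best is not None:
                ri = best[1]
                coverage_by_ref.setdefault(ref_feats[ri].locus_tag, []).append(
                    (
                        uf.locus_tag,
                        _ref_interval(uf.cds_seq, ref_seqs[ri], sc),
                    )
                )
    for ref_tag, frags in coverage_by_ref.items():
        if len(frags) < 2:
            continue
        frags = sorted(frags, key=lambda t: t[1])
        disjoint = all(
            frags[i][1][1] <= frags[i + 1][1][0] + 0.2 * len(ref_by_tag[ref_tag])
            for i in range(len(frags) - 1)
        )
        if disjoint:
            events.append(
                FragmentationEvent(
                    reference_locus=ref_tag,
                    fragments=[t for t, _ in frags],
                    cause="split_annotation",
                    positions=[iv for _, iv in frags],
                )
            )

    # (iii) truncations among paired genes
    split_refs = {e.reference_locus for e in events}
    for p in map_.pairs:
        if p.locus_a in split_refs:
            continue
        tf = by_b.get(p.locus_b)
        rf = ref_by_tag.get(p.locus_a)
        if tf is None or rf is None:
            continue
        missing = len(rf.cds_seq) - len(tf.cds_seq)
        if missing <= 0 or len(tf.cds_seq) >= coverage_threshold * len(rf.cds_seq):
            continue
        scaffold_len = len(target.scaffold_seq(tf.scaffold_id))
        flush = tf.start >= missing and scaffold_len - tf.end >= missing
        if flush:
            events.append(
                FragmentationEvent(
                    reference_locus=p.locus_a,
                    fragments=[p.locus_b],
                    cause="truncation",
                    positions=[(len(tf.cds_seq) + 1, len(rf.cds_seq))],
                )
            )
    return events


def fragment_parent_map(events: list[FragmentationEvent]) -> dict[str, str]:
    """target locus -> reference parent, for census merging."""
    out: dict[str, str] = {}
    for e in events:
        for t in e.fragments:
            out[t] = e.reference_locus
    return out


# ---------------------------------------------------------- reduction report


def reference_regions(reference: AnnotatedGenome) -> list[dict]:
    """Phage/accessory region definitions on the reference.

    Uses explicit region metadata when the genome carries it (simulated
    genomes do); otherwise derives regions as contiguous runs of
    phage-category loci.
    """
    meta = reference.metadata.get("regions")
    if meta:
        return meta
    regions = []
    run: list[str] = []
    for f in reference.gene_order():
        if f.category == "phage":
            run.append(f.locus_tag)
        elif run:
            regions.append(
                {"region_id": f"phage_{len(regions)}", "kind": "phage", "loci": run}
            )
            run = []
    if run:
        regions.append(
            {"region_id": f"phage_{len(regions)}", "kind": "phage", "loci": run}
        )
    return regions


def reduction_report(
    reference: AnnotatedGenome,
    target: AnnotatedGenome,
    map_: OrthologMap,
    regions: list[PhageRegion],
    events: list[FragmentationEvent],
    missing: list[tuple[str, float]],
) -> dict:
    """Genome-reduction summary against the reference's phage/accessory
    regions: per-region retention and status, the ortholog-level retained
    phage-gene census, and flanks of fully absent regions."""
    by_a = map_.pair_by_a()
    parents = set(fragment_parent_map(events).values())
    missing_set = {t for t, _ in missing}
    ref_order = [f.locus_tag for f in reference.gene_order()]
    ref_feats = reference.features_by_tag()

    def retained(tag: str) -> bool:
        return tag in by_a or tag in parents

    out_regions = []
    for rdef in reference_regions(reference):
        loci = list(rdef["loci"])
        kept = [t for t in loci if retained(t)]
        lost = [t for t in loci if not retained(t)]
        if not kept:
            status = "absent"
        elif not lost:
            status = "intact"
        else:
            status = "reduced"
        flanking = None
        if status == "absent":
            idxs = [ref_order.index(t) for t in loci]
            lo, hi = min(idxs), max(idxs)
            flanking = (
                ref_order[lo - 1] if lo > 0 else None,
                ref_order[hi + 1] if hi + 1 < len(ref_order) else None,
            )
        out_regions.append(
            {
                "region_id": rdef["region_id"],
                "kind": rdef.get("kind", "phage"),
                "n_genes": len(loci),
                "n_retained": len(kept),
                "retained_fraction": len(kept) / len(loci),
                "status": status,
                "lost_loci": lost,
                "lost_span_bp": sum(len(ref_feats[t]) for t in lost),
                "flanking_loci": flanking,
                "lost_confirmed_missing": sorted(set(lost) & missing_set),
            }
        )
    phage_ref_loci = {
        f.locus_tag for f in reference.features if f.category == "phage"
    }
    census = sum(1 for t in phage_ref_loci if retained(t))
    return {
        "regions": out_regions,
        "phage_gene_census": census,
        "n_reference_phage_genes": len(phage_ref_loci),
        "total_lost_span_bp": sum(r["lost_span_bp"] for r in out_regions),
        "target_regions_detected": len(regions),
    }
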