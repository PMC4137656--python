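"""Divergence / positive-selection screen and outgroup polarization.

Mirrors the classic two-filter screen for a near-clonal genome pair:
ortholog pairs below an identity threshold (default: strictly less than
98%) are tabulated with lengths, SNP breakdown, Ka/Ks and indel notes, and
pairs with a defined Ka/Ks strictly above 1 are flagged as candidates for
positive selection. Undefined omega (Ks = 0) is carried as an explicit
marker, never as 0 or infinity. Derived-vs-ancestral alleles are polarized
against an earlier-branching outgroup by projecting pairwise alignments
onto the reference sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import IndelEvent, PairwiseAlignment, Scoring, gap_runs, global_align
from .divergence import SubstitutionSummary
from .orthology import OrthologMap


@dataclass
class ScreenConfig:
    identity_threshold: float = 98.0  # strict less-than
    omega_threshold: float = 1.0  # strict greater-than

    def __post_init__(self):
        if self.identity_threshold <= 0 or self.omega_threshold <= 0:
            raise ValueError("screen thresholds must be positive")


def annotate_indels(aln: PairwiseAlignment) -> list[IndelEvent]:
    """Maximal gap runs of an alignment as indel events.

    Each event names the side that gained sequence, the 1-based position in
    the other sequence after which the extra bases sit, and the length. The
    events always satisfy the length bookkeeping
    sum(insertions) - sum(deletions) = len(a) - len(b).
    """
    events = gap_runs(aln.aligned_a, aln.aligned_b)
    net = sum(e.length if e.side == "a" else -e.length for e in events)
    la = len(aln.aligned_a.replace("-", ""))
    lb = len(aln.aligned_b.replace("-", ""))
    assert net == la - lb, "indel bookkeeping violated"
    return events


def indel_notes(aln: PairwiseAlignment) -> str:
    """Human-readable note string, e.g. '189 bp insertion, 6 bp deletion'.

    Insertion/deletion is phrased relative to sequence a as the reference:
    extra sequence in b is an insertion, missing sequence in b a deletion.
    """
    parts = []
    for e in annotate_indels(aln):
        kind = "insertion" if e.side == "b" else "deletion"
        parts.append(f"{e.length} bp {kind}")
    return ", ".join(parts)


def screen_divergent_genes(
    map_: OrthologMap,
    summaries: list[SubstitutionSummary],
    cfg: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Table of ortholog pairs below the identity threshold (strict).

    Output is deterministically sorted by identity ascending then locus
    tag, with identity to one decimal and an explicit '-' for undefined
    omega — one row per divergent pair, shaped like a published
    divergent-gene table.
    """
    cfg = cfg or ScreenConfig()
    by_a = {s.locus_a: s for s in summaries}
    rows = []
    for p in map_.pairs:
        if p.identity_pct >= cfg.identity_threshold:
            continue
        s = by_a.get(p.locus_a)
        la = len(p.aligned_a.replace("-", ""))
        lb = len(p.aligned_b.replace("-", ""))
        rows.append(
            {
                "locus_a": p.locus_a,
                "locus_b": p.locus_b,
                "identity_pct": round(p.identity_pct, 1),
                "len_a": la,
                "len_b": lb,
                "snp_count": s.snp_count if s else None,
                "nonsyn_snp_count": s.nonsyn_snp_count if s else None,
                "omega": s.omega if s and s.omega is not None else None,
                "omega_display": (
                    f"{s.omega:.2f}" if s and s.omega is not None else "-"
                ),
                "indel_notes": indel_notes(p),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "locus_a", "locus_b", "identity_pct", "len_a", "len_b",
            "snp_count", "nonsyn_snp_count", "omega", "omega_display",
            "indel_notes",
        ],
    )
    return df.sort_values(
        ["identity_pct", "locus_a"], kind="mergesort"
    ).reset_index(drop=True)


def flag_positive_selection(
    summaries: list[SubstitutionSummary], cfg: ScreenConfig | None = None
) -> tuple[list[str], list[str]]:
    """Loci with defined omega strictly above the threshold.

    Returns (flagged, undefined): undefined-omega loci (Ks = 0 with
    substitutions, or excluded/saturated genes) are listed separately and
    never flagged.
    """
    cfg = cfg or ScreenConfig()
    flagged, undefined = [], []
    for s in summaries:
        if s.omega is None:
            if s.snp_count or s.excluded_reason or s.saturated:
                undefined.append(s.locus_a)
        elif s.omega > cfg.omega_threshold:
            flagged.append(s.locus_a)
    return sorted(flagged), sorted(undefined)


# --------------------------------------------------------------- polarization


@dataclass
class PolarizationResult:
    locus_a: str
    locus_b: str
    locus_outgroup: str | None
    diverged_sites: int = 0
    matches_outgroup_a: int = 0
    matches_outgroup_b: int = 0
    unpolarizable: int = 0
    indel_sites_excluded: int = 0
    derived_lineage: str | None = None  # lineage whose alleles look derived

    def check(self) -> None:
        assert (
            self.matches_outgroup_a + self.matches_outgroup_b + self.unpolarizable
            == self.diverged_sites
        )


def _project_onto_reference(aln: PairwiseAlignment) -> list[str | None]:
    """Per reference (a) position: the aligned partner base or None (gap)."""
    out: list[str | None] = []
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-":
            out.append(y if y != "-" else None)
    return out


def polarize_with_outgroup(
    gene_a: str,
    gene_b: str,
    gene_og: str | None,
    locus_a: str = "a",
    locus_b: str = "b",
    locus_og: str = "outgroup",
    scoring: Scoring | None = None,
) -> PolarizationResult:
    """Attribute a/b differences to a lineage using an outgroup allele.

    The three-way comparison is built by aligning b and the outgroup each
    onto a (the reference) and projecting — deterministic and adequate at
    the few-percent divergence this screen operates on, rather than a full
    MSA. Per diverged site: outgroup allele equal to a's counts toward
    ``matches_outgroup_a``, equal to b's toward ``matches_outgroup_b``,
    anything else (third allele, or outgroup gap) is unpolarizable. Sites
    where b is gapped relative to a are excluded and counted separately. A
    lineage is called derived when the *other* lineage's matches form a
    strict majority of diverged sites.
    """
    sc = scoring or Scoring()
    res = PolarizationResult(locus_a, locus_b, locus_og if gene_og else None)
    proj_b = _project_onto_reference(global_align(gene_a, gene_b, sc))
    proj_og = (
        _project_onto_reference(global_align(gene_a, gene_og, sc))
        if gene_og
        else [None] * len(proj_b)
    )
    for pos, (base_a, base_b) in enumerate(zip(gene_a.upper(), proj_b)):
        if base_b is None:
            res.indel_sites_excluded += 1
            continue
        if base_a == base_b:
            continue
        res.diverged_sites += 1
        og = proj_og[pos]
        if og == base_a:
            res.matches_outgroup_a += 1
        elif og == base_b:
            res.matches_outgroup_b += 1
        else:
            res.unpolarizable += 1
    if res.matches_outgroup_a * 2 > res.diverged_sites:
        res.derived_lineage = "b"
    elif res.matches_outgroup_b * 2 > res.diverged_sites:
        res.derived_lineage = "a"
    res.check()
    return res
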