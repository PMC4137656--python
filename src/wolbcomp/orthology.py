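"""Reciprocal-best-hit orthology over the internal aligner.

Candidate homolog discovery is seed-and-extend: exact k-mer seeds (default
k=12) nominate candidate pairs, which are then scored with the affine-gap
global aligner. A pair (a, b) is kept iff b is a's best-scoring hit and a is
b's; tied bests are recorded as ambiguous and broken toward the
lexicographically smallest partner tag. This deliberately replaces an
external BLAST screen: at the sub-percent divergence this package targets,
any conventional homology hit sits far above the identity/coverage floor
used here, and all thresholds are exposed.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from ._codons import revcomp
from .align import PairwiseAlignment, Scoring, global_align, glocal_align
from .genome import AnnotatedGenome

DEFAULT_K = 12
# one chance ~14 nt match already yields 2-3 overlapping shared 12-mers, so
# the seed-count floor must sit well above that; true orthologs at <10%
# divergence share hundreds of exact 12-mers on a typical CDS
DEFAULT_MIN_SEEDS = 10
DEFAULT_BAND = 64


@dataclass
class OrthologMap:
    pairs: list[PairwiseAlignment] = field(default_factory=list)
    unpaired_a: list[str] = field(default_factory=list)
    unpaired_b: list[str] = field(default_factory=list)
    ambiguous_a: list[str] = field(default_factory=list)
    ambiguous_b: list[str] = field(default_factory=list)

    def pair_by_a(self) -> dict[str, PairwiseAlignment]:
        return {p.locus_a: p for p in self.pairs}

    def pair_by_b(self) -> dict[str, PairwiseAlignment]:
        return {p.locus_b: p for p in self.pairs}

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def identity_fraction_at_least(self, threshold: float) -> float:
        """Fraction of pairs whose identity is >= threshold percent."""
        if not self.pairs:
            return 0.0
        return sum(p.identity_pct >= threshold for p in self.pairs) / len(self.pairs)


def _kmer_index(seqs: list[str], k: int, cap: int = 50) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = defaultdict(list)
    for i, s in enumerate(seqs):
        seen = set()
        for p in range(0, len(s) - k + 1):
            kmer = s[p : p + k]
            if kmer in seen:
                continue
            seen.add(kmer)
            bucket = idx[kmer]
            if len(bucket) < cap:
                bucket.append(i)
    return idx


def _candidates(
    seqs_a: list[str], seqs_b: list[str], k: int, min_seeds: int
) -> dict[int, list[int]]:
    idx_b = _kmer_index(seqs_b, k)
    cands: dict[int, list[int]] = {}
    for ia, s in enumerate(seqs_a):
        counts: dict[int, int] = defaultdict(int)
        seen = set()
        for p in range(0, len(s) - k + 1):
            kmer = s[p : p + k]
            if kmer in seen:
                continue
            seen.add(kmer)
            for ib in idx_b.get(kmer, ()):
                counts[ib] += 1
        cands[ia] = [ib for ib, c in counts.items() if c >= min_seeds]
    return cands


def reciprocal_best_hits(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    min_identity: float = 60.0,
    min_coverage: float = 0.5,
    scoring: Scoring | None = None,
    k: int = DEFAULT_K,
    min_seeds: int = DEFAULT_MIN_SEEDS,
    band: int | None = DEFAULT_BAND,
) -> OrthologMap:
    """One-to-one ortholog pairing of CDS between two genomes.

    Hits must pass ``min_identity`` percent and cover ``min_coverage`` of
    the shorter CDS. Multi-copy families surface through the ambiguous
    lists; each locus appears in at most one pair.
    """
    sc = scoring or Scoring()
    feats_a = genome_a.gene_order()
    feats_b = genome_b.gene_order()
    seqs_a = [f.cds_seq for f in feats_a]
    seqs_b = [f.cds_seq for f in feats_b]
    tags_a = [f.locus_tag for f in feats_a]
    tags_b = [f.locus_tag for f in feats_b]

    cands = _candidates(seqs_a, seqs_b, k, min_seeds)
    alignments: dict[tuple[int, int], PairwiseAlignment] = {}
    for ia, ibs in cands.items():
        for ib in ibs:
            aln = global_align(
                seqs_a[ia], seqs_b[ib], sc, tags_a[ia], tags_b[ib], band=band
            )
            if aln.identity_pct >= min_identity and aln.coverage >= min_coverage:
                alignments[(ia, ib)] = aln

    best_for_a: dict[int, tuple[int, list[int]]] = {}
    best_for_b: dict[int, tuple[int, list[int]]] = {}
    for (ia, ib), aln in alignments.items():
        for store, key, other in ((best_for_a, ia, ib), (best_for_b, ib, ia)):
            if key not in store or aln.score > store[key][0]:
                store[key] = (aln.score, [other])
            elif aln.score == store[key][0]:
                store[key][1].append(other)

    m = OrthologMap()
    paired_a: set[int] = set()
    paired_b: set[int] = set()
    for ia in sorted(best_for_a):
        score, ib_list = best_for_a[ia]
        if len(ib_list) > 1:
            m.ambiguous_a.append(tags_a[ia])
        ib = min(ib_list, key=lambda i: tags_b[i])
        back = best_for_b.get(ib)
        if back is None:
            continue
        _, ia_list = back
        if len(ia_list) > 1 and tags_b[ib] not in m.ambiguous_b:
            m.ambiguous_b.append(tags_b[ib])
        ia_back = min(ia_list, key=lambda i: tags_a[i])
        if ia_back == ia and ib not in paired_b:
            m.pairs.append(alignments[(ia, ib)])
            paired_a.add(ia)
            paired_b.add(ib)
    m.unpaired_a = [tags_a[i] for i in range(len(tags_a)) if i not in paired_a]
    m.unpaired_b = [tags_b[i] for i in range(len(tags_b)) if i not in paired_b]
    return m


def _scaffold_index(
    target: AnnotatedGenome, k: int
) -> list[tuple[str, dict[str, list[int]]]]:
    out = []
    for _, scaffold in target.scaffolds:
        idx: dict[str, list[int]] = defaultdict(list)
        for p in range(0, len(scaffold) - k + 1):
            idx[scaffold[p : p + k]].append(p)
        out.append((scaffold, idx))
    return out


def scan_scaffolds(
    query: str,
    target: AnnotatedGenome,
    scoring: Scoring | None = None,
    k: int = DEFAULT_K,
    band: int = 128,
    _index: list[tuple[str, dict[str, list[int]]]] | None = None,
) -> tuple[float, float]:
    """Best (identity_pct, coverage) of a CDS against the target scaffolds.

    Both strands are searched via exact k-mer seeds; seed clusters are
    re-aligned glocally (query end-to-end, free subject end gaps). Returns
    (0, 0) when no seed matches anywhere.
    """
    sc = scoring or Scoring()
    best = (0.0, 0.0)
    best_key = (-1, 0.0)
    for scaffold, idx in _index if _index is not None else _scaffold_index(target, k):
        for q in (query, revcomp(query)):
            hits: list[int] = []
            for p in range(0, len(q) - k + 1):
                hits.extend(idx.get(q[p : p + k], ()))
            if not hits:
                continue
            hits.sort()
            clusters: list[list[int]] = [[hits[0]]]
            for h in hits[1:]:
                if h - clusters[-1][-1] > len(q):
                    clusters.append([h])
                else:
                    clusters[-1].append(h)
            clusters.sort(key=len, reverse=True)
            for cl in clusters[:3]:
                margin = max(60, len(q) // 5)
                lo = max(0, cl[0] - margin)
                hi = min(len(scaffold), cl[-1] + k + margin)
                aln = glocal_align(q, scaffold[lo:hi], sc, band=band)
                matches = sum(
                    1
                    for x, y in zip(aln.aligned_a, aln.aligned_b)
                    if x == y and x in "ACGT"
                )
                both = sum(
                    1
                    for x, y in zip(aln.aligned_a, aln.aligned_b)
                    if x != "-" and y != "-"
                )
                # gap columns count against identity: gappy junk alignments
                # of compositionally biased DNA must not look homologous
                ident = 100.0 * matches / aln.length if aln.length else 0.0
                cov = both / len(q)
                if (matches, ident) > best_key:
                    best_key = (matches, ident)
                    best = (ident, cov)
                if best[0] >= 95.0 and best[1] >= 0.95:
                    return best  # unambiguously present; stop scanning
    return best


def find_missing_genes(
    reference: AnnotatedGenome,
    target: AnnotatedGenome,
    min_identity: float = 60.0,
    min_coverage: float = 0.5,
    scoring: Scoring | None = None,
    k: int = DEFAULT_K,
) -> list[tuple[str, float]]:
    """Reference CDS with no homologous stretch anywhere in the target.

    A gene counts as present when some scaffold stretch aligns at
    >= ``min_identity`` percent over >= ``min_coverage`` of the CDS length;
    everything else is returned with its best sub-threshold identity for
    audit.
    """
    index = _scaffold_index(target, k)  # built once, shared across queries
    missing: list[tuple[str, float]] = []
    for f in reference.gene_order():
        ident, cov = scan_scaffolds(f.cds_seq, target, scoring, k, _index=index)
        if ident < min_identity or cov < min_coverage:
            missing.append((f.locus_tag, round(ident, 1)))
    return missing
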