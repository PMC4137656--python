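"""NG86 / Jukes–Cantor divergence tests.

The independent oracle re-derives site and substitution counts from the
translation table by direct enumeration (different code path from the
package: no precomputed neighbour lists, recursive pathway walk).
"""

import itertools
import math

import numpy as np
import pytest
from Bio.Data import CodonTable

from wolbcomp.align import PairwiseAlignment
from wolbcomp.divergence import (
    ClockModel,
    DivergenceError,
    FrameBreak,
    codon_align,
    estimate_divergence_time,
    gene_ka_ks,
    genome_wide_divergence,
    jukes_cantor,
    ng_sites,
    ng_substitutions,
    SubstitutionSummary,
)

_T11 = CodonTable.unambiguous_dna_by_id[11]
AA = dict(_T11.forward_table)
STOPS = set(_T11.stop_codons)
SENSE = sorted(AA)


# ------------------------------------------------------------------- oracles


def oracle_sites(codon):
    """Neighbour enumeration: each non-stop single-nt neighbour weighs 1/3."""
    s = n = 0.0
    for pos, alt in itertools.product(range(3), "ACGT"):
        if alt == codon[pos]:
            continue
        nb = codon[:pos] + alt + codon[pos + 1 :]
        if nb in STOPS:
            continue
        if AA[nb] == AA[codon]:
            s += 1 / 3
        else:
            n += 1 / 3
    return s, n


def oracle_subs(ca, cb):
    """Recursive pathway enumeration of (sd, nd), skipping stop pathways."""
    diff = [p for p in range(3) if ca[p] != cb[p]]

    def walk(cur, remaining):
        if not remaining:
            return [(0.0, 0.0)]
        out = []
        for p in remaining:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if nxt in STOPS:
                continue
            step_syn = AA[cur] == AA[nxt]
            for sd, nd in walk(nxt, [q for q in remaining if q != p]):
                out.append((sd + step_syn, nd + (not step_syn)))
        return out

    paths = walk(ca, diff)
    if not paths:
        return None  # all pathways blocked
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


# ----------------------------------------------------------------- ng_sites


def test_ng_sites_worked_examples():
    s, n = ng_sites("TTT")
    assert s == pytest.approx(1 / 3)
    assert n == pytest.approx(8 / 3)
    s, n = ng_sites("ATG")  # no synonymous neighbour, no stop neighbour
    assert s == 0.0
    assert n == pytest.approx(3.0)
    s, n = ng_sites("TGG")  # TAG and TGA neighbours are excluded stops
    assert s == 0.0
    assert n == pytest.approx(7 / 3)


def test_ng_sites_matches_enumeration_oracle_for_all_sense_codons():
    for codon in SENSE:
        s, n = ng_sites(codon)
        es, en = oracle_sites(codon)
        assert s == pytest.approx(es, abs=1e-12)
        assert n == pytest.approx(en, abs=1e-12)
        has_stop_neighbour = any(
            codon[:p] + alt + codon[p + 1 :] in STOPS
            for p in range(3)
            for alt in "ACGT"
            if alt != codon[p]
        )
        assert s + n <= 3.0 + 1e-12
        assert (abs(s + n - 3.0) < 1e-12) == (not has_stop_neighbour)


def test_ng_sites_rejects_stops_and_ambiguity():
    with pytest.raises(DivergenceError):
        ng_sites("TAA")
    with pytest.raises(DivergenceError):
        ng_sites("ANT")


# -------------------------------------------------------- ng_substitutions


def test_ng_substitutions_worked_examples():
    assert ng_substitutions("TTT", "TTC")[:2] == (1.0, 0.0)
    sd, nd, _, flagged = ng_substitutions("TTT", "GTA")
    assert (sd, nd) == (0.5, 1.5)
    assert not flagged
    for codon in ("ATG", "TTT", "GGG"):
        assert ng_substitutions(codon, codon)[:2] == (0.0, 0.0)


def test_ng_substitutions_matches_pathway_oracle_on_random_pairs():
    rng = np.random.default_rng(2024)
    checked = 0
    while checked < 500:
        ca, cb = (SENSE[i] for i in rng.integers(0, len(SENSE), size=2))
        expected = oracle_subs(ca, cb)
        sd, nd, per_pos, flagged = ng_substitutions(ca, cb)
        if expected is None:
            assert flagged
        else:
            assert sd == pytest.approx(expected[0], abs=1e-12)
            assert nd == pytest.approx(expected[1], abs=1e-12)
            ndiff = sum(ca[p] != cb[p] for p in range(3))
            assert sd + nd == pytest.approx(ndiff, abs=1e-12)
            assert sum(per_pos.values()) == pytest.approx(sd, abs=1e-12)
        checked += 1


# ------------------------------------------------------------- codon_align


def _aln(a, b):
    return PairwiseAlignment("x", "y", a, b, score=0)


def test_codon_align_gapless():
    a = "ATG" * 33
    pairs, dropped = codon_align(_aln(a, a))
    assert len(pairs) == 33
    assert dropped == 0


def test_codon_align_drops_gapped_column():
    a = "ATGAAATTTGGG"
    b = "ATG---TTTGGG"
    pairs, dropped = codon_align(_aln(a, b))
    assert len(pairs) == 3
    assert dropped == 1


def test_codon_align_insertion_relative_to_anchor_drops_only_insert():
    a = "ATG---TTTGGG"
    b = "ATGCCCTTTGGG"
    pairs, dropped = codon_align(_aln(a, b))
    assert len(pairs) == 3  # anchor has 9 nt = 3 codons, all clean
    assert dropped == 1


def test_codon_align_frame_break_on_non_triplet_gap():
    with pytest.raises(FrameBreak):
        codon_align(_aln("ATGA-ATTTGGGAAA", "ATGAAATTTGGGAA-"))


# ------------------------------------------------------------- gene_ka_ks


def brute_force_summary(codon_pairs):
    """Independent site-by-site recomputation using the oracles above."""
    S = N = Sd = Nd = 0.0
    for ca, cb in codon_pairs:
        s1, n1 = oracle_sites(ca)
        s2, n2 = oracle_sites(cb)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        subs = oracle_subs(ca, cb)
        if subs:
            Sd += subs[0]
            Nd += subs[1]
    return S, N, Sd, Nd


def test_identical_gene_has_zero_distance_and_undefined_omega():
    pairs = [("ATG", "ATG")] * 40
    s = gene_ka_ks(pairs)
    assert s.Ks == 0.0 and s.Ka == 0.0
    assert s.omega is None and not s.omega_defined


def test_short_alignment_excluded():
    pairs = [("ATG", "ATG")] * 29
    s = gene_ka_ks(pairs)
    assert s.excluded_reason == "too_short"


def test_gene_ka_ks_matches_brute_force_on_random_fixtures():
    rng = np.random.default_rng(99)
    for _ in range(3):
        pairs = []
        for _ in range(1000):
            ca = SENSE[rng.integers(0, len(SENSE))]
            if rng.random() < 0.1:
                cb = SENSE[rng.integers(0, len(SENSE))]
            else:
                cb = ca
            pairs.append((ca, cb))
        s = gene_ka_ks(pairs)
        S, N, Sd, Nd = brute_force_summary(
            [(a, b) for a, b in pairs if oracle_subs(a, b) is not None]
        )
        # pairs whose pathways are all blocked are classified directly; they
        # are rare and excluded from the brute-force comparison set
        clean = [(a, b) for a, b in pairs if oracle_subs(a, b) is not None]
        s2 = gene_ka_ks(clean)
        assert s2.S == pytest.approx(S, abs=1e-12)
        assert s2.Sd == pytest.approx(Sd, abs=1e-12)
        assert s2.Nd == pytest.approx(Nd, abs=1e-12)
        if s2.pS < 0.75:
            assert s2.Ks == pytest.approx(jukes_cantor(Sd / S), abs=1e-12)


def test_gene_ka_ks_symmetric_under_sequence_swap():
    rng = np.random.default_rng(5)
    pairs = [
        (SENSE[rng.integers(0, 61)], SENSE[rng.integers(0, 61)]) for _ in range(200)
    ]
    s1 = gene_ka_ks(pairs)
    s2 = gene_ka_ks([(b, a) for a, b in pairs])
    assert s1.Ks == s2.Ks and s1.Ka == s2.Ka and s1.S == s2.S


def test_jc_correction_monotone_and_above_raw_proportion():
    grid = np.linspace(0.0, 0.74, 50)
    vals = [jukes_cantor(p) for p in grid]
    assert all(v2 > v1 for v1, v2 in zip(vals, vals[1:]))
    assert all(v >= p for v, p in zip(vals, grid))
    with pytest.raises(DivergenceError):
        jukes_cantor(0.75)


# -------------------------------------------------- genome-wide and clock


def test_single_gene_concat_equals_gene_values():
    pairs = [("TTT", "TTC")] * 3 + [("AAA", "AAA")] * 40
    s = gene_ka_ks(pairs)
    gw = genome_wide_divergence([s])
    assert gw.ks_concat == pytest.approx(s.Ks)
    assert gw.ka_concat == pytest.approx(s.Ka)


def test_synonymous_percentage_reported_from_snp_totals():
    # two genes whose SNP ledgers sum to 2,009 with 599 synonymous
    a = SubstitutionSummary("g1", "h1", 300, 100, 200, 9, 9, snp_count=1000,
                            syn_snp_count=300.0, Ks=0.0, Ka=0.0)
    b = SubstitutionSummary("g2", "h2", 300, 100, 200, 9, 9, snp_count=1009,
                            syn_snp_count=299.0, Ks=0.0, Ka=0.0)
    gw = genome_wide_divergence([a, b])
    assert gw.snp_total == 2009
    assert gw.syn_snp_total == 599.0
    assert round(gw.syn_snp_percent, 1) == 29.8


def test_no_eligible_genes_errors():
    s = gene_ka_ks([("ATG", "ATG")] * 10)  # too_short
    with pytest.raises(DivergenceError):
        genome_wide_divergence([s])


def test_clock_worked_example_and_edge_cases():
    t = estimate_divergence_time(0.314, ClockModel(0.9))
    assert round(t.years_raw) == 348889
    assert t.years_rounded == 350000
    assert estimate_divergence_time(0.0, ClockModel(0.9)).years_raw == 0
    assert estimate_divergence_time(0.9, ClockModel(0.9)).years_raw == 1_000_000
    with pytest.raises(DivergenceError):
        ClockModel(0.0)


def test_omega_class_recovery_across_seeds(omega_sweep):
    """Parameter recovery: the three simulated omega classes rank-order
    correctly in every seed, and the suite-pooled estimates are within 30%
    of their targets."""
    for run in omega_sweep["runs"]:
        o = run["omega_by_class"]
        assert o["core"] < o["hypothetical"] < o["phage"], run
    for cat, target in omega_sweep["omega_targets"].items():
        pooled = omega_sweep["pooled_omega"][cat]
        assert abs(pooled - target) / target < 0.30, (cat, pooled)
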