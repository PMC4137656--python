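"""Simulator tests: determinism, construction constraints, event ledgers."""

import pytest

from wolbcomp._codons import STOP_CODONS, translate_cds
from wolbcomp.divergence import jukes_cantor
from wolbcomp.simulate import (
    EvolutionConfig,
    SimulationError,
    evolve_pair,
    generate_ancestor,
)


def small_cfg(**kw):
    base = dict(
        n_genes=50,
        seed=1,
        phage_regions=[(10, 21)],
        accessory_regions=[],
        region_deletions=[],
        fragmentation_events=0,
        repeat_insertions=0,
        indel_gene_fraction=0.0,
    )
    base.update(kw)
    return EvolutionConfig(**base)


def genome_bytes(g):
    return (
        tuple(g.scaffolds),
        tuple(
            (f.locus_tag, f.start, f.end, f.strand, f.category, f.cds_seq)
            for f in g.features
        ),
    )


def test_ancestor_deterministic_under_seed():
    g1 = generate_ancestor(small_cfg())
    g2 = generate_ancestor(small_cfg())
    assert genome_bytes(g1) == genome_bytes(g2)


def test_phage_region_layout():
    g = generate_ancestor(small_cfg())
    cats = [f.category for f in g.gene_order()]
    assert all(c == "phage" for c in cats[10:31])
    assert not any(c == "phage" for c in cats[:10] + cats[31:])


def test_generated_cds_have_no_internal_stops_and_canonical_ends():
    g = generate_ancestor(small_cfg(seed=4))
    for f in g.features:
        assert f.cds_seq.startswith("ATG")
        assert f.cds_seq[-3:] in STOP_CODONS
        assert "*" not in translate_cds(f.cds_seq)[:-1]


def test_overlapping_regions_rejected():
    with pytest.raises(SimulationError, match="overlap"):
        generate_ancestor(small_cfg(phage_regions=[(10, 21)], accessory_regions=[(20, 5)]))


def test_bad_proportion_rejected():
    with pytest.raises(SimulationError):
        EvolutionConfig(repeat_gene_fraction=1.5).validate()
    with pytest.raises(SimulationError):
        EvolutionConfig(indel_len_range=(4, 10)).validate()
    with pytest.raises(SimulationError, match="saturated"):
        EvolutionConfig(target_ks=3.5).validate()


def test_zero_divergence_yields_identical_descendants():
    cfg = small_cfg(target_ks=0.0)
    anc = generate_ancestor(cfg)
    ga, gb, og, truth = evolve_pair(anc, cfg)
    assert og is None
    for fa, fb in zip(ga.gene_order(), gb.gene_order()):
        assert fa.cds_seq == fb.cds_seq
    assert truth.events == []
    assert truth.lineage_counts("a") == (0, 0)
    assert truth.lineage_counts("b") == (0, 0)


def test_evolve_deterministic_under_seed():
    cfg = small_cfg(target_ks=0.01, include_outgroup=True)
    anc = generate_ancestor(cfg)
    out1 = evolve_pair(anc, cfg)
    out2 = evolve_pair(anc, cfg)
    for g1, g2 in zip(out1[:3], out2[:3]):
        assert genome_bytes(g1) == genome_bytes(g2)


def test_fragmentation_bookkeeping():
    cfg = small_cfg(fragmentation_events=2)
    anc = generate_ancestor(cfg)
    anc_by_tag = anc.features_by_tag()
    _, gb, _, truth = evolve_pair(anc, cfg)
    assert len(truth.fragmented_genes) == 2
    gb_by_tag = gb.features_by_tag()
    for tag, positions in truth.fragmented_genes.items():
        assert positions
        aa = translate_cds(gb_by_tag[tag].cds_seq)
        anc_aa = translate_cds(anc_by_tag[tag].cds_seq)
        assert "*" in aa[:-1]
        assert "*" not in anc_aa[:-1]
        for nt in positions:
            assert gb_by_tag[tag].cds_seq[nt - 1 : nt + 2] in STOP_CODONS


def test_deleted_genes_absent_from_genome_b():
    cfg = small_cfg(region_deletions=[(0, 2, 3)])
    anc = generate_ancestor(cfg)
    ga, gb, _, truth = evolve_pair(anc, cfg)
    assert len(truth.deleted_genes) == 21 - 2 - 3
    b_tags = {f.locus_tag for f in gb.features}
    assert not b_tags & set(truth.deleted_genes)
    assert set(truth.deleted_genes) <= {f.locus_tag for f in ga.features}
    # retained edges survive
    region = [f"ANC_{i:04d}" for i in range(10, 31)]
    assert set(region[:2] + region[-3:]) <= b_tags


def test_repeat_insertions_live_inside_surviving_phage_region():
    cfg = small_cfg(repeat_insertions=2, region_deletions=[(0, 8, 8)])
    anc = generate_ancestor(cfg)
    _, gb, _, truth = evolve_pair(anc, cfg)
    assert len(truth.inserted_repeats) == 2
    order = [f.locus_tag for f in gb.gene_order()]
    phage_tags = {f.locus_tag for f in gb.features if f.category == "phage"}
    for tag in truth.inserted_repeats:
        i = order.index(tag)
        assert gb.feature(tag).category == "repeat"
        assert order[i - 1] in phage_tags or order[i + 1] in phage_tags


def test_substitution_conservation_between_lineages():
    """Every event is in exactly one lineage ledger; pairwise SNP count is
    bounded by events_a + events_b and reduced at most 2 per overlap site."""
    cfg = small_cfg(target_ks=0.02, n_genes=80, phage_regions=[])
    anc = generate_ancestor(cfg)
    ga, gb, _, truth = evolve_pair(anc, cfg)
    ev_a = sum(truth.lineage_counts("a"))
    ev_b = sum(truth.lineage_counts("b"))
    assert ev_a + ev_b == len([e for e in truth.events if e["lineage"] in "ab"])
    snps = 0
    for fa, fb in zip(ga.gene_order(), gb.gene_order()):
        snps += sum(x != y for x, y in zip(fa.cds_seq, fb.cds_seq))
    assert ev_a + ev_b - 2 * truth.overlap_sites <= snps <= ev_a + ev_b


def test_pooled_omega_near_one_when_all_classes_neutral():
    """With omega = 1 everywhere and >1e4 realised substitutions, the
    pooled NG86 estimate lands in [0.9, 1.1] (seed-pinned)."""
    from wolbcomp.divergence import genome_wide_divergence, summary_from_alignment
    from wolbcomp.orthology import reciprocal_best_hits

    cfg = EvolutionConfig(
        n_genes=400, mean_gene_len=900, target_ks=0.05, seed=13,
        phage_regions=[], accessory_regions=[], region_deletions=[],
        fragmentation_events=0, repeat_insertions=0, indel_gene_fraction=0.0,
        omega_by_class={"default": 1.0},
    )
    anc = generate_ancestor(cfg)
    ga, gb, _, truth = evolve_pair(anc, cfg)
    total_events = sum(truth.lineage_counts("a")) + sum(truth.lineage_counts("b"))
    assert total_events >= 10_000
    m = reciprocal_best_hits(ga, gb)
    summaries = [summary_from_alignment(p) for p in m.pairs]
    S = sum(s.S for s in summaries)
    N = sum(s.N for s in summaries)
    Sd = sum(s.Sd for s in summaries)
    Nd = sum(s.Nd for s in summaries)
    omega = jukes_cantor(Nd / N) / jukes_cantor(Sd / S)
    assert 0.9 <= omega <= 1.1


def test_yaml_round_trip(tmp_path):
    cfg = small_cfg(target_ks=0.004, include_outgroup=True)
    cfg.to_yaml(tmp_path / "cfg.yaml")
    back = EvolutionConfig.from_yaml(tmp_path / "cfg.yaml")
    assert back == cfg
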