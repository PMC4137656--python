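"""Prophage labelling, region delineation, fragmentation, reduction report."""

import numpy as np
import pytest

from tests.conftest import make_genome, random_cds
from wolbcomp.orthology import reciprocal_best_hits, find_missing_genes
from wolbcomp.phage import (
    delineate_regions,
    detect_fragmentation,
    fragment_parent_map,
    label_phage_homologs,
    reduction_report,
)


def build_pair(categories, seed=0, scaffold_of=None, target_edit=None):
    """Two genomes with identical random genes of the given categories.

    ``target_edit`` optionally rewrites the target gene list (receives the
    list of (tag, cat, cds) and returns a new list).
    """
    rng = np.random.default_rng(seed)
    genes = [
        (f"R{i:03d}", cat, random_cds(rng, 70 + (i % 5) * 10))
        for i, cat in enumerate(categories)
    ]
    ga = make_genome(genes, "ref")
    tgenes = [(t.replace("R", "T"), c, s) for t, c, s in genes]
    if target_edit:
        tgenes = target_edit(tgenes)
    gb = make_genome(tgenes, "tgt", scaffold_of=scaffold_of)
    return ga, gb, genes


def flags_and_map(ga, gb):
    m = reciprocal_best_hits(ga, gb)
    phage_loci = {f.locus_tag for f in ga.features if f.category == "phage"}
    flags = label_phage_homologs(gb, phage_loci, m)
    return m, flags


def test_phage_flagging_and_repeat_distinction():
    cats = ["core", "phage", "phage", "repeat", "phage", "core"]
    ga, gb, _ = build_pair(cats)
    m, flags = flags_and_map(ga, gb)
    assert flags["T001"] == "phage"
    assert flags["T003"] == "repeat"
    assert flags["T000"] is None


def test_contiguous_run_single_region_gene_count():
    ga, gb, _ = build_pair(["core"] + ["phage"] * 21 + ["core"])
    m, flags = flags_and_map(ga, gb)
    regions = delineate_regions(gb, flags, m, reference=ga)
    assert len(regions) == 1
    assert regions[0].gene_count == 21
    assert regions[0].reference_block == ("R001", "R021")


def test_two_runs_separated_by_core_genes():
    cats = ["phage"] * 4 + ["core"] * 5 + ["phage"] * 3
    ga, gb, _ = build_pair(cats)
    m, flags = flags_and_map(ga, gb)
    regions = delineate_regions(gb, flags, m, gap_tolerance=2)
    assert [r.gene_count for r in regions] == [4, 3]


def test_repeat_interruption_within_tolerance_keeps_one_region():
    cats = ["phage"] * 3 + ["repeat", "repeat"] + ["phage"] * 3
    ga, gb, _ = build_pair(cats)
    m, flags = flags_and_map(ga, gb)
    regions = delineate_regions(gb, flags, m, gap_tolerance=2)
    assert len(regions) == 1
    assert regions[0].interrupting_loci == ["T003", "T004"]
    assert regions[0].gene_count == 6
    regions1 = delineate_regions(gb, flags, m, gap_tolerance=1)
    assert len(regions1) == 2


def test_region_crosses_scaffold_break():
    cats = ["phage"] * 6
    scaffold_of = {f"T{i:03d}": ("tgt_s1" if i < 3 else "tgt_s2") for i in range(6)}
    ga, gb, _ = build_pair(cats, scaffold_of=scaffold_of)
    m, flags = flags_and_map(ga, gb)
    regions = delineate_regions(gb, flags, m, reference=ga)
    assert len(regions) == 1
    assert regions[0].scaffold_ids == ["tgt_s1", "tgt_s2"]


def test_premature_stop_detection_positions():
    def edit(tgenes):
        out = []
        for tag, cat, cds in tgenes:
            if tag == "T001":
                # TAA at codon 50 (1-based) of a 300-codon gene
                cds = cds[: 49 * 3] + "TAA" + cds[49 * 3 + 3 :]
            out.append((tag, cat, cds))
        return out

    rng = np.random.default_rng(1)
    genes = [(f"R{i:03d}", "core", random_cds(rng, 300)) for i in range(3)]
    ga = make_genome(genes, "ref")
    tgenes = edit([(t.replace("R", "T"), c, s) for t, c, s in genes])
    gb = make_genome(tgenes, "tgt")
    m = reciprocal_best_hits(ga, gb)
    events = detect_fragmentation(m, gb, ga)
    stops = [e for e in events if e.cause == "premature_stop"]
    assert len(stops) == 1
    assert stops[0].fragments == ["T001"]
    assert stops[0].positions == [(148, 150)]


def test_identical_orfs_produce_no_events():
    ga, gb, _ = build_pair(["core"] * 4)
    m = reciprocal_best_hits(ga, gb)
    assert detect_fragmentation(m, gb, ga) == []


def test_split_annotation_two_fragments_of_one_reference_gene():
    rng = np.random.default_rng(6)
    big = random_cds(rng, 1030)
    other = random_cds(rng, 100)
    ga = make_genome([("R000", "phage", big), ("R001", "core", other)], "ref")
    # target annotates the gene as two disjoint pieces (codons 1-700, 710-1030)
    frag1 = big[: 700 * 3]
    frag2 = big[709 * 3 :]
    gb = make_genome(
        [("T000", "phage", frag1), ("T00X", "phage", frag2), ("T001", "core", other)],
        "tgt",
    )
    m = reciprocal_best_hits(ga, gb)
    events = detect_fragmentation(m, gb, ga)
    splits = [e for e in events if e.cause == "split_annotation"]
    assert len(splits) == 1
    assert splits[0].reference_locus == "R000"
    assert sorted(splits[0].fragments) == ["T000", "T00X"]
    parents = fragment_parent_map(events)
    assert parents["T00X"] == "R000"


def test_truncation_flagged_only_when_flush():
    rng = np.random.default_rng(9)
    full = random_cds(rng, 200)
    other = random_cds(rng, 90)
    ga = make_genome([("R000", "core", full), ("R001", "core", other)], "ref")
    truncated = full[: 120 * 3]
    gb = make_genome(
        [("T000", "core", truncated), ("T001", "core", other)], "tgt", spacer=400
    )
    m = reciprocal_best_hits(ga, gb)
    events = detect_fragmentation(m, gb, ga)
    assert [e.cause for e in events if e.reference_locus == "R000"] == ["truncation"]


def test_region_partition_invariant(rich_pair, rich_map):
    _, _, ga, gb, _, _ = rich_pair
    m = rich_map
    phage_loci = {f.locus_tag for f in ga.features if f.category == "phage"}
    flags = label_phage_homologs(gb, phage_loci, m)
    regions = delineate_regions(gb, flags, m, reference=ga)
    phage_flagged = [t for t, v in flags.items() if v == "phage"]
    member_counts = {}
    for r in regions:
        for t in r.members:
            member_counts[t] = member_counts.get(t, 0) + 1
    for t in phage_flagged:
        assert member_counts.get(t, 0) == 1


def test_region_boundaries_recover_truth(rich_pair, rich_map):
    """With gap_tolerance >= inserted repeats per region, detected regions
    equal the surviving truth regions exactly (plus listed interruptions)."""
    cfg, anc, ga, gb, _, truth = rich_pair
    m = rich_map
    phage_loci = {f.locus_tag for f in ga.features if f.category == "phage"}
    flags = label_phage_homologs(gb, phage_loci, m)
    regions = delineate_regions(gb, flags, m, gap_tolerance=2, reference=ga)
    deleted = set(truth.deleted_genes)
    expected = []
    for r in anc.metadata["regions"]:
        if r["kind"] != "phage":
            continue
        survivors = [t for t in r["loci"] if t not in deleted]
        if survivors:
            expected.append(survivors)
    got = [
        [t for t in r.members if t not in truth.inserted_repeats] for r in regions
    ]
    assert got == expected
    interrupting = [t for r in regions for t in r.interrupting_loci]
    assert set(interrupting) == set(truth.inserted_repeats)


def test_reduction_report_statuses_and_census(rich_pair, rich_map):
    _, _, ga, gb, _, truth = rich_pair
    m = rich_map
    missing = [(t, 0.0) for t in truth.deleted_genes]
    events = detect_fragmentation(m, gb, ga)
    phage_loci = {f.locus_tag for f in ga.features if f.category == "phage"}
    flags = label_phage_homologs(gb, phage_loci, m, fragment_parent_map(events))
    regions = delineate_regions(gb, flags, m, reference=ga)
    red = reduction_report(ga, gb, m, regions, events, missing)
    by_id = {r["region_id"]: r for r in red["regions"]}
    assert by_id["accessory_3"]["status"] == "absent"
    assert by_id["accessory_3"]["n_retained"] == 0
    assert by_id["accessory_3"]["flanking_loci"] is not None
    assert by_id["phage_0"]["status"] == "reduced"
    assert by_id["phage_2"]["status"] == "intact"
    # census: phage genes retained at ortholog level
    n_phage_deleted = len([t for t in truth.deleted_genes if t in phage_loci])
    assert red["phage_gene_census"] == len(phage_loci) - n_phage_deleted
    # lost span within one mean gene length of the truth
    true_span = sum(len(ga.features_by_tag()[t]) for t in truth.deleted_genes)
    assert abs(red["total_lost_span_bp"] - true_span) <= 1000


def test_no_deletions_means_all_intact():
    cats = ["phage"] * 5 + ["core"] * 3 + ["phage"] * 4
    ga, gb, _ = build_pair(cats)
    m = reciprocal_best_hits(ga, gb)
    phage_loci = {f.locus_tag for f in ga.features if f.category == "phage"}
    flags = label_phage_homologs(gb, phage_loci, m)
    regions = delineate_regions(gb, flags, m, reference=ga)
    red = reduction_report(ga, gb, m, regions, [], [])
    assert all(r["status"] == "intact" for r in red["regions"])
    assert red["phage_gene_census"] == len(phage_loci)
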