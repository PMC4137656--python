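"""Shared fixtures: hand-built mini genomes and simulated study fixtures.

The expensive simulated fixtures are session-scoped so the orthology,
phage, synteny and acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from wolbcomp.divergence import genome_wide_divergence, jukes_cantor, summary_from_alignment
from wolbcomp.genome import AnnotatedGenome, GeneFeature
from wolbcomp.orthology import reciprocal_best_hits
from wolbcomp.simulate import EvolutionConfig, evolve_pair, generate_ancestor


def make_genome(genes, genome_id="toy", spacer=30, seed=0, scaffold_of=None):
    """Build an AnnotatedGenome from (tag, category, cds) triples.

    ``scaffold_of`` optionally maps tag -> scaffold id; genes stay in list
    order within each scaffold. All genes are plus-strand with fixed-length
    random spacers, which keeps coordinates easy to reason about in tests.
    """
    rng = np.random.default_rng(seed)
    by_scaffold: dict[str, list] = {}
    for tag, cat, cds in genes:
        sid = (scaffold_of or {}).get(tag, f"{genome_id}_s1")
        by_scaffold.setdefault(sid, []).append((tag, cat, cds))
    scaffolds = []
    features = []
    for sid, items in by_scaffold.items():
        parts = []
        pos = 0
        for tag, cat, cds in items:
            sp = "".join(rng.choice(list("ACGT"), size=spacer))
            parts.append(sp)
            pos += spacer
            parts.append(cds)
            features.append(
                GeneFeature(tag, sid, pos, pos + len(cds), "+", "", cat, cds)
            )
            pos += len(cds)
        parts.append("".join(rng.choice(list("ACGT"), size=spacer)))
        scaffolds.append((sid, "".join(parts)))
    g = AnnotatedGenome(genome_id, scaffolds, features)
    g.validate()
    return g


def random_cds(rng, n_codons):
    """A stop-free CDS: ATG + random sense codons + TAA."""
    from wolbcomp._codons import SENSE_CODONS

    body = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + "TAA"


RICH_CONFIG = dict(
    n_genes=200,
    seed=3,
    phage_regions=[(30, 12), (100, 8), (140, 5)],
    accessory_regions=[(170, 6)],
    region_deletions=[(0, 7, 0), (1, 0, 3), (3, 0, 0)],
    fragmentation_events=3,
    repeat_insertions=2,
    include_outgroup=True,
)


@pytest.fixture(scope="session")
def rich_pair():
    """A fully featured simulated comparison: deletions, fragmentation,
    repeat insertions, outgroup — the study's structure at fixture scale."""
    cfg = EvolutionConfig(**RICH_CONFIG)
    anc = generate_ancestor(cfg)
    ga, gb, og, truth = evolve_pair(anc, cfg)
    return cfg, anc, ga, gb, og, truth


@pytest.fixture(scope="session")
def rich_map(rich_pair):
    _, _, ga, gb, _, _ = rich_pair
    return reciprocal_best_hits(ga, gb)


OMEGA_CLASSES = {"core": 0.2, "hypothetical": 1.0, "phage": 4.0}
SWEEP_SEEDS = list(range(20))
SWEEP_TARGET_KS = 0.0031


def _sweep_config(seed):
    return EvolutionConfig(
        n_genes=999,
        target_ks=SWEEP_TARGET_KS,
        seed=seed,
        phage_regions=[(0, 333)],
        accessory_regions=[],
        repeat_gene_fraction=0.0,
        hypothetical_fraction=0.5,
        region_deletions=[],
        fragmentation_events=0,
        repeat_insertions=0,
        indel_gene_fraction=0.0,
        omega_by_class=dict(OMEGA_CLASSES),
    )


@pytest.fixture(scope="session")
def omega_sweep():
    """20-seed parameter-recovery sweep: 999 genes, Ks 0.0031, three omega
    classes. Returns per-seed pooled statistics plus suite-pooled totals."""
    runs = []
    totals = {"S": 0.0, "Sd": 0.0}
    class_totals = {c: {"S": 0.0, "N": 0.0, "Sd": 0.0, "Nd": 0.0} for c in OMEGA_CLASSES}
    for seed in SWEEP_SEEDS:
        cfg = _sweep_config(seed)
        anc = generate_ancestor(cfg)
        ga, gb, _, truth = evolve_pair(anc, cfg)
        m = reciprocal_best_hits(ga, gb)
        summaries = [summary_from_alignment(p) for p in m.pairs]
        gw = genome_wide_divergence(summaries)
        cats = {f.locus_tag: f.category for f in ga.features}
        per_class = {}
        for cat in OMEGA_CLASSES:
            ss = [s for s in summaries if cats[s.locus_a] == cat]
            S = sum(s.S for s in ss)
            N = sum(s.N for s in ss)
            Sd = sum(s.Sd for s in ss)
            Nd = sum(s.Nd for s in ss)
            per_class[cat] = jukes_cantor(Nd / N) / jukes_cantor(Sd / S)
            for k, v in (("S", S), ("N", N), ("Sd", Sd), ("Nd", Nd)):
                class_totals[cat][k] += v
        totals["S"] += sum(s.S for s in summaries)
        totals["Sd"] += sum(s.Sd for s in summaries)
        runs.append(
            {
                "seed": seed,
                "n_pairs": m.n_pairs,
                "ks": gw.ks_concat,
                "omega_by_class": per_class,
            }
        )
    pooled_ks = jukes_cantor(totals["Sd"] / totals["S"])
    pooled_omega = {
        c: jukes_cantor(t["Nd"] / t["N"]) / jukes_cantor(t["Sd"] / t["S"])
        for c, t in class_totals.items()
    }
    p = totals["Sd"] / totals["S"]
    se = float(np.sqrt(p * (1 - p) / totals["S"]))
    return {
        "runs": runs,
        "pooled_ks": pooled_ks,
        "pooled_omega": pooled_omega,
        "pooled_se": se,
        "target_ks": SWEEP_TARGET_KS,
        "omega_targets": dict(OMEGA_CLASSES),
    }
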