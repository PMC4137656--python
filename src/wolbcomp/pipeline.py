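"""End-to-end pipeline: (simulate | load) -> orthologs -> divergence ->
selection screen -> phage inventory -> synteny -> consolidated report.

Every stage's outputs are written to the output directory as plain text
(TSV/JSON/GFF3/FASTA); the consolidated ``report.json`` also echoes every
effective parameter so a run is self-describing and reproducible
byte-for-byte under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import divergence as dv
from . import phage as ph
from . import screen as sc
from . import synteny as sy
from .align import Scoring
from .genome import AnnotatedGenome, genome_summary, load_genome, write_genome
from .orthology import OrthologMap, find_missing_genes, reciprocal_best_hits
from .simulate import EvolutionConfig, evolve_pair, generate_ancestor

log = logging.getLogger("wolbcomp")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    # exactly one of (reference_fasta/... paths) or (simulation) must be set
    reference_fasta: str | None = None
    reference_annotation: str | None = None
    target_fasta: str | None = None
    target_annotation: str | None = None
    outgroup_fasta: str | None = None
    outgroup_annotation: str | None = None
    simulation: dict | None = None

    clock_rate: float = 0.9  # percent synonymous divergence per Myr
    identity_threshold: float = 98.0
    omega_threshold: float = 1.0
    min_identity: float = 60.0
    min_coverage: float = 0.5
    min_codons: int = 30
    gap_tolerance: int = 2
    displaced_distance: int = 50
    scoring: dict = field(
        default_factory=lambda: {
            "match": 2, "mismatch": -3, "gap_open": -5, "gap_extend": -2
        }
    )
    weighted_mean_omega: bool = False
    seed: int = 0

    def validate(self) -> None:
        have_paths = self.reference_fasta is not None
        have_sim = self.simulation is not None
        if have_paths == have_sim:
            raise PipelineError(
                "exactly one of genome paths or a simulation block required"
            )
        if have_paths and not (
            self.reference_annotation and self.target_fasta and self.target_annotation
        ):
            raise PipelineError("reference and target FASTA + annotation required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (logging.StreamHandler(sys.stderr),
              logging.FileHandler(outdir / "pipeline.log")):
        h.setFormatter(fmt)
        log.addHandler(h)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception:
                log.exception("stage %s: FAILED", name)
                raise PipelineError(f"stage {name} failed")
            log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            fh.write("\t".join("" if v is None else str(v) for v in r) + "\n")


def write_ortholog_tsv(map_: OrthologMap, path: Path) -> None:
    rows = [
        [
            p.locus_a,
            p.locus_b,
            f"{p.identity_pct:.1f}",
            p.score,
            f"{p.coverage:.3f}",
            "; ".join(
                f"{e.side}:+{e.length}@{e.position}" for e in p.indel_events
            ),
        ]
        for p in map_.pairs
    ]
    _write_tsv(
        path,
        ["locus_a", "locus_b", "identity_pct", "score", "coverage", "indels"],
        rows,
    )


def write_divergence_tsv(summaries: list[dv.SubstitutionSummary], path: Path) -> None:
    rows = []
    for s in summaries:
        rows.append(
            [
                s.locus_a, s.locus_b, s.codons_compared,
                f"{s.S:.2f}", f"{s.N:.2f}", f"{s.Sd:.2f}", f"{s.Nd:.2f}",
                "" if s.Ks is None else f"{s.Ks:.6f}",
                "" if s.Ka is None else f"{s.Ka:.6f}",
                "-" if s.omega is None else f"{s.omega:.3f}",
                s.snp_count, s.syn_snp_count, s.dropped_codons,
                s.excluded_reason or "",
            ]
        )
    _write_tsv(
        path,
        ["locus_a", "locus_b", "codons", "S", "N", "Sd", "Nd", "Ks", "Ka",
         "omega", "snps", "syn_snps", "dropped_codons", "excluded"],
        rows,
    )


@_stage("genomes")
def _obtain_genomes(cfg: PipelineConfig, outdir: Path):
    truth = None
    if cfg.simulation is not None:
        sim_raw = dict(cfg.simulation)
        sim_raw.setdefault("seed", cfg.seed)
        sim_raw["phage_regions"] = [tuple(x) for x in sim_raw.get("phage_regions", EvolutionConfig().phage_regions)]
        sim_raw["accessory_regions"] = [tuple(x) for x in sim_raw.get("accessory_regions", EvolutionConfig().accessory_regions)]
        sim_raw["region_deletions"] = [tuple(x) for x in sim_raw.get("region_deletions", EvolutionConfig().region_deletions)]
        if "indel_len_range" in sim_raw:
            sim_raw["indel_len_range"] = tuple(sim_raw["indel_len_range"])
        sim = EvolutionConfig(**sim_raw)
        ancestor = generate_ancestor(sim)
        ref, target, outgroup, truth = evolve_pair(ancestor, sim)
        for g, stem in ((ref, "reference"), (target, "target")) + (
            ((outgroup, "outgroup"),) if outgroup else ()
        ):
            write_genome(g, outdir / f"{stem}.fasta", outdir / f"{stem}.gff3")
        truth.to_json(outdir / "truth.json")
        sim.to_yaml(outdir / "simulation.yaml")
    else:
        ref = load_genome(cfg.reference_fasta, cfg.reference_annotation, "reference")
        target = load_genome(cfg.target_fasta, cfg.target_annotation, "target")
        outgroup = (
            load_genome(cfg.outgroup_fasta, cfg.outgroup_annotation, "outgroup")
            if cfg.outgroup_fasta
            else None
        )
    return ref, target, outgroup, truth


def run_pipeline(cfg: PipelineConfig, outdir: str | Path, force: bool = False) -> dict:
    """Execute all stages; returns the consolidated report dict.

    Writes per-stage TSV/JSON artifacts plus ``report.json``. Identical
    config + seed reproduce identical outputs; ``force`` merely allows
    writing into a non-empty directory.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not force and (outdir / "report.json").exists():
        raise PipelineError(f"{outdir} already contains a report (use force)")
    _setup_logging(outdir)
    scoring = Scoring(**cfg.scoring)

    ref, target, outgroup, truth = _obtain_genomes(cfg, outdir)

    report: dict = {
        "parameters": {
            **{
                k: v
                for k, v in dataclasses.asdict(cfg).items()
                if not k.startswith(("reference_", "target_", "outgroup_"))
            },
        },
        "genomes": {
            "reference": genome_summary(ref),
            "target": genome_summary(target),
        },
    }

    map_ = _stage("orthologs")(reciprocal_best_hits)(
        ref, target, cfg.min_identity, cfg.min_coverage, scoring
    )
    write_ortholog_tsv(map_, outdir / "orthologs.tsv")
    report["orthologs"] = {
        "n_pairs": map_.n_pairs,
        "n_unpaired_reference": len(map_.unpaired_a),
        "n_unpaired_target": len(map_.unpaired_b),
        "n_ambiguous": len(map_.ambiguous_a) + len(map_.ambiguous_b),
        "pct_pairs_ge_99_identity": round(
            100.0 * map_.identity_fraction_at_least(99.0), 1
        ),
    }

    @_stage("divergence")
    def _divergence():
        summaries = [
            dv.summary_from_alignment(p, cfg.min_codons) for p in map_.pairs
        ]
        gw = dv.genome_wide_divergence(summaries, cfg.weighted_mean_omega)
        t = dv.estimate_divergence_time(gw.ks_percent, dv.ClockModel(cfg.clock_rate))
        return summaries, gw, t

    summaries, gw, dtime = _divergence()
    write_divergence_tsv(summaries, outdir / "per_gene_divergence.tsv")
    report["divergence"] = {
        "ks_percent": round(gw.ks_percent, 3),
        "ka_percent": round(gw.ka_percent, 3),
        "snp_total": gw.snp_total,
        "syn_snp_total": gw.syn_snp_total,
        "syn_snp_percent": round(gw.syn_snp_percent, 1),
        "mean_gene_omega": (
            None if gw.mean_gene_omega is None else round(gw.mean_gene_omega, 3)
        ),
        "n_genes_used": gw.n_genes_used,
        "n_excluded": gw.n_excluded,
        "divergence_time_years_raw": dtime.years_raw,
        "divergence_time_years": dtime.years_rounded,
    }

    @_stage("screen")
    def _screen():
        scfg = sc.ScreenConfig(cfg.identity_threshold, cfg.omega_threshold)
        table = sc.screen_divergent_genes(map_, summaries, scfg)
        flagged, undefined = sc.flag_positive_selection(summaries, scfg)
        polar = []
        if outgroup is not None and flagged:
            og_map = reciprocal_best_hits(
                ref, outgroup, cfg.min_identity, cfg.min_coverage, scoring
            )
            og_by_a = og_map.pair_by_a()
            ref_by_tag = ref.features_by_tag()
            tgt_by_a = map_.pair_by_a()
            og_by_tag = outgroup.features_by_tag()
            tgt_by_tag = target.features_by_tag()
            for tag in flagged:
                og_pair = og_by_a.get(tag)
                pair = tgt_by_a[tag]
                res = sc.polarize_with_outgroup(
                    ref_by_tag[tag].cds_seq,
                    tgt_by_tag[pair.locus_b].cds_seq,
                    og_by_tag[og_pair.locus_b].cds_seq if og_pair else None,
                    tag, pair.locus_b,
                    og_pair.locus_b if og_pair else "missing",
                    scoring,
                )
                polar.append(res)
        return table, flagged, undefined, polar

    table, flagged, undefined, polar = _screen()
    table.drop(columns=["omega"]).to_csv(
        outdir / "screened_genes.tsv", sep="\t", index=False
    )
    _write_tsv(
        outdir / "polarization.tsv",
        ["locus_a", "locus_b", "outgroup", "diverged", "matches_a", "matches_b",
         "unpolarizable", "derived_lineage"],
        [
            [
                r.locus_a, r.locus_b, r.locus_outgroup, r.diverged_sites,
                r.matches_outgroup_a, r.matches_outgroup_b, r.unpolarizable,
                r.derived_lineage or "",
            ]
            for r in polar
        ],
    )
    report["screen"] = {
        "n_divergent_pairs": int(len(table)),
        "divergent_pairs": table.drop(columns=["omega"]).to_dict("records"),
        "positive_selection_flags": flagged,
        "undefined_omega": undefined,
        "polarization": [
            {
                "locus_a": r.locus_a,
                "locus_b": r.locus_b,
                "diverged_sites": r.diverged_sites,
                "matches_outgroup_a": r.matches_outgroup_a,
                "matches_outgroup_b": r.matches_outgroup_b,
                "unpolarizable": r.unpolarizable,
                "derived_lineage": r.derived_lineage,
            }
            for r in polar
        ],
    }

    @_stage("phage")
    def _phage():
        missing = find_missing_genes(
            ref, target, cfg.min_identity, cfg.min_coverage, scoring
        )
        events = ph.detect_fragmentation(map_, target, ref, scoring=scoring)
        parents = ph.fragment_parent_map(events)
        phage_loci = {f.locus_tag for f in ref.features if f.category == "phage"}
        flags = ph.label_phage_homologs(target, phage_loci, map_, parents)
        regions = ph.delineate_regions(
            target, flags, map_, cfg.gap_tolerance, parents, ref
        )
        red = ph.reduction_report(ref, target, map_, regions, events, missing)
        return missing, events, regions, red

    missing, events, regions, red = _phage()
    _write_tsv(
        outdir / "missing_genes.tsv",
        ["locus", "best_identity"],
        [[t, i] for t, i in missing],
    )
    _write_tsv(
        outdir / "phage_regions.tsv",
        ["region_id", "gene_count", "span_bp", "members", "interrupting",
         "scaffolds", "reference_block"],
        [
            [
                r.region_id, r.gene_count, r.span_bp, ",".join(r.members),
                ",".join(r.interrupting_loci), ",".join(r.scaffold_ids),
                "-".join(r.reference_block) if r.reference_block else "",
            ]
            for r in regions
        ],
    )
    with open(outdir / "reduction_report.json", "w") as fh:
        json.dump(red, fh, indent=1, sort_keys=True)
    report["phage"] = {
        "n_missing_reference_genes": len(missing),
        "missing_reference_genes": [t for t, _ in missing],
        "n_target_regions": len(regions),
        "regions": [
            {
                "region_id": r.region_id,
                "gene_count": r.gene_count,
                "span_bp": r.span_bp,
                "interrupting_loci": r.interrupting_loci,
            }
            for r in regions
        ],
        "fragmentation_events": [
            {
                "reference_locus": e.reference_locus,
                "fragments": e.fragments,
                "cause": e.cause,
                "positions": e.positions,
            }
            for e in events
        ],
        "reduction": red,
    }

    @_stage("synteny")
    def _synteny():
        order = sy.order_scaffolds_by_reference(target, map_, ref)
        blocks = sy.synteny_blocks(
            map_, target, ref, order, displaced_distance=cfg.displaced_distance
        )
        sy.plot_synteny(target, map_, ref, str(outdir / "synteny.png"), order)
        return order, blocks

    order, blocks = _synteny()
    _write_tsv(
        outdir / "synteny_blocks.tsv",
        ["block_id", "scaffold", "n_pairs", "ref_start", "ref_end",
         "target_start", "target_end", "orientation", "displaced"],
        [
            [
                b.block_id, b.scaffold_id, len(b.pairs), *b.ref_interval,
                *b.target_interval, b.orientation, b.displaced,
            ]
            for b in blocks
        ],
    )
    report["synteny"] = {
        "scaffold_order": order,
        "n_blocks": len(blocks),
        "n_displaced": sum(b.displaced for b in blocks),
        "blocks": [
            {
                "block_id": b.block_id,
                "n_pairs": len(b.pairs),
                "ref_interval": b.ref_interval,
                "orientation": b.orientation,
                "displaced": b.displaced,
            }
            for b in blocks
        ],
    }

    if truth is not None:
        report["truth_comparison"] = {
            "true_deleted": len(truth.deleted_genes),
            "detected_missing": len(missing),
            "missing_exactly_recovered": sorted(t for t, _ in missing)
            == truth.deleted_genes,
            "true_fragmented": sorted(truth.fragmented_genes),
            "detected_premature_stop": sorted(
                e.fragments[0] for e in events if e.cause == "premature_stop"
            ),
        }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    log.info("pipeline complete: %s", outdir)
    return report
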