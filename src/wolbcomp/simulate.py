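"""Ground-truth genome-evolution simulator.

Builds an ancestral endosymbiont-like genome (~1.1 Mb, ~1,200 CDS, AT-rich,
contiguous prophage and accessory gene regions, scattered repeat-class
genes) and evolves two descendants — optionally plus an earlier-branching
outgroup — under a codon-aware substitution model with configurable per-gene
Ka/Ks, in-frame indels, deletion of contiguous regions, premature-stop gene
fragmentation, and repeat-gene insertions into surviving prophage regions.
Every event is recorded in a TruthTable so downstream modules can be scored
against known truth.

Substitutions are placed site-category-aware: a synonymous event is drawn
among the synonymous single-nucleotide codon changes available in the gene
(weighted by each codon's synonymous-neighbour count), a nonsynonymous event
among the nonsynonymous non-stop changes, so the realised NG86 Ka/Ks is
controlled by construction. The raw substitution density is the inverse
Jukes–Cantor transform of ``target_ks``, split equally over the two
descendant branches.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from ._codons import (
    NONSYN_NEIGHBORS,
    SENSE_CODONS,
    STOP_CODONS,
    SYN_NEIGHBORS,
    revcomp,
)
from .genome import AnnotatedGenome, GeneFeature

STOPS = ("TAA", "TAG", "TGA")


class SimulationError(ValueError):
    pass


@dataclass
class EvolutionConfig:
    """Study conditions for one simulated genome pair.

    Defaults emulate a wMel/wRec-scale comparison: ~1,200 genes of mean
    length ~750 bp at 35% GC, two large prophage regions plus a small one
    and an eight-gene accessory island, ~6% repeat-class genes, 0.31%
    synonymous divergence with mean omega ~0.7, sparse in-frame indels,
    deletion of most prophage DNA (21 and 7 genes surviving, the accessory
    island lost outright), a few premature-stop fragmentations, and repeat
    insertions inside surviving prophage regions.
    """

    n_genes: int = 1200
    mean_gene_len: int = 750
    intergenic_mean: int = 150
    gc_content: float = 0.35
    n_scaffolds: int = 1
    phage_regions: list[tuple[int, int]] = field(
        default_factory=lambda: [(150, 40), (600, 24), (700, 5)]
    )
    accessory_regions: list[tuple[int, int]] = field(
        default_factory=lambda: [(900, 8)]
    )
    repeat_gene_fraction: float = 0.06
    hypothetical_fraction: float = 0.25
    target_ks: float = 0.0031
    omega_by_class: dict = field(default_factory=lambda: {"default": 0.7})
    indel_gene_fraction: float = 0.008
    indel_len_range: tuple[int, int] = (3, 189)
    region_deletions: list[tuple[int, int, int]] = field(
        default_factory=lambda: [(0, 21, 0), (1, 0, 7), (3, 0, 0)]
    )
    fragmentation_events: int = 3
    repeat_insertions: int = 2
    include_outgroup: bool = False
    outgroup_scale: float = 3.0
    modified_lineage: str = "b"
    seed: int = 0

    def validate(self) -> None:
        for name in ("repeat_gene_fraction", "hypothetical_fraction",
                     "indel_gene_fraction", "gc_content"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{name} must be in [0, 1]")
        if self.target_ks < 0:
            raise SimulationError("target_ks must be >= 0")
        if self.target_ks >= 3.0:
            raise SimulationError(
                "target_ks implies a saturated synonymous proportion "
                "(pS >= 0.75); the JC correction is undefined there"
            )
        for lo, hi in [self.indel_len_range]:
            if lo % 3 or hi % 3 or lo < 3 or hi < lo:
                raise SimulationError("indel lengths must be multiples of 3")
        if self.n_genes < 1 or self.mean_gene_len < 150:
            raise SimulationError("n_genes >= 1 and mean_gene_len >= 150 required")
        if self.modified_lineage not in ("a", "b"):
            raise SimulationError("modified_lineage must be 'a' or 'b'")
        spans = []
        for start, count in list(self.phage_regions) + list(self.accessory_regions):
            if start < 0 or count < 1 or start + count > self.n_genes:
                raise SimulationError("region outside gene range")
            spans.append((start, start + count))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise SimulationError("overlapping regions")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "EvolutionConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["phage_regions"] = [tuple(x) for x in raw.get("phage_regions", [])]
        raw["accessory_regions"] = [
            tuple(x) for x in raw.get("accessory_regions", [])
        ]
        raw["region_deletions"] = [
            tuple(x) for x in raw.get("region_deletions", [])
        ]
        raw["indel_len_range"] = tuple(raw.get("indel_len_range", (3, 189)))
        return cls(**raw)


@dataclass
class TruthTable:
    """Everything the simulator did, for recovery scoring."""

    target_ks: float
    omega_by_gene: dict[str, float] = field(default_factory=dict)
    counts: dict[str, dict[str, dict[str, int]]] = field(default_factory=dict)
    events: list[dict] = field(default_factory=list)
    overlap_sites: int = 0
    deleted_genes: list[str] = field(default_factory=list)
    fragmented_genes: dict[str, list[int]] = field(default_factory=dict)
    inserted_repeats: list[str] = field(default_factory=list)
    indel_genes: dict[str, int] = field(default_factory=dict)

    def lineage_counts(self, lineage: str) -> tuple[int, int]:
        syn = nonsyn = 0
        for per_gene in self.counts.values():
            c = per_gene.get(lineage, {})
            syn += c.get("syn", 0)
            nonsyn += c.get("nonsyn", 0)
        return syn, nonsyn

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            return cls(**json.load(fh))


# ----------------------------------------------------------------- internals


@dataclass
class _SimGene:
    tag: str
    category: str
    strand: str
    cds: str


def _nt_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=_nt_probs(gc))])


def _expected_codon_gc(gc: float) -> float:
    """Expected GC fraction of a sense codon drawn at base composition gc
    (stop codons rejected)."""
    p = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
    tot = wgc = 0.0
    for c in SENSE_CODONS:
        w = p[c[0]] * p[c[1]] * p[c[2]]
        tot += w
        wgc += w * sum(ch in "GC" for ch in c) / 3.0
    return wgc / tot


_GC_ADJUST_CACHE: dict[float, float] = {}


def _codon_gc(gc_target: float) -> float:
    """Base composition to feed the codon sampler so that accepted (sense)
    codons average ``gc_target`` GC — rejecting the AT-rich stop codons
    otherwise drags coding GC above the configured value."""
    if gc_target not in _GC_ADJUST_CACHE:
        lo, hi = 1e-3, 1 - 1e-3
        for _ in range(60):
            mid = (lo + hi) / 2
            if _expected_codon_gc(mid) < gc_target:
                lo = mid
            else:
                hi = mid
        _GC_ADJUST_CACHE[gc_target] = (lo + hi) / 2
    return _GC_ADJUST_CACHE[gc_target]


def _random_codons(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    """n sense codons averaging the genome's GC (stops rejected, composition
    compensated)."""
    gc_eff = _codon_gc(gc)
    out: list[str] = []
    while len(out) < n:
        chunk = _random_seq(rng, 3 * (n - len(out) + 8), gc_eff)
        for i in range(0, len(chunk) - 2, 3):
            c = chunk[i : i + 3]
            if c not in STOPS:
                out.append(c)
                if len(out) == n:
                    break
    return out


def _gene_regions(cfg: EvolutionConfig) -> list[dict]:
    regions = []
    for i, (start, count) in enumerate(cfg.phage_regions):
        regions.append(
            {"kind": "phage", "start": start, "count": count, "index": len(regions)}
        )
    for start, count in cfg.accessory_regions:
        regions.append(
            {
                "kind": "accessory",
                "start": start,
                "count": count,
                "index": len(regions),
            }
        )
    return regions


def generate_ancestor(cfg: EvolutionConfig) -> AnnotatedGenome:
    """Build the ancestral genome: ATG-started, stop-terminated CDS of random
    sense codons, prophage/accessory regions contiguous, repeat genes
    scattered outside them. Deterministic under ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0])
    regions = _gene_regions(cfg)
    in_region: dict[int, str] = {}
    for r in regions:
        for g in range(r["start"], r["start"] + r["count"]):
            in_region[g] = r["kind"]

    genes: list[_SimGene] = []
    lo = max(120, int(cfg.mean_gene_len * 0.4) // 3 * 3)
    hi = max(lo + 3, int(cfg.mean_gene_len * 1.6) // 3 * 3)
    for idx in range(cfg.n_genes):
        ncod = int(rng.integers(lo // 3, hi // 3 + 1))
        body = _random_codons(rng, ncod - 2, cfg.gc_content)
        cds = "ATG" + "".join(body) + STOPS[int(rng.integers(0, 3))]
        kind = in_region.get(idx)
        if kind == "phage":
            cat = "phage"
        elif kind == "accessory":
            cat = "hypothetical"
        else:
            u = rng.random()
            if u < cfg.repeat_gene_fraction:
                cat = "repeat"
            elif u < cfg.repeat_gene_fraction + cfg.hypothetical_fraction:
                cat = "hypothetical"
            else:
                cat = "core"
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(_SimGene(f"ANC_{idx:04d}", cat, strand, cds))

    spacers = [
        _random_seq(rng, int(rng.integers(20, 2 * cfg.intergenic_mean - 19)),
                    cfg.gc_content)
        for _ in range(cfg.n_genes + 1)
    ]
    g = _render(genes, spacers, "ancestor", cfg.n_scaffolds)
    g.metadata["regions"] = [
        {
            "region_id": f"{r['kind']}_{r['index']}",
            "kind": r["kind"],
            "loci": [genes[i].tag for i in range(r["start"], r["start"] + r["count"])],
        }
        for r in regions
    ]
    g.metadata["config_seed"] = cfg.seed
    return g


def _render(
    genes: list[_SimGene], spacers: list[str], genome_id: str, n_scaffolds: int
) -> AnnotatedGenome:
    assert len(spacers) == len(genes) + 1
    chunks = np.array_split(np.arange(len(genes)), max(1, n_scaffolds))
    scaffolds = []
    features = []
    for si, chunk in enumerate(chunks):
        sid = f"{genome_id}_s{si + 1}"
        seq_parts = []
        pos = 0
        for k, gi in enumerate(chunk):
            gene = genes[gi]
            spacer = spacers[gi] if k > 0 or si == 0 else spacers[gi]
            seq_parts.append(spacer)
            pos += len(spacer)
            embedded = gene.cds if gene.strand == "+" else revcomp(gene.cds)
            features.append(
                GeneFeature(
                    locus_tag=gene.tag,
                    scaffold_id=sid,
                    start=pos,
                    end=pos + len(gene.cds),
                    strand=gene.strand,
                    product=f"{gene.category} protein",
                    category=gene.category,
                    cds_seq=gene.cds,
                )
            )
            seq_parts.append(embedded)
            pos += len(gene.cds)
        if len(chunk):
            tail = spacers[chunk[-1] + 1] if si == len(chunks) - 1 else ""
            seq_parts.append(tail)
        scaffolds.append((sid, "".join(seq_parts)))
    g = AnnotatedGenome(genome_id=genome_id, scaffolds=scaffolds, features=features)
    g.validate()
    return g


def _units_from_genome(g: AnnotatedGenome) -> tuple[list[_SimGene], list[str]]:
    genes = []
    spacers = []
    order = g.gene_order()
    prev_end = 0
    prev_sid = None
    for f in order:
        if f.scaffold_id != prev_sid:
            prev_end = 0
            prev_sid = f.scaffold_id
        spacers.append(g.scaffold_seq(f.scaffold_id)[prev_end : f.start])
        genes.append(_SimGene(f.locus_tag, f.category, f.strand, f.cds_seq))
        prev_end = f.end
    if order:
        last = order[-1]
        spacers.append(g.scaffold_seq(last.scaffold_id)[last.end :])
    return genes, spacers


def _omega_for(cfg: EvolutionConfig, category: str) -> float:
    m = cfg.omega_by_class
    return float(m.get(category, m.get("default", 1.0)))


def _mutate_gene(
    gene: _SimGene,
    p_branch: float,
    omega: float,
    rng: np.random.Generator,
    lineage: str,
    truth: TruthTable,
) -> None:
    codons = [gene.cds[i : i + 3] for i in range(0, len(gene.cds), 3)]
    mutable = list(range(1, len(codons) - 1))  # keep ATG start and final stop
    syn_w = sum(len(SYN_NEIGHBORS[codons[i]]) for i in mutable) / 3.0
    non_w = sum(len(NONSYN_NEIGHBORS[codons[i]]) for i in mutable) / 3.0
    n_syn = rng.poisson(p_branch * syn_w)
    n_non = rng.poisson(p_branch * omega * non_w)
    cnt = truth.counts.setdefault(gene.tag, {}).setdefault(
        lineage, {"syn": 0, "nonsyn": 0}
    )
    for kind, n_events in (("syn", n_syn), ("nonsyn", n_non)):
        table = SYN_NEIGHBORS if kind == "syn" else NONSYN_NEIGHBORS
        for _ in range(n_events):
            weights = np.array(
                [len(table[codons[i]]) for i in mutable], dtype=float
            )
            tot = weights.sum()
            if tot == 0:
                break
            ci = mutable[int(rng.choice(len(mutable), p=weights / tot))]
            options = table[codons[ci]]
            pos, alt = options[int(rng.integers(0, len(options)))]
            truth.events.append(
                {
                    "lineage": lineage,
                    "locus": gene.tag,
                    "codon": ci,
                    "pos": pos,
                    "ref": codons[ci][pos],
                    "alt": alt[pos],
                    "syn": kind == "syn",
                }
            )
            codons[ci] = alt
            cnt[kind] += 1
    gene.cds = "".join(codons)


def evolve_pair(
    ancestor: AnnotatedGenome, cfg: EvolutionConfig
) -> tuple[AnnotatedGenome, AnnotatedGenome, AnnotatedGenome | None, TruthTable]:
    """Evolve two descendants (and optionally an outgroup) from an ancestor.

    RNG draw order is fixed and documented: outgroup substitutions, lineage-a
    substitutions, lineage-b substitutions, indels, fragmentations, repeat
    insertions (region deletions are deterministic given the config). The
    structural modifications — indels, region deletions, fragmentation,
    repeat insertions — are applied to ``cfg.modified_lineage`` (default b).
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    truth = TruthTable(target_ks=cfg.target_ks)

    # raw substitution density whose JC correction equals target_ks
    p_pair = 0.75 * (1.0 - math.exp(-4.0 * cfg.target_ks / 3.0))
    if p_pair >= 0.75:
        raise SimulationError("target_ks saturated")
    p_branch = p_pair / 2.0

    base_genes, spacers = _units_from_genome(ancestor)
    for g in base_genes:
        truth.omega_by_gene[g.tag] = _omega_for(cfg, g.category)

    lineages: dict[str, list[_SimGene]] = {}
    names = (["og"] if cfg.include_outgroup else []) + ["a", "b"]
    for name in names:
        genes = [dataclasses.replace(g) for g in base_genes]
        scale = cfg.outgroup_scale if name == "og" else 1.0
        if cfg.target_ks > 0:
            for gene in genes:
                _mutate_gene(
                    gene, p_branch * scale, truth.omega_by_gene[gene.tag],
                    rng, name, truth,
                )
        lineages[name] = genes

    # back-mutation / same-site overlap between the two descendant branches
    seen: dict[tuple, set] = {}
    for ev in truth.events:
        if ev["lineage"] in ("a", "b"):
            seen.setdefault((ev["locus"], ev["codon"], ev["pos"]), set()).add(
                ev["lineage"]
            )
    truth.overlap_sites = sum(1 for v in seen.values() if len(v) > 1)

    mod = cfg.modified_lineage
    genes_mod = lineages[mod]
    tag_index = {g.tag: i for i, g in enumerate(genes_mod)}
    regions = _gene_regions(cfg)

    deleted: set[str] = set()
    for rd in cfg.region_deletions:
        ridx, keep_left, keep_right = rd
        if ridx >= len(regions):
            raise SimulationError(f"region index {ridx} out of range")
        r = regions[ridx]
        loci = [base_genes[i].tag for i in range(r["start"], r["start"] + r["count"])]
        doomed = loci[keep_left : len(loci) - keep_right if keep_right else None]
        deleted.update(doomed)
    truth.deleted_genes = sorted(deleted)

    survivors = [g for g in genes_mod if g.tag not in deleted]

    # in-frame indels in a minority of surviving genes
    n_indel = int(round(cfg.indel_gene_fraction * len(survivors)))
    if n_indel:
        idxs = rng.choice(len(survivors), size=n_indel, replace=False)
        lo, hi = cfg.indel_len_range
        for si in sorted(int(i) for i in idxs):
            gene = survivors[si]
            length = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
            insertion = rng.random() < 0.5
            codons = [gene.cds[i : i + 3] for i in range(0, len(gene.cds), 3)]
            if insertion:
                at = int(rng.integers(1, len(codons) - 1))
                new = _random_codons(rng, length // 3, cfg.gc_content)
                codons[at:at] = new
                truth.indel_genes[gene.tag] = truth.indel_genes.get(gene.tag, 0) + length
            else:
                k = length // 3
                if len(codons) - 2 - k < 30:  # keep the gene comfortably long
                    k = max(1, (len(codons) - 32) // 2)
                at = int(rng.integers(1, len(codons) - 1 - k))
                del codons[at : at + k]
                truth.indel_genes[gene.tag] = truth.indel_genes.get(gene.tag, 0) - 3 * k
            gene.cds = "".join(codons)

    # premature-stop fragmentation, preferentially inside surviving phage DNA
    phage_survivors = [g for g in survivors if g.category == "phage"]
    pool = phage_survivors if len(phage_survivors) >= cfg.fragmentation_events else survivors
    if cfg.fragmentation_events:
        picks = rng.choice(
            len(pool), size=min(cfg.fragmentation_events, len(pool)), replace=False
        )
        for pi in sorted(int(i) for i in picks):
            gene = pool[pi]
            codons = [gene.cds[i : i + 3] for i in range(0, len(gene.cds), 3)]
            ci = int(rng.integers(max(1, len(codons) // 4), max(2, 3 * len(codons) // 4)))
            codons[ci] = "TAA"
            gene.cds = "".join(codons)
            truth.fragmented_genes.setdefault(gene.tag, []).append(3 * ci + 1)

    # rebuild the modified lineage's unit list (drop deleted genes + spacer)
    new_genes: list[_SimGene] = []
    new_spacers: list[str] = [spacers[0]]
    for i, g in enumerate(genes_mod):
        if g.tag in deleted:
            continue
        new_genes.append(g)
        new_spacers.append(spacers[i + 1])

    # repeat-class insertions inside surviving phage regions
    phage_region_tags = [
        set(r["loci"]) for r in ancestor.metadata.get("regions", [])
        if r["kind"] == "phage"
    ]
    for k in range(cfg.repeat_insertions):
        slots = [
            i
            for i in range(1, len(new_genes))
            if any(
                new_genes[i - 1].tag in tags and new_genes[i].tag in tags
                for tags in phage_region_tags
            )
        ]
        if not slots:
            break
        at = int(slots[int(rng.integers(0, len(slots)))])
        ncod = int(rng.integers(100, 300))
        cds = "ATG" + "".join(_random_codons(rng, ncod, cfg.gc_content)) + "TAA"
        tag = f"RIN_{k:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        new_genes.insert(at, _SimGene(tag, "repeat", strand, cds))
        new_spacers.insert(
            at + 1, _random_seq(rng, cfg.intergenic_mean, cfg.gc_content)
        )
        truth.inserted_repeats.append(tag)

    rendered: dict[str, AnnotatedGenome] = {}
    for name in names:
        if name == mod:
            rendered[name] = _render(
                new_genes, new_spacers, f"genome_{name}", cfg.n_scaffolds
            )
        else:
            rendered[name] = _render(
                lineages[name], spacers, f"genome_{name}", cfg.n_scaffolds
            )
        rendered[name].metadata["regions"] = ancestor.metadata.get("regions", [])
    out_og = rendered.get("og")
    return rendered["a"], rendered["b"], out_og, truth
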