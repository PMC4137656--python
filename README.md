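# wolbcomp

Pairwise comparative genomics for closely related bacterial genomes —
built for the *Wolbachia*-style situation where two endosymbiont strains
are nearly clonal at the nucleotide level (≪ 1% divergence) and almost all
of the interesting difference is **gene loss in prophage regions**,
pseudogenization, and a handful of fast-evolving loci.

Given two annotated genomes (FASTA + GFF3/GenBank), optionally an
outgroup, the package:

1. pairs genes by **reciprocal best hit** over an internal affine-gap
   aligner (seed-and-extend, no external search tool);
2. computes codon-level divergence per gene and genome-wide —
   **Nei–Gojobori** site/substitution counting with **Jukes–Cantor**
   correction: pS = Sd/S, Ks = −(3/4)·ln(1 − 4·pS/3), likewise Ka, and
   ω = Ka/Ks;
3. dates the split on a **synonymous molecular clock**,
   T = Ks% / r × 10⁶ years (default r = 0.9% per Myr);
4. screens for divergent genes (identity < 98%) and candidate **positive
   selection** (ω > 1), annotates indels, and polarizes derived alleles
   against the outgroup;
5. delineates **prophage-relic regions** in gene order — tolerant of
   repeat-element interruptions and scaffold breaks — detects
   pseudogenization (premature stops, split annotations, truncations) and
   writes a genome-reduction report with an ortholog-level phage-gene
   census;
6. assesses **synteny**: scaffold ordering by reference gene rank,
   collinear block detection, displaced/inverted segment flagging, and a
   gradient plot.

A first-class **simulator** generates an ancestral genome and evolves a
descendant pair (plus outgroup) with configurable per-gene ω, in-frame
indels, region deletions, premature-stop fragmentation, and repeat
insertions — recording every event in a TruthTable so the whole pipeline
can be validated against known ground truth.

## Worked example

```python
from wolbcomp import (EvolutionConfig, generate_ancestor, evolve_pair,
                      reciprocal_best_hits, summary_from_alignment,
                      genome_wide_divergence, estimate_divergence_time)

cfg = EvolutionConfig(seed=1)           # default study conditions (~1,200 CDS)
anc = generate_ancestor(cfg)
ref, target, _, truth = evolve_pair(anc, cfg)

m = reciprocal_best_hits(ref, target)
summaries = [summary_from_alignment(p) for p in m.pairs]
gw = genome_wide_divergence(summaries)
t = estimate_divergence_time(gw.ks_percent)

print(f"{m.n_pairs} ortholog pairs, {len(m.unpaired_a)} reference genes unpaired")
print(f"Ks = {gw.ks_percent:.3f}%  syn SNPs = {gw.syn_snp_percent:.1f}%  "
      f"T = {t.years_rounded:,.0f} years")
```

prints

```
1156 ortholog pairs, 44 reference genes unpaired
Ks = 0.291%  syn SNPs = 27.9%  T = 320,000 years
```

i.e. of 1,200 simulated genes exactly the 44 truth-deleted
prophage/accessory genes are unpaired in the reference, the genome-wide
synonymous divergence recovers the configured 0.31% to within sampling
noise, about 28% of coding SNPs are synonymous at the configured ω ≈ 0.7,
and the clock dates the pair to ~320,000 years (the configured truth is
~340,000; one seed's estimate scatters around it).

The same run end to end, via the CLI:

```bash
wolbcomp run --config pipeline.yaml --out results/
# pipeline.yaml:  {simulation: {include_outgroup: true}, seed: 1}
```

writes `orthologs.tsv`, `per_gene_divergence.tsv`, `screened_genes.tsv`,
`missing_genes.tsv`, `phage_regions.tsv`, `reduction_report.json`,
`synteny_blocks.tsv`, `synteny.png`, and a consolidated `report.json`
(all parameters echoed; identical seed ⇒ byte-identical outputs). Stage
subcommands (`simulate`, `orthologs`, `divergence`, `screen`,
`phage-report`, `synteny`) run the same steps on genomes you supply.

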