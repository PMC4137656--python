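# Methods

`wolbcomp` analyses a pair of closely related, annotated bacterial genomes —
the motivating system is a *Wolbachia* endosymbiont pair whose divergence is
dominated by prophage-region loss rather than point mutation — and ships a
genome-evolution simulator that generates such pairs with known ground
truth. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic validation does and does not show.

## Orthology

Orthologs are called by reciprocal best hit (RBH) over nucleotide CDS.
Candidate homologs are discovered by exact k-mer seeding (default k = 12): a
pair is aligned only if the two CDS share at least `min_seeds` (default 10)
distinct 12-mers. The floor is deliberately far above 2 because a single
chance match of ~14 nt already produces 2–3 overlapping shared 12-mers;
genuine orthologs in the sub-10%-divergence regime this package targets
share hundreds. Candidates are scored with the internal affine-gap global
aligner and must pass `min_identity` (default 60%) over `min_coverage`
(default 50%) of the shorter CDS. A pair is kept iff each member is the
other's best-scoring hit; tied bests are recorded as ambiguous and resolved
toward the lexicographically smallest tag, so multi-copy families surface
rather than silently pairing.

### Alignment

The aligner is a three-state (match / gap-in-a / gap-in-b) affine-gap DP
with default scoring +2 / −3 / −5 open / −2 extend; the first gap character
costs the open penalty, each further one the extend penalty. The exact
values are immaterial at 99% identity but are pinned for determinism, as is
the tie-break (diagonal preferred over gaps at equal score). Direct
insertion↔deletion transitions are disallowed; with this scoring family a
mismatch column always outscores adjacent opposite gaps, so the optimum is
unaffected (cross-checked against an independent DP and against
`Bio.Align.PairwiseAligner` in the tests). The production path through RBH
uses a banded fill (band = length difference + 64) whose band doubles and
re-runs whenever the traceback touches a band edge; `global_align` itself
defaults to the exact full matrix. Percent identity is identical columns
over all alignment columns, gap columns counting as non-identical and `N`
never counting as identical.

### Missing genes

A reference CDS is declared missing from the target when no scaffold
stretch (either strand) aligns at ≥ 60% identity over ≥ 50% of the CDS
length; each missing call carries its best sub-threshold identity for
audit. Identity here also counts gap columns as mismatches — without that,
glocal alignments of compositionally biased (AT-rich) random DNA reach
~73% gap-excluded identity and the criterion stops discriminating. This
seed-and-extend criterion replaces an external homology-search screen; at
sub-percent divergence any conventional hit clears this floor with a wide
margin, so the substitution is conservative.

## Divergence

Ka/Ks uses Nei–Gojobori (1986) counting with equal-weight pathway averaging
and Jukes–Cantor correction — the classic, oracle-checkable default of the
standard population-genetics tools; transition/transversion-weighted or
maximum-likelihood variants are out of scope. Per codon position, each of
the nine single-nucleotide neighbours carries weight 1/3; neighbours that
are stop codons are excluded from both numerator and total (so s + n < 3
for codons with stop neighbours), and substitution pathways passing through
a stop are dropped, falling back to direct per-position classification
(flagged) in the rare case that every pathway is blocked.

Codon alignment is anchored on the reference frame; any gap run whose
length is not a multiple of 3 makes the frame unrecoverable and excludes
the gene (`frame_break`); codon columns containing a gap are dropped and
counted. Alignments shorter than 30 codons after gap-dropping are excluded
(`too_short`). Stop- or N-containing codon pairs are skipped. Sites are
averaged over the two sequences, so per-gene results are exactly symmetric
under swapping the genomes.

Genome-wide ("concatenated") divergence pools Sd, Nd, S, N over eligible
genes and applies one JC correction, which is equivalent to running the
method on a whole-genome concatenated CDS alignment. SNP totals are
reported both over the filtered gene set and unfiltered. An integer SNP is
called synonymous when its pathway-averaged synonymous weight exceeds 0.5;
exact ties count 0.5/0.5. The mean per-gene omega is unweighted by default
(length-weighted by flag) and is known to be biased low at very low
divergence (genes with one substitution have omega 0 or undefined); the
pooled Ka/Ks ratio is the stable summary at that depth.

Divergence dating divides percent synonymous divergence by a clock rate
(default 0.9% per Myr, the established synonymous rate for this clade) and
reports raw years plus a 2-significant-figure rounding. Percentages are
reported at 1 decimal throughout.

## Selection screen and polarization

The screen reproduces the two-filter convention for near-clonal pairs:
identity strictly below 98% tabulates a gene (sorted by identity, then
tag), and defined omega strictly above 1 flags it; undefined omega (Ks = 0)
is an explicit marker, never 0 or ∞, and is never flagged. Indel events are
maximal gap runs with a net-length consistency check.

Polarization aligns the target and the outgroup each onto the reference and
projects — a deterministic progressive construction that is adequate below
a few percent divergence, rather than a full MSA. Sites where the outgroup
shows a third allele or a gap are unpolarizable; indel columns are excluded
and counted separately. A lineage is called derived when the other
lineage's outgroup matches form a strict majority.

## Prophage inventory

Region delineation works on gene order, not coordinates: maximal runs of
phage-flagged loci, absorbing up to `gap_tolerance` (default 2) consecutive
interleaved repeat-class loci — mirroring mobile-element insertions into
relic regions — while any core-gene interruption or longer repeat run
breaks the region. Scaffold boundaries between members do not break a
region (draft assemblies split relic regions routinely); spans are summed
per scaffold crossed. Gene counts are ortholog-level: fragments of one
reference gene count once.

Fragmentation has three causes: `premature_stop` (internal stop in the
target frame where the reference has none, positions reported 1-based),
`split_annotation` (≥ 2 target loci covering disjoint segments — < 20%
mutual overlap — of one reference CDS), and `truncation` (< 90% of the
reference length with enough flush scaffold sequence on both sides to rule
out an assembly edge). The reduction report scores each reference
phage/accessory region as intact, reduced, or absent (with flanking loci
reported for absent regions) and produces the retained phage-gene census.

## Synteny

Scaffolds are ordered by the median reference rank of their orthologs
(orphan scaffolds last, by ID). Blocks are maximal within-scaffold runs of
ortholog pairs whose reference ranks are consecutive-monotone, tolerating
one unpaired target locus between members and a rank step of ≤ 2
(absorbing single lineage-specific insertions or losses on either side);
descending runs are inverted blocks. A block is displaced when the
reference rank jumps by more than `displaced_distance` (default 50) at
every junction with its target-order neighbours — junction discontinuity,
not interval distance, so a relocated segment whose ranks happen to abut a
neighbour's interval numerically is still caught. The gradient plot colours
target genes by the reference rank of their ortholog.

## Simulator

The generator emulates a reduced endosymbiont genome: by default ~1,200 CDS
of mean length 750 bp at 35% GC on one scaffold with ~150 bp intergenic
spacers (≈ 1.1 Mb), two large prophage regions (40 and 24 genes) plus a
small intact one (5) and an eight-gene accessory island, ~6% repeat-class
genes scattered outside regions. Codons are sampled from a base composition
solved numerically so that sense codons (stops rejected) average the target
GC — naive rejection drags coding GC ~1 point AT-poor of target.

Evolution places substitutions site-category-aware: synonymous events are
drawn among the synonymous single-nucleotide codon changes available in the
gene (weighted by neighbour counts), nonsynonymous events among the
non-stop nonsynonymous changes, with per-gene counts Poisson at rate
(raw density) × (NG86 site count) per branch. The raw density is the
inverse-JC transform of `target_ks` (default 0.0031) split equally over the
two branches, so the pipeline's JC-corrected estimate is centred on the
target; omega per gene comes from `omega_by_class` (default 0.7 for every
class). Start and stop codons never mutate; intergenic sequence does not
mutate (the analysis only reads coding SNPs). An optional outgroup branches
before the pair splits, with `outgroup_scale` (default 3×) the per-branch
density — close enough to polarize, distant enough to carry its own
substitutions.

Structural events apply to one configurable lineage (default the target):
in-frame indels in a small fraction of genes (default 0.8%, uniform
multiples of 3 over 3–189 bp — published events in this system are all
in-frame, but no empirical length distribution exists, so uniform is a
modelling choice); region deletions specified as (region index, genes
retained left, genes retained right) with defaults leaving 21- and 7-gene
relics and deleting the accessory island outright (~44 genes lost, ~33
phage genes retained); premature-stop fragmentation preferentially inside
surviving phage DNA; and repeat-class gene insertions between surviving
phage genes. One seeded RNG stream drives everything in documented order
(outgroup, lineage a, lineage b, indels, fragmentation, insertions), so
fixtures are byte-reproducible.

The TruthTable records per-gene targets and realized events, deleted /
fragmented / inserted locus sets with positions, and the count of sites hit
in both lineages (which bounds the back-mutation discrepancy between event
totals and observed SNPs).

What the simulator does **not** model: codon-usage bias, rate heterogeneity
along the genome, recombination or gene conversion, frameshift indels
outside the fragmentation process, intergenic evolution, sequencing or
assembly error. Passing the recovery tests therefore shows the analysis
chain is correct under a clean substitution process at realistic density —
not that it is robust to annotation noise or assembly artifacts in real
data.

## Validation design and problem sizes

The stochastic recovery suite runs 20 seeds of 999-gene pairs at target Ks
0.0031 with omega classes {0.2, 1.0, 4.0}; the suite checks that the three
classes rank-order correctly in every seed and that Ks and per-class omega
pooled over the suite sit within 3 binomial SE and 30% of target
respectively. Pooling is the right level for the tolerance checks: a
single-seed omega for the 0.2 class rests on roughly a hundred events
(CV ≈ 12%), so per-seed bounds at these widths would trip on sampling noise
rather than on implementation error. Structural-recovery tests (missing
genes, region boundaries, fragmentation recall) use a 200-gene fixture
carrying every event type plus an outgroup, where recovery is required to
be exact. These sizes keep the full suite within a few minutes while
leaving every per-gene quantity at the same statistical depth as the
full-scale defaults, which the acceptance script runs end to end.

## Known limitations

* RBH is one-to-one by construction; paralog families appear as ambiguous
  or unpaired loci rather than many-to-many groups.
* The banded alignment path is heuristically exact (band-edge detection and
  doubling); pathological alignments whose optimal path leaves the band
  without touching its edge are possible in principle.
* Split-annotation detection requires the fragments to seed against the
  reference CDS (shared 12-mers), so very short or very diverged fragments
  can be missed.
* The clock date inherits the full uncertainty of the assumed synonymous
  rate; no confidence interval is attached.
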