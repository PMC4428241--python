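# Methods

`strainpan` quantifies gene content variation of bacterial strains across
individuals from *per-gene read coverage* of a species' representative
genome — the situation of fragment-recruitment metagenomics, where reads
from many unrelated gut samples are mapped onto one reference per species.
The package implements the analysis chain (presence calling → filtering →
core/accessory classification → rarefaction extrapolation → deletion-block
architecture → pairwise distances and enrichment) together with a synthetic
strain-community generator that provides ground truth for every stage.

## Presence calling and filtering

A gene is called **present** in a sample when reads cover at least 40% of
its length (`covered_bp / gene_length_bp >= 0.40`, boundary inclusive).
The threshold protects against spuriously assigned reads and against reads
recruited by orthologues of close relatives, at the cost of missing genes
whose remaining homologous stretch is short. At a cutoff of exactly 0 the
literal rule is vacuous (every gene, even one with zero coverage, would
pass), so presence there degrades to "covered by at least one base"; this
keeps the call monotone in the cutoff and makes the 0% point of the
calibration curve informative about spurious coverage instead of being
identically zero.

The cutoff is **calibrated** rather than assumed: presence is called in
biological replicate pairs (same individual, different time points) at
cutoffs 0, 0.1, …, 1.0, and the cutoff minimising the mean replicate
gene-content difference is chosen, ties going to the smallest minimiser
(which retains more genes). Cutoffs at which a pair has an empty union of
present genes are excluded from the minimisation. On communities produced
by the bundled simulator the calibration recovers 0.40, because both noise
channels of the coverage model straddle that boundary from opposite sides
(see below).

A sample × species combination enters the analysis only if

1. **breadth**: ≥ 40% of the genome is covered by at least one read,
2. **markers**: all flagged universal single-copy marker genes (40
   expected) are called present, and
3. **depth**: mean genome coverage is ≥ 30×.

Breadth and depth are accepted as given when the coverage table carries
genome-level values; otherwise they are approximated from the per-gene
records weighted by gene length. The approximation ignores intergenic
sequence — unavailable at gene resolution — and is therefore slightly
optimistic for breadth in gene-dense genomes; callers with read-level
breadth should supply it. Whether the 30× depth averages over uncovered
positions is a convention; here it does (absent genes contribute zero).

Species with fewer than 10 passing individuals are excluded. Otherwise 10
individuals are drawn uniformly at random (seeded), one **primary sample**
each — the earliest time point, lowest lane; the tie rule is a
deterministic convention, not a biological claim.

## Core, accessory, unobserved

Over the selected cohort, a reference gene is **core** if present in every
individual, **unobserved** if present in none, and **accessory**
otherwise. Unobserved genes are reference-specific sequence not seen in
any sample; they are excluded from enrichment tests and from the
rarefaction universe but reported, since they represent a floor on gene
content not shared with the reference strain.

## Rarefaction and extrapolation

For every subset size *k* = 2…*n*, the *subsample-based fraction* of a
*k*-subset is the share of **universe** genes absent in at least one
member, where the universe is fixed to the genes observed in ≥ 1 of the
full cohort. All C(*n*, *k*) combinations are used at cohort scale
(*n* = 10); for larger pools, up to 500 distinct random combinations per
size (rejection-sampled, seeded). The fixed-universe denominator is a
deliberate choice: under it the expected fraction is provably
non-decreasing in *k* (a gene missing in one of a subset is missing in one
of any superset), and the *k* = *n* point equals the cohort's accessory
fraction among observed genes. The implementation asserts the monotonicity
on every exhaustive run; sampled runs only warn, since finitely many
random combinations can fluctuate. Means are fitted by default; medians
are computed and can be fitted instead.

Four models are fitted to the per-size fractions by least squares
(`scipy.optimize.curve_fit`, bounded, ≤ 20 random restarts):

| model | form | asymptote |
|---|---|---|
| exponential | f(k) = a − b·exp(−k/c), b, c > 0 | a |
| negative exponential | f(k) = a·(1 − exp(−b·k)) | a |
| power law | f(k) = a·k^b | none for b > 0 |
| spline | monotone cubic (PCHIP) through the means | none |

The exponential is initialised from a log-linear fit of the residuals
against a₀ = (last mean + 0.05). The **accessory percentage** of a species
is 100·a from a model with a finite asymptote; the per-gene deletion
frequencies underlying real cohorts form a *mixture* of exponentials in
*k*, which a single exponential systematically undershoots, so the
estimate is a lower bound. For the power law with positive exponent the
value at a stated horizon (default k = 100) is reported with a warning;
the spline has no asymptote at all and only reports the horizon value.
Model quality is scored as the mean absolute deviation (percentage points)
between the fitted curve and *expected fractions* — the same subsampling
statistic computed on all available individuals of the pool, beyond the
10 used for fitting.

## Deletion blocks

Relative to the reference gene order, a **deletion block** is a maximal
run of contiguous absent genes in one individual, confined to a contig
(adjacency across contigs of a draft assembly is unknown, so runs are
never merged across them — a real block may thus be split in two). A
size-1 block is a **single-gene deletion** only when its flanking genes
exist and are present; with the default flank depth of 1, maximality
already guarantees presence, so the criterion reduces to not touching a
contig edge. A stricter reading — two present neighbours on each side —
is available as `flank_depth=2`. Size-1 blocks at contig edges are
excluded from all tallies (a contig break would otherwise masquerade as a
single-gene deletion); multi-gene edge blocks are counted but flagged,
and the spectrum can be recomputed without them. Blocks of ≥ 50 genes are
**large**. Block sizes always partition the absent genes of an individual;
exclusion affects tallies only. The size spectrum reports, per size, the
frequency among counted blocks and the share of deleted genes, averaged
across individuals; individuals with no counted blocks are omitted from
the averages with a warning.

## Distances, tests, diagnostics

The gene-content difference between two samples is the symmetric
difference of their present-gene sets divided by their union — the Jaccard
distance, a proper metric. The replicate map classifies pairs as
inter-individual (primary samples of different individuals), biological
replicates (time points of one individual, first lane of each) or
technical replicates (lanes of one sample). For pairs of completely
sequenced genomes the **reference-conditioned** variant emulates the
reference dependency of read mapping: a third "reference" gene set filters
both numerator and denominator, so genes absent from it are invisible.
When the reference contains every gene of the pair the measure reduces to
the plain Jaccard distance.

Distance distributions are compared with the Wilcoxon–Mann–Whitney test:
exact null distribution when both groups have ≤ 20 tie-free values,
normal approximation with tie correction otherwise. Functional-category
enrichment of accessory versus core genes uses the two-sided Fisher exact
test (minimum-likelihood definition — the sum of all table probabilities
not exceeding the observed one; tail-doubling is available as an option)
with Benjamini–Hochberg adjustment across categories. A diagnostic checks
that the per-sample accessory fraction does not correlate (Pearson by
default, Spearman optional) with coverage or species abundance; nothing is
gated on it, and constant inputs are reported as undefined rather than
raised. When correlating against depth, use depth over covered genes —
whole-genome depth is mechanically depressed by the very absences whose
fraction is being tested.

## The synthetic community generator

The generator emulates the *conditions* of a multi-individual gut
metagenomic study — 11 species whose genome structures span single-contig
closed genomes to 71-contig drafts (1.8–5.8 k genes), per-species pools of
10–58 individuals with a 10-individual analysis cohort, accessory-fraction
targets spread over 21–45%, ~50× depth, and replicate noise ordered
technical < biological < inter-individual. No generative model for strain
populations can be taken from data here, so the distributional choices
below are stand-ins, chosen once for realism.

**Reference.** Genes with Normal(900, 300) bp lengths (≥ 150 bp) laid
consecutively with short gaps on the configured number of contigs. The 40
marker genes are placed in 8 operon-like clusters dealt across contigs
(ribosomal-protein style). Clustering matters: markers are exempt from
deletion, and evenly spaced markers (every ~50 genes) would make ≥ 50-gene
deletion blocks geometrically impossible.

**Strain population.** A cohort-level pool of candidate deletion blocks is
placed uniformly at random — sizes from a mixture of 35% singletons, 60%
geometric (mean 4) and 5% uniform(50, 175) — without overlap or adjacency,
until the pool covers the target accessory fraction (a rejection rule
limits overshoot to ~1% of genes; if the target is unreachable, e.g. on a
marker-saturated toy genome, generation fails loudly after bounded
attempts). Each block carries a deletion frequency q ~ U(0.1, 0.9), and
each individual deletes each block independently with probability q. The
two-level design is essential: placing blocks independently per individual
until the cohort union reaches the target would make nearly every
accessory gene a singleton (absent in ~1 individual), produce near-linear
rarefaction curves and per-individual absence fractions that shrink with
pool size — none of which resembles the saturating curves and
double-digit inter-individual differences of real cohorts. With per-block
frequencies, rarefaction curves are mixtures of exponentials in *k* and
saturate. Non-adjacent placement keeps every planted block a maximal run,
so noiseless detection must recover the planted blocks exactly — an exact,
not approximate, test oracle. Placement constraints (contig fragmentation,
marker clusters, collisions) reshape the realized spectrum relative to the
drawn mixture; large blocks survive at roughly one per species pool. A
`hotspot` placement mode concentrating blocks near a few genomic islands
is available but off by default; uniform placement suffices for
correctness testing.

**Coverage and noise.** Present genes draw covered fractions in
(0.85, 1.0) and depths around the configured mean; absent genes are
exactly zero. Four noise channels, all per-gene probabilities:

* `presence_noise` (default 0.002) — in any sample, a spurious flip of
  the covered fraction across the 0.40 boundary, in either direction
  (false presents land in (0.42, 0.70), false absents in (0.02, 0.38)).
  Present markers are never flipped absent: the markers' joint presence is
  the species-detection criterion, and the generator models within-species
  gene-content noise, not species mis-detection.
* `biological_noise` (default 0.01) — presence flips of a *non-primary
  time point* relative to the individual's strain truth, so a biological
  pair differs at about this rate. The primary time point is the truth.
* `technical_noise` (default 0.001) — each lane of a multi-lane sample
  flips at half this rate, so any lane pair differs at about the full
  rate. Single-lane samples carry no technical term (the noise of a
  single sequencing reaction is part of `presence_noise`). The half-rate
  convention makes equal configured biological and technical rates give
  equal pair-difference distributions, which is what the "replicates are
  statistically indistinguishable" check requires. The multi-lane
  individual is never also a biological-replicate individual, so each
  replicate class carries exactly one noise term.
* `spurious_coverage_rate` (default 0.05) — sub-threshold structure that
  never crosses 0.40: absent genes gain partial coverage in (0.01, 0.35)
  (mis-assigned reads from relatives' orthologues) and present genes are
  eroded into (0.45, 0.85) (strain-variable gene ends). Calls at the 0.40
  cutoff are unaffected, but cutoffs below it see the spurious coverage
  and cutoffs above it see the erosion — which is why replicate-based
  calibration lands on 0.40.

Everything is driven by one `numpy` generator per species seed; a fixed
seed yields byte-identical references, truth sets and profiles.

**What the simulator does not model.** Reads (coverage is drawn at gene
resolution, since the decision rule consumes only per-gene covered
length), sequencing error profiles, SNPs, paralogy and orthologue
cross-mapping beyond the aggregate noise rates, gene gain relative to the
reference (the method measures deletions only, so estimates are lower
bounds by construction), horizontal-transfer dynamics, and compositional
coupling between species. Passing tests therefore demonstrate the
correctness and calibration of the *method* under controlled conditions,
not the biological accuracy of any particular published estimate.

## Problem sizes used in the shipped checks

The test suite runs the full noiseless recovery at 11 species × 10
individuals × 2,000 genes; parameter recovery at 1,000 genes with a
30-individual super-cohort over 10 seeds and three accessory targets
(0.20/0.32/0.45, each within ±5 pp of brute force); the block scanner
against an independent run-length oracle on 1,000+ random multi-contig
vectors; Fisher p-values against full hypergeometric enumeration for all
2×2 tables with N ≤ 60 (reduced by the p-preserving symmetries); and the
replicate-ordering and equal-noise experiments over 20 seeds each.
`scripts/acceptance.py` regenerates the complete default study (11
species, pools of 10–58 individuals) and recomputes every headline
quantity from scratch; with the defaults it completes in well under a
minute on one CPU.
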