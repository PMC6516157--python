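# Methods

This note documents the models, estimators and design choices behind
`agecap`, in the order the pipeline runs them, together with the defaults and
the reasoning for each.

## Synthetic data model (`agecap.simdata`)

The generator emulates a bulk RNA-seq aging time course: two genotypes
(wild type and a *daf-16*-null-like mutant) × adult days 1–7 × 3 biological
replicates, 5,000 genes by default. Counts are negative binomial with
Var = μ + αμ², drawn as a gamma–Poisson mixture, with

* baseline expression `base_mean` log-normal (ln-scale mean 5.0, sd 1.2 —
  a median of ~150 counts with a realistic four-decade spread),
* a mean–dispersion trend α(μ) = a1/μ + a0 with a1 = 1.5, a0 = 0.01
  (α ≈ 0.02 at the median gene, typical for isogenic worm cohorts),
* per-sample size factors log-normal (sd 0.15), re-centred to geometric
  mean 1 so that normalization recovery is identifiable.

Gene archetypes plant the structure the analysis must recover. Default
fractions: 50% stable, 20% capacitor, 10% up-targets, 6% down-targets,
5% + 5% genotype-shared age trends, 2% + 2% IIS-class-like profiles.

* **Age trends** (`age_up`/`age_down`): genotype-shared log2 slopes of
  magnitude U(0.2, 0.6)/day — moderate drift reaching 1.2–3.6 log2 by day 7.
* **DAF-16 targets** (`daf16_target_up`/`daf16_target_down`): a WT-only
  effect of ±2 log2 (the mutant lacks it), zero before day 4 and ramping
  linearly to full strength at day 6. The sign convention makes the
  WT-vs-mutant log2FC of an up-target positive on late days.
* **Capacitor genes**: amplitude A with |A| ~ U(1.2, 1.8) and random sign.
  The wild type drifts linearly, reaching A on day 7; the mutant moves
  `capacitor_gain` (= 3) times faster and saturates at 1.15·A. A naive
  "mutant slope = 3 × WT slope" trend was rejected: it drives the late-day
  genotype contrast to ~4 log2, which would (a) remove capacitor genes from
  region F (F requires a *non-significant* genotype contrast) and (b) flood
  the day-6/7 target calls. The saturating shape gives the intended
  phenotype — the mutant transcriptome is already remodelled on day 2 while
  the wild type has barely moved, and by day 7 the genotypes nearly coincide
  so capacitor genes stay out of the target definition. The 1.15 overshoot
  keeps the mutant's fold-change spread above the wild type's on every day
  even after the wild type catches up.
* **Class-1-like** genes carry a WT-only late induction of +1.5 log2 (same
  ramp as the targets); **class-2-like** genes decline at −0.3 log2/day in
  both genotypes. Their distinct shapes are what the profile-clustering
  stage separates.
* **Outlier samples**: counts permuted across genes within the sample. This
  preserves the count distribution but destroys rank correlation — exactly
  the signal the QC screen uses.

Lifespan records are discretized Weibull: shape 4 (the steep sigmoidal
mortality of worm assays), scale set so the continuous mean equals the
requested mean lifespan, days obtained by ceiling. Censored animals get a
uniform observation day at or before their death day.

What the generator does **not** emulate: batch effects, GC/length biases,
transcript-level ambiguity, count outliers within otherwise-good samples,
and correlated gene modules. Passing recovery tests therefore demonstrate
that the estimators work at realistic effect sizes and replication — not
that the pipeline is robust to every artefact of real libraries.

## Differential expression (`agecap.de_core`)

Size factors are median-of-ratios against a geometric-mean reference; genes
with a zero in any sample drop out of the reference (an error is raised when
none remain).

Dispersion is estimated per gene by method of moments from within-group
(genotype × day) normalized counts — α̂ = (pooled within-group variance −
mean)/mean², floored at 1e-8 and capped at 10 — then averaged
half-and-half with a least-squares fit of the trend α(μ) = a1/μ + a0.
This deliberately replaces heavier Cox–Reid/MAP machinery: at this design
size what matters is test calibration, which is asserted by simulation
(type-I error of the full pipeline at nominal 0.05 lands in [0.02, 0.08]).
All-zero genes take the trend value at the median positive mean.

The Wald contrast uses closed-form group means of normalized counts
(pseudo-count 0.5 when a group is silent), log2 fold change
log2(μ̂_A/μ̂_B), and the delta-method standard error derived from
Var(count/s) = μ/s + αμ². The statistic is compared two-sided to a standard
normal. Genes with zero counts everywhere report log2FC 0 and p 1. BH
adjustment is the classical step-up, implemented directly and
oracle-checked against brute force (and statsmodels) in the tests. DEG
calling uses the strict inequality `p_adj < alpha` (default 0.05).

## Quality screen (`agecap.qc`)

Correlations are Spearman rho on log2(normalized count + 1). A sample is
flagged when its **best** rho to any other sample is below `min_rho`
(default 0.9). Rationale: a permuted sample correlates with nothing
(rho ≈ 0), while every genuine replicate has a ≥ 0.97 within-cell partner or
a ≥ 0.94 neighbouring-day partner; the per-cell median, by contrast, is not
robust in triplicate cells (one bad replicate drags both neighbours' medians
to ~0.5). The within-cell median is still reported for diagnostics. Cells
left with fewer than two samples are marked low-confidence and the contrasts
that need them are skipped.

## Region taxonomy (`agecap.regions`)

With w/m/g the significance indicators in W, M and G, the mapping is
A = w·g·¬m, B = w·m·g, C = w·¬m·¬g, D = ¬w·m·g, E = w·m·¬g, F = ¬w·m·¬g,
plus G_only and unchanged. It is the unique assignment satisfying
A+B+C+E = W, A+C = "unique to wild type", F = "unique to the mutant".
Membership uses significance only; per-contrast directions are reported but
do not affect the label. `region_counts` adds the A+B share of age-DEGs and
first-detection-day bookkeeping (new vs previously seen DEGs).
`fold_change_spread` summarizes per-genotype log2FC dispersion by
interdecile range and variance; the mutant/wild-type interdecile ratio is
the capacitor index. `trend_correlation` is Spearman rho between the WT age
response and the WT-vs-mutant contrast; on the default synthetic data the
series rises from ≈ 0.03 (day 2) to ≈ 0.35 (day 7) with a shallow day-3 dip
caused by the capacitor genes' mid-course genotype gap, so monotonicity is
measured as the rank correlation of the series with day.

## Target definition (`agecap.targets`)

A gene is an age-dependent target when the genotype contrast has adjusted
p < 0.1 on **both** day 6 and day 7, the fold changes agree in sign on the
two days (a gene cannot be both up and down), and |log2FC| exceeds the
day-1 magnitude on both days. The fold-change gate compares absolute values;
signed comparison would silently pass sign-flipped genes. Binding-site folds
are ratios of site fractions, phrased the way the field reports them:
r-fold enrichment when r ≥ 1, (1/r)-fold depletion otherwise. The optional
BED helper assigns a site to a gene when an interval (0-based, half-open)
overlaps the gene body or its 1 kb strand-aware promoter window — a stated
convention, since site-to-gene rules vary.

## Temporal profiles (`agecap.trends`)

Z-scores standardize each gene across **all** samples (both genotypes,
every day, replicates kept as columns) with the sample standard deviation
(ddof = 1); constant genes are excluded and listed. Clustering is Lloyd
k-means with k-means++ seeding from an explicit seed, one initialization,
defaults k = 6 and ≤ 1,000 iterations (backed by scikit-learn's Lloyd
implementation; fixed seed makes runs bit-reproducible). Percentile bands
report the 20th/50th/80th percentiles per genotype × day with linear
interpolation between closest ranks.

## Enrichment (`agecap.enrichment`)

Upper-tail hypergeometric P(X ≥ k) with parameters (N, K, n); BH across the
terms of one collection; the reporting filter is strict on both criteria
(adjusted p < 0.05, fold > 2). The universe is the set of genes that
survived expression filtering in the analyzed matrix — not the whole
annotation — the standard guard against background inflation.

## Organismal statistics (`agecap.phenostats`)

The 2×c Fisher test (c ∈ {2, 3}) enumerates all tables with the observed
margins; the two-sided p is the total probability of tables no more probable
than the observed one (ties included with a 1e-9 relative tolerance). The
enumeration is bounded at 500 animals; beyond that the chi-square test
(Pearson, no continuity correction) is the advertised alternative, and a
documented collapse rule merges the weakly- and strongly-nuclear categories
when a 2×2 is wanted. Localization scores are 0 (cytoplasmic), 1 (weakly
nuclear), 2 (strongly nuclear); the group score is the count-weighted mean.
Kaplan-Meier curves and the 1-df log-rank test come from lifelines; mean
lifespan is the restricted mean — the KM curve integrated to the last
observed uncensored event across both groups — and the percent reduction is
100·(mean_A − mean_B)/mean_A.

## Pipeline (`agecap.pipeline`)

QC filtering happens once, before all contrasts. Genes with fewer than 10
total counts across retained samples are dropped before DE (stabilizes the
dispersion fit). The contrast plan for a full design is 19: day x vs day 1
within each genotype (6 + 6) plus WT vs mutant on each day (7); contrasts
touching a cell with fewer than 2 samples are skipped with a warning.
Dispersions are estimated once from all genotype × day cells and shared by
every contrast. The clustering stage runs on the called target genes.
The manifest records config, retained dimensions, contrast names, target
counts and a SHA-256 checksum per output file; a rerun with the same
configuration is bit-identical.

## Problem sizes and tolerances

Recovery and structural properties are checked on the default configuration
(5,000 genes × 42 samples) across 20 seeds in the test suite and 5 seeds in
`scripts/acceptance.py`. Calibration uses 2,000 null genes (3 vs 3) for the
Wald test and 500–1,000 null lifespan assays (50 vs 50) for the log-rank
test, with the acceptance band [0.02, 0.08] at nominal 0.05. Oracle
equivalence is exact: BH vs brute force at 1e-12 on random vectors; the
hypergeometric tail vs integer-binomial summation at 1e-12 for every
(N ≤ 60, K, n); Fisher vs independent enumeration at 1e-10; the region
classifier vs an 8-cell truth table on random universes. Known limitations:
the Wald test is slightly anticonservative at n = 3 per group (observed
type-I ≈ 0.06 at nominal 0.05, inside the stated band); the dispersion trend
fit is a plain least-squares fit and can be pulled by heavy-tailed
method-of-moments estimates; the outlier screen targets whole-sample
corruption and will not catch a sample that is wrong but internally
consistent with another wrong sample.
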