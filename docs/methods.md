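# Methods

`evmirna` analyses small-RNA sequencing counts of extracellular-vesicle (EV)
miRNAs collected across the development of region-patterned brain organoids:
two genotypes (an isogenic control line, IC, and a MeCP2:R255X Rett-syndrome
line, RTT), an iPSC state sampled at day 0 and dorsally/ventrally patterned
organoids sampled at days 13, 40 and 75, with three replicates per condition
(14 condition cells, 42 libraries). This note records the models, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Normalization

Small-RNA libraries are dominated by a few very abundant species, so column
totals confound sequencing depth with composition. Per-sample scaling
factors are estimated by the trimmed mean of M-values (TMM): against a
reference sample (the one whose 75th-percentile count fraction is closest
to the mean of those quantities), per-miRNA log2 proportion ratios (M) and
average log2 proportions (A) are formed over miRNAs positive in both
samples, doubly trimmed (30% of M at each tail, 5% of A), and combined by a
precision-weighted mean using delta-method binomial variances; the factor is
2 to that mean, and factors are rescaled to geometric mean 1. The
implementation reproduces the reference R implementation of this estimator
to ~1e-16 on identical inputs (checked during development; the shipped test
uses an independent straight-line re-computation as the oracle).

Expression is reported as log2 CPM on TMM-effective library sizes with a
prior count (default 2). The prior is a *pseudo-CPM*: sample j receives
`prior_count * lib_eff_j / 1e6` pseudo-counts, so a library at depth 1e6
gets exactly `prior_count` of them and the transform is exactly invariant
to rescaling all counts and library sizes together. This matters because
the ubiquitous-expression rule (log2 CPM >= 12 in every IC sample) reads
this matrix; under the pseudo-CPM convention the rule has the same meaning
at any depth.

Low-expression filtering keeps miRNAs with unnormalized CPM >= 1 in at
least 3 samples (the smallest condition-cell size); both thresholds are
arguments.

## Count model and testing

Counts follow a negative-binomial GLM with log link and offset
`log(effective library size)`; one coefficient per condition cell, so
contrasts are differences of cell means and there is no intercept
ambiguity. Inference is quasi-likelihood:

* NB dispersion trend: genes are binned by average log2 CPM (>= 10 bins);
  each bin's common dispersion maximizes the summed Cox-Reid adjusted
  profile likelihood (profiled over log10 dispersion in [-8, 1]); the
  binned estimates are lowess-smoothed against abundance and interpolated
  to every gene. Gene-wise shrinkage at the NB layer is deliberately
  omitted — gene-specific variability is carried by the quasi-dispersion.
* Quasi-dispersion: `s2_g = residual deviance / residual df` at the
  trended dispersion, moderated across genes by empirical Bayes. A
  scaled-F prior is moment-matched on the log scale (digamma/trigamma
  identities; the trigamma inverse by Newton iteration); when the observed
  spread of log quasi-dispersions does not exceed pure chi-square sampling
  noise the prior df is infinite and every gene is fully squeezed. If the
  quasi-dispersions are exactly identical there is no sampling noise to
  correct and they are returned unchanged.
* Test: for contrast `C'beta = 0`,
  `F = (deviance drop / df1) / s2_post ~ F(df1, d0 + df_resid)`; with
  infinite prior df the chi-square limit is used. BH adjustment is applied
  within the tested miRNA set. GLMs are fitted by Fisher-scoring IRLS
  vectorized across genes (tolerance 1e-8 relative deviance change, 100
  iterations; non-converged rows get p = 1 and a warning).

Fold changes are `contrast estimate / log 2`. A row with all-zero counts on
one side of a contrast has an unbounded MLE; such rows are refitted on
prior-augmented counts (0.5, scaled to library size) for reporting.

Calibration under the null (2,000 NB genes, dispersion 0.1, 3 vs 3) puts
the raw p < 0.05 fraction at ~0.05 and BH discoveries at zero; both are
asserted by the test suite. A 3-vs-3 comparison at biological coefficient
of variation ~0.32 has low power against 2-fold changes (~0.25 at BH 0.05
— the same on this fixture for the reference R implementation), so power
properties are asserted at 4-fold or on the temporal design, where monotone
effects compound across timepoints.

## Temporal dynamics

Per region, the model pools the shared iPSC day-0 samples with the region's
three organoid timepoints (IC samples only; 4 timepoint coefficients,
residual df 8). Two routes identify miRNAs changed between at least two
timepoints:

* `dynamic_mirnas_joint` (pipeline default): one rank-3 joint F-test of all
  timepoint differences per region — the count-model analogue of one-way
  ANOVA — with a single BH pass, unioned over the two regions. The dynamic
  set's false-discovery rate stays near nominal, and planted-profile
  recovery reaches sensitivity 1.0 / precision >= 0.93 in the shipped
  experiment.
* `dynamic_mirnas`: the union of the six pairwise contrasts (D13-D0,
  D40-D0, D75-D0, D40-D13, D75-D13, D75-D40) per region at q < 0.05 each,
  retained for per-contrast reporting. Unioning twelve separately adjusted
  tests compounds their FDR to ~20-25%, an arithmetic property of
  BH-per-test unions, not an implementation artifact; the joint test is the
  statistically sound reading of "changed between at least two timepoints".

Dynamic miRNAs are standardized per row (zero mean, unit variance, sample
(n-1) sd; constant rows map to zeros with a warning) over all IC samples
jointly and clustered with Ward linkage on Euclidean distances (scipy's
deterministic nearest-neighbor-chain implementation), cut at k = 3 by
default to mirror the increasing / decreasing / remainder structure; k is a
parameter and no automatic selection is attempted. Per-cluster monotonicity
is called from the sign pattern of the cluster-mean profile across ordered
timepoints within each region (strictly rising in both regions →
increasing; strictly falling → decreasing; else mixed).

Ubiquitous miRNAs are exactly those with log2 CPM >= 12 in *every* IC
sample; RTT columns are never read.

## Genotype contrasts and genomic clusters

RTT vs IC is tested at each of the seven condition cells. Dispersion is
estimated per regional model (iPSC day 0 plus one region's three
timepoints, both genotypes, 24 samples); the iPSC:D0 contrast comes from an
iPSC-only model so it is reported once. Fold changes are signed RTT minus
IC, and BH is applied within each comparison separately (a global-adjust
option exists). Cells missing a genotype or with < 2 replicates per
genotype are skipped with a warning.

A genomic miRNA cluster (the C14MC-like unit in the generator) is
summarized by ordering members along the genome (0-based half-open
intervals), reporting per-condition mean log2 CPM per member, the count and
fraction of tested members significant in >= 1 comparison, and the mean
member log2FC per comparison. Cluster membership comes from the annotation,
not from coordinate clustering.

## Pathway enrichment

The query gene set of a miRNA set is the union of its members' target
genes. Each pathway is scored by the upper-tail hypergeometric probability
P(X >= k) with the universe defaulting to all genes in the pathway
collection (configurable to the union of mapped targets), BH-adjusted
across the collection. Because target-set sizes are heavy-tailed, the
hypergeometric p is calibrated against 10,000 random miRNA sets of the same
size drawn without replacement from the pool of measured miRNAs (including
target-less ones); all pathways are evaluated on the same permuted sets so
cross-pathway correlation is preserved. The permutation p is
`(b+1)/(n_perm+1)` with ties counted as <= (a valid, never-zero p);
`paper_parity=True` reports the raw fraction `b/n_perm`.

## The synthetic-data generator

The generator is first-class, tested code that emulates the study design:
42 NB libraries (mean depth 1e6, log-normal library-size CV 0.2, common
dispersion 0.1) on a log-normal abundance backbone (log2 mean 6, sd 2) with
planted classes — 15 increasing and 15 decreasing miRNAs (2-fold per
timepoint step), a 50-member genomically contiguous cluster elevated 2-fold
in RTT, 10 ubiquitous miRNAs pinned at true log2 CPM 14 (two units above
the calling threshold so biological noise rarely drops a single replicate
below it), and 10% composition-biased null miRNAs (half elevated 2-fold in
RTT libraries, half in IC — the same magnitude of composition shift the
planted cluster itself produces). Abundances are renormalized per condition
(sequencing depth is fixed), so the recoverable normalization factor is
`library scale / (realized column total x condition abundance total)`;
this is the planted truth the TMM test compares against. Optional switches
confine temporal effects to one region per miRNA and floor planted-class
abundances (used by the recovery experiments so power is tested on
detectable effects rather than the abundance lottery).

What the generator does **not** emulate: mapping/annotation artifacts,
sample-specific GC or length biases, correlated dispersions, batch effects,
isomiR structure, or real miRNA target networks (the target map and pathway
collection are synthetic, with one designated enriched gene block shared by
the elevated class so enrichment recovery is testable). Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to those real-data phenomena.

Reproducibility: every stochastic routine takes one integer seed and
derives sub-streams via `numpy.random.SeedSequence`; identical seeds give
bit-identical outputs, and the end-to-end runner writes byte-identical
tables on repeated runs.

## Experiment sizes used by tests and the acceptance script

Chosen to exercise each property at meaningful scale: normalization
recovery at 1,000 miRNAs with 15% composition bias and dispersion 0.01
(technical scale — at biological dispersion the trimmed weighted mean's
sampling error, not composition, dominates, for any implementation of the
estimator); null calibration at 2,000 genes; temporal recovery at 600
miRNAs with 100 planted dynamics; clustering recovery at 40-60 profiles;
the study-conditions run at the generator defaults with 10,000
permutations.

## Known limitations

* The NB layer uses the dispersion trend without gene-wise NB shrinkage;
  genes with dispersion far above the trend rely on the quasi-dispersion
  layer to absorb the excess.
* Deviance-based quasi-dispersions are biased at very small counts; the
  expression filter is assumed to have removed such rows.
* TMM factors inherit the estimator's known sensitivity to very asymmetric
  DE mass; with >~15% of the library shifted in one direction, part of the
  planted signal is absorbed into normalization (visible as mean cluster
  log2FC ~0.92 for a planted 1.0).
* The permutation null matches set *size* only; it does not condition on
  the abundance or target-set-size profile of the observed miRNAs.
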