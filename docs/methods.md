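# Methods

This note documents the statistical models the package implements, the
synthetic data the validation runs on, and the design decisions taken where
the underlying procedures are commonly under-specified.

## The discovery model

Methylation is analysed on two scales.  Beta values (β ∈ [0,1], methylated
over total signal) are kept for effect sizes and visualization because they
are the biologically interpretable scale; all regression is done on
M-values, M = log2(β/(1−β)), which are approximately homoscedastic in the
range where betas are informative.  The transform clamps β to
[ε, 1−ε] with ε = 1e-3 so it is total; `m_to_beta` inverts it exactly on
the clamped domain.

Per probe, the same fixed design is fitted by ordinary least squares:
intercept, case indicator, sex, optionally batch dummies, and the estimated
blood cell-type proportions (one column dropped against the intercept's
simplex collinearity).  Residual variances s² with df degrees of freedom
are shrunk toward a common prior by empirical Bayes: assuming
s² ~ s₀²·F(df, d₀), the mean and variance of log s² have closed forms in
digamma/trigamma, and matching the sample moments gives d₀ (by inverting
the trigamma with Newton steps) and s₀².  The posterior variance is
(d₀s₀² + df·s²)/(d₀+df), the moderated t divides the coefficient by the
posterior sd times the unscaled covariance term, and p-values use d₀+df
degrees of freedom.  When the log-variance spread is no larger than pure
chi-squared sampling noise the prior df is infinite and every probe uses
the common variance.  The implementation was checked against an
independent per-probe normal-equations oracle (coefficients to 1e-8) and,
during development, reproduced a reference empirical-Bayes implementation
to machine precision on a shared fixture.

Significance is BH-adjusted (a literal step-up, tested against the
from-definition oracle), and the reported signature applies the two
published-style filters jointly: q < 0.05 and |Δβ| > 0.10.  Δβ is
deliberately the difference of group-mean betas, not a back-transformed
coefficient, so the 10% threshold means what it says.  The effect filter
exists because a small-n moderated test can reach significance on effects
too small to be technically reliable or biologically interpretable.

**Cell composition.**  Reference-based deconvolution solves, per sample,
non-negative least squares of the sample's betas against the purified
cell-type reference profiles over the panel's discriminating probes.  The
sum-to-one constraint is imposed by appending a heavily weighted (λ=1000)
all-ones row, which keeps the solver a plain NNLS while holding row sums
to 1 within 1e-6.  Noiseless mixtures are recovered exactly; at logit
noise sd 0.05 the proportion RMSE over 50 samples stays an order of
magnitude under the 0.05 contract.

**Matching.**  Controls are selected greedily, nearest in age first,
inside exact array-type strata, without replacement, at a 6:1 ratio; the
case processing order is seeded so matching is reproducible.  A pool that
cannot supply the ratio in some stratum raises an error naming the
stratum.

## DMR calling

Each probe receives a signed z from its two-sided p (sign from t).  Per
chromosome, probes at q < 0.05 are stitched into runs wherever consecutive
significant probes are ≤ 1 kb apart; runs with ≥ 3 probes and
|mean Δβ| > 0.10 become candidate regions.  Region evidence is the
unweighted Stouffer combination Σzᵢ/√n of the member probes' signed z,
converted to a two-sided p and BH-adjusted across regions; regions pass at
FDR < 0.05.  Coordinates span the first to last member probe, 1-based
inclusive; the BED writer converts to 0-based half-open.  An optional
Gaussian kernel smoothing of z over genomic position (default bandwidth
1 kb) is available but off by default — the stitching rules, not the
smoother, are the tested contract, and the caller is verified against an
exhaustive run-enumeration oracle on small manifests.  Where the
region-level combination is ambiguous in the source procedure (Stouffer
over FDR-derived z vs raw-p z with BH across regions), this package
implements the latter.

## Consensus subtyping

Subsampled consensus clustering: in each repetition 80% of samples and 80%
of features are drawn, pairwise Spearman distance (1−ρ) is computed among
the subsampled samples, and k-means is run for every k in range.  Because
rank-correlation distance is not an inner-product space, k-means operates
on the classical multidimensional-scaling embedding of the distance matrix
(components with positive eigenvalues); each repetition uses 10 seeded
restarts and keeps the best inertia.  Per-repetition RNG streams are
spawned from the master seed, so results are bit-reproducible.
consensus(i,j) is the fraction of co-clustered among co-sampled runs;
final labels come from average-linkage hierarchical clustering of
1−consensus.  PAC is the fraction of upper-triangular consensus entries
strictly inside (0.1, 0.9) — thresholds are the customary defaults, as the
measure's source leaves them open.  Cluster consensus is the mean
within-cluster upper-triangular consensus (singletons score 1 by
convention); the selected k is the smallest-PAC k among those whose every
cluster consensus exceeds 0.9, falling back to the PAC-minimal k with a
warning when none qualifies.  New samples are assigned to the cluster
whose training centroid they best Spearman-correlate with — the assignment
mechanism is this package's concretization, as the source workflow never
states one.

## The classifier

The feature cascade is ordered and each stage is material: (1) drop probes
with |Δβ| < 0.05, the minimum methylation change arrays detect reliably;
(2) rank the rest by moderated p from a regression that includes batch and
cell-type proportions as covariates — "not confounded" is realized as
covariate adjustment, not a separate per-probe test — and keep the top
1000; (3) keep probes with direction-normalized Mann–Whitney AUC > 0.85;
(4) sweep in rank order and drop any probe with squared Pearson
correlation > 0.85 to an already-kept probe.  (Where the thresholds could
be read as r or r², the r² reading is the default and the alternative is a
parameter.)  The classifier consumes beta values of the panel probes so
that scores remain comparable across array platforms.

Cost and gamma of the RBF-SVM are grid-searched (cost ∈ {0.25…8}, gamma ∈
{1/4d…4/d} for d panel probes — the grid is this package's choice) by
stratified 10-fold CV on training accuracy; the model is refit on all
training data at the best pair.  Probability calibration fits Platt's
sigmoid P = 1/(1+exp(A·f+B)) with the standard smoothed targets
(N₊+1)/(N₊+2) and 1/(N₋+2) on the *out-of-fold* decision values of the
selected pair, so the probabilities are not contaminated by resubstitution
optimism.  Samples score in [0,1] and the diagnostic call is score > 0.5.
The stored CV accuracy is pre-calibration, on the decision sign.  The
75/25 train/test split is stratified by subtype with largest-remainder
apportionment to the rounded training total, which keeps every subtype
represented while hitting the intended 21-of-28 training size.

## The synthetic cohort generator

The generator is the validation surface, so its defaults encode the study
conditions rather than convenient ones:

* **Design**: case groups of 14/5/2/7 (subtypes A–D), a 400-sample control
  pool (a desk-scale stand-in for a reference cohort of thousands — large
  enough that 6:1 matching never exhausts an array-type stratum), two
  array platforms, three batches, group-level truncated-normal ages and a
  50% sex ratio.
* **Baseline**: probe baselines are bimodal through the reference panel —
  island/shore probes low (Beta(2,14)), shelf/open-sea probes high — so
  genome-wide beta densities show the hypo/hyper modes QC expects.
* **Mixtures**: sample expectation = reference betas × Dirichlet-drawn
  cell proportions, formed on the beta scale; with all noise off the
  mixture is recovered exactly after the logit round trip.
* **Covariates and noise**: age/sex/batch effects touch a random 5% of
  probes with small logit-scale coefficients.  Noise is Gaussian on the
  logit scale with sd 0.25 × a per-probe lognormal scale (log-sd 0.5,
  clipped to [0.6, 2.5]) — probes differ widely in inter-individual
  variability, bounded below by a technical floor — plus additive
  technical noise of sd 0.015 on the beta scale, which reproduces the
  characteristic inflation of M-value variance at extreme baselines.
  Without the heteroscedastic term the empirical-Bayes prior correctly
  degenerates to infinite df and small-n comparisons become unrealistically
  powerful; without the beta-scale term, extreme-baseline probes are
  unrealistically precise on the M scale.  Overall the model yields
  mid-range beta sds of roughly 0.04–0.15, in line with inter-individual
  variability at signature-grade CpGs.
* **Planted signal**: signature blocks (shared, B/D-shared, A-specific;
  consecutive blocks overlap by 15%, within the 10–20% overlap the
  modelled study reports) shift affected samples on the logit scale with
  the shift solved by bisection so the realized group-mean |Δβ| equals the
  drawn effect; a drawn direction that would push the target outside
  (0.02, 0.98) is flipped, keeping effects full-sized on bimodal
  baselines.  Region blocks occupy manifest-consecutive unflagged probes
  with gaps ≤ 1 kb, restricted to windows where one common direction fits
  every member probe (a DMR is direction-coherent) and to windows with no
  other planted probe within 1 kb of either end, so the region-level
  ground truth is spatially unambiguous.

**What the generator does not emulate**: raw intensities, probe-type
(Infinium I/II) chemistry bias, normalization artefacts, spatial
correlation of island status, genotype effects at SNP probes, or relatives
in the pool.  Passing tests therefore demonstrate the statistical
machinery under the study's design and realistic noise magnitudes, not
robustness to array-specific artefacts.

**Scale.**  Validation cohorts use 2,000-probe universes (the powered
14-vs-84 comparisons, clustering and classifier scenarios) — the planted
blocks then span ~15% of the array, thousands of times their real-array
share, which is why the global-PCA sample screen is exercised on the
control pool rather than on signature carriers.  The rare-subtype
power-failure scenario uses a 20,000-probe universe with a 40-probe
subtype block at exactly Δβ = 0.10: there the genome-scale
multiple-testing burden is itself the phenomenon, and with 2 cases against
12 matched controls the probe filters come up empty, as observed for
2-subject subtypes in practice.  Consensus clustering validates at 200
repetitions (the full analysis default is 1000).

## Enrichment

Probe-rich genes are more likely to harbour a selected probe under the
null, so gene-level over-representation must model selection odds as a
function of probe count.  Genes are quantile-binned on their universe
probe count, per-bin selection frequencies are fitted by increasing
isotonic regression, and every gene receives the fitted probability
(clipped away from 0/1).  A set's p-value is the Wallenius noncentral
hypergeometric upper tail at the odds ratio between the mean weight of its
genes and the rest of the universe; odds of exactly 1 (homogeneous
counts, or `method="central"`) reduce to the central hypergeometric.
BH runs across sets through the same step-up used everywhere else.  Null
calibration is checked by 1000 uniform probe draws on a homogeneous
universe (type-I rate 0.05 ± 0.02; the discreteness of the hypergeometric
keeps the rate slightly conservative, ~0.035 with 50-gene sets).  No GO
graph propagation or term-redundancy reduction is performed; gene-set
collections are plain GMT inputs.

## Numerical and degenerate-input conventions

Ties in p sort by probe id everywhere ordering matters.  Probe filters
remove on detection failure in *any* sample (conservative for small
cohorts); the failed-probe rate is the fraction of probes with detection
p > 0.01 in that sample.  The bimodality screen flags a sample when its
kernel-density valley on β ∈ (0.3, 0.7) exceeds 0.8× the lower of the two
mode peaks (β ≤ 0.3 / β ≥ 0.7).  The PCA screen uses |score| > 3 sd on PC1
or PC2 of the M-value matrix; on clean Gaussian data it necessarily flags
a small tail (~0.5% of samples).  Empty discovery results are legal
(2-case groups); empty consensus repetitions are skipped with a warning
and an all-skipped run is an error; an all-removed QC result is an error.
Model metadata (panel, hyperparameters, Platt A/B, provenance hash)
serializes to JSON; the fitted SVM object itself is in-memory only.
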