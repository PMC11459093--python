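# Methods

This note documents the models, conventions, and numerical choices behind
`chronophylo`, and what the synthetic test bed does and does not emulate.

## Phylogenetic diversity metrics

All metrics operate on a rooted tree with branch lengths. Tip labels are
normalised (whitespace trimmed, spaces → underscores) so trees and survey
tables match by exact string comparison. Pruning collapses unary nodes with
branch lengths summed, so patristic distances among retained tips are
invariant (property-tested on random trees).

**Faith's PD** uses the root-inclusive convention: the spanning subtree is
anchored at the root, so a monoculture's PD is its root-to-tip distance.
This is the classic definition; `include_root=False` switches to the
MRCA-anchored variant.

**PSV/PSR/PSE** are built from the phylogenetic correlation matrix
C = V/√(diag V · diag Vᵀ), where V_ij is the shared root-to-MRCA branch
length, computed for arbitrary (also non-ultrametric) trees via
V_ij = (tᵢ + tⱼ − d_ij)/2 from tip depths t and patristic distances d.
The PSE closed form
(N·Σ mᵢCᵢᵢ − m′Cm)/(N² − N·N/k)
was cross-validated against the R reference implementation of the
Helmus-family metrics (`picante::psd`) on ultrametric and non-ultrametric
trees before freezing; it reduces to PSV exactly at equal abundances and is
invariant under scaling all abundances by a common factor (property-tested).

**MPD/MNTD** are presence-based (unweighted) by default, matching the
"average distance among all species" reading used for NRI/NTI;
abundance-weighted variants are available via a `weights` argument but are
not used in the default pipeline.

Metrics needing ≥ 2 species return `nan` with a logged warning for
monocultures; downstream stages drop those rows rather than failing.

## Null models (NRI/NTI)

The null is richness-preserving: each of `n_reps` (default 999) replicates
draws k species uniformly without replacement from the pool — by default
every tip of the pruned regional phylogeny — and the score is
−(observed − null mean)/null sd, with the sample (n−1) sd of the replicate
distribution. Degenerate nulls (sd < 1e−12, e.g. k = pool size, or any
subset of a star tree) are flagged undefined, never reported as 0.

Pool choice per analysis level: the total community is scored against the
whole phylogeny; herb and woody communities against their life-form
subpools (configurable, since either convention is defensible).

Per-plot RNG streams derive from the master seed and a CRC32 hash of the
plot id, so results are independent of plot iteration order and
bit-reproducible. A taxa-label-shuffle mode is provided; for presence-based
metrics it is distributionally identical to pool draws.

Monte-Carlo moments are tested against exhaustive subset enumeration; the
sd comparison uses a kurtosis-aware standard error, because null MPD
distributions are skewed and the normal-theory sd error is too tight.

## Biomass accounting

AGB (g/m²) = herb + litter + woody densities, exactly additive. Herb boxes
are 1 m²; litter boxes 0.317 m × 0.317 m (0.100489 m²); plot densities are
means over (by default three) boxes of each kind. Woody biomass evaluates
registered allometric equations per stem — forms B = a·Dᵇ, B = a·(D²H)ᵇ,
and ln B = a + b ln D, with component (stem/branch/leaf) rows summed — and
divides the plot total (kg → g) by plot area. Model lookup falls back
species → genus → life-form default, each fallback logged. Inputs are
assumed oven-dry; no moisture correction. The shipped registry contains
documented placeholder coefficients on the scale of temperate-forest
allometries (a ≈ 0.06–0.1, b ≈ 2.4 for B = a·Dᵇ in kg, D in cm); it is an
editable CSV, not a literature compilation, and the synthetic generator
uses the same registry so analyses are internally consistent.

## Chronosequence statistics

Normality is checked by Shapiro–Wilk and variance homogeneity by Levene
(mean-centered). The normalising-transform search tries identity, then log
(with an automatic positive shift when values are ≤ 0), then a Box–Cox
power fit, returning the first transform passing Shapiro–Wilk at α = 0.05,
else the best-W candidate flagged as failed. Note that strongly multimodal
responses (e.g. AGB spanning three orders of magnitude across stages)
legitimately fail all three; the flag propagates rather than aborting.

Trend fits are degree-2 least-squares polynomials (configurable degree)
with the overall F-test p, R², a pointwise 95% confidence band, and an
interior peak location reported only when the quadratic coefficient is
negative and the vertex lies inside the observed range.

Duncan's multiple range test uses studentized-range quantiles at protection
level (1−α)^(p−1) for a span of p means, critical range
R_p = q·√(MSE/n_h) with harmonic-mean group size, the step-down containment
rule, and a compact letter display in which the largest mean gets "a".

## Inference layer

The mixed model is a Gaussian random-intercept model (recovery stage as the
grouping factor) on possibly transformed AGB — the faithful reading of a
"GLMM" whose response has been transformed to normality. Predictors are
z-scored so t-values are comparable across levels. Variance components come
from REML; AIC from an ML refit so fixed-effect structures are comparable.
R²m/R²c follow the variance-components definition: σ²_fixed over (and plus
σ²_stage over) the total of fixed, stage, and residual variances. Vanishing
stage variance is reported as a flagged boundary fit.

VPA partitions adjusted R² between a diversity set (PD, PSE) and a
structure set (NRI): unique fractions are full-model adjusted R² minus the
other set's, the shared fraction closes the identity exactly (tested to
1e−8), and negative fractions — an adjusted-R² artifact — are reported
unclipped with a clipped display option. Fractions are reported both as
shares of total variance and of explained variance, since either
normalisation is seen in practice.

The PLS path model uses a reflective (mode A) outer model and the path
inner weighting scheme: predecessor weights are multiple-regression
coefficients, successor weights correlations; outer weights iterate until
the maximum absolute change is < 1e−6 (cap 300 iterations; single-indicator
blocks converge immediately). Inner paths are OLS on the unit-variance
latent scores, communality is the mean squared loading, and
GOF = √(mean communality × mean endogenous R²). With single-indicator
blocks the estimates coincide with standardized recursive path analysis to
1e−6 (oracle-tested). Path significance comes from a seeded nonparametric
bootstrap (default 500 resamples). The default inner model is
TVR → {diversity, structure} → AGB; a direct TVR → AGB path is off by
default and toggleable. Default estimation choices (mode A, path scheme)
are the conventional ones and are exposed as configuration.

## Synthetic chronosequence generator

The generator emulates the study design the pipeline targets: 8 recovery
stages (0, 10, 20, 40, 70, 120, 135, 150 years) × 6 plots, a 130-species
pool on a unit-depth pure-birth (Yule) tree, Brownian traits, and
clade-clumped life forms (a second Brownian trait thresholded at the herb
share of the pool, 79/128).

Community assembly combines the two canonical processes. Environmental
filtering samples species within each life form with Gaussian weights
exp(−(trait − optimum)²/2σ_f²); the stage optimum drifts linearly from
−0.5 to +0.5 (trait units; tip trait variance ≈ 1) and σ_f shrinks from
3.0 (essentially neutral) to 0.2 by stage 120, then relaxes. Competition
(limiting similarity) replaces, with stage probability c rising to 0.95 at
stage 150, the less-abundant member of the phylogenetically closest pair
with the most distant available species. Defaults were calibrated once so
the generator's three contractual patterns hold: a unimodal total-community
PD trend, late-stage NRI moving from aggregation (stage 70 positive) to
dispersion (stages 135–150 negative), and AGB peaking at stage 135 (a
two-dominant mixed stand) above stage 150 (single-dominant stand) above
stage 70.

Biomass realism is target-driven: per-stage component densities (herb,
litter, woody; woody up to ~23 kg/m² dry mass at the stage-135 peak) with
lognormal plot noise (CV 0.2); stems are drawn from stage-specific
lognormal diameter distributions (means 3 → 28 cm) and accumulated until
the plot reaches its target, with the late-stage dominants carrying ~75% of
stems. Survey, stems, harvest, plots, and registry files round-trip through
the pipeline readers byte-identically for a fixed seed.

Two measured properties of the design are worth knowing when interpreting
test results. First, because life forms are clade-clumped, stratified
sampling at life-form quotas different from the pool's own woody share is
*not* neutral against a whole-pool null (measured bias ≈ −0.4 at a 50%
woody quota); the neutral regime is quotas at pool proportions, where the
measured mean NRI is ≈ −0.05. Second, trait-band filtering on a Brownian
trait saturates near mean NRI 0.3–0.5 — trait proximity only partially
tracks phylogeny — so "strong filtering" in this generator means clearly
positive NRI, not arbitrarily large.

What the generator does not emulate: demographic forest dynamics (growth,
mortality, gap formation), spatial structure and dispersal limitation,
measurement error in diameters, name-resolution noise, or a dated empirical
megatree. Passing tests therefore demonstrate correctness of the estimators
and the qualitative soundness of the assembly logic, not calibration to any
particular real flora.

## Problem sizes and determinism

Default analyses use 999 null replicates × 48 plots × 3 levels and a
500-resample bootstrap; the full synthetic pipeline completes in well under
a minute on one CPU. The test suite scales simulations to what makes each
property sharp (e.g. 500 communities for null-mean checks, 100 seeds for
power checks, exhaustive enumeration only where C(n,k) ≤ 10⁵). Every
stochastic stage takes an explicit seed; one master seed propagates through
fixed spawn tags, so all outputs are bit-reproducible.

## Known limitations

- "GLMM" is a Gaussian linear mixed model on transformed response; count or
  gamma families are not fitted.
- Duncan letters assume the one-way layout; no repeated-measures or spatial
  autocorrelation corrections.
- The bootstrap treats plots as exchangeable (no stage-stratified
  resampling).
- PD/PSE behaviour with zero-length terminal branches is untested territory;
  the readers reject negative, but not zero, branch lengths.
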