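# Methods

## Index definitions and conventions

The fasting indices are computed from fasting glucose `G0` (mmol/L) and
fasting insulin `I0` (µU/mL), the unit convention under which the HOMA-IR
denominator 22.5 (a "normal" `G0·I0` product) and FIRI's 25 are defined.
QUICKI and revised QUICKI use base-10 logarithms, the convention of the
index's originating literature; the inter-index transformations use the
matching base (`HOMA-IR = 10^(1/QUICKI) / 22.5`). Every rank-based result
in this package is invariant to the choice of logarithm base, since
changing base is a strictly monotone re-parameterisation.

The OGTT-based indices are documented in their customary units — Matsuda
with glucose in mg/dL and insulin in µU/mL, Stumvoll with 120-min insulin
in pmol/L and 90-min glucose in mmol/L — and the package performs no unit
conversion, silent or otherwise: feeding values in other units produces
numbers on a different scale (though, again, identical ranks). Matsuda is
implemented as 10000 *divided by* the square root of the four-concentration
product, the established definition. Missing OGTT fields fail per index
with an explicit error; values are never imputed, because imputation would
change the semantics of the index.

`transform_index` recovers the common driver `P = G0·I0` from any of the
fasting trio and re-expresses it as the target index. Round trips are exact
to ~1e-15 relative; the HOMA-IR/FIRI ratio equals 25/22.5 to double
precision (bitwise equality of a quotient of two rounded divisions is not
attainable in IEEE arithmetic, and is not claimed).

## The evaluation toolkit

Pearson correlation is computed directly from its definition
`Σ(xᵢ−x̄)(yᵢ−ȳ) / √(Σ(xᵢ−x̄)²·Σ(yᵢ−ȳ)²)`; Spearman is Pearson applied to
mid-ranks (tied observations receive the average of their rank block).
One numerical detail matters for the equivalence demonstration: the
denominator is evaluated as a *single* square root of the product of the
two sums of squares. For exactly reversed rank vectors the centred vectors
are exact elementwise negations (half-integer arithmetic is exact in
doubles, and rounding-to-nearest is symmetric under negation), so the
numerator is the exact negation of the sum of squares and
`sqrt(s·s) == s`, making the reported Spearman correlation exactly −1.0
rather than −1 ± 1 ulp. The equivalence verdicts therefore assert bitwise
equality, not a tolerance.

`spearman_to_pearson(ρ) = 2·sin(ρπ/6)` assumes bivariate normality and is
unreliable for the skewed distributions typical of insulin-sensitivity
measures; it is provided for meta-analytic comparability. Inputs ±1 are
returned exactly (the floating evaluation of `2·sin(π/6)` is 1 − 1 ulp).
No confidence intervals for correlations are produced: their standard
forms assume bivariate normality, which these data violate.

ROC curves sweep the distinct oriented score values from most to least
extreme; tied scores move as a block (one vertex per distinct value), and
the AUC is the trapezoidal area, which equals the tie-corrected pairwise
probability `(wins + ½·ties)/(n₊·n₋)` — the package ships that brute-force
oracle (`auc_probability_oracle`) as an independent check. Sensitivity-up
indices (QUICKI and friends) are oriented by negating the scores
(`lower_is_positive`), after which all three fasting indices produce the
identical point set against any label.

Mann-Whitney uses the normal approximation with mid-ranks, tie correction
and a continuity correction of ½ shrinking toward the null, two-sided; the
statistic reported is U for the first group. Exact enumeration is not used
at runtime (the identity-across-indices property holds under either); the
tests validate U against brute-force pair counting and the p-value against
an independent implementation. The parametric comparator is Welch's
unequal-variance t-test, the safer default when no variance homogeneity is
known; the divergence between indices under parametric testing holds for
any t-variant. Two-sided testing is used throughout, as the neutral choice
for a method-comparison demonstration.

## The synthetic cohort generator

The generator emulates a cross-sectional cohort in which all three fasting
indices and a clamp measurement are available:

* `G0 ~ Lognormal(μ_g, σ_g)` and `I0 ~ Lognormal(μ_i, σ_i)`, independent.
  Defaults: `μ_g = ln 5.4, σ_g = 0.11` (median fasting glucose
  5.4 mmol/L, tight physiological spread) and `μ_i = ln 8, σ_i = 0.5`
  (median fasting insulin 8 µU/mL with the wide right skew typical of
  insulin). These are configuration values, not constants.
* `M_LBM ~ Lognormal(μ_m, σ_m)` with defaults `μ_m = ln 6.5, σ_m = 0.45`,
  giving ≈ 24 % resistant subjects under the strict cutoff
  `M_LBM < 4.7 mg/(kg·min)` (a subject exactly at the cutoff is not
  resistant).
* Coupling: let `S = ln G0 + ln I0` and let
  `X = −(S − E[S])/SD[S]` be the standardized latent *sensitivity* score
  (QUICKI is strictly increasing in X). The log-scale driver of `M_LBM`
  is `Z = r·X + √(1−r²)·ε` with independent standard-normal ε, so the
  marginal of `ln M_LBM` is exactly the configured normal for every `r`.
  The latent correlation `r*` is found by bisection so that the raw-scale
  `Pearson(QUICKI, M_LBM)` equals the configured target (default 0.75,
  interpreted on raw scales). The achieved raw-scale correlation is a
  smooth, strictly increasing function of `r` evaluated by a
  common-random-numbers Monte Carlo (default size 100,000) at a fixed
  internal seed, so calibration is deterministic given the configuration
  and independent of the cohort seed; a target of exactly 0 short-circuits
  to `r* = 0` (true independence). An unattainable target raises an error
  reporting the closest achievable correlation. A Gaussian latent coupling
  was chosen because both drivers are normal on the log scale while the
  induced raw-scale Pearson has no convenient closed form.

What the generator does **not** emulate: measurement error and replicate
visits (so repeatability/reproducibility questions are out of scope),
OGTT time courses, treatment effects, and any real cohort's parameter
values — the defaults are plausible, not fitted. Passing tests therefore
show that the *mathematical* equivalence claims hold on data with the
stated distributional shape; they say nothing about how well any index
tracks a clamp in a particular population. In particular the AUC of the
indices against the resistance label is a free function of the marginal
parameters even after the 0.75 calibration (≈ 0.88 under the defaults
here), so published AUC values from other datasets are reproduced only
with those datasets' parameters.

## Study pipeline

`run_study` evaluates the fasting trio on one cohort: both correlation
coefficients between indices, correlations of each index with `M_LBM` and
with `log M_LBM` (Spearman entries identical between the two panels by
construction, Pearson entries not), per-index ROC/AUC against the
resistance label, and Mann-Whitney plus Welch tests for a median split of
`M_LBM` — a deterministic two-group split chosen because the equivalence
property is split-agnostic. For the Mann-Whitney identity the
sensitivity-up index is orientation-reversed (negated) so the U statistic,
not just the two-sided p, coincides across indices; Welch tests run on the
raw index values. Verdicts are booleans accompanied by the largest
observed discrepancy; an undefined correlation (n < 3 or constant series)
is reported as `undefined`/NaN and fails the verdict rather than being
fabricated.

Cohorts are written and read as CSV with `%.17g` floats and round-trip
parsing, so save → load is value-exact; XLSX ingestion (header-matched
case-insensitively) is supported for externally supplied cohort tables.
Reports are a human-readable text file plus CSV tables; writing is
deterministic, so re-running a seeded study is byte-identical.

## Problem sizes

Default cohorts are n = 1,000; headline correlation checks use n = 10,000
with the 100,000-draw calibration Monte Carlo (sub-second in total). The
property sweep over randomized configurations uses 100 small cohorts
(n = 40–120) with a reduced calibration Monte Carlo, since the rank
identities under test do not depend on calibration accuracy.
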