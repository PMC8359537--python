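# Methods

## Scope and model

`cmetspipe` analyses one biallelic SNP (labels AA/AG/GG, risk allele A by
default) against a continuous metabolic-syndrome severity score in a
cross-sectional cohort, with body-fat-distribution variables as candidate
mediators.  Everything is linear-Gaussian: the score construction, the
path analysis and the synthetic generator all assume additive effects and
homoscedastic normal noise.  Heavier-tailed errors, interactions,
multi-locus genetics and longitudinal structure are out of scope.

## cMetS score

For each component v ∈ {WC, MAP, FBS, HDL, TG} the score fits
`v = β0 + β1·age + ε` by OLS and takes `z = ε̂ / s`, where `s` is the
residual sample SD (n−1 denominator) by default, so each component is
exactly mean-0/SD-1 and exactly uncorrelated with age on the fitting
cohort.  A `standardize_by="component_sd"` option divides by the raw
component SD instead (both conventions appear in the applied literature;
the residual-SD default matches the z-score framing).  MAP is derived as
`(SBP − DBP)/3 + DBP` before fitting.  The HDL z is negated *after*
standardization.  `z_total` is the sum of the five (signed) components.
Residual standardization makes the score invariant to affine unit changes
of any raw component (mg/dL ↔ mmol/L) to numerical precision.

The fitted slopes, intercepts and scales are stored on the scorer, so
held-out subjects can be scored against a reference cohort's
transformation.  The cohort is modelled as all-female (as in the kind of
study this pipeline targets), so no sex term exists anywhere.

Degenerate inputs raise explicit errors: components constant or perfectly
linear in age (zero residual variance), constant age, n < 10.

## Screening

Normality screening reports, per variable, the one-sample KS statistic
against a normal with the sample's own mean/SD plus a Lilliefors-corrected
p-value (the naive KS p is anti-conservative with estimated parameters,
via `statsmodels`' table-based Lilliefors implementation).  Screening is
advisory only and never removes rows.

Outlier removal is a single-pass univariate rule: remove a subject when
|z| > threshold (default 3.0) in *any* screened variable, with means/SDs
computed once on the input cohort, never iteratively.  The underlying
study style reports only "outliers removed", not a rule; the rule and
threshold are therefore exposed configuration, and we make no claim of
reproducing any particular published subject count.

## Genetics

Allele frequency is `(2·n_AA + n_AG) / (2n)`.  The HWE test is the exact
conditional test: given n and the minor-allele count, the probability of
h heterozygotes is ∝ `n!/(n_rare! h! n_common!)·2^h` over all h of the
right parity; the two-sided p sums probabilities ≤ the observed outcome's.
For n ≤ 2000 the weights are exact integers (`math.comb`), which makes
tie comparison exact; above that, log-space gammaln arithmetic with a
1e-12 relative tie tolerance.  A Lancaster mid-p variant is available
behind a flag (off by default).  Monomorphic samples return p = 1, and the
p-value is floored at the smallest positive float rather than
underflowing to 0.

A note on printed genotype counts of the form 103/90/193 with allele
frequency 0.3834: such counts carry a massive heterozygote deficit
(~90 observed vs ~182 expected under HWE) and the exact test returns
p ≈ 1e-23.  The implementation reports what the arithmetic gives; it is
not tuned to agree with any published claim of HWE consistency.

## Mediation

Three OLS regressions with a shared covariate set: `a` from M ~ X + C;
`b` and `c′` from Y ~ X + M + C; `c` from Y ~ X + C.  Using the same
covariates everywhere makes `c = c′ + a·b` an algebraic identity, which
the test suite asserts at 1e-10 universally.  Covariates are internally
z-scored purely for conditioning (this cannot change the coefficients on
X or M).  Full-sample fits use SVD least squares; rank deficiency raises
an error naming the offending columns.

Standardization follows the partial convention for a binary exposure:
M and Y are z-scored, X stays 0/1, so the standardized indirect effect is
`a·b / SD(Y)`.

The bootstrap resamples subjects (rows) with replacement, preserving the
joint X–M–Y–C dependence, and refits `a·b` on each resample via batched
normal-equation solves (eigenvalue check for singularity; degenerate
resamples are redrawn and counted, >10% raises an error).  On the
standardized scale each resample's estimate is divided by that resample's
own outcome SD, so scale uncertainty propagates into the interval.
Percentile intervals use linear interpolation between order statistics;
bias-corrected (BC) intervals shift the quantile positions by
`z0 = Φ⁻¹(fraction of bootstrap draws strictly below the point estimate)`
(clipped to (1/(B+1), B/(B+1)) to keep the probit finite) and reduce
exactly to percentile when z0 = 0.  BC is the default (the convention in
PROCESS-style analyses); acceleration (BCa) is deliberately not included.
A degenerate bootstrap distribution (all draws equal) collapses the
interval to the point estimate.

Proportion mediated is `a·b / c`, reported as undefined when |c| ≤ 1e-8
and flagged inconsistent when indirect and total effects disagree in sign.
Mediators are always fitted as separate single-mediator models (matching
the two-panel convention of such studies); a joint parallel-mediator fit
(`fit_parallel_paths`, point estimates only) exists for sensitivity
checks.

Random-number contract: `run_mediation` spawns one independent
`SeedSequence` child per mediator from the master seed, so adding a
mediator to the request list never changes the earlier models' intervals,
and point estimates never depend on the seed at all.

## Synthetic cohorts and ground truth

The generator emulates the study design the pipeline assumes:

* genotypes i.i.d. in HWE proportions (p², 2p(1−p), (1−p)²) at
  `p_risk` (default 0.3834);
* age ~ truncated normal (36.67 ± 9.1 y on 18–55), energy intake ~
  truncated normal (2200 ± 550 kcal/d, ≥ 800);
* mediators `VFL = 13.7 + a_vfl·X + 0.05·age + ε` (σ = 2.9) and
  `TBF = 30.5 + a_tbf·X + 0.08·age + ε` (σ = 8.5), X the dominant coding;
* each component linear in VFL, TBF, X and age with Gaussian noise, HDL
  with negative coefficients; intercepts sized to overweight-female
  reference means (WC ≈ 100 cm, MAP ≈ 90 mmHg, FBS ≈ 90 mg/dL,
  HDL ≈ 48 mg/dL, TG ≈ 120 mg/dL);
* DBP = MAP − pp/3 and SBP = DBP + pp with pulse pressure pp from a
  truncated normal (40 ± 8 mmHg, ≥ 10), so the MAP formula recovers the
  model's MAP identically and SBP > DBP always.

Because the model is linear-Gaussian, every population path coefficient
of the X → M → cMetS chain has a closed form (`true_effects`): each
component's population age-residual is
`A_k(X−μ_X) + b_vfl,k ε_v + b_tbf,k ε_t + ε_k` with
`A_k = b_vfl,k a_v + b_tbf,k a_t + c_k`; dividing by its SD and summing
(HDL negated) makes the score linear in X and the independent noise
sources, from which a, b, c, c′, the SDs and the standardized indirect
effect follow exactly.  `config_with_true_indirect(t)` rescales the
genotype→mediator path by Brent root-finding so the population
standardized indirect equals any requested t exactly — this is what
recovery and coverage checks measure against.

The default ("paper-like") preset fixes n = 386 and sizes effects so the
VFL pathway is detectable at that sample size (standardized indirect
≈ 0.19, ≈ 35% of the total effect) while the TBF pathway is essentially
null (genotype→TBF real, TBF→components ≈ 0): the qualitative pattern of
one significant and one non-significant mediator.  A consequence of this
choice is that the preset does *not* make TBF marginally associated with
the score — only the detectability pattern, not every marginal
association, is emulated.  `null_config()` removes every genotype effect
(a = 0, direct effects 0) while keeping the mediator→outcome paths: the
classic "a = 0, b ≠ 0" null used for type-I calibration.

What passing tests on these cohorts show — and what they do not: the
estimators recover known linear-Gaussian truth, the identity and
invariance properties hold, and the BC bootstrap is calibrated under this
generative family.  Real cohorts have skewed TG distributions, measurement
error, missingness patterns and population structure that the generator
deliberately omits; results on synthetic data bound implementation
correctness, not real-world robustness.

## Problem sizes in the test suite

Simulation-based checks use sizes chosen to keep Monte-Carlo error well
inside the asserted bands: CI coverage at n = 386 over 300 replicates of
1000 resamples; estimator recovery (truth 0, 0.1, 0.2) at n = 5000 over
100 replicates each; null calibration over 2000 replicates (the
exclusion-rate SE is then ≈ 0.5%, comfortably below the margin between
the measured ~4.9% rate and the asserted 6% bound); the qualitative
preset pattern over 100 replicates.  The HWE implementation is compared
against a brute-force exact-rational enumeration oracle for every
genotype triple with n ≤ 50 (≈ 23k cases) at 1e-12.

## Known limitations

* The exact HWE test is bit-exact only up to n = 2000; beyond that the
  log-space path is accurate to ~1e-12 relative but not exact.
* BC intervals (no acceleration) are known to be slightly anti-conservative
  for product effects when one path is null; measured here at ~4.9%
  exclusion at nominal 5% under the a = 0 null.
* Complete-case handling per analysis; no imputation.
* The score's fitted transformation is cohort-relative: z-scores from
  different cohorts are not directly comparable unless one cohort's
  stored fit is applied to the other.
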