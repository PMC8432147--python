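# Methods

## Recruitment model

Each of the N pool members carries a d-vector of covariates **x**;
binary covariates are coded −1/+1 and continuous covariates are used on
an anchored scale (see *Covariate scaling*). The protocol assigns every
individual a recruitment probability ρ(**x**) chosen so that the
recruited cohort's covariate distribution is, in expectation, uniform —
exactly uniform over the two levels of a binary covariate, and uniform
between the 0.05 and 0.95 pool quantiles of a continuous covariate
(a covariate with unbounded support cannot be uniformized globally;
truncating at these quantiles is a pragmatic compromise that leaves the
10% of individuals in the thin tails maximally weighted).

* Binary, pool +1-proportion p: unnormalized weight (1 − p) for +1 and
  p for −1, normalized by c = Σ_i ρ(x_i). The single-draw probability of
  recruiting a +1 individual is then exactly 1/2 for every p ∈ (0, 1) —
  an identity the test suite asserts symbolically. p ∈ {0, 1} is a hard
  error (the rule is undefined); an explicit `fallback_uniform` flag
  opts into uniform weights instead, so degenerate data cannot silently
  pass through.
* Continuous: unnormalized weight q/(c′ p̂(x)) inside [x_l, x_u] and 1
  outside, with q = 1/(x_u − x_l) and c′ = max_{[x_l,x_u]} q/p̂(x), so
  every unnormalized weight lies in (0, 1].
* Multiple covariates: the row-wise product of marginal weights,
  renormalized. This balances each marginal only approximately (exact
  marginal uniformity is not guaranteed by a product rule); for
  all-binary covariates the jointly balanced protocol instead draws
  exactly n/2^d individuals uniformly from each joint stratum, which is
  feasible only when every stratum holds at least n/2^d members.

## Density estimation

p̂ is a Gaussian kernel density estimate with Silverman's bandwidth
(`scipy.stats.gaussian_kde`); a density-normalized histogram is
available behind `method="histogram"` for auditability. The estimator
choice is a genuine degree of freedom — any smooth estimate of the pool
density serves; KDE is the default because the weight profile it
produces is smooth. p̂ is floored at 1e−12 before division so weights
stay finite, and c′ is maximized over a 512-point grid on [x_l, x_u].
Quantiles use the linear-interpolation empirical definition, and the
quantile levels (0.05, 0.95) are configurable.

## Cohort sampling

Cohorts are drawn *without replacement* by successive weighted draws
with renormalization among the remaining pool
(`numpy.random.Generator.choice(..., replace=False, p=ρ)`). The
per-individual probabilities are single-draw targets; under successive
sampling the realized inclusion probabilities only approximate them,
with an O(n/N) bias against small weighted groups (the minority level is
depleted faster than the majority, shifting later draws). At the
package's default scales (n/N ≈ 5%) the effect on the mean cohort
composition is below 0.01 in the +1 fraction; the balance tests
therefore assert |mean fraction − 0.5| < 0.02 rather than equality at
Monte-Carlo resolution. For exact balance with binary covariates use the
jointly balanced protocol.

## Covariate scaling

Continuous covariates are linearly rescaled so their 0.05/0.95 pool
quantiles map to −1/+1 (the same anchors as the binary coding), which
makes coefficient magnitudes comparable across covariate types. A
zero-mean normal covariate already anchored this way has standard
deviation 1/Φ⁻¹(0.95) ≈ 0.608 — the default scale of the
single-continuous-covariate pool generator.

## Synthetic pools

* `generate_binary_pool` draws two −1/+1 covariates i.i.d. from an
  explicit 4-cell joint distribution; the default (0.4, 0.3, 0.2, 0.1)
  over ((+,+), (+,−), (−,+), (−,−)) is deliberately non-uniform so
  balancing protocols have something to correct.
* `generate_normal_pool` draws one Normal(μ, σ²) covariate
  (default μ=0, σ=0.608).
* `generate_ehr_pool` draws 30 covariates — 21 Bernoulli at prevalences
  from published summaries of a UK stable coronary artery disease
  registry (e.g. male 57.2%, diabetes 15.4%, hypertension 88.2%) and 9
  normal with the published mean and 5th–95th percentile span (e.g.
  systolic BP 140.5 mmHg, span 110–178). Columns are **mutually
  independent**: only marginal summaries are public, so the real
  registry's correlation structure is deliberately not modelled. Tests
  passing on this pool therefore demonstrate marginal-balance behaviour,
  not robustness to correlated covariates.

Outcome generators: logistic, p(y=+1|**x**) = 1/(1+exp(−w₀−**w·x**));
and a proportional-hazards mechanism with exponential baseline
(rate·exp(**β·x**)), independent exponential censoring, and an optional
administrative horizon. The PH generator is the simplest mechanism
consistent with a Cox analysis; the censoring rate is calibrated by
bisection so the expected event fraction hits a target (default 23%,
matching the registry's death rate). With β=0 the event fraction follows
the competing-exponentials closed form r/(r+c), which the tests use as
an oracle.

## Evaluation metrics

Power is the proportion, over replicates and over coefficients with
nonzero generating value, of two-sided Wald tests significant at α
(default 0.05, uncorrected — deliberately, as is standard in these
simulation designs); type-I error is the same proportion over zero-truth
coefficients; MSE is the mean squared deviation of non-intercept
estimates from the generating values. The intercept is excluded from all
three (its near-certain significance under w₀≠0 would inflate power).
Monte-Carlo standard errors use the binomial formula for proportions
(denominator = replicates) and the empirical SE for MSE. Logistic fits
use `statsmodels` maximum likelihood (separation and non-convergence are
flagged, not raised, and flagged replicates are excluded from
summaries); Cox fits use `lifelines` with Efron tie handling.

## Experiments

Power curves fix the pool once per experiment and re-randomize outcomes
and cohort draws each replicate, isolating recruitment-protocol variance
from pool-sampling variance (regenerating the pool per replicate is
available by calling the runner with fresh pools). Per-cell seeds derive
from the master seed by hashing (master, protocol, n, replicate), so
runs are reproducible end to end and cells are independent. The
90%-power sample size is read from the isotonic-regression-smoothed
curve (power is monotone in n up to Monte-Carlo noise; raw threshold
crossing is seed-noisy), reporting both the smallest grid point at or
above the target and the linear interpolation between the bracketing
grid points. In the curve runner the jointly balanced protocol uses
largest-remainder quotas when n is not divisible by the stratum count;
direct calls to `jointly_balanced_sample` require exact divisibility
unless `allow_remainder=True`.

The continuous-covariate experiment defaults to logistic truth
w₀ = −1/4, w = −1/2 on the σ = 0.608 pool. An asymptotic Wald-power
calculation from the Fisher information under the exact pool and cohort
densities gives 90%-power sample sizes of ≈295 (selective) and ≈493
(random) for these values, consistent with the Monte-Carlo estimates
(≈275 and ≈490 at 500 replicates); the test suite freezes this analytic
oracle.

The EHR-style study generates the 30-covariate pool (default
N = 82 089), draws one generating β (seeded; 3 randomly chosen
coefficients exactly zero, the rest with magnitudes uniform on
[0.05, 0.25] and random signs — large enough that the full-pool fit
detects essentially all of them, small enough that a 1000-cohort fit
detects only a subset), simulates outcomes once for the whole pool,
fits the full-pool reference Cox model, then splits the pool into 10
sub-pools and recruits a cohort of 1000 from each under the selective
and random protocols. Reported per protocol: mean overlap with the
reference fit's significant coefficients, mean squared coefficient
difference to the reference, median minority ratio (minority/majority
count per binary covariate), and mean number of truly nonzero
coefficients recovered. Because the generating truth is known, recovery
can be measured directly — something impossible with a real registry,
where the full-data fit is itself only an estimate.

## Numerical and degenerate-input choices

* Weight vectors must sum to 1 within 1e−9 (asserted at construction).
* Products of ≥2 marginal weight vectors stay far above double-precision
  underflow at realistic d (30 covariates, N ≈ 10⁴: magnitudes ≳1e−120).
* Observed survival times are floored at the smallest positive double
  (Cox fitters require strictly positive durations).
* Constant columns raise dedicated errors in density estimation,
  rescaling, and binary weighting rather than producing NaN weights.
* A cohort of size n = N returns the whole pool under any weights.

## Problem sizes

Defaults were chosen so every simulation is a desk-scale computation:
power curves use 13 grid points × 500 replicates on N = 10⁴ pools
(~30 s on one CPU); the type-I study 2000 replicates × 3 protocols
(~15 s); the split-pool survival study N = 82 089 with 10 sub-pools
(~1 min, dominated by the full-pool Cox fit). The example scripts use
reduced replicate counts and pool sizes and say so inline.

## Known limitations

* Uniformity is an in-expectation, single-draw property; successive
  without-replacement sampling realizes it only approximately (above).
* The marginal product rule does not guarantee uniform marginals, and
  with strongly correlated covariates marginal balancing can be much
  less effective than joint balancing.
* The EHR-style generator calibrates marginals only; conclusions about
  correlated real-world registries require real data.
* Selective recruitment deliberately sacrifices representativeness of
  the pool for informativeness; estimates remain consistent for the
  generating model, but a misspecified model biases selective and random
  designs alike, and descriptive pool-level statistics should not be
  computed from a selectively recruited cohort.
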