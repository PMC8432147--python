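# selrecruit

Selective recruitment of informative study cohorts from large covariate
pools — with a Monte-Carlo framework for quantifying the resulting gains
in statistical power.

## The problem

Large electronic health record (EHR) databases make it possible to
*choose* whom to invite into a prospective observational study: the
covariates **x** of millions of eligible individuals are already
recorded, while the outcome *y* of interest still has to be measured on
the recruited cohort. Randomly sampling *n* of the *N* eligible
individuals reproduces the pool's covariate distribution — including its
imbalances — in the cohort. A cohort in which each covariate is instead
close to *uniformly* distributed makes more efficient use of the same
*n*: observations are spread evenly through covariate space rather than
concentrated where the pool happens to be dense, which increases the
statistical power for detecting covariate–outcome associations.

`selrecruit` implements this selective recruitment protocol:

* **Binary covariate** coded x ∈ {−1, +1} with pool proportion
  p = P(x = +1): recruit with probability ρ(x) ∝ (1 − p) for x = +1 and
  ρ(x) ∝ p for x = −1 (inverse-probability weighting). A single draw is
  then equally likely to return either level.
* **Continuous covariate**: estimate the pool density p̂(x), and between
  the 0.05 and 0.95 pool quantiles x_l < x_u recruit with
  ρ(x) ∝ q / (c′ p̂(x)), where q = 1/(x_u − x_l) is the height of the
  uniform target and c′ = max_{x_l ≤ x ≤ x_u} q/p̂(x) caps the
  unnormalized weight at 1; outside the quantiles the weight is maximal.
* **Several covariates**: the row-wise product of the marginal weights,
  renormalized (marginally balanced protocol), or — for all-binary
  covariates — exact stratified sampling with equal counts per joint
  stratum (jointly balanced protocol).

Cohorts are drawn without replacement by successive weighted draws, and
evaluated by fitting the generating model class (logistic regression or
Cox proportional hazards) and summarizing power, mean square error and
type-I error across Monte-Carlo replicates.

## Worked example

```python
import selrecruit as sr

pool = sr.generate_binary_pool(10000, joint_probs=(0.4, 0.3, 0.2, 0.1), seed=1)
weights = sr.marginal_weights(pool)
selective = sr.sample_cohort(pool, weights, 1000, seed=2)
random = sr.random_sample(pool, 1000, seed=2)
```

Running `examples/01_binary_recruitment.py` prints:

```
pool +1 fractions: [0.696 0.595]
product_marginal cohort: +1 fractions [0.509 0.518], median minority ratio 0.948
          random cohort: +1 fractions [0.677 0.565], median minority ratio 0.624
```

The pool is skewed (70%/60% of individuals at +1), the random cohort
inherits the skew, and the selectively recruited cohort sits at ~50/50
on both covariates (minority ratio ≈ 1 means perfect balance).

`examples/03_power_curve.py` runs the single-continuous-covariate
experiment (pool N = 10 000 from Normal(0, 0.608), logistic outcomes)
and reports the smallest cohort size reaching 90% power:

```
marginal: smallest grid n with >=90% power: 250 (interpolated 250)
random:   smallest grid n with >=90% power: 500 (interpolated 489)
```

— selective recruitment roughly halves the required sample size.
`examples/02_continuous_recruitment.py` shows the density flattening
behind that gain, and `examples/04_ehr_study.py` runs a simulated
prospective survival study on a 30-covariate EHR-style pool.

A thin CLI mirrors the library: `selrecruit generate-pool`,
`selrecruit weights`, `selrecruit recruit`, `selrecruit simulate-power`,
`selrecruit find-n`, `selrecruit simulate-study` (see `--help`).

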