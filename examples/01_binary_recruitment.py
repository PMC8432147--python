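"""Inverse-probability recruitment for binary covariates.

Builds a pool with two unevenly distributed binary covariates, computes
marginally balanced recruitment weights, draws a cohort, and compares
covariate balance against a randomly selected cohort of the same size.
"""

import numpy as np

import selrecruit as sr

pool = sr.generate_binary_pool(10000, joint_probs=(0.4, 0.3, 0.2, 0.1), seed=1)
print("pool +1 fractions:", (pool.matrix == 1).mean(axis=0).round(3))

weights = sr.marginal_weights(pool)
selective = sr.sample_cohort(pool, weights, 1000, seed=2)
random = sr.random_sample(pool, 1000, seed=2)

for cohort in (selective, random):
    frac = (cohort.matrix == 1).mean(axis=0).round(3)
    ratios = sr.minority_ratio(cohort)
    print(
        f"{cohort.protocol:>16} cohort: +1 fractions {frac},"
        f" median minority ratio {ratios.median:.3f}"
    )

# The selective cohort's +1 fractions sit near 0.5 (uniform target) and its
# minority ratio near 1, while the random cohort mirrors the skewed pool.

joint = sr.jointly_balanced_sample(pool, 1000, seed=3)
counts = {
    (a, b): int(np.sum((joint.matrix[:, 0] == a) & (joint.matrix[:, 1] == b)))
    for a in (1, -1)
    for b in (1, -1)
}
print("jointly balanced stratum counts:", counts)  # exactly 250 per stratum
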