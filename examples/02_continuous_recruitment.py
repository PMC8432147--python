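"""Density-inverse recruitment for a continuous covariate.

Estimates the pool density of a normal covariate, inverts it between the
0.05/0.95 quantiles to form recruitment weights, and shows that the
recruited cohort's distribution is much flatter than the pool's.
"""

import numpy as np
from scipy import stats

import selrecruit as sr

pool = sr.generate_normal_pool(10000, mu=0.0, sigma=0.608, seed=4)
x = pool.covariates["x"].to_numpy()

dens = sr.estimate_density(x)
print(
    f"quantiles x_l={dens.x_l:.3f}, x_u={dens.x_u:.3f};"
    f" uniform target height q={dens.q:.3f}; weight cap c'={dens.c_prime:.3f}"
)

weights = sr.continuous_weights(dens, x)
cohort = sr.sample_cohort(pool, weights, 1000, seed=5)


def ks_to_uniform(values):
    inside = values[(values >= dens.x_l) & (values <= dens.x_u)]
    return stats.kstest(inside, "uniform", args=(dens.x_l, dens.x_u - dens.x_l)).statistic


print(f"KS distance to uniform, pool:   {ks_to_uniform(x):.3f}")
print(f"KS distance to uniform, cohort: {ks_to_uniform(cohort.matrix[:, 0]):.3f}")
print(f"cohort sd {cohort.matrix.std():.3f} vs pool sd {x.std():.3f}")

# The cohort is far closer to uniform between the quantiles and has a
# broader spread than the pool — the extra spread is where the power gain
# of selective recruitment comes from.
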