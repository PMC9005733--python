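"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own numerical paths: the diffusion
oracle is a plain Euler-Maruyama simulator (with the Broadie-Glasserman
continuity correction for the discrete-time boundary bias), the PSRF
oracle a direct transcription of the variance formula, and the prior
oracle a term-by-term scipy.stats summation.
"""

import math

import numpy as np
from numba import njit
from scipy import stats


@njit(cache=True)
def _euler_kernel(n, a, z, ter, v, s, deadline, dt, seed):
    """Euler-Maruyama first-passage simulation with inline noise draws.
    Returns (bound, rt) with bound +1 upper / -1 lower / 0 censored."""
    np.random.seed(seed)
    # continuity correction: shrink both boundaries by 0.5826*s*sqrt(dt)
    shift = 0.5826 * s * math.sqrt(dt)
    lo = 0.0 + shift
    hi = a - shift
    max_steps = int(math.ceil((deadline - ter) / dt))
    sq = s * math.sqrt(dt)
    bound = np.zeros(n, dtype=np.int8)
    rt = np.full(n, np.nan)
    for i in range(n):
        x = z
        for k in range(max_steps):
            x += v * dt + sq * np.random.normal()
            if x >= hi:
                t = ter + (k + 1) * dt
                if t <= deadline:
                    bound[i] = 1
                    rt[i] = t
                break
            if x <= lo:
                t = ter + (k + 1) * dt
                if t <= deadline:
                    bound[i] = -1
                    rt[i] = t
                break
    return bound, rt


def euler_simulate(n, a, z, ter, v, s, deadline, dt=1e-4, seed=0):
    """Simulate n trials by Euler discretization of the diffusion SDE."""
    return _euler_kernel(n, a, z, ter, v, s, deadline, dt, seed)


def psrf_reference(chains):
    """Textbook potential scale reduction factor for (m, n) samples."""
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return math.sqrt(var_plus / W)


def hier_prior_reference(h, X, group_signs):
    """Term-by-term hierarchical log prior via scipy.stats (no shared code
    with the package's implementation)."""
    mu, sig, dl = h[0:5], h[5:10], h[10:15]
    if np.any(sig <= 0):
        return -np.inf
    total = 0.0
    # hyperpriors
    total += stats.truncnorm.logpdf(mu[0], -0.2 / 0.2, np.inf, 0.2, 0.2)
    total += stats.truncnorm.logpdf(mu[1], (0 - 0.5) / 0.2, (1 - 0.5) / 0.2, 0.5, 0.2)
    total += stats.truncnorm.logpdf(mu[2], -0.3 / 0.3, np.inf, 0.3, 0.3)
    total += stats.norm.logpdf(mu[3], 0.0, 0.1)
    total += stats.norm.logpdf(mu[4], 0.3, 0.3)
    total += stats.gamma.logpdf(sig, 1.0, scale=1.0).sum()
    total += stats.norm.logpdf(dl, 0.0, 0.01).sum()
    # participant level
    for p in range(X.shape[0]):
        g = group_signs[p]
        m = mu + g * dl
        total += stats.truncnorm.logpdf(X[p, 0], -m[0] / sig[0], np.inf, m[0], sig[0])
        total += stats.truncnorm.logpdf(X[p, 1], (0 - m[1]) / sig[1],
                                        (1 - m[1]) / sig[1], m[1], sig[1])
        total += stats.truncnorm.logpdf(X[p, 2], -m[2] / sig[2], np.inf, m[2], sig[2])
        total += stats.norm.logpdf(X[p, 3], m[3], sig[3])
        total += stats.norm.logpdf(X[p, 4], m[4], sig[4])
    return float(total)
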