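"""Independent numerical oracles used by the test suite.

These deliberately share no code with the package: plain least squares,
explicit loops over every covariate subset, and direct numerical
integration of likelihood x prior. They re-derive the quantities the
package computes so agreement is informative.
"""

import itertools
import math

import numpy as np
from scipy import integrate
from scipy.special import gammaln


def brute_force_bma(y, x, g):
    """Loop over every subset with plain least squares and explicit weights.

    Returns (model weights, pip, post_mean, post_sd) with the subsets in
    size-then-lexicographic order.
    """
    n, s = x.shape
    tss = float(y @ y)
    delta = g / (1.0 + g)
    subsets = []
    for k in range(s + 1):
        subsets.extend(itertools.combinations(range(s), k))
    log_ml, means, varis = [], [], []
    for sub in subsets:
        if sub:
            xs = x[:, list(sub)]
            bh, *_ = np.linalg.lstsq(xs, y, rcond=None)
            r2 = float(bh @ xs.T @ y) / tss
            vd = np.diag(np.linalg.inv(xs.T @ xs))
        else:
            bh = np.zeros(0)
            r2 = 0.0
            vd = np.zeros(0)
        k = len(sub)
        ss = tss * (1 + g * (1 - r2)) / (1 + g)
        lm = (
            gammaln((n - 1) / 2)
            - (n - 1) / 2 * math.log(2 * math.pi)
            - 0.5 * math.log(n)
            - k / 2 * math.log(1 + g)
            - (n - 1) / 2 * math.log(ss / 2)
        )
        log_ml.append(lm)
        means.append(delta * bh)
        varis.append(delta * vd * ss / (n - 3))
    w = np.exp(np.array(log_ml) - max(log_ml))
    w /= w.sum()
    pip = np.zeros(s)
    post_mean = np.zeros(s)
    second = np.zeros(s)
    for sub, wk, mk, vk in zip(subsets, w, means, varis):
        for pos, j in enumerate(sub):
            pip[j] += wk
            post_mean[j] += wk * mk[pos]
            second[j] += wk * (vk[pos] + mk[pos] ** 2)
    post_sd = np.sqrt(np.maximum(second - post_mean**2, 0.0))
    return w, pip, post_mean, post_sd


def log_marginal_quadrature(y, x, g):
    """2-D quadrature of likelihood x prior over (slope, log variance).

    Priors: flat intercept (already centered out; its integral on
    centered data contributes sqrt(2 pi sigma^2 / n)), 1/sigma^2 on the
    variance, N(0, g sigma^2 / (x'x)) on the slope.
    """
    n = len(y)
    xtx = float(x @ x)

    def integrand(beta, logv):
        v = math.exp(logv)
        resid = y - beta * x
        log_like = (
            -0.5 * n * math.log(2 * math.pi * v)
            + 0.5 * math.log(2 * math.pi * v / n)
            - float(resid @ resid) / (2 * v)
        )
        log_prior = -0.5 * math.log(2 * math.pi * g * v / xtx) - beta**2 * xtx / (
            2 * g * v
        )
        return math.exp(log_like + log_prior)

    val, err = integrate.dblquad(
        integrand, -12.0, 6.0, -8.0, 8.0, epsabs=1e-14, epsrel=1e-11
    )
    assert err < abs(val) * 1e-7
    return math.log(val)


def log_marginal_null_quadrature(y):
    """1-D quadrature for the intercept-only model."""
    n = len(y)
    tss = float(y @ y)

    def integrand(logv):
        v = math.exp(logv)
        return math.exp(
            -0.5 * n * math.log(2 * math.pi * v)
            + 0.5 * math.log(2 * math.pi * v / n)
            - tss / (2 * v)
        )

    val, err = integrate.quad(integrand, -12.0, 6.0, epsabs=1e-14, epsrel=1e-11)
    return math.log(val)
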