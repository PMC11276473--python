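"""Brute-force numerical oracle for the conjugate outcome-model evidences.

Integrates the normal-gamma model directly with adaptive quadrature: block
means one at a time (they are conditionally independent given the
precision), then the precision.  Deliberately independent of the
closed-form expressions in dpmlpa.outcomes — every density is evaluated
pointwise and integrated numerically.
"""

import numpy as np
from scipy.integrate import quad
from scipy.special import gammaln

_TINY_ABS = 1e-300


def _block_integral(y_block, xi, c):
    """integral over theta of prod_i N(y_i; theta, 1/xi) * N(theta; 0, c/xi)."""
    y_block = np.asarray(y_block, dtype=float)

    def log_f(theta):
        ll = -0.5 * xi * np.sum((y_block - theta) ** 2) \
            + 0.5 * y_block.size * (np.log(xi) - np.log(2 * np.pi))
        lp = -0.5 * xi * theta**2 / c + 0.5 * (np.log(xi) - np.log(2 * np.pi * c))
        return ll + lp

    # scale at the integrand's mode so exp() never overflows at any xi
    mode = y_block.sum() / (y_block.size + 1.0 / c)
    shift = log_f(mode)
    val, _ = quad(lambda t: np.exp(log_f(t) - shift), -np.inf, np.inf,
                  points=None, epsabs=_TINY_ABS, epsrel=1e-10, limit=200)
    return np.log(val) + shift


def log_evidence_quadrature(y, labels, block_of, a0=1.0, b0=1.0, c=1.0):
    """log marginal likelihood of y under a block partition, by quadrature.

    block_of maps profile label t (1-based) to its block index; profiles in
    one block share one mean.
    """
    blocks = sorted(set(block_of))
    grouped = {
        b: [yi for yi, z in zip(y, labels) if block_of[z - 1] == b] for b in blocks
    }

    def log_outer(xi):
        out = a0 * np.log(b0) - gammaln(a0) + (a0 - 1.0) * np.log(xi) - b0 * xi
        for b in blocks:
            if grouped[b]:
                out += _block_integral(grouped[b], xi, c)
        return out

    shift = log_outer(1.0)
    val, _ = quad(lambda x: np.exp(log_outer(x) - shift), 0, np.inf,
                  epsabs=_TINY_ABS, epsrel=1e-10, limit=200)
    return float(np.log(val) + shift)


def posterior_mean_quadrature(y, a0=1.0, b0=1.0, c=1.0):
    """Posterior mean of the single profile mean given all of y, by nested
    quadrature over (theta, xi)."""
    y = np.asarray(y, dtype=float)

    def log_joint(theta, xi):
        out = (a0 - 1.0) * np.log(xi) - b0 * xi
        out += -0.5 * xi * theta**2 / c + 0.5 * (np.log(xi) - np.log(2 * np.pi * c))
        out += -0.5 * xi * np.sum((y - theta) ** 2) \
            + 0.5 * y.size * (np.log(xi) - np.log(2 * np.pi))
        return out

    def inner(xi, weighted):
        f = lambda t: (t if weighted else 1.0) * np.exp(log_joint(t, xi))
        val, _ = quad(f, -np.inf, np.inf, epsabs=_TINY_ABS, epsrel=1e-10, limit=200)
        return val

    num, _ = quad(lambda x: inner(x, True), 0, np.inf, epsabs=_TINY_ABS,
                  epsrel=1e-10, limit=200)
    den, _ = quad(lambda x: inner(x, False), 0, np.inf, epsabs=_TINY_ABS,
                  epsrel=1e-10, limit=200)
    return float(num / den)
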