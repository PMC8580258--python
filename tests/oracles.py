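"""Independent reference computations used to check the package's closed
forms. Everything here is deliberately written as plain per-point loops and
generic quadrature, never via the package's vectorised likelihood paths."""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import quad
from scipy.special import logsumexp


def log_gauss2(x, mu, sigma):
    """Log isotropic 2-D normal density."""
    x = np.asarray(x, float)
    mu = np.asarray(mu, float)
    return -math.log(2 * math.pi * sigma**2) - float(
        ((x - mu) ** 2).sum()
    ) / (2 * sigma**2)


def brute_log_joint(z, mu, x, model):
    """Per-point product of the printed generative densities."""
    out = 0.0
    for zi, xi in zip(z, x):
        if zi:
            out += log_gauss2(xi, mu, model.sigma)
        else:
            out += -math.log(math.pi * model.R**2)
    return out


def brute_log_prior_z(z, p_aff):
    out = 0.0
    for zi in z:
        out += math.log(p_aff) if zi else math.log(1 - p_aff)
    return out


def brute_log_L_given_mu(mu, x, model):
    """Sum over all 2^N partitions of prior * joint likelihood (the slow
    route to the per-point mixture form)."""
    n = len(x)
    p = model.p_aff_for(n)
    terms = []
    for z in itertools.product([0, 1], repeat=n):
        terms.append(brute_log_prior_z(z, p) + brute_log_joint(z, mu, x, model))
    return float(logsumexp(terms))


def quad_log_L_given_z(z, x, model):
    """Marginal likelihood of a fixed partition by adaptive 1-D quadrature.

    The integrand factorises over the two coordinates, so the 2-D integral
    over mu is a product of two 1-D integrals."""
    z = np.asarray(z, int)
    x = np.asarray(x, float)
    n0 = int((z == 0).sum())
    members = x[z == 1]
    out = -n0 * math.log(math.pi * model.R**2)
    if members.shape[0] == 0:
        return out
    for dim in range(2):
        coords = members[:, dim]

        def integrand(mu_d, coords=coords):
            val = math.exp(
                -((mu_d**2) / (2 * model.sigma_s**2))
            ) / math.sqrt(2 * math.pi * model.sigma_s**2)
            for c in coords:
                val *= math.exp(
                    -((c - mu_d) ** 2) / (2 * model.sigma**2)
                ) / math.sqrt(2 * math.pi * model.sigma**2)
            return val

        lo = min(coords.min(), 0.0) - 12 * model.sigma_s
        hi = max(coords.max(), 0.0) + 12 * model.sigma_s
        val, _ = quad(integrand, lo, hi, epsabs=0, epsrel=1e-12, limit=400)
        out += math.log(val)
    return out


def brute_best_partition_llr(x, model):
    """Max over all 2^N partitions of log L(z) - log L0, via the quadrature
    marginal (slow; small N only)."""
    n = len(x)
    base = -n * math.log(math.pi * model.R**2)
    best = -np.inf
    for z in itertools.product([0, 1], repeat=n):
        best = max(best, quad_log_L_given_z(z, x, model) - base)
    return best
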