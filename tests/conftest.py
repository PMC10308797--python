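"""Shared independent oracles for the test suite.

These deliberately avoid the package's own code paths: binomial tails by
direct summation with exact integer binomial coefficients, Fisher p-values
by conditional hypergeometric enumeration, and the CRM posterior by a dense
trapezoid quadrature.  They exist so the implementation can be checked
against a second, slower route.
"""
from __future__ import annotations

import math

import numpy as np
import pytest


def binom_tail_oracle(n: int, p: float, r: int) -> float:
    """P(X >= r) for X ~ Binomial(n, p), by direct pmf summation."""
    if r <= 0:
        return 1.0
    if r > n:
        return 0.0
    q = 1.0 - p
    return sum(math.comb(n, k) * p**k * q ** (n - k) for k in range(r, n + 1))


def critical_value_oracle(n: int, p0: float, alpha: float) -> int:
    """Smallest r with the exact upper tail at p0 at or below alpha."""
    for r in range(0, n + 1):
        if binom_tail_oracle(n, p0, r) <= alpha + 1e-12:
            return r
    return n + 1


def fisher_pvalue_oracle(x1: int, n1: int, x0: int, n0: int) -> float:
    """One-sided Fisher p-value by conditional enumeration over the margin."""
    s = x1 + x0
    denom = math.comb(n1 + n0, s)
    num = sum(
        math.comb(n1, k) * math.comb(n0, s - k)
        for k in range(x1, min(n1, s) + 1)
        if 0 <= s - k <= n0
    )
    return num / denom


def fisher_power_oracle(n: int, p1: float, p0: float, alpha: float) -> float:
    """Exact unconditional power by exhaustive enumeration of outcome pairs."""
    total = 0.0
    for x1 in range(n + 1):
        w1 = math.comb(n, x1) * p1**x1 * (1 - p1) ** (n - x1)
        for x0 in range(n + 1):
            if fisher_pvalue_oracle(x1, n, x0, n) <= alpha + 1e-12:
                w0 = math.comb(n, x0) * p0**x0 * (1 - p0) ** (n - x0)
                total += w1 * w0
    return total


def crm_posterior_oracle(skeleton, prior_sd, assignments, dlt, npts=100_001):
    """Posterior-mean dose toxicities by dense trapezoid quadrature on beta."""
    beta = np.linspace(-10.0, 10.0, npts)
    prior = np.exp(-0.5 * (beta / prior_sd) ** 2)
    loglik = np.zeros_like(beta)
    with np.errstate(divide="ignore"):
        for dose, y in zip(assignments, dlt):
            p = skeleton[dose - 1] ** np.exp(beta)
            loglik += np.log(p) if y else np.log1p(-p)
    w = np.exp(loglik - loglik.max()) * prior
    denom = np.trapezoid(w, beta)
    out = []
    for s in skeleton:
        out.append(np.trapezoid((s ** np.exp(beta)) * w, beta) / denom)
    return np.array(out)


@pytest.fixture(scope="session")
def rng_factory():
    def make(seed: int) -> np.random.Generator:
        return np.random.default_rng(seed)

    return make
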