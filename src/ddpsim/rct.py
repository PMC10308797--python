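"""Two-arm 1:1 randomized trial analyzed by a one-sided Fisher exact test.

The confirmatory phase III trial compares responder counts between an
experimental and a control arm of equal size.  The test conditions on the
table margins (hypergeometric upper tail); *unconditional* power sums the
joint Binomial outcome distribution over the rejection region.  Sample-size
selection targets a power level at the treatment effect estimated by the
preceding trial, with a hard cap on the total enrollment.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple

import numpy as np
from scipy import stats

from .single_arm import TIE_EPS, _check_prob

__all__ = [
    "RctDesign",
    "RctResult",
    "Phase3Size",
    "fisher_one_sided_pvalue",
    "exact_unconditional_power",
    "normal_approx_per_arm",
    "phase3_sample_size",
    "run_rct",
]


@dataclass(frozen=True)
class RctDesign:
    """1:1 randomized design analyzed by a one-sided Fisher exact test."""

    n_per_arm: int
    alpha: float = 0.05
    target_power: float = 0.90
    max_total: int = 400

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError(f"n_per_arm must be >= 1, got {self.n_per_arm}")
        if 2 * self.n_per_arm > self.max_total:
            raise ValueError(
                f"2*n_per_arm={2 * self.n_per_arm} exceeds max_total={self.max_total}"
            )
        _check_prob("alpha", self.alpha)
        _check_prob("target_power", self.target_power)


@dataclass(frozen=True)
class RctResult:
    """Outcome of one simulated randomized trial."""

    x_exp: int
    x_ctl: int
    p_value: float
    reject: bool
    n_per_arm: int


class Phase3Size(NamedTuple):
    n_per_arm: int
    capped: bool


def fisher_one_sided_pvalue(x1: int, n1: int, x0: int, n0: int) -> float:
    """One-sided Fisher exact p-value for more responses in the experimental arm.

    Conditional on the margins, the experimental-arm responder count is
    hypergeometric; the p-value is its upper tail at the observed count.
    """
    if not (0 <= x1 <= n1 and 0 <= x0 <= n0):
        raise ValueError(f"counts out of range: x1={x1}/{n1}, x0={x0}/{n0}")
    return float(stats.hypergeom.sf(x1 - 1, n1 + n0, x1 + x0, n1))


@lru_cache(maxsize=512)
def _pvalue_matrix(n: int) -> np.ndarray:
    """Fisher p-value for every (x1, x0) outcome of two arms of size n."""
    x = np.arange(n + 1)
    x1 = x[:, None]
    x0 = x[None, :]
    m = stats.hypergeom.sf(x1 - 1, 2 * n, x1 + x0, n)
    m.setflags(write=False)
    return m


@lru_cache(maxsize=512)
def _rejection_matrix(n: int, alpha: float) -> np.ndarray:
    r = _pvalue_matrix(n) <= alpha + TIE_EPS
    r.setflags(write=False)
    return r


def exact_unconditional_power(
    n_per_arm: int, p1: float, p0: float, alpha: float
) -> float:
    """Sum of Binomial(n,p1) x Binomial(n,p0) mass over the rejection region."""
    if n_per_arm < 1:
        raise ValueError(f"n_per_arm must be >= 1, got {n_per_arm}")
    for name, p in (("p1", p1), ("p0", p0)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {p!r}")
    _check_prob("alpha", alpha)
    x = np.arange(n_per_arm + 1)
    b1 = stats.binom.pmf(x, n_per_arm, p1)
    b0 = stats.binom.pmf(x, n_per_arm, p0)
    return float(b1 @ _rejection_matrix(n_per_arm, alpha) @ b0)


def normal_approx_per_arm(
    p1: float, p0: float, alpha: float, target_power: float
) -> int:
    """Classic two-proportion normal-approximation per-arm sample size."""
    za = stats.norm.isf(alpha)
    zb = stats.norm.ppf(target_power)
    pbar = 0.5 * (p1 + p0)
    num = za * np.sqrt(2.0 * pbar * (1.0 - pbar)) + zb * np.sqrt(
        p1 * (1.0 - p1) + p0 * (1.0 - p0)
    )
    return int(np.ceil((num / (p1 - p0)) ** 2))


@lru_cache(maxsize=None)
def phase3_sample_size(
    p1_hat: float,
    p0_ref: float,
    alpha: float = 0.05,
    target_power: float = 0.90,
    max_total: int = 400,
    method: str = "exact",
) -> Phase3Size:
    """Smallest per-arm n whose Fisher power at (p1_hat, p0_ref) meets the target.

    Totals are kept even (equal 1:1 allocation).  When even the cap
    ``max_total`` cannot reach the target, the trial still runs at the cap
    and the ``capped`` flag is set.  ``method='normal'`` sizes by the
    two-proportion normal approximation instead of exact unconditional
    power (sensitivity switch; exact is the default).

    The exact search brackets with the normal approximation and then scans
    linearly upward from well below the bracket, because exact power is a
    sawtooth in n.  Results are memoized: the estimate feeding ``p1_hat``
    takes at most n+1 distinct values per simulation run.
    """
    if not p1_hat > p0_ref:
        raise ValueError(f"need p1_hat > p0_ref, got {p1_hat} <= {p0_ref}")
    cap = max_total // 2
    n_approx = normal_approx_per_arm(p1_hat, p0_ref, alpha, target_power)
    if method == "normal":
        n = max(2, n_approx)
        return Phase3Size(cap, True) if n > cap else Phase3Size(n, False)
    if method != "exact":
        raise ValueError(f"unknown sizing method {method!r}")
    lo = max(2, int(0.5 * n_approx))
    if lo > cap:
        # Approximation says the target is far out of reach; confirm at the cap.
        if exact_unconditional_power(cap, p1_hat, p0_ref, alpha) < target_power - TIE_EPS:
            return Phase3Size(cap, True)
        lo = 2  # approximation was badly off; fall back to a full scan
    for n in range(lo, cap + 1):
        if exact_unconditional_power(n, p1_hat, p0_ref, alpha) >= target_power - TIE_EPS:
            return Phase3Size(n, False)
    return Phase3Size(cap, True)


def run_rct(
    n_per_arm: int,
    true_p1: float,
    true_p0: float,
    alpha: float,
    rng: np.random.Generator,
) -> RctResult:
    """Simulate one 1:1 trial; arms drawn independently Binomial(n, .)."""
    x_exp = int(rng.binomial(n_per_arm, true_p1))
    x_ctl = int(rng.binomial(n_per_arm, true_p0))
    p = fisher_one_sided_pvalue(x_exp, n_per_arm, x_ctl, n_per_arm)
    return RctResult(
        x_exp=x_exp,
        x_ctl=x_ctl,
        p_value=p,
        reject=bool(p <= alpha + TIE_EPS),
        n_per_arm=n_per_arm,
    )
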