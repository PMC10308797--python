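"""One-sided exact binomial single-arm trial.

A single-arm phase II trial tests H0: ORR <= orr0 against a one-sided
alternative by counting responders among ``n2`` patients and rejecting when
the count reaches the exact binomial critical value.  This module provides
the critical value, exact power, a linear sample-size search (exact-test
power is a sawtooth in n, so bisection is unsound), and a seeded simulator.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "SingleArmDesign",
    "SingleArmResult",
    "PowerUnachievableError",
    "critical_value",
    "exact_power",
    "minimum_sample_size",
    "run_single_arm_trial",
]

# p-values landing exactly on alpha reject; the epsilon only guards float
# round-off of tail sums, not a change of convention.
TIE_EPS = 1e-12


class PowerUnachievableError(ValueError):
    """No sample size in the allowed range reaches the target power."""


def _check_prob(name: str, x: float) -> None:
    if not (0.0 < x < 1.0):
        raise ValueError(f"{name} must lie strictly in (0, 1), got {x!r}")


@dataclass(frozen=True)
class SingleArmDesign:
    """Exact binomial single-arm design testing H0: ORR <= orr0.

    Parameters
    ----------
    n2 : int
        Number of patients enrolled (analysis once, at the end).
    orr0 : float
        Reference (historical standard-of-care) response probability.
    orr1_alt : float
        Alternative response probability used for design-time power.
    alpha : float
        One-sided significance level.
    """

    n2: int
    orr0: float = 0.4
    orr1_alt: float = 0.6
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n2 < 1:
            raise ValueError(f"n2 must be >= 1, got {self.n2}")
        _check_prob("orr0", self.orr0)
        _check_prob("alpha", self.alpha)
        if not (self.orr0 < self.orr1_alt <= 1.0):
            raise ValueError(
                f"need orr0 < orr1_alt <= 1, got orr0={self.orr0}, orr1_alt={self.orr1_alt}"
            )

    @property
    def critical_value(self) -> int:
        """Smallest responder count that rejects H0; ``n2 + 1`` if none."""
        return critical_value(self.n2, self.orr0, self.alpha)

    def power(self, true_orr: Optional[float] = None) -> float:
        """Exact power against ``true_orr`` (default: the design alternative)."""
        p1 = self.orr1_alt if true_orr is None else true_orr
        return exact_power(self.n2, self.orr0, p1, self.alpha)


@dataclass(frozen=True)
class SingleArmResult:
    """Outcome of one simulated single-arm trial."""

    responses: int
    orr_hat: float
    reject: bool
    toxicities: int = 0


@lru_cache(maxsize=None)
def critical_value(n: int, p0: float, alpha: float) -> int:
    """Smallest r with P(X >= r | X ~ Binomial(n, p0)) <= alpha.

    Returns ``n + 1`` when no r <= n gives a valid rejection region (the
    test then never rejects).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    _check_prob("p0", p0)
    _check_prob("alpha", alpha)
    # tail[r] = P(X >= r) = sf(r - 1), r = 0..n
    tail = stats.binom.sf(np.arange(0, n + 1) - 1, n, p0)
    ok = np.nonzero(tail <= alpha + TIE_EPS)[0]
    return int(ok[0]) if ok.size else n + 1


def exact_power(n: int, p0: float, p1: float, alpha: float) -> float:
    """P(X >= critical_value(n, p0, alpha)) under X ~ Binomial(n, p1)."""
    if not (0.0 < p1 <= 1.0):
        raise ValueError(f"p1 must lie in (0, 1], got {p1!r}")
    r = critical_value(n, p0, alpha)
    if r > n:
        return 0.0
    return float(stats.binom.sf(r - 1, n, p1))


def minimum_sample_size(
    p0: float,
    p1: float,
    alpha: float,
    target_power: float,
    n_min: int = 1,
    n_max: int = 500,
) -> int:
    """Smallest n in [n_min, n_max] with exact power >= target_power.

    The scan is linear: exact-test power is non-monotone (sawtooth) in n,
    so a bisection over n could skip the true minimum.
    """
    _check_prob("target_power", target_power)
    if n_min > n_max:
        raise ValueError(f"n_min={n_min} exceeds n_max={n_max}")
    for n in range(max(1, n_min), n_max + 1):
        if exact_power(n, p0, p1, alpha) >= target_power - TIE_EPS:
            return n
    raise PowerUnachievableError(
        f"no n in [{n_min}, {n_max}] reaches power {target_power} "
        f"for p0={p0}, p1={p1}, alpha={alpha}"
    )


def run_single_arm_trial(
    design: SingleArmDesign,
    true_orr: float,
    true_tox: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> SingleArmResult:
    """Simulate one trial: responses ~ Binomial(n2, true_orr).

    Toxicity events are drawn only when ``true_tox`` is given (they do not
    enter the rejection rule here; downstream safety monitors use them).
    """
    if rng is None:
        raise ValueError("an explicitly seeded numpy Generator is required")
    if not (0.0 <= true_orr <= 1.0):
        raise ValueError(f"true_orr must lie in [0, 1], got {true_orr!r}")
    responses = int(rng.binomial(design.n2, true_orr))
    toxicities = 0
    if true_tox is not None:
        if not (0.0 <= true_tox <= 1.0):
            raise ValueError(f"true_tox must lie in [0, 1], got {true_tox!r}")
        toxicities = int(rng.binomial(design.n2, true_tox))
    reject = responses >= design.critical_value
    return SingleArmResult(
        responses=responses,
        orr_hat=responses / design.n2,
        reject=bool(reject),
        toxicities=toxicities,
    )
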