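"""Phase I Continual Reassessment Method (CRM) engine.

The empiric one-parameter model sets the toxicity probability at dose j to
``skeleton_j ** exp(beta)`` with a Normal(0, prior_sd^2) prior on beta.
Patients are assigned one at a time; after each outcome the posterior is
re-integrated and the next patient receives the dose whose estimated
toxicity is closest to the target (without skipping untried levels upward
when ``no_skip`` is set).  At the end, the maximum tolerated dose (MTD) is
the highest dose whose posterior toxicity estimate does not exceed the
target; if even the lowest dose exceeds it, no dose is selected and the
development program stops.

The posterior mean of each dose's toxicity probability is a 1-D integral
over beta, evaluated on a fixed 4001-point Simpson grid on [-10, 10] with
per-skeleton cached dose-probability tables, making a full model refit a
pair of small matrix products.  Accuracy against a much denser independent
quadrature is part of the test suite (< 1e-6).
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CrmDesign",
    "CrmResult",
    "CrmNumericError",
    "posterior_tox_estimates",
    "next_dose",
    "run_crm_trial",
    "select_optimal_dose",
    "DEFAULT_SKELETON",
]

TIE_EPS = 1e-12

# Default six-level skeleton centered so the prior MTD sits at level 3 for a
# 0.25 toxicity target; the prior scale 1.34 is the conventional default for
# the empiric power model.  All of these are overridable in CrmDesign.
DEFAULT_SKELETON: Tuple[float, ...] = (0.05, 0.12, 0.25, 0.40, 0.55, 0.68)
DEFAULT_PRIOR_SD = 1.34

_GRID_LO = -10.0
_GRID_HI = 10.0
_GRID_N = 4001  # odd, so Simpson weights apply exactly


class CrmNumericError(RuntimeError):
    """Posterior integration produced a non-finite or zero normalizer."""


def _validate_skeleton(skeleton: Sequence[float]) -> Tuple[float, ...]:
    sk = tuple(float(s) for s in skeleton)
    if len(sk) < 1:
        raise ValueError("skeleton must have at least one dose level")
    if not all(0.0 < s < 1.0 for s in sk):
        raise ValueError(f"skeleton entries must lie in (0, 1): {sk}")
    if any(b <= a for a, b in zip(sk, sk[1:])):
        raise ValueError(f"skeleton must be strictly increasing: {sk}")
    return sk


@dataclass(frozen=True)
class CrmDesign:
    """CRM design parameters.

    ``start_dose`` is the prior guess of the MTD (the first patient's dose);
    ``no_skip`` forbids escalating more than one level above the highest
    dose tried so far.
    """

    n1: int
    skeleton: Tuple[float, ...] = DEFAULT_SKELETON
    tox_target: float = 0.25
    prior_sd: float = DEFAULT_PRIOR_SD
    start_dose: int = 3
    no_skip: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "skeleton", _validate_skeleton(self.skeleton))
        if self.n1 < 1:
            raise ValueError(f"n1 must be >= 1, got {self.n1}")
        if not (0.0 < self.tox_target < 1.0):
            raise ValueError(f"tox_target must lie in (0, 1), got {self.tox_target}")
        if self.prior_sd <= 0:
            raise ValueError(f"prior_sd must be positive, got {self.prior_sd}")
        if not (1 <= self.start_dose <= self.n_doses):
            raise ValueError(
                f"start_dose must lie in 1..{self.n_doses}, got {self.start_dose}"
            )

    @property
    def n_doses(self) -> int:
        return len(self.skeleton)


@dataclass(frozen=True)
class CrmResult:
    """Full trajectory of one simulated CRM trial (doses are 1-based)."""

    assignments: Tuple[int, ...]
    dlt: Tuple[bool, ...]
    tox_estimates: Tuple[float, ...]
    selected_dose: Optional[int]


@lru_cache(maxsize=32)
def _model_tables(skeleton: Tuple[float, ...], prior_sd: float):
    """Cached beta grid, per-dose probability tables and Simpson weights."""
    beta = np.linspace(_GRID_LO, _GRID_HI, _GRID_N)
    a = np.exp(beta)
    log_sk = np.log(np.asarray(skeleton))
    logp = np.outer(log_sk, a)  # (J, N): log p_j(beta) = exp(beta) log s_j
    p = np.exp(logp)
    log1mp = np.log1p(-p)
    log_prior = -0.5 * (beta / prior_sd) ** 2  # unnormalized; constant cancels
    h = (_GRID_HI - _GRID_LO) / (_GRID_N - 1)
    w = np.full(_GRID_N, 2.0)
    w[1::2] = 4.0
    w[0] = w[-1] = 1.0
    w *= h / 3.0
    for arr in (beta, p, logp, log1mp, log_prior, w):
        arr.setflags(write=False)
    return beta, p, logp, log1mp, log_prior, w


def _dose_counts(
    n_doses: int, assignments: Sequence[int], dlt: Sequence[int]
) -> Tuple[np.ndarray, np.ndarray]:
    if len(assignments) != len(dlt):
        raise ValueError("assignments and dlt must have equal length")
    m = np.zeros(n_doses)
    t = np.zeros(n_doses)
    for d, y in zip(assignments, dlt):
        if not (1 <= d <= n_doses):
            raise ValueError(f"dose index {d} outside 1..{n_doses}")
        m[d - 1] += 1.0
        t[d - 1] += 1.0 if y else 0.0
    return m, t


def posterior_tox_estimates(
    skeleton: Sequence[float],
    prior_sd: float,
    assignments: Sequence[int],
    dlt: Sequence[int],
) -> np.ndarray:
    """Posterior-mean toxicity probability per dose under the empiric model.

    With no data the likelihood is flat and the prior means are returned.
    Estimates are strictly increasing across doses for any data because
    each ``p_j(beta)`` is increasing in j pointwise in beta.
    """
    sk = _validate_skeleton(skeleton)
    if prior_sd <= 0:
        raise ValueError(f"prior_sd must be positive, got {prior_sd}")
    _, p, logp, log1mp, log_prior, w = _model_tables(sk, float(prior_sd))
    m, t = _dose_counts(len(sk), assignments, dlt)
    loglik = t @ logp + (m - t) @ log1mp  # (N,)
    logw = loglik + log_prior
    logw = logw - logw.max()
    weights = np.exp(logw) * w
    denom = weights.sum()
    if not np.isfinite(denom) or denom <= 0.0:
        raise CrmNumericError(
            f"posterior normalizer non-finite (denom={denom!r}, "
            f"n={len(assignments)}, dlt={int(t.sum())})"
        )
    est = (p @ weights) / denom
    if not np.all(np.isfinite(est)):
        raise CrmNumericError(f"non-finite posterior estimates: {est}")
    return est


def next_dose(
    tox_estimates: Sequence[float],
    tox_target: float,
    current_dose: int,
    max_tried: int,
    no_skip: bool,
) -> int:
    """Dose whose estimated toxicity is closest to the target (ties go low).

    With ``no_skip``, escalation is clamped to one level above the highest
    dose tried so far.  ``current_dose`` is carried for context and does
    not constrain de-escalation.
    """
    est = np.asarray(tox_estimates, dtype=float)
    d = np.abs(est - tox_target)
    best = int(np.nonzero(d <= d.min() + TIE_EPS)[0][0]) + 1
    if no_skip:
        best = min(best, max_tried + 1)
    return best


def run_crm_trial(design: CrmDesign, scenario, rng: np.random.Generator) -> CrmResult:
    """Simulate one CRM trial under a true dose-toxicity scenario.

    ``scenario`` must expose a per-dose true DLT probability vector ``tox``
    of length ``design.n_doses``.  The model is refit after every patient.
    """
    tox_true = np.asarray(scenario.tox, dtype=float)
    if tox_true.shape != (design.n_doses,):
        raise ValueError(
            f"scenario has {tox_true.size} doses, design has {design.n_doses}"
        )
    assignments: list[int] = []
    dlt: list[bool] = []
    dose = design.start_dose
    est = None
    for _ in range(design.n1):
        assignments.append(dose)
        dlt.append(bool(rng.random() < tox_true[dose - 1]))
        est = posterior_tox_estimates(design.skeleton, design.prior_sd, assignments, dlt)
        dose = next_dose(est, design.tox_target, dose, max(assignments), design.no_skip)
    assert est is not None
    acceptable = np.nonzero(est <= design.tox_target + TIE_EPS)[0]
    selected = int(acceptable[-1]) + 1 if acceptable.size else None
    return CrmResult(
        assignments=tuple(assignments),
        dlt=tuple(dlt),
        tox_estimates=tuple(float(e) for e in est),
        selected_dose=selected,
    )


def select_optimal_dose(
    tox_estimates: Sequence[float],
    orr_estimates: Sequence[float],
    tox_target: float,
) -> Optional[int]:
    """Optimal dose: highest response rate among doses with acceptable toxicity.

    Relevant when dose-response is non-monotone, where the MTD may sit on a
    response plateau.  Ties go to the lower dose; ``None`` when no dose has
    toxicity at or below the target.
    """
    tox = np.asarray(tox_estimates, dtype=float)
    orr = np.asarray(orr_estimates, dtype=float)
    if tox.shape != orr.shape:
        raise ValueError("toxicity and response estimate vectors must align")
    ok = np.nonzero(tox <= tox_target + TIE_EPS)[0]
    if not ok.size:
        return None
    sub = orr[ok]
    best = ok[np.nonzero(sub >= sub.max() - TIE_EPS)[0][0]]
    return int(best) + 1
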