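"""Truth models and default fixtures for the three development segments.

Scenarios are the data-generating truths the simulator runs against: per-dose
toxicity/response curves for the dose-finding segment, a continuous
biomarker-response curve for the enrichment segment, the flat two-rate truth
for the phase II -> III segment, and a simple enrollment/duration model.

The default dose and biomarker curves are package-chosen fixtures: their
qualitative constraints (which doses are safe and effective, where the
biomarker benefit threshold sits) define the stylized study conditions, and
every numeric default is overridable through the config layer.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "DoseScenario",
    "BiomarkerScenario",
    "EnrollmentModel",
    "make_example1_scenario",
    "make_default_dose_scenario",
    "make_nonmonotone_dose_scenario",
    "make_default_biomarker_scenario",
    "make_null_biomarker_scenario",
    "sample_biomarker",
    "segment_duration",
]


def _check_unit_vector(name: str, v: Tuple[float, ...]) -> None:
    if not all(0.0 <= x <= 1.0 for x in v):
        raise ValueError(f"{name} entries must lie in [0, 1]: {v}")


@dataclass(frozen=True)
class DoseScenario:
    """True per-dose DLT probability and true ORR for J dose levels."""

    tox: Tuple[float, ...]
    orr: Tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tox", tuple(float(x) for x in self.tox))
        object.__setattr__(self, "orr", tuple(float(x) for x in self.orr))
        if len(self.tox) < 1 or len(self.tox) != len(self.orr):
            raise ValueError("tox and orr must be equal-length, non-empty vectors")
        _check_unit_vector("tox", self.tox)
        _check_unit_vector("orr", self.orr)

    @property
    def n_doses(self) -> int:
        return len(self.tox)

    @property
    def labels(self) -> Tuple[int, ...]:
        return tuple(range(1, self.n_doses + 1))

    def good_doses(self, tox_target: float = 0.25, orr_ref: float = 0.4) -> Tuple[int, ...]:
        """Doses that are both safe (tox <= target) and effective (ORR > ref)."""
        return tuple(
            j + 1
            for j in range(self.n_doses)
            if self.tox[j] <= tox_target and self.orr[j] > orr_ref
        )

    def bad_doses(self, tox_target: float = 0.25, orr_ref: float = 0.4) -> Tuple[int, ...]:
        """Doses that are unsafe (tox > target) or ineffective (ORR <= ref)."""
        good = set(self.good_doses(tox_target, orr_ref))
        return tuple(j for j in self.labels if j not in good)


@dataclass(frozen=True)
class BiomarkerScenario:
    """Biomarker-response truth: logistic ORR1(x), constant ORR0.

    ORR1(x) = expit(orr1_intercept + orr1_slope * x) for biomarker x in
    [0, 1]; the control (standard-of-care) response probability is constant.
    ``biomarker_lower`` is the lower bound of the uniform biomarker
    distribution (0 for an unselected population; the chosen cutoff for an
    enriched one).
    """

    orr0: float
    orr1_intercept: float
    orr1_slope: float
    biomarker_lower: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.orr0 <= 1.0):
            raise ValueError(f"orr0 must lie in [0, 1], got {self.orr0}")
        if not (0.0 <= self.biomarker_lower < 1.0):
            raise ValueError(
                f"biomarker_lower must lie in [0, 1), got {self.biomarker_lower}"
            )

    @classmethod
    def from_crossing(
        cls,
        slope: float,
        crossing: float,
        orr0: float,
        biomarker_lower: float = 0.0,
    ) -> "BiomarkerScenario":
        """Build a curve that equals ``orr0`` exactly at ``crossing``."""
        intercept = float(logit(orr0) - slope * crossing)
        return cls(
            orr0=orr0,
            orr1_intercept=intercept,
            orr1_slope=float(slope),
            biomarker_lower=biomarker_lower,
        )

    def orr1(self, x):
        """Experimental-arm response probability at biomarker value(s) x."""
        return expit(self.orr1_intercept + self.orr1_slope * np.asarray(x, dtype=float))

    def curve_grid(self, n: int = 101) -> np.ndarray:
        """(x, ORR1(x)) columns on an even grid, for CSV export/plotting."""
        x = np.linspace(0.0, 1.0, n)
        return np.column_stack([x, self.orr1(x)])


@dataclass(frozen=True)
class EnrollmentModel:
    """Accrual rates and assessment windows used for segment duration.

    Defaults (4 patients/month early trial, 10/month late trial, 6-month
    white space between trials, 6-month response-assessment window each)
    are package-chosen planning values, exposed in the config.
    """

    rate_phase_a: float = 4.0
    rate_phase_b: float = 10.0
    gap_months: float = 6.0
    followup_months_a: float = 6.0
    followup_months_b: float = 6.0

    def __post_init__(self) -> None:
        if self.rate_phase_a <= 0 or self.rate_phase_b <= 0:
            raise ValueError("enrollment rates must be positive")
        if min(self.gap_months, self.followup_months_a, self.followup_months_b) < 0:
            raise ValueError("gap and follow-up durations must be non-negative")


def make_example1_scenario(null: bool = False) -> Tuple[float, float]:
    """(true ORR1, true ORR0) for the phase II -> phase III segment.

    The effective-treatment truth is (0.6, 0.4); the ``null`` variant sets
    the experimental rate equal to the standard of care for type-I-error
    studies.
    """
    return (0.4, 0.4) if null else (0.6, 0.4)


def make_default_dose_scenario() -> DoseScenario:
    """Six-level truth where exactly doses 3 and 4 are safe and effective.

    Doses 1-2 are safe but ineffective (ORR <= 0.4), doses 5-6 effective
    but unsafe (DLT probability > 0.25).  The specific values are package
    fixtures chosen to satisfy those constraints.
    """
    return DoseScenario(
        tox=(0.02, 0.06, 0.12, 0.20, 0.35, 0.50),
        orr=(0.15, 0.30, 0.50, 0.60, 0.65, 0.67),
    )


def make_nonmonotone_dose_scenario() -> DoseScenario:
    """Increasing toxicity with response peaking at an interior dose.

    The response argmax (dose 3) sits strictly below the highest
    acceptable-toxicity dose (dose 4), so an MTD rule and an optimal-dose
    rule disagree on the truth: the case motivating response-informed dose
    selection.
    """
    return DoseScenario(
        tox=(0.02, 0.06, 0.12, 0.20, 0.35, 0.50),
        orr=(0.20, 0.45, 0.62, 0.55, 0.50, 0.45),
    )


def make_default_biomarker_scenario() -> BiomarkerScenario:
    """Logistic benefit curve crossing the 0.4 standard-of-care rate at x=0.6.

    Patients with biomarker above 0.6 respond better on the experimental
    arm, those below respond worse; the slope 4 puts the average
    experimental response in the benefiting subgroup near 0.6.
    """
    return BiomarkerScenario.from_crossing(slope=4.0, crossing=0.6, orr0=0.4)


def make_null_biomarker_scenario() -> BiomarkerScenario:
    """Flat curve: ORR1(x) = ORR0 = 0.4 everywhere (global null)."""
    return BiomarkerScenario(orr0=0.4, orr1_intercept=float(logit(0.4)), orr1_slope=0.0)


def sample_biomarker(lower: float, rng: np.random.Generator, size: Optional[int] = None):
    """Uniform biomarker draw(s) on [lower, 1)."""
    if not (0.0 <= lower < 1.0):
        raise ValueError(f"lower must lie in [0, 1), got {lower}")
    return lower + (1.0 - lower) * rng.random(size)


def segment_duration(
    n_first: int,
    n_second: Optional[int],
    model: EnrollmentModel,
) -> float:
    """Months to complete the segment: accrual plus follow-up per trial.

    The second trial contributes only when it runs; the between-trial gap
    covers analysis and start-up white space.
    """
    if n_first < 0 or (n_second is not None and n_second < 0):
        raise ValueError("patient counts must be non-negative")
    months = n_first / model.rate_phase_a + model.followup_months_a
    if n_second is not None:
        months += model.gap_months + n_second / model.rate_phase_b + model.followup_months_b
    return months
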