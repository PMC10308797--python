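"""Two-trial development segments: gating, Monte-Carlo engine, metrics.

A *segment* is a pair of consecutive trials with a go/no-go gate between
them: the first trial's result decides whether the second runs and supplies
the estimates that size it.  Three segment types are modeled:

* Segment A — single-arm phase II (exact binomial) gating a phase III RCT
  (one-sided Fisher) sized at the phase II response estimate, capped.
* Segment B — CRM phase I dose finding gating a fixed-size single-arm
  phase II at the selected dose, with an end-of-trial toxicity monitor.
* Segment C — adaptive biomarker-enrichment phase II gating a phase III
  RCT restricted to the selected biomarker subgroup, sized at the
  subgroup estimates reported by the enrichment trial.

``estimate_operating_characteristics`` runs seeded replicates (replicate i
draws its stream from (seed, i), so estimates are invariant to execution
order and pooling) and aggregates the segment-level metrics: segment power,
expected total enrollment, exposure to unsafe/ineffective doses, duration,
and the selection distribution.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .crm import CrmDesign, run_crm_trial
from .enrichment import EnrichmentDesign, run_enrichment_trial
from .rct import phase3_sample_size, run_rct, fisher_one_sided_pvalue
from .scenarios import (
    BiomarkerScenario,
    DoseScenario,
    EnrollmentModel,
    sample_biomarker,
    segment_duration,
)
from .single_arm import (
    SingleArmDesign,
    TIE_EPS,
    critical_value,
    run_single_arm_trial,
)

__all__ = [
    "Phase3Rules",
    "SegmentResult",
    "MetricsTable",
    "SegmentASpec",
    "SegmentBSpec",
    "SegmentCSpec",
    "replicate_rng",
    "simulate_replicates",
    "summarize_replicates",
    "estimate_operating_characteristics",
    "sweep",
]


@dataclass(frozen=True)
class Phase3Rules:
    """Sizing rules for a data-driven confirmatory RCT."""

    alpha: float = 0.05
    target_power: float = 0.90
    max_total: int = 400
    sizing: str = "exact"  # or "normal" (two-proportion approximation)


@dataclass(frozen=True)
class SegmentResult:
    """One replicate's trajectory through a two-trial segment.

    ``positive`` is the segment-level success indicator (both trials
    positive; for Segment B additionally a truly safe and effective dose
    selected).  ``positive_unconditional`` (Segment B only) drops the
    dose-quality condition.
    """

    segment: str
    phase_a_positive: bool
    continued: bool
    phase_b_positive: Optional[bool]
    selected_dose: Optional[int]
    selected_cutoff: Optional[float]
    n_total: int
    n_unsafe_or_ineffective: int
    duration_months: float
    phase_b_n: Optional[int]
    capped: bool
    positive: bool
    positive_unconditional: Optional[bool] = None


@dataclass(frozen=True)
class MetricsTable:
    """Monte-Carlo operating characteristics of a segment, with MC SEs.

    Proportion SEs are sqrt(p(1-p)/n); mean SEs use the sample standard
    deviation.  SEs are ``None`` for a single replicate.
    """

    ddp_power: float
    ddp_power_se: Optional[float]
    expected_n_total: float
    expected_n_total_se: Optional[float]
    prob_unsafe_or_ineffective_exposure: float
    prob_unsafe_or_ineffective_exposure_se: Optional[float]
    expected_duration: float
    expected_duration_se: Optional[float]
    selection_distribution: Dict[str, float]
    n_reps: int
    seed: int
    phase_a_positive_rate: float
    ddp_power_unconditional: Optional[float] = None

    def to_row(self) -> Dict[str, object]:
        """Flat dict (selection distribution expanded) for CSV output."""
        row: Dict[str, object] = {
            "n_reps": self.n_reps,
            "seed": self.seed,
            "ddp_power": self.ddp_power,
            "ddp_power_se": self.ddp_power_se,
            "phase_a_positive_rate": self.phase_a_positive_rate,
            "expected_n_total": self.expected_n_total,
            "expected_n_total_se": self.expected_n_total_se,
            "prob_unsafe_or_ineffective_exposure": self.prob_unsafe_or_ineffective_exposure,
            "prob_unsafe_or_ineffective_exposure_se": self.prob_unsafe_or_ineffective_exposure_se,
            "expected_duration": self.expected_duration,
            "expected_duration_se": self.expected_duration_se,
        }
        if self.ddp_power_unconditional is not None:
            row["ddp_power_unconditional"] = self.ddp_power_unconditional
        for label, p in self.selection_distribution.items():
            row[f"sel_{label}"] = p
        return row


# ---------------------------------------------------------------------------
# Segment specifications


@dataclass(frozen=True)
class SegmentASpec:
    """Phase II single-arm trial gating an adaptively sized phase III RCT."""

    phase2: SingleArmDesign
    phase3: Phase3Rules = Phase3Rules()
    true_orr1: float = 0.6
    true_orr0: float = 0.4
    enrollment: EnrollmentModel = EnrollmentModel()

    def simulate(self, rng: np.random.Generator) -> SegmentResult:
        n2 = self.phase2.n2
        r2 = run_single_arm_trial(self.phase2, self.true_orr1, rng=rng)
        if not r2.reject:
            return SegmentResult(
                segment="A",
                phase_a_positive=False,
                continued=False,
                phase_b_positive=None,
                selected_dose=None,
                selected_cutoff=None,
                n_total=n2,
                n_unsafe_or_ineffective=0,
                duration_months=segment_duration(n2, None, self.enrollment),
                phase_b_n=None,
                capped=False,
                positive=False,
            )
        size = phase3_sample_size(
            r2.orr_hat,
            self.phase2.orr0,
            self.phase3.alpha,
            self.phase3.target_power,
            self.phase3.max_total,
            self.phase3.sizing,
        )
        r3 = run_rct(size.n_per_arm, self.true_orr1, self.true_orr0, self.phase3.alpha, rng)
        n3_total = 2 * size.n_per_arm
        return SegmentResult(
            segment="A",
            phase_a_positive=True,
            continued=True,
            phase_b_positive=r3.reject,
            selected_dose=None,
            selected_cutoff=None,
            n_total=n2 + n3_total,
            n_unsafe_or_ineffective=0,
            duration_months=segment_duration(n2, n3_total, self.enrollment),
            phase_b_n=n3_total,
            capped=size.capped,
            positive=r3.reject,
        )

    def selection_label(self, result: SegmentResult) -> str:
        return "phase3" if result.continued else "none"


def _phase2_at_dose(
    true_orr: float,
    true_tox: float,
    n: int,
    orr0: float,
    alpha: float,
    tox_monitor_threshold: float,
    rng: np.random.Generator,
) -> Tuple[bool, int, int]:
    """Fixed-size single-arm phase II at a selected dose, with toxicity monitor.

    Positive requires exact binomial efficacy rejection AND an observed
    adverse-event rate at or below the monitor threshold.
    """
    responses = int(rng.binomial(n, true_orr))
    toxicities = int(rng.binomial(n, true_tox))
    efficacy = responses >= critical_value(n, orr0, alpha)
    safe = toxicities / n <= tox_monitor_threshold + TIE_EPS
    return bool(efficacy and safe), responses, toxicities


@dataclass(frozen=True)
class SegmentBSpec:
    """CRM phase I gating a fixed-size single-arm phase II at the chosen dose.

    A dose is counted unsafe/ineffective when its *true* DLT probability
    exceeds the phase I toxicity target or its true ORR does not beat the
    historical reference.
    """

    phase1: CrmDesign
    scenario: DoseScenario
    phase2_n: int = 42
    phase2_orr0: float = 0.4
    phase2_alpha: float = 0.05
    tox_monitor_threshold: float = 0.25
    enrollment: EnrollmentModel = EnrollmentModel()

    def simulate(self, rng: np.random.Generator) -> SegmentResult:
        crm = run_crm_trial(self.phase1, self.scenario, rng)
        bad = set(self.scenario.bad_doses(self.phase1.tox_target, self.phase2_orr0))
        n_bad = sum(1 for d in crm.assignments if d in bad)
        n1 = self.phase1.n1
        if crm.selected_dose is None:
            return SegmentResult(
                segment="B",
                phase_a_positive=False,
                continued=False,
                phase_b_positive=None,
                selected_dose=None,
                selected_cutoff=None,
                n_total=n1,
                n_unsafe_or_ineffective=n_bad,
                duration_months=segment_duration(n1, None, self.enrollment),
                phase_b_n=None,
                capped=False,
                positive=False,
                positive_unconditional=False,
            )
        j = crm.selected_dose
        positive_b, _, _ = _phase2_at_dose(
            self.scenario.orr[j - 1],
            self.scenario.tox[j - 1],
            self.phase2_n,
            self.phase2_orr0,
            self.phase2_alpha,
            self.tox_monitor_threshold,
            rng,
        )
        if j in bad:
            n_bad += self.phase2_n
        return SegmentResult(
            segment="B",
            phase_a_positive=True,
            continued=True,
            phase_b_positive=positive_b,
            selected_dose=j,
            selected_cutoff=None,
            n_total=n1 + self.phase2_n,
            n_unsafe_or_ineffective=n_bad,
            duration_months=segment_duration(n1, self.phase2_n, self.enrollment),
            phase_b_n=self.phase2_n,
            capped=False,
            positive=bool(positive_b and j not in bad),
            positive_unconditional=bool(positive_b),
        )

    def selection_label(self, result: SegmentResult) -> str:
        return "none" if result.selected_dose is None else str(result.selected_dose)


@dataclass(frozen=True)
class SegmentCSpec:
    """Enrichment phase II gating a phase III RCT in the selected subgroup.

    The phase III is sized from the enrichment trial's own subgroup
    estimates (experimental vs control), enrolls biomarkers uniform on
    [selected cutoff, 1), and responds according to the true curves
    restricted to that subgroup.
    """

    phase2: EnrichmentDesign
    scenario: BiomarkerScenario
    phase3: Phase3Rules = Phase3Rules()
    enrollment: EnrollmentModel = EnrollmentModel()

    def simulate(self, rng: np.random.Generator) -> SegmentResult:
        n2 = self.phase2.n2
        er = run_enrichment_trial(self.phase2, self.scenario, rng)
        if not er.reject:
            return SegmentResult(
                segment="C",
                phase_a_positive=False,
                continued=False,
                phase_b_positive=None,
                selected_dose=None,
                selected_cutoff=None,
                n_total=n2,
                n_unsafe_or_ineffective=0,
                duration_months=segment_duration(n2, None, self.enrollment),
                phase_b_n=None,
                capped=False,
                positive=False,
            )
        cutoff = er.final_cutoff
        assert cutoff is not None
        size = phase3_sample_size(
            er.orr1_hat_sub,
            er.orr0_hat_sub,
            self.phase3.alpha,
            self.phase3.target_power,
            self.phase3.max_total,
            self.phase3.sizing,
        )
        n = size.n_per_arm
        x_exp = sample_biomarker(cutoff, rng, n)
        y_exp = int(np.sum(rng.random(n) < self.scenario.orr1(x_exp)))
        y_ctl = int(rng.binomial(n, self.scenario.orr0))
        p = fisher_one_sided_pvalue(y_exp, n, y_ctl, n)
        reject3 = p <= self.phase3.alpha + TIE_EPS
        return SegmentResult(
            segment="C",
            phase_a_positive=True,
            continued=True,
            phase_b_positive=bool(reject3),
            selected_dose=None,
            selected_cutoff=cutoff,
            n_total=n2 + 2 * n,
            n_unsafe_or_ineffective=0,
            duration_months=segment_duration(n2, 2 * n, self.enrollment),
            phase_b_n=2 * n,
            capped=size.capped,
            positive=bool(reject3),
        )

    def selection_label(self, result: SegmentResult) -> str:
        if result.selected_cutoff is None:
            return "none"
        return format(result.selected_cutoff, ".1f")


SegmentSpec = Union[SegmentASpec, SegmentBSpec, SegmentCSpec]


# ---------------------------------------------------------------------------
# Monte-Carlo engine


def replicate_rng(seed: int, i: int) -> np.random.Generator:
    """Independent stream for replicate i, derived from (seed, i)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))


def simulate_replicates(
    spec: SegmentSpec,
    n_reps: int,
    seed: int,
    start: int = 0,
    progress: Optional[Callable[[int, int], None]] = None,
) -> List[SegmentResult]:
    """Run replicates ``start .. start+n_reps-1`` under per-replicate streams.

    Because replicate i's stream depends only on (seed, i), splitting a run
    into batches and pooling the results reproduces the full run exactly.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    out: List[SegmentResult] = []
    for k in range(n_reps):
        out.append(spec.simulate(replicate_rng(seed, start + k)))
        if progress is not None and (k + 1) % 1000 == 0:
            progress(k + 1, n_reps)
    return out


def _prop_se(p: float, n: int) -> Optional[float]:
    return float(np.sqrt(p * (1.0 - p) / n)) if n > 1 else None


def _mean_se(values: np.ndarray) -> Optional[float]:
    n = values.size
    return float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else None


def summarize_replicates(
    spec: SegmentSpec, results: Sequence[SegmentResult], seed: int
) -> MetricsTable:
    """Aggregate replicate trajectories into a metrics table."""
    n = len(results)
    positive = np.array([r.positive for r in results], dtype=float)
    phase_a = np.array([r.phase_a_positive for r in results], dtype=float)
    n_total = np.array([r.n_total for r in results], dtype=float)
    exposure = np.array(
        [r.n_unsafe_or_ineffective / r.n_total for r in results], dtype=float
    )
    duration = np.array([r.duration_months for r in results], dtype=float)
    labels = [spec.selection_label(r) for r in results]
    counts: Dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    selection = {lab: counts[lab] / n for lab in sorted(counts)}
    uncond = [r.positive_unconditional for r in results]
    ddp_uncond = (
        float(np.mean([bool(u) for u in uncond])) if all(u is not None for u in uncond) else None
    )
    p = float(positive.mean())
    expo = float(exposure.mean())
    return MetricsTable(
        ddp_power=p,
        ddp_power_se=_prop_se(p, n),
        expected_n_total=float(n_total.mean()),
        expected_n_total_se=_mean_se(n_total),
        prob_unsafe_or_ineffective_exposure=expo,
        prob_unsafe_or_ineffective_exposure_se=_mean_se(exposure),
        expected_duration=float(duration.mean()),
        expected_duration_se=_mean_se(duration),
        selection_distribution=selection,
        n_reps=n,
        seed=seed,
        phase_a_positive_rate=float(phase_a.mean()),
        ddp_power_unconditional=ddp_uncond,
    )


def estimate_operating_characteristics(
    spec: SegmentSpec,
    n_reps: int = 10_000,
    seed: int = 0,
    progress: Optional[Callable[[int, int], None]] = None,
) -> MetricsTable:
    """Seeded Monte-Carlo estimate of a segment's operating characteristics."""
    results = simulate_replicates(spec, n_reps, seed, progress=progress)
    return summarize_replicates(spec, results, seed)


def _replace_nested(obj, dotted: str, value):
    head, _, rest = dotted.partition(".")
    if not hasattr(obj, head):
        raise AttributeError(f"{type(obj).__name__} has no field {head!r}")
    if rest:
        value = _replace_nested(getattr(obj, head), rest, value)
    return dataclasses.replace(obj, **{head: value})


def sweep(
    spec: SegmentSpec,
    param: str,
    grid: Sequence,
    n_reps: int = 10_000,
    seed: int = 0,
    progress: Optional[Callable[[int, int], None]] = None,
) -> pd.DataFrame:
    """One metrics row per grid value of a (possibly nested) design field.

    ``param`` is a dotted path on the segment spec, e.g. ``"phase2.n2"``.
    All grid points share the same replicate streams (common random
    numbers), which sharpens between-point comparisons such as
    power-versus-sample-size curves.
    """
    rows = []
    for v in grid:
        point = _replace_nested(spec, param, v)
        table = estimate_operating_characteristics(point, n_reps, seed, progress=progress)
        rows.append({"param": param, "value": v, **table.to_row()})
    return pd.DataFrame(rows)
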