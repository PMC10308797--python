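"""Phase II adaptive biomarker-enrichment randomized trial.

Patients carry a continuous biomarker in [0, 1].  Accrual runs in three
stages (50% / 25% / 25%); after stages 1 and 2 an interim analysis may raise
the eligibility cutoff over a fixed candidate grid, restricting later
enrollment to patients whose biomarker meets the cutoff.  Patients are
randomized 1:1 within consecutive enrollment pairs, and the final analysis
applies an exact one-sided McNemar (sign) test to the discordant pairs whose
members both meet the final cutoff.

The interim adaptation rule implemented here — move to the candidate cutoff
(at or above the current one, with enough complete pairs above it) that
maximizes the observed response-rate difference, requiring strict
improvement and breaking ties toward the larger population — is one member
of the family of staged enrichment designs; alternatives fit behind the
same interface.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .scenarios import BiomarkerScenario, sample_biomarker
from .single_arm import TIE_EPS, _check_prob

__all__ = [
    "EnrichmentDesign",
    "EnrichmentResult",
    "DEFAULT_CUTOFFS",
    "stage_sizes",
    "mcnemar_one_sided",
    "interim_cutoff_update",
    "run_enrichment_trial",
]

DEFAULT_CUTOFFS: Tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 10))

# Eligibility starts fully open: a cutoff of 0.0 means "no enrichment".
NO_ENRICHMENT = 0.0


@dataclass(frozen=True)
class EnrichmentDesign:
    """Design of the staged enrichment trial."""

    n2: int
    cutoffs: Tuple[float, ...] = DEFAULT_CUTOFFS
    stage_fractions: Tuple[float, float, float] = (0.5, 0.25, 0.25)
    alpha: float = 0.05
    min_subgroup_pairs: int = 5

    def __post_init__(self) -> None:
        if self.n2 < 4:
            raise ValueError(f"n2 must be >= 4, got {self.n2}")
        cuts = tuple(float(c) for c in self.cutoffs)
        object.__setattr__(self, "cutoffs", cuts)
        if not all(0.0 < c < 1.0 for c in cuts):
            raise ValueError(f"cutoffs must lie in (0, 1): {cuts}")
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError(f"cutoffs must be strictly increasing: {cuts}")
        fr = tuple(float(f) for f in self.stage_fractions)
        object.__setattr__(self, "stage_fractions", fr)
        if len(fr) != 3 or abs(sum(fr) - 1.0) > 1e-9 or min(fr) <= 0:
            raise ValueError(f"stage_fractions must be 3 positive values summing to 1: {fr}")
        _check_prob("alpha", self.alpha)
        if self.min_subgroup_pairs < 1:
            raise ValueError("min_subgroup_pairs must be >= 1")


@dataclass(frozen=True)
class EnrichmentResult:
    """Final state of one simulated enrichment trial.

    ``final_cutoff`` is the eligibility cutoff at trial end when the trial
    is positive (0.0 meaning no enrichment) and ``None`` when the final
    test fails.  ``cutoff_trajectory`` records the eligibility cutoff at
    the start of each stage plus the final value.
    """

    final_cutoff: Optional[float]
    reject: bool
    orr1_hat_sub: float
    orr0_hat_sub: float
    n_enrolled: int
    pairs_analyzed: int
    p_value: float
    b_discordant: int
    c_discordant: int
    cutoff_trajectory: Tuple[float, ...]


def stage_sizes(n2: int, stage_fractions: Sequence[float] = (0.5, 0.25, 0.25)):
    """Per-stage enrollment counts: rounded stages 1-2, remainder to stage 3."""
    if n2 < 4:
        raise ValueError(f"n2 must be >= 4, got {n2}")
    f1, f2, _ = stage_fractions
    s1 = round(n2 * f1)
    s2 = round(n2 * f2)
    s3 = n2 - s1 - s2
    if min(s1, s2, s3) < 0:
        raise ValueError(f"stage fractions {stage_fractions} give negative stage for n2={n2}")
    return s1, s2, s3


def mcnemar_one_sided(b: int, c: int) -> float:
    """Exact one-sided sign-test p-value for paired binary outcomes.

    ``b`` counts discordant pairs favoring the experimental arm, ``c``
    those favoring control; under the null the split is Binomial(b+c, 1/2).
    Returns 1.0 when there are no discordant pairs.
    """
    if b < 0 or c < 0:
        raise ValueError(f"discordant counts must be non-negative, got b={b}, c={c}")
    if b + c == 0:
        return 1.0
    return float(stats.binom.sf(b - 1, b + c, 0.5))


def _arm_difference_above(
    pairs: np.ndarray, cutoff: float
) -> Optional[float]:
    """ORR difference (experimental - control) among patients above cutoff."""
    xe, ye, xc, yc = pairs[:, 0], pairs[:, 1], pairs[:, 2], pairs[:, 3]
    me = xe >= cutoff
    mc = xc >= cutoff
    if not (me.any() and mc.any()):
        return None
    return float(ye[me].mean() - yc[mc].mean())


def interim_cutoff_update(
    pairs: np.ndarray,
    cutoffs: Sequence[float],
    current_cutoff: float,
    min_subgroup_pairs: int = 5,
) -> float:
    """Interim eligibility-cutoff adaptation (monotone non-decreasing).

    ``pairs`` holds one row per complete pair: columns (biomarker_exp,
    response_exp, biomarker_ctl, response_ctl).  Candidate cutoffs at or
    above the current one qualify when at least ``min_subgroup_pairs``
    complete pairs have both biomarkers above them; among qualifying
    candidates the one maximizing the observed per-arm response-rate
    difference wins, with ties to the lower cutoff, and the current cutoff
    is kept unless some candidate strictly improves on its difference.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.size == 0:
        return current_cutoff
    base = _arm_difference_above(pairs, current_cutoff)
    best_c = current_cutoff
    best_d = -np.inf if base is None else base
    xe, xc = pairs[:, 0], pairs[:, 2]
    for c in cutoffs:
        if c < current_cutoff - TIE_EPS:
            continue
        n_complete = int(np.sum((xe >= c) & (xc >= c)))
        if n_complete < min_subgroup_pairs:
            continue
        d = _arm_difference_above(pairs, c)
        if d is not None and d > best_d + TIE_EPS:
            best_c, best_d = c, d
    return best_c


def _final_analysis(
    pairs: np.ndarray, cutoff: float, alpha: float
) -> Tuple[bool, float, int, int, int, float, float]:
    """McNemar test on complete pairs with both biomarkers >= cutoff."""
    if pairs.size == 0:
        return False, 1.0, 0, 0, 0, 0.0, 0.0
    mask = (pairs[:, 0] >= cutoff) & (pairs[:, 2] >= cutoff)
    sub = pairs[mask]
    n_pairs = int(sub.shape[0])
    if n_pairs == 0:
        return False, 1.0, 0, 0, 0, 0.0, 0.0
    ye = sub[:, 1] > 0.5
    yc = sub[:, 3] > 0.5
    b = int(np.sum(ye & ~yc))
    c = int(np.sum(~ye & yc))
    p = mcnemar_one_sided(b, c)
    reject = p <= alpha + TIE_EPS
    return reject, p, n_pairs, b, c, float(ye.mean()), float(yc.mean())


def _enroll_stage(
    size: int,
    lower: float,
    scenario: BiomarkerScenario,
    rng: np.random.Generator,
) -> np.ndarray:
    """Enroll a stage of ``size`` eligible patients as consecutive 1:1 pairs.

    Returns one row per complete pair; an odd trailing patient is enrolled
    (their biomarker and outcome are drawn) but cannot form a pair and
    contributes nothing to the analysis.  Because both pair members draw
    i.i.d. biomarkers and outcomes, randomizing the order within a pair is
    statistically equivalent to labeling the first member experimental.
    """
    n_pairs = size // 2
    xe = sample_biomarker(lower, rng, n_pairs)
    ye = (rng.random(n_pairs) < scenario.orr1(xe)).astype(float)
    xc = sample_biomarker(lower, rng, n_pairs)
    yc = (rng.random(n_pairs) < scenario.orr0).astype(float)
    if size % 2:
        x_last = sample_biomarker(lower, rng)
        arm_exp = rng.random() < 0.5
        p_last = float(scenario.orr1(x_last)) if arm_exp else scenario.orr0
        rng.random() < p_last  # outcome observed but unpaired
    return np.column_stack([xe, ye, xc, yc])


def run_enrichment_trial(
    design: EnrichmentDesign,
    scenario: BiomarkerScenario,
    rng: np.random.Generator,
) -> EnrichmentResult:
    """Simulate one staged enrichment trial.

    Stage 1 enrolls from the full biomarker range; interim analyses after
    stages 1 and 2 may raise the eligibility cutoff, and stages 2-3 enroll
    only patients at or above it.  The final analysis tests all complete
    pairs whose members both meet the final cutoff.
    """
    sizes = stage_sizes(design.n2, design.stage_fractions)
    cutoff = NO_ENRICHMENT
    trajectory = [cutoff]
    pair_blocks: list[np.ndarray] = []
    for stage, size in enumerate(sizes):
        pair_blocks.append(_enroll_stage(size, cutoff, scenario, rng))
        if stage < 2:
            pairs_so_far = np.vstack(pair_blocks)
            cutoff = interim_cutoff_update(
                pairs_so_far, design.cutoffs, cutoff, design.min_subgroup_pairs
            )
            trajectory.append(cutoff)
    pairs = np.vstack(pair_blocks)
    reject, p, n_pairs, b, c, orr1_hat, orr0_hat = _final_analysis(
        pairs, cutoff, design.alpha
    )
    trajectory.append(cutoff)
    return EnrichmentResult(
        final_cutoff=cutoff if reject else None,
        reject=reject,
        orr1_hat_sub=orr1_hat,
        orr0_hat_sub=orr0_hat,
        n_enrolled=design.n2,
        pairs_analyzed=n_pairs,
        p_value=p,
        b_discordant=b,
        c_discordant=c,
        cutoff_trajectory=tuple(trajectory),
    )
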