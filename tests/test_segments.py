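"""Segment composition, gating logic, Monte-Carlo engine and metrics."""
import dataclasses

import numpy as np
import pytest
from scipy import stats

from ddpsim.crm import CrmDesign
from ddpsim.enrichment import EnrichmentDesign
from ddpsim.rct import exact_unconditional_power, phase3_sample_size
from ddpsim.scenarios import (
    DoseScenario,
    make_default_biomarker_scenario,
    make_default_dose_scenario,
    make_null_biomarker_scenario,
)
from ddpsim.segments import (
    SegmentASpec,
    SegmentBSpec,
    SegmentCSpec,
    _phase2_at_dose,
    estimate_operating_characteristics,
    replicate_rng,
    simulate_replicates,
    summarize_replicates,
    sweep,
)
from ddpsim.single_arm import SingleArmDesign, critical_value


def _spec_a(n2: int, true_orr1: float = 0.6) -> SegmentASpec:
    return SegmentASpec(phase2=SingleArmDesign(n2=n2), true_orr1=true_orr1)


def test_rejecting_phase2_always_beats_reference():
    """Any rejecting phase II yields an estimate above the historical 0.4.

    This guarantees the precondition of the phase III sizing (p1_hat >
    p0_ref) over the whole design range.
    """
    for n2 in range(20, 141):
        assert critical_value(n2, 0.4, 0.05) / n2 > 0.4


def test_segment_gating_invariants_all_types():
    specs = [
        _spec_a(40),
        SegmentBSpec(phase1=CrmDesign(n1=12), scenario=make_default_dose_scenario()),
        SegmentCSpec(
            phase2=EnrichmentDesign(n2=40), scenario=make_default_biomarker_scenario()
        ),
    ]
    for spec in specs:
        for res in simulate_replicates(spec, 150, seed=101):
            if res.continued:
                assert res.phase_a_positive
            if res.positive:
                assert res.continued and res.phase_b_positive
            if not res.continued:
                assert res.phase_b_positive is None and res.phase_b_n is None
            assert res.n_total >= (res.phase_b_n or 0)
            assert res.duration_months > 0


def test_segment_a_terminates_on_negative_phase2():
    spec = _spec_a(30, true_orr1=0.0)
    res = spec.simulate(replicate_rng(1, 0))
    assert not res.continued and res.n_total == 30


def test_segment_a_total_and_cap_bounds():
    for res in simulate_replicates(_spec_a(30), 300, seed=7):
        if res.continued:
            assert 30 < res.n_total <= 30 + 400
            assert res.n_total == 30 + res.phase_b_n
        else:
            assert res.n_total == 30


def test_segment_a_matches_semianalytic_decomposition():
    """Simulated segment power equals the no-simulation decomposition.

    Independent oracle: sum over rejecting phase II outcomes x of
    Binomial(n2, 0.6) mass times the exact unconditional Fisher power of
    the phase III sized at x/n2 — no phase III simulation involved.
    """
    n2, n_reps = 30, 10_000
    r = critical_value(n2, 0.4, 0.05)
    exact = sum(
        stats.binom.pmf(x, n2, 0.6)
        * exact_unconditional_power(
            phase3_sample_size(x / n2, 0.4).n_per_arm, 0.6, 0.4, 0.05
        )
        for x in range(r, n2 + 1)
    )
    table = estimate_operating_characteristics(_spec_a(n2), n_reps, seed=2027)
    se = np.sqrt(exact * (1 - exact) / n_reps)
    assert abs(table.ddp_power - exact) <= 3 * se


def test_segment_b_phase2_positive_rate_matches_closed_form(rng_factory):
    """Efficacy x toxicity-monitor pass rate factorizes into binomial tails."""
    orr, tox, n, thr = 0.6, 0.12, 42, 0.25
    expected = float(
        stats.binom.sf(critical_value(n, 0.4, 0.05) - 1, n, orr)
        * stats.binom.cdf(int(np.floor(thr * n)), n, tox)
    )
    rng = rng_factory(55)
    n_reps = 10_000
    hits = sum(
        _phase2_at_dose(orr, tox, n, 0.4, 0.05, thr, rng)[0] for _ in range(n_reps)
    )
    se = np.sqrt(expected * (1 - expected) / n_reps)
    assert abs(hits / n_reps - expected) <= 3 * se


def test_segment_b_stops_without_safe_dose_and_counts_exposure():
    brutal = DoseScenario(tox=(0.9,) * 6, orr=(0.5,) * 6)
    spec = SegmentBSpec(phase1=CrmDesign(n1=20), scenario=brutal)
    results = simulate_replicates(spec, 300, seed=11)
    stopped = [r for r in results if not r.continued]
    assert len(stopped) / len(results) >= 0.95
    for r in stopped:
        assert r.n_total == 20 and r.selected_dose is None
    # every dose is unsafe here, so every phase I patient counts as exposed
    for r in results:
        assert r.n_unsafe_or_ineffective >= 20 or r.continued


def test_segment_b_exposure_zero_when_all_doses_good():
    benign = DoseScenario(tox=(0.01, 0.02, 0.03), orr=(0.6, 0.65, 0.7))
    spec = SegmentBSpec(
        phase1=CrmDesign(n1=15, skeleton=(0.05, 0.12, 0.25), start_dose=1),
        scenario=benign,
    )
    table = estimate_operating_characteristics(spec, 100, seed=13)
    assert table.prob_unsafe_or_ineffective_exposure == 0.0
    assert table.ddp_power == table.ddp_power_unconditional


def test_segment_c_duration_and_termination():
    spec = SegmentCSpec(
        phase2=EnrichmentDesign(n2=40), scenario=make_null_biomarker_scenario()
    )
    for res in simulate_replicates(spec, 100, seed=3):
        if not res.continued:
            assert res.n_total == 40
            assert res.duration_months == pytest.approx(40 / 4 + 6)
        else:
            assert res.selected_cutoff is not None


def test_selection_distribution_sums_to_one():
    specs = [
        _spec_a(30),
        SegmentBSpec(phase1=CrmDesign(n1=10), scenario=make_default_dose_scenario()),
        SegmentCSpec(
            phase2=EnrichmentDesign(n2=40), scenario=make_default_biomarker_scenario()
        ),
    ]
    for spec in specs:
        table = estimate_operating_characteristics(spec, 400, seed=19)
        assert abs(sum(table.selection_distribution.values()) - 1.0) < 1e-12
        assert all(0 <= v <= 1 for v in table.selection_distribution.values())


def test_engine_determinism_and_split_pooling():
    spec = _spec_a(40)
    t1 = estimate_operating_characteristics(spec, 400, seed=23)
    t2 = estimate_operating_characteristics(spec, 400, seed=23)
    assert t1 == t2  # bit-identical tables
    # replicate streams depend only on (seed, index): halves pool exactly
    full = simulate_replicates(spec, 400, seed=23)
    halves = simulate_replicates(spec, 200, seed=23) + simulate_replicates(
        spec, 200, seed=23, start=200
    )
    assert full == halves
    assert summarize_replicates(spec, halves, 23) == t1


def test_single_replicate_metrics_degenerate():
    table = estimate_operating_characteristics(_spec_a(40), 1, seed=5)
    assert table.n_reps == 1
    assert table.ddp_power in (0.0, 1.0)
    assert table.ddp_power_se is None and table.expected_n_total_se is None


def test_sweep_power_monotone_and_gated():
    spec = _spec_a(30)
    grid = list(range(20, 141, 20))
    df = sweep(spec, "phase2.n2", grid, n_reps=800, seed=29)
    assert list(df["value"]) == grid
    # gating: segment power can never exceed the phase II rejection rate
    assert (df["ddp_power"] <= df["phase_a_positive_rate"] + 1e-12).all()
    # power climbs with n2 up to twice the Monte-Carlo noise
    p = df["ddp_power"].to_numpy()
    se = df["ddp_power_se"].to_numpy()
    for i in range(len(grid) - 1):
        tol = 2 * np.sqrt(se[i] ** 2 + se[i + 1] ** 2)
        assert p[i + 1] >= p[i] - tol
    # accrual arithmetic: expected duration grows with the first-trial size
    d = df["expected_duration"].to_numpy()
    assert (np.diff(d) > 0).all()


def test_sweep_rejects_unknown_parameter():
    with pytest.raises(AttributeError):
        sweep(_spec_a(30), "phase2.nonsense", [1], n_reps=1, seed=0)


def test_specs_are_immutable():
    spec = _spec_a(30)
    with pytest.raises(dataclasses.FrozenInstanceError):
        spec.true_orr1 = 0.5
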