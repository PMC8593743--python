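import dataclasses

import numpy as np
import pytest

from psorcea import (RewardConvention, Strategy, Timeline, build_strategies,
                     degenerate_scenario, enumerate_pathways, evaluate_arm,
                     generate_scenario, review_schedule, SyntheticSpec)
from psorcea.engine import evaluate_arms_vectorized
from psorcea.scenario import BscCosts, MonitoringCosts

CONVENTIONS = [
    RewardConvention(),
    RewardConvention("cycle_start_membership"),
    RewardConvention("cycle_end_membership"),
    RewardConvention("half_cycle_on_failure", "stop_mid_cycle"),
]


@pytest.mark.parametrize("start, expected", [
    (0, [12, 36, 60, 84]),
    (36, [48, 72]),
    (90, []),
])
def test_review_schedule(start, expected):
    assert review_schedule(start, Timeline()) == expected


def test_review_schedule_terminal_boundary():
    # a line starting at week 84 is reviewed exactly at the horizon
    assert review_schedule(84, Timeline()) == []
    assert review_schedule(84, Timeline(), include_terminal=True) == [96]


def test_flat_utility_gives_closed_form_qalys():
    cfg = degenerate_scenario("flat_utility", flat_utility=0.5)
    expected = 96 / 52 * 0.5
    for conv in CONVENTIONS:
        for s in build_strategies(cfg):
            r = evaluate_arm(s, cfg, conv, want_trace=False)
            assert r.total_qaly == pytest.approx(expected, abs=1e-6)


def _drug_costs_only(cfg):
    return dataclasses.replace(
        cfg,
        monitoring=MonitoringCosts(0, 0, 0, 0),
        bsc=BscCosts(0, 0, 0, 0),
    )


def test_zero_efficacy_single_line_drug_cost():
    """With no responders, a one-line tildrakizumab cohort buys exactly the
    two induction dispenses (plain per-cycle cost accrual)."""
    cfg = _drug_costs_only(degenerate_scenario("zero_efficacy"))
    strategy = Strategy("tild_only", ("tildrakizumab",))
    r = evaluate_arm(strategy, cfg, RewardConvention("cycle_end_membership"),
                     want_trace=False)
    assert r.total_cost == pytest.approx(2 * 3246, abs=1e-3)


def test_zero_efficacy_cohort_in_bsc_from_week_36(base_config):
    cfg = degenerate_scenario("zero_efficacy")
    s = build_strategies(cfg)[0]
    r = evaluate_arm(s, cfg)
    states = r.trace.states
    late = states[(states.week_start >= 36)
                  & (~states.state.str.startswith("BSC"))]
    assert late.fraction.sum() == pytest.approx(0.0, abs=1e-9)


def test_perfect_efficacy_stays_on_first_line():
    cfg = degenerate_scenario("perfect_efficacy")
    s = build_strategies(cfg)[0]
    r = evaluate_arm(s, cfg)
    states = r.trace.states
    final = states[states.cycle == states.cycle.max()]
    on_first = final[final.state.str.startswith(f"{s.name}:maintenance")]
    assert on_first.fraction.sum() == pytest.approx(1.0, abs=1e-9)


def test_mass_conservation_and_nonnegativity(base_results):
    for r in base_results:
        per_cycle = r.trace.states.groupby("cycle")["fraction"].sum()
        assert np.allclose(per_cycle.values, 1.0, atol=1e-9)
        assert (r.trace.states.fraction >= -1e-15).all()


def test_qaly_bounds_on_base_case(base_results):
    lo, hi = 96 / 52 * 0.64, 96 / 52 * 0.89
    for r in base_results:
        assert lo <= r.total_qaly <= hi
        assert r.total_cost >= 0


@pytest.mark.parametrize("seed", range(12))
@pytest.mark.parametrize("conv", CONVENTIONS, ids=lambda c: f"{c.utility_timing[:9]}-{c.failure_dosing[:4]}")
def test_engine_equals_pathway_oracle_on_synthetic_scenarios(seed, conv):
    """Cohort propagation and exhaustive pathway enumeration are independent
    routes to the same expectations."""
    cfg = generate_scenario(SyntheticSpec(seed=seed, n_drugs=3))
    strategy = Strategy("all_lines", tuple(cfg.drugs))
    r = evaluate_arm(strategy, cfg, conv, want_trace=False)
    paths = enumerate_pathways(strategy, cfg, conv)
    p = sum(x.probability for x in paths)
    assert p == pytest.approx(1.0, abs=1e-12)
    assert sum(x.probability * x.cost for x in paths) == pytest.approx(
        r.total_cost, abs=1e-6)
    assert sum(x.probability * x.qaly for x in paths) == pytest.approx(
        r.total_qaly, abs=1e-9)


def test_single_line_qaly_monotone_in_efficacy(base_config):
    """More induction or maintenance response never lowers lifetime QALYs."""
    strategy = Strategy("tild_only", ("tildrakizumab",))
    conv = RewardConvention()
    grid = np.linspace(0.05, 0.95, 7)
    for key in ("p_induction", "p_maintenance"):
        qalys = [
            float(evaluate_arms_vectorized(
                strategy, base_config, conv,
                {(key, "tildrakizumab"): v})[1])
            for v in grid
        ]
        assert all(b >= a - 1e-12 for a, b in zip(qalys, qalys[1:]))


def test_identical_drugs_give_identical_arms(base_config):
    profile = base_config.drugs["tildrakizumab"]
    clones = {
        name: dataclasses.replace(profile, name=name)
        for name in base_config.drugs
    }
    cfg = dataclasses.replace(base_config, drugs=clones).validate()
    results = [evaluate_arm(s, cfg, want_trace=False)
               for s in build_strategies(cfg)]
    costs = {round(r.total_cost, 9) for r in results}
    qalys = {round(r.total_qaly, 12) for r in results}
    assert len(costs) == 1 and len(qalys) == 1


def test_vectorized_matches_scalar(base_config):
    strategy = build_strategies(base_config)[0]
    conv = RewardConvention()
    scalar = evaluate_arm(strategy, base_config, conv, want_trace=False)
    overrides = {("p_induction", "tildrakizumab"):
                 np.full(5, base_config.drugs["tildrakizumab"].p_induction)}
    c, q = evaluate_arms_vectorized(strategy, base_config, conv, overrides)
    assert np.allclose(c, scalar.total_cost, atol=1e-9)
    assert np.allclose(q, scalar.total_qaly, atol=1e-12)


def test_unknown_drug_in_strategy_raises(base_config):
    with pytest.raises(KeyError):
        evaluate_arm(Strategy("bad", ("notadrug",)), base_config)
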