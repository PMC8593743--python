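import math
import warnings

import numpy as np
import pytest

from psorcea import (OwsaSpec, RewardConvention, beta_from_mean_ci,
                     beta_from_mean_sd, build_strategies, classify,
                     evaluate_arm, gamma_from_mean_cv, icur, owsa_ranges,
                     run_owsa, run_psa)
from psorcea.sensitivity import DistributionSpec, psa_distributions


class TestBetaFromMeanCI:
    def test_method_of_moments_fit(self):
        spec = beta_from_mean_ci(0.886, 0.806, 0.936)
        assert spec.family == "beta"
        a, b = spec.params["alpha"], spec.params["beta"]
        assert a == pytest.approx(80.5, abs=0.5)
        assert b == pytest.approx(10.4, abs=0.2)
        assert spec.mean == pytest.approx(0.886, abs=1e-9)

    def test_degenerate_ci_is_point_mass(self):
        assert beta_from_mean_ci(0.5, 0.5, 0.5).family == "point_mass"

    def test_infeasible_falls_back_with_warning(self):
        with pytest.warns(UserWarning):
            spec = beta_from_mean_ci(0.05, 0.0001, 0.9999)
        assert spec.family == "point_mass"

    def test_sampled_mean_matches(self):
        spec = beta_from_mean_ci(0.886, 0.806, 0.936)
        rng = np.random.default_rng(0)
        x = spec.sample(rng, 1_000_000)
        se = x.std() / 1000
        assert abs(x.mean() - 0.886) < 3 * se


class TestBetaFromMeanSD:
    def test_fit(self):
        spec = beta_from_mean_sd(0.89, 0.11)
        assert spec.params["alpha"] == pytest.approx(6.31, abs=0.02)
        assert spec.params["beta"] == pytest.approx(0.78, abs=0.02)
        assert spec.mean == pytest.approx(0.89, abs=1e-9)

    def test_infeasible_sd_clamped(self):
        # max feasible sd is sqrt(0.64*0.36) ~ 0.48 < 0.49
        with pytest.warns(UserWarning):
            spec = beta_from_mean_sd(0.64, 0.49)
        assert spec.family == "beta"
        assert spec.mean == pytest.approx(0.64, abs=1e-9)
        a, b = spec.params["alpha"], spec.params["beta"]
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert math.sqrt(var) == pytest.approx(0.99 * math.sqrt(0.64 * 0.36),
                                               rel=1e-6)

    def test_zero_sd_point_mass(self):
        assert beta_from_mean_sd(0.3, 0.0).family == "point_mass"

    def test_mean_outside_unit_interval_raises(self):
        with pytest.raises(ValueError):
            beta_from_mean_sd(1.2, 0.1)


class TestGamma:
    def test_closed_form(self):
        spec = gamma_from_mean_cv(5644, 0.2)
        assert spec.params["shape"] == pytest.approx(25.0)
        assert spec.params["scale"] == pytest.approx(225.76)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gamma_from_mean_cv(-1, 0.2)
        with pytest.raises(ValueError):
            gamma_from_mean_cv(100, 0)

    def test_sampled_mean(self):
        spec = gamma_from_mean_cv(5644, 0.2)
        rng = np.random.default_rng(1)
        x = spec.sample(rng, 1_000_000)
        assert abs(x.mean() - 5644) < 3 * x.std() / 1000


class TestOwsa:
    def test_base_value_reproduces_base_icur(self, base_config, base_by_name):
        spec = OwsaSpec("tildrakizumab.p_induction", 0.629, 0.629, 0.629,
                        ("p_induction", "tildrakizumab"))
        tor = run_owsa(base_config, specs=[spec])
        base_icur = icur(
            base_by_name["secukinumab"].total_cost,
            base_by_name["secukinumab"].total_qaly,
            base_by_name["tildrakizumab"].total_cost,
            base_by_name["tildrakizumab"].total_qaly)
        got = tor[tor.strategy == "secukinumab"]["icur_vs_reference"]
        assert np.allclose(got, base_icur, rtol=1e-12)

    def test_single_parameter_two_rows_per_strategy(self, base_config):
        spec = OwsaSpec("utility_controlled", 0.8, 0.89, 0.95, "u_controlled")
        tor = run_owsa(base_config, specs=[spec])
        assert len(tor) == 2 * 7    # low/high x non-reference strategies

    def test_reference_never_displaced(self, base_config):
        """At every parameter bound tildrakizumab stays on the frontier: no
        arm is simultaneously cheaper and more effective."""
        tor = run_owsa(base_config)
        displaced = tor[(tor.cost <= tor.reference_cost)
                        & (tor.qaly >= tor.reference_qaly)]
        assert displaced.empty

    def test_range_drivers(self, base_config):
        tor = run_owsa(base_config)
        r = owsa_ranges(tor).set_index("strategy")
        assert r.loc["secukinumab", "driver_min"] == "secukinumab.p_maintenance"
        assert r.loc["secukinumab", "driver_max"] == "secukinumab.p_maintenance"
        assert r.loc["risankizumab", "driver_max"] == "utility_controlled"


class TestPsa:
    def test_degenerate_psa_equals_base_case(self, base_config, base_by_name):
        dists = {k: DistributionSpec("point_mass", {"value": d.mean})
                 for k, d in psa_distributions(base_config).items()}
        res = run_psa(base_config, n_iterations=3, seed=0,
                      distributions=dists)
        for _, row in res.summary.iterrows():
            base = base_by_name[row.strategy]
            assert row.mean_cost == pytest.approx(base.total_cost, abs=1e-9)
            assert row.mean_qaly == pytest.approx(base.total_qaly, abs=1e-12)

    def test_fixed_seed_reproducible(self, base_config):
        a = run_psa(base_config, n_iterations=200, seed=42)
        b = run_psa(base_config, n_iterations=200, seed=42)
        assert a.summary.equals(b.summary)
        assert a.ceac.equals(b.ceac)

    def test_ceac_rows_sum_to_one(self, base_config):
        res = run_psa(base_config, n_iterations=500, seed=7)
        arms = [c for c in res.ceac.columns if c != "wtp"]
        assert np.allclose(res.ceac[arms].sum(axis=1), 1.0, atol=1e-9)
        assert ((res.ceac[arms] >= 0) & (res.ceac[arms] <= 1)).all().all()

    def test_ceac_at_zero_wtp_is_cheapest_fraction(self, base_config):
        res = run_psa(base_config, n_iterations=500, seed=3)
        cheapest = (res.costs.values.argmin(axis=1))
        frac = (res.costs.columns[cheapest] == "tildrakizumab").mean()
        row0 = res.ceac.iloc[0]
        assert row0["wtp"] == 0
        assert row0["tildrakizumab"] == pytest.approx(frac, abs=1e-12)

    def test_single_iteration_indicators(self, base_config):
        res = run_psa(base_config, n_iterations=1, seed=9)
        arms = [c for c in res.ceac.columns if c != "wtp"]
        vals = res.ceac[arms].values
        assert set(np.unique(vals)) <= {0.0, 1.0}

    def test_two_seeds_agree_within_monte_carlo_error(self, base_config):
        n = 2000
        a = run_psa(base_config, n_iterations=n, seed=1)
        b = run_psa(base_config, n_iterations=n, seed=2)
        for arm in a.costs.columns:
            se = math.hypot(a.costs[arm].std() / math.sqrt(n),
                            b.costs[arm].std() / math.sqrt(n))
            assert abs(a.costs[arm].mean() - b.costs[arm].mean()) < 4 * se
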