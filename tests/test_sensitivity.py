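import copy

import numpy as np
import pandas as pd
import pytest

from crcscreen.cohort import run_all_strategies
from crcscreen.sensitivity import (
    DistributionSpec,
    default_psa_distributions,
    get_param,
    one_way_sa,
    run_psa,
    sample_psa_draw,
    scenario_intervals_and_endage,
    scenario_lb_polyp,
    set_param,
    strategy_frontier,
    threshold_price,
)


class TestParameterAddressing:
    def test_get_and_set_round_trip(self, params):
        assert get_param(params, "costs.lb") == 949.0
        assert get_param(params, "tests.lb.cancer_sensitivity") == 0.82
        p = set_param(params, "costs.lb", 500.0)
        assert get_param(p, "costs.lb") == 500.0
        assert get_param(params, "costs.lb") == 949.0  # original untouched

    def test_detection_rate_pair_stays_complementary(self, params):
        p = set_param(params, "tests.colonoscopy.colo_cancer_detection_rate", 0.9)
        assert p.tests["colonoscopy"].colo_interval_cancer_rate == pytest.approx(0.1)

    def test_unknown_path_rejected(self, params):
        with pytest.raises(KeyError, match="unknown parameter path"):
            get_param(params, "costs.nope")
        with pytest.raises(KeyError):
            set_param(params, "tests.mri.specificity", 0.9)


class TestOneWay:
    def test_unused_parameter_has_zero_range(self, params):
        # stool-DNA specificity plays no role in the NH-vs-LB comparison
        entry = one_way_sa(
            "tests.sdna.specificity", (0.85, 0.95), ("NH", "LB"), params
        )
        assert entry.icer_low == pytest.approx(entry.icer_high, rel=1e-12)
        assert entry.range_width == pytest.approx(0.0, abs=1e-6)

    def test_icer_increases_with_blood_test_price(self, params):
        grid = [0.0, 200.0, 500.0, 949.0]
        icers = []
        from crcscreen.sensitivity import _icer

        for price in grid:
            icers.append(_icer(set_param(params, "costs.lb", price), ("NH", "LB")))
        assert all(a < b for a, b in zip(icers, icers[1:]))

    def test_cost_bounds_match_direct_recomputation(self, params):
        entry = one_way_sa("costs.lb", (949.0 * 0.75, 949.0 * 1.25), ("NH", "LB"), params)
        from crcscreen.sensitivity import _icer

        assert entry.icer_low == pytest.approx(
            _icer(set_param(params, "costs.lb", 949.0 * 0.75), ("NH", "LB"))
        )
        assert entry.icer_high == pytest.approx(
            _icer(set_param(params, "costs.lb", 949.0 * 1.25), ("NH", "LB"))
        )

    def test_bounds_must_bracket_base(self, params):
        with pytest.raises(ValueError, match="bracket"):
            one_way_sa("costs.lb", (1000.0, 2000.0), ("NH", "LB"), params)


class TestThreshold:
    def test_linear_closed_form_oracle(self, params):
        """The ICER is exactly linear in the blood-test price, so the
        bisection must agree with the closed-form crossing."""
        from crcscreen.sensitivity import _icer

        i0 = _icer(set_param(params, "costs.lb", 0.0), ("NH", "LB"))
        i949 = _icer(set_param(params, "costs.lb", 949.0), ("NH", "LB"))
        b = (i949 - i0) / 949.0
        closed_form = (100_000.0 - i0) / b
        res = threshold_price(
            "costs.lb", ("NH", "LB"), 100_000.0, params, (0.0, 949.0), tol=0.5
        )
        assert res.crossed
        assert res.price == pytest.approx(closed_form, abs=0.5)

    def test_threshold_far_below_market_price(self, params):
        res = threshold_price("costs.lb", ("NH", "LB"), 100_000.0, params, (0.0, 949.0))
        assert res.crossed and res.price < 300.0

    def test_no_crossing_returns_endpoint_with_flag(self, params):
        res = threshold_price(
            "costs.lb", ("NH", "LB"), 1e9, params, (0.0, 949.0), tol=1.0
        )
        assert not res.crossed
        assert res.price == 949.0
        assert "already cost-effective" in res.message

    def test_stable_under_tolerance_halving(self, params):
        a = threshold_price("costs.lb", ("NH", "LB"), 100_000.0, params, (0.0, 949.0), tol=2.0)
        b = threshold_price("costs.lb", ("NH", "LB"), 100_000.0, params, (0.0, 949.0), tol=1.0)
        assert abs(a.price - b.price) <= 2 * 2.0


class TestScenarios:
    def test_zero_polyp_sensitivity_is_base_case(self, params):
        df = scenario_lb_polyp([0.0], [0.0], params)
        base = strategy_frontier(params)
        row = df[df.strategy == "C-LB"].iloc[0]
        assert row["icer"] == pytest.approx(base["C-LB"].icer)
        assert row["status"] == base["C-LB"].status

    def test_polyp_detection_lowers_hybrid_icer(self, params):
        df = scenario_lb_polyp([0.0, 0.10], [0.0, 0.05], params)
        clb = df[df.strategy == "C-LB"].set_index(["hr_sensitivity", "lr_sensitivity"])
        base_icer = clb.loc[(0.0, 0.0), "icer"]
        assert clb.loc[(0.10, 0.05), "icer"] < base_icer
        # monotone along the HR-sensitivity axis at fixed LR sensitivity
        assert clb.loc[(0.10, 0.0), "icer"] < base_icer

    def test_grid_outside_unit_interval_rejected(self, params):
        with pytest.raises(ValueError):
            scenario_lb_polyp([1.5], [0.0], params)

    def test_longer_lr_interval_means_fewer_surveillance_colonoscopies(self, params):
        from crcscreen.cohort import _run_subcohort
        from crcscreen.strategies import build_strategy

        def surveillance_mass(lr_interval):
            spec = build_strategy("Colonoscopy", lr_surveillance_interval=lr_interval)
            trace = _run_subcohort("colonoscopy", 10, spec, params)
            return sum(
                ev.colonoscopies.get("surveillance_plain", 0.0)
                + ev.colonoscopies.get("surveillance_polypectomy", 0.0)
                for ev in trace.events
            )

        assert surveillance_mass(10) < surveillance_mass(5)

    def test_extended_end_age_never_reduces_life_years(self, params):
        df = scenario_intervals_and_endage((5,), (75, 85), params)
        lyg = df.pivot_table(index="strategy", columns="screen_end_age", values="lyg")
        for name in ("FIT", "Colonoscopy", "S-DNA", "LB", "C-LB"):
            assert lyg.loc[name, 85] >= lyg.loc[name, 75] - 1e-12

    def test_base_configuration_row_matches_base_case(self, params):
        df = scenario_intervals_and_endage((5,), (75,), params)
        base = strategy_frontier(params)
        row = df[df.strategy == "Colonoscopy"].iloc[0]
        assert row["cost"] == pytest.approx(base["Colonoscopy"].cost)
        assert row["lyg"] == pytest.approx(base["Colonoscopy"].effectiveness)
        assert bool(row["conclusion_unchanged"])


class TestDistributions:
    def test_degenerate_returns_mean(self):
        rng = np.random.default_rng(0)
        d = DistributionSpec("degenerate", 0.82)
        assert d.sample(rng) == 0.82

    def test_beta_moment_matching(self):
        rng = np.random.default_rng(1)
        d = DistributionSpec("beta", 0.82, 0.05)
        draws = np.array([d.sample(rng) for _ in range(20_000)])
        assert np.all((draws >= 0) & (draws <= 1))
        assert draws.mean() == pytest.approx(0.82, abs=0.005)
        assert draws.std() == pytest.approx(0.05, abs=0.005)

    def test_gamma_moment_matching(self):
        rng = np.random.default_rng(2)
        d = DistributionSpec("gamma", 949.0, 120.0)
        draws = np.array([d.sample(rng) for _ in range(20_000)])
        assert np.all(draws >= 0)
        assert draws.mean() == pytest.approx(949.0, rel=0.02)
        assert draws.std() == pytest.approx(120.0, rel=0.05)

    def test_infeasible_beta_moments_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="infeasible beta"):
            DistributionSpec("beta", 0.5, 0.6).sample(rng)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            DistributionSpec("normal", 0.5, 0.1)


class TestPsa:
    def test_degenerate_distributions_collapse_to_base_case(self, params, base_outcomes):
        dists = {
            path: DistributionSpec("degenerate", spec.mean)
            for path, spec in default_psa_distributions(params).items()
        }
        res = run_psa(3, seed=11, wtp_grid=[100_000.0], params=params, distributions=dists)
        for name, o in base_outcomes.items():
            sub = res.draws[res.draws.strategy == name]
            np.testing.assert_allclose(sub["cost"], o.discounted_cost, rtol=1e-12)
            np.testing.assert_allclose(sub["effect"], o.undiscounted_lyg, rtol=1e-12)

    def test_same_seed_bit_identical(self, params):
        a = run_psa(8, seed=42, wtp_grid=[50_000.0, 100_000.0], params=params)
        b = run_psa(8, seed=42, wtp_grid=[50_000.0, 100_000.0], params=params)
        pd.testing.assert_frame_equal(a.draws, b.draws)
        pd.testing.assert_frame_equal(a.ceac, b.ceac)

    def test_ceac_rows_sum_to_one_and_reference_declines(self, params):
        res = run_psa(20, seed=5, wtp_grid=[0.0, 20_000.0, 100_000.0], params=params)
        sums = res.ceac.groupby("wtp")["probability"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        nh = res.ceac[res.ceac.strategy == "NH"].sort_values("wtp")["probability"]
        assert np.all(np.diff(nh.to_numpy()) <= 1e-9)

    def test_draw_respects_support(self, params):
        rng = np.random.default_rng(9)
        draw = sample_psa_draw(default_psa_distributions(params), rng, params)
        for mod in ("fit", "sdna", "lb"):
            t = draw.tests[mod]
            assert 0 <= t.cancer_sensitivity <= 1
            assert 0 <= t.specificity <= 1
        assert draw.costs.lb >= 0
        det = draw.tests["colonoscopy"]
        assert det.colo_cancer_detection_rate + det.colo_interval_cancer_rate == pytest.approx(1.0)

    def test_invalid_iteration_count(self, params):
        with pytest.raises(ValueError):
            run_psa(0, seed=1, wtp_grid=[1.0], params=params)
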