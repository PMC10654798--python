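import numpy as np
import pytest

from crcscreen.cohort import (
    CohortTrace,
    CostSet,
    Outcomes,
    accrue_outcomes,
    discount_factor,
    run_cohort,
)
from crcscreen.natural_history import StateSpace
from crcscreen.sensitivity import set_param
from crcscreen.strategies import STRATEGY_NAMES, build_strategy
from crcscreen.synthetic_epi import life_expectancy


class TestDiscounting:
    def test_year_zero_and_zero_rate(self):
        assert discount_factor(0, 0.03) == 1.0
        assert discount_factor(17, 0.0) == 1.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -0.01)
        with pytest.raises(ValueError):
            discount_factor(-1, 0.03)

    def test_sum_matches_annuity_closed_form(self):
        total = sum(discount_factor(t, 0.03) for t in range(55))
        r = 1.03
        closed = (1 - r**-55) / (1 - r**-1)
        assert total == pytest.approx(closed, abs=1e-9)


def test_occupancy_conserved_every_cycle(params):
    for name in STRATEGY_NAMES:
        trace = run_cohort(build_strategy(name), params)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)


def test_alive_mass_non_increasing(params):
    for name in ("NH", "Colonoscopy", "C-LB"):
        trace = run_cohort(build_strategy(name), params)
        assert np.all(np.diff(trace.life_years) <= 1e-12)


def test_mortality_never_exceeds_incidence(base_outcomes):
    for o in base_outcomes.values():
        assert o.crc_mortality <= o.lifetime_crc_incidence + 1e-9


def test_nh_cost_is_cancer_care_only(params):
    """With cancer care priced at zero, the unscreened arm costs nothing."""
    p = params
    for path in ("colonoscopy_polypectomy", "colonoscopy", "fit", "sdna", "lb"):
        p = set_param(p, f"costs.{path}", 0.0)
    free_cancer = CostSet(
        colonoscopy_polypectomy=0, colonoscopy=0, fit=0, sdna=0, lb=0,
        cancer_first_year=np.zeros(3),
        cancer_continuing=np.zeros(3),
        cancer_final_year=np.zeros(3),
    )
    import copy

    p2 = copy.deepcopy(params)
    p2.costs = free_cancer
    nh = accrue_outcomes(run_cohort(build_strategy("NH"), p2))
    assert nh.discounted_cost == 0.0


def test_nh_reduces_to_life_table_without_crc(params):
    import copy

    from crcscreen.natural_history import NaturalHistoryRates

    p = copy.deepcopy(params)
    p.rates = NaturalHistoryRates(
        lr_onset=p.epi.lr_polyp_onset.scaled(0.0),
        lr_to_hr=0.0,
        hr_to_cancer=0.0,
        direct_cancer_fraction=0.0,
    )
    out = accrue_outcomes(run_cohort(build_strategy("NH"), p))
    assert out.undiscounted_lyg == pytest.approx(
        life_expectancy(p.epi.all_cause_mortality), abs=1e-12
    )
    assert out.lifetime_crc_incidence == 0.0


def test_hand_computed_three_cycle_trace():
    """Totals of a tiny hand-built trace match pencil-and-paper arithmetic."""
    sp = StateSpace()
    ages = np.arange(45, 101)
    T = ages.size
    occ = np.zeros((T, sp.n))
    occ[:, sp.HEALTHY] = 1.0
    ly = np.zeros(T)
    costs = np.zeros(T)
    inflow = np.zeros((T, 3))
    deaths = np.zeros((T, 3))
    ly[:3] = [1.0, 0.9, 0.8]
    costs[:3] = [100.0, 50.0, 25.0]
    inflow[1] = [0.01, 0.005, 0.0]
    deaths[2] = [0.0, 0.001, 0.0]
    trace = CohortTrace(
        ages=ages, occupancy=occ, life_years=ly, costs=costs,
        cancer_inflow=inflow, crc_death_inflow=deaths, space=sp,
    )
    out = accrue_outcomes(trace, rate=0.03)
    d = 1.03
    assert out.discounted_cost == pytest.approx(100 + 50 / d + 25 / d**2, abs=1e-12)
    assert out.undiscounted_lyg == pytest.approx(2.7, abs=1e-12)
    assert out.discounted_lyg == pytest.approx(1 + 0.9 / d + 0.8 / d**2, abs=1e-12)
    assert out.lifetime_crc_incidence == pytest.approx(1.5, abs=1e-12)  # percent
    assert out.crc_mortality == pytest.approx(0.1, abs=1e-12)  # percent
    np.testing.assert_allclose(
        out.stage_distribution_of_diagnosed, [0.01 / 0.015, 0.005 / 0.015, 0.0]
    )


def test_lyg_ordering_matches_published_pattern(base_outcomes):
    """Qualitative life-year ordering of the six arms (asserted with slack
    for the nearly-tied stool-test pair)."""
    lyg = {n: o.undiscounted_lyg for n, o in base_outcomes.items()}
    slack = 0.01
    assert lyg["C-LB"] >= lyg["Colonoscopy"] - 1e-9
    assert lyg["Colonoscopy"] >= lyg["S-DNA"] - slack
    assert lyg["S-DNA"] >= lyg["FIT"] - slack
    assert lyg["FIT"] >= lyg["LB"] - slack
    assert lyg["LB"] >= lyg["NH"] - 1e-9


def test_screening_reduces_cancer_burden(base_outcomes):
    nh = base_outcomes["NH"]
    for name in ("FIT", "Colonoscopy", "S-DNA", "C-LB"):
        assert base_outcomes[name].lifetime_crc_incidence < nh.lifetime_crc_incidence
        assert base_outcomes[name].crc_mortality < nh.crc_mortality
    # blood test detects no polyps: incidence unchanged, mortality reduced
    assert base_outcomes["LB"].lifetime_crc_incidence <= nh.lifetime_crc_incidence + 1e-9
    assert base_outcomes["LB"].crc_mortality < nh.crc_mortality


def test_no_stage_shift_removes_blood_test_benefit(params):
    """With identical screen/symptomatic stage vectors the blood test's only
    effect is cost: life-years collapse to the unscreened value."""
    import copy

    from crcscreen.synthetic_epi import EpiTables

    p = copy.deepcopy(params)
    e = p.epi
    p.epi = EpiTables(
        all_cause_mortality=e.all_cause_mortality,
        crc_incidence_baseline=e.crc_incidence_baseline,
        lr_polyp_onset=e.lr_polyp_onset,
        polyp_prevalence_lr=e.polyp_prevalence_lr,
        polyp_prevalence_hr=e.polyp_prevalence_hr,
        stage_dist_symptomatic=e.stage_dist_symptomatic,
        stage_dist_screen=e.stage_dist_symptomatic,
        cancer_death_prob=e.cancer_death_prob,
    )
    nh = accrue_outcomes(run_cohort(build_strategy("NH"), p))
    lb = accrue_outcomes(run_cohort(build_strategy("LB"), p))
    assert lb.undiscounted_lyg == pytest.approx(nh.undiscounted_lyg, abs=1e-12)


def test_distant_death_probability_one_is_absorbing(params):
    import copy

    p = copy.deepcopy(params)
    dp = np.array(p.rates.cancer_death_prob, copy=True)
    dp[2] = 1.0
    object.__setattr__(p.rates, "cancer_death_prob", dp)
    trace = run_cohort(build_strategy("NH"), p)
    sp = trace.space
    # distant continuing state can only be reached by surviving a year; with
    # certain cancer death it stays empty (other-cause deaths exit too)
    assert np.all(trace.occupancy[:, sp.CANCER_CONT[2]] == 0.0)


def test_outcomes_validation():
    with pytest.raises(ValueError):
        Outcomes(
            discounted_cost=0.0,
            discounted_lyg=10.0,
            undiscounted_lyg=9.0,  # discounted exceeds undiscounted
            lifetime_crc_incidence=5.0,
            crc_mortality=1.0,
            stage_distribution_of_diagnosed=np.array([1.0, 0.0, 0.0]),
        )
    with pytest.raises(ValueError):
        Outcomes(
            discounted_cost=0.0,
            discounted_lyg=9.0,
            undiscounted_lyg=10.0,
            lifetime_crc_incidence=1.0,
            crc_mortality=2.0,  # mortality exceeds incidence
            stage_distribution_of_diagnosed=np.array([1.0, 0.0, 0.0]),
        )
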