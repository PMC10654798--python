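"""Annual-cycle Markov cohort engine.

Runs a strategy's cohort from age 45 until death or age 100. Each cycle:
(1) surveillance-tunnel advancement and, when due, screening events;
(2) natural-history and death transitions; (3) accrual of life-years
(start-of-cycle alive mass, no half-cycle correction) and costs.

Costs cover screening tests, screening/follow-up/surveillance colonoscopies
(with or without polypectomy), colonoscopy complications, and phase-of-care
cancer costs: the first-year cost is charged on the flow into a first-year
cancer state, the continuing cost per person-year in a continuing state, and
the final-year cost on the transition into cancer death. Costs are always
discounted; life-years are reported both discounted and undiscounted, and
the cost-effectiveness layer uses undiscounted life-years by default.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .schedules import AGE_MAX, AGE_MIN, AgeSchedule, schedule_from_fn
from .synthetic_epi import EpiTables, default_epi_tables
from .natural_history import (
    NaturalHistoryRates,
    StateSpace,
    calibrate_natural_history,
    transition_matrix,
)
from .strategies import (
    CycleEvents,
    StrategySpec,
    TestPerformance,
    apply_screening_cycle,
    default_test_performance,
    surveillance_cycle,
)

STAGE_NAMES = ("local", "regional", "distant")


def default_complication_cost() -> AgeSchedule:
    """Age-specific cost of a colonoscopy complication (2022 USD)."""
    return schedule_from_fn(lambda a: 7000.0 * (1.0 + 0.01 * (a - AGE_MIN)), role="cost")


@dataclass(frozen=True)
class CostSet:
    """Unit costs in 2022 USD (base case equals the published inputs)."""

    colonoscopy_polypectomy: float = 1366.0
    colonoscopy: float = 1119.0
    fit: float = 52.0
    sdna: float = 492.0
    lb: float = 949.0
    complication_cost: AgeSchedule = field(default_factory=default_complication_cost)
    # rows: (local, regional, distant)
    cancer_first_year: np.ndarray = field(
        default_factory=lambda: np.array([42347.0, 56019.0, 55705.0])
    )
    cancer_continuing: np.ndarray = field(
        default_factory=lambda: np.array([3941.0, 8188.0, 27586.0])
    )
    cancer_final_year: np.ndarray = field(
        default_factory=lambda: np.array([14158.0, 25270.0, 34464.0])
    )

    def __post_init__(self) -> None:
        for name in ("colonoscopy_polypectomy", "colonoscopy", "fit", "sdna", "lb"):
            if getattr(self, name) < 0:
                raise ValueError(f"cost {name} must be >= 0")
        for name in ("cancer_first_year", "cancer_continuing", "cancer_final_year"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (3,) or np.any(arr < 0):
                raise ValueError(f"{name} must be three non-negative stage costs")
            object.__setattr__(self, name, arr)

    def test_cost(self, modality: str) -> float:
        return {
            "colonoscopy": self.colonoscopy,
            "fit": self.fit,
            "sdna": self.sdna,
            "lb": self.lb,
        }[modality]


@dataclass(frozen=True)
class Policy:
    """Run-level constants: discounting, WTP, adherence, age windows."""

    discount_rate: float = 0.03
    wtp: float = 100_000.0
    adherence: float = 0.606
    lb_adherence: float = 1.0
    screen_start_age: int = 45
    screen_stop_age: int = 75
    surveillance_stop_age: int = 85
    hr_surveillance_interval: int = 3
    lr_surveillance_interval: int = 5
    discount_lyg: bool = False
    direct_cancer_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValueError("discount rate must be >= 0")
        if self.wtp <= 0:
            raise ValueError("WTP must be > 0")
        if not 0.0 <= self.adherence <= 1.0 or not 0.0 <= self.lb_adherence <= 1.0:
            raise ValueError("adherence must be in [0, 1]")


@dataclass
class ParameterSet:
    """Complete model input bundle."""

    epi: EpiTables
    rates: NaturalHistoryRates
    tests: dict[str, TestPerformance]
    costs: CostSet
    policy: Policy = field(default_factory=Policy)

    def state_space(self) -> StateSpace:
        return StateSpace(
            self.policy.lr_surveillance_interval, self.policy.hr_surveillance_interval
        )


def default_parameter_set(calibrate: bool = True, policy: Policy | None = None) -> ParameterSet:
    """Base-case parameter set from the synthetic bundle (optionally calibrated)."""
    policy = policy or Policy()
    epi = default_epi_tables()
    if calibrate:
        rates = calibrate_natural_history(
            epi, direct_cancer_fraction=policy.direct_cancer_fraction
        )
    else:
        from .natural_history import default_rates

        rates = default_rates(epi, policy.direct_cancer_fraction)
    return ParameterSet(
        epi=epi,
        rates=rates,
        tests=default_test_performance(),
        costs=CostSet(),
        policy=policy,
    )


def discount_factor(year_index: int, rate: float) -> float:
    """Present-value factor ``(1 + rate) ** (-year_index)`` (year 0 = age 45)."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    if year_index < 0:
        raise ValueError("year index must be >= 0")
    return float((1.0 + rate) ** (-year_index))


@dataclass
class CohortTrace:
    """Per-cycle record of one strategy's cohort run (undiscounted accruals)."""

    ages: np.ndarray
    occupancy: np.ndarray  # (T, n_states), start-of-cycle, post-screening
    life_years: np.ndarray  # (T,)
    costs: np.ndarray  # (T,)
    cancer_inflow: np.ndarray  # (T, 3) new diagnoses by stage
    crc_death_inflow: np.ndarray  # (T, 3) cancer deaths by stage of origin
    space: StateSpace
    events: list[CycleEvents] | None = None

    def validate(self) -> None:
        sums = self.occupancy.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise AssertionError(f"occupancy does not sum to 1 at cycle {bad}")
        if np.any(self.costs < -1e-9):
            raise AssertionError("negative per-cycle cost")

    def to_frame(self) -> pd.DataFrame:
        labels = self.space.labels()
        df = pd.DataFrame(self.occupancy, columns=labels)
        df.insert(0, "age", self.ages)
        df["life_years"] = self.life_years
        df["cost"] = self.costs
        return df


@dataclass(frozen=True)
class Outcomes:
    """Per-person lifetime outcomes of one strategy.

    Incidence and mortality are percentages of the starting cohort, matching
    the convention of the published base-case table.
    """

    discounted_cost: float
    discounted_lyg: float
    undiscounted_lyg: float
    lifetime_crc_incidence: float
    crc_mortality: float
    stage_distribution_of_diagnosed: np.ndarray

    def __post_init__(self) -> None:
        if self.crc_mortality > self.lifetime_crc_incidence + 1e-9:
            raise ValueError("CRC mortality cannot exceed lifetime incidence")
        if self.discounted_lyg > self.undiscounted_lyg + 1e-9:
            raise ValueError("discounted LYG cannot exceed undiscounted LYG")

    def effectiveness(self, discount_lyg: bool = False) -> float:
        return self.discounted_lyg if discount_lyg else self.undiscounted_lyg


def _events_cost(ev: CycleEvents, costs: CostSet, age: int) -> float:
    total = 0.0
    for modality, fraction in ev.tests_performed.items():
        total += fraction * costs.test_cost(modality)
    for kind, fraction in ev.colonoscopies.items():
        unit = costs.colonoscopy_polypectomy if kind.endswith("polypectomy") else costs.colonoscopy
        total += fraction * unit
    total += ev.complications * costs.complication_cost(age)
    return total


def _run_subcohort(
    modality: str | None,
    interval: int | None,
    spec: StrategySpec,
    params: ParameterSet,
    base: np.ndarray | None = None,
    keep_events: bool = True,
) -> CohortTrace:
    """Run one persistent sub-cohort (single modality, full adherence)."""
    sp = spec.state_space()
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    if base is None:
        base = np.stack(
            [transition_matrix(a, params.rates, params.epi, sp) for a in ages]
        )
    v = np.zeros(sp.n)
    v[sp.HEALTHY] = 1.0
    T = ages.size
    occupancy = np.zeros((T, sp.n))
    life_years = np.zeros(T)
    cycle_costs = np.zeros(T)
    cancer_inflow = np.zeros((T, 3))
    death_inflow = np.zeros((T, 3))
    all_events: list[CycleEvents] = []
    colo_perf = params.tests["colonoscopy"]
    for t, age in enumerate(ages):
        v, ev = surveillance_cycle(
            v, int(age), spec, colo_perf, params.rates, params.epi, sp
        )
        if modality is not None:
            v, ev_scr = apply_screening_cycle(
                v, int(age), spec, params.tests, params.rates, params.epi, sp,
                modality=modality, interval=interval, adherence=1.0,
            )
            ev.merge(ev_scr)
            ev.stage_mix.update(ev_scr.stage_mix)
        occupancy[t] = v
        M = base[t]
        if ev.stage_mix:
            M = M.copy()
            for state, mix in ev.stage_mix.items():
                M[state] = transition_matrix(
                    int(age), params.rates, params.epi, sp, stage_mix={state: mix}
                )[state]
        w = v @ M
        for k in range(3):
            cancer_inflow[t, k] = float(v @ M[:, sp.CANCER_Y1[k]])
            death_inflow[t, k] = (
                v[sp.CANCER_Y1[k]] * M[sp.CANCER_Y1[k], sp.DEAD_CRC]
                + v[sp.CANCER_CONT[k]] * M[sp.CANCER_CONT[k], sp.DEAD_CRC]
            )
        life_years[t] = 1.0 - v[sp.DEAD_CRC] - v[sp.DEAD_OTHER]
        cost = _events_cost(ev, params.costs, int(age))
        cost += float(cancer_inflow[t] @ params.costs.cancer_first_year)
        cost += float(w[sp.CANCER_CONT] @ params.costs.cancer_continuing)
        cost += float(death_inflow[t] @ params.costs.cancer_final_year)
        cycle_costs[t] = cost
        all_events.append(ev)
        v = w
    trace = CohortTrace(
        ages=ages,
        occupancy=occupancy,
        life_years=life_years,
        costs=cycle_costs,
        cancer_inflow=cancer_inflow,
        crc_death_inflow=death_inflow,
        space=sp,
        events=all_events if keep_events else None,
    )
    trace.validate()
    return trace


def run_cohort(
    spec: StrategySpec,
    params: ParameterSet,
    base: np.ndarray | None = None,
    _subcohort_cache: dict | None = None,
) -> CohortTrace:
    """Run a strategy's cohort as a mixture of persistent sub-cohorts.

    The adherent fraction follows the first-line modality for life and the
    remainder follows the second-line modality (or no screening); this is
    the cohort-level reading of fixed screening adherence. A sub-cohort
    cache may be shared across strategies so the unscreened and single-
    modality runs are computed once per parameter set.
    """
    parts = spec.subcohorts()
    traces = []
    for weight, modality, interval in parts:
        key = (modality, interval)
        if _subcohort_cache is not None and key in _subcohort_cache:
            tr = _subcohort_cache[key]
        else:
            tr = _run_subcohort(modality, interval, spec, params, base=base)
            if _subcohort_cache is not None:
                _subcohort_cache[key] = tr
        traces.append((weight, tr))
    first = traces[0][1]
    mixed = CohortTrace(
        ages=first.ages,
        occupancy=sum(w * tr.occupancy for w, tr in traces),
        life_years=sum(w * tr.life_years for w, tr in traces),
        costs=sum(w * tr.costs for w, tr in traces),
        cancer_inflow=sum(w * tr.cancer_inflow for w, tr in traces),
        crc_death_inflow=sum(w * tr.crc_death_inflow for w, tr in traces),
        space=first.space,
        events=None,
    )
    mixed.validate()
    return mixed


def accrue_outcomes(
    trace: CohortTrace, rate: float = 0.03, conventions: dict | None = None
) -> Outcomes:
    """Discount and total a trace into per-person lifetime outcomes."""
    trace.validate()
    T = trace.ages.size
    factors = np.array([discount_factor(t, rate) for t in range(T)])
    inflow_total = trace.cancer_inflow.sum()
    stage = (
        trace.cancer_inflow.sum(axis=0) / inflow_total
        if inflow_total > 0
        else np.full(3, 1.0 / 3.0)
    )
    return Outcomes(
        discounted_cost=float(trace.costs @ factors),
        discounted_lyg=float(trace.life_years @ factors),
        undiscounted_lyg=float(trace.life_years.sum()),
        lifetime_crc_incidence=100.0 * float(inflow_total),
        crc_mortality=100.0 * float(trace.crc_death_inflow.sum()),
        stage_distribution_of_diagnosed=stage,
    )


def run_strategy(spec: StrategySpec, params: ParameterSet, **kw) -> Outcomes:
    return accrue_outcomes(run_cohort(spec, params, **kw), params.policy.discount_rate)


def run_all_strategies(
    params: ParameterSet, names: tuple[str, ...] | None = None
) -> dict[str, Outcomes]:
    """Outcomes for all (or the named) strategies, sharing sub-cohort runs."""
    from .strategies import STRATEGY_NAMES, build_strategy

    names = names or STRATEGY_NAMES
    cache: dict = {}
    out = {}
    for name in names:
        spec = build_strategy(
            name,
            adherence=params.policy.adherence,
            lb_adherence=params.policy.lb_adherence,
            start_age=params.policy.screen_start_age,
            stop_age=params.policy.screen_stop_age,
            surveillance_stop_age=params.policy.surveillance_stop_age,
            hr_surveillance_interval=params.policy.hr_surveillance_interval,
            lr_surveillance_interval=params.policy.lr_surveillance_interval,
        )
        trace = run_cohort(spec, params, _subcohort_cache=cache)
        out[name] = accrue_outcomes(trace, params.policy.discount_rate)
    return out
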