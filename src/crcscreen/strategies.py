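"""The six screening strategies and the per-cycle screening mechanics.

Strategies: no screening (NH), annual FIT, stool DNA every 3 years,
colonoscopy every 10 years, liquid biopsy (LB) every 3 years, and the
colonoscopy-LB hybrid (C-LB: 60.6% of the cohort screened by colonoscopy,
the remaining 39.4% by LB). Screening runs from age 45 through 75;
post-polypectomy surveillance colonoscopy (every 3 years for high-risk,
5 years for low-risk polyps, 100% adherence) continues through age 85.

A positive non-colonoscopy test always triggers a follow-up colonoscopy.
Detected polyps are removed (polypectomy) and the person enters the
corresponding surveillance tunnel. Cancer detection by screening is a stage
shift: the incident-cancer flow from screened compartments in a screening
cycle receives ``sens * screen-detected + (1 - sens) * symptomatic`` stage
distribution (for colonoscopy, the detection-rate/interval-cancer-rate pair
plays the role of sensitivity). Colonoscopies carry an age-specific
complication probability and cost; stool and blood tests have no
complications.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .schedules import AGE_MAX, AGE_MIN, AgeSchedule, schedule_from_fn
from .natural_history import DEFAULT_SPACE, NaturalHistoryRates, StateSpace
from .synthetic_epi import EpiTables

STRATEGY_NAMES = ("NH", "FIT", "Colonoscopy", "S-DNA", "LB", "C-LB")
MODALITIES = ("colonoscopy", "fit", "sdna", "lb")


@dataclass(frozen=True)
class TestPerformance:
    """Per-test detection characteristics (fractions, not percent).

    Polyp sensitivities may be age-specific schedules (colonoscopy) or
    scalars. For colonoscopy, the cancer detection rate and interval-cancer
    (miss) rate must be complementary.
    """

    __test__ = False  # not a pytest class despite the Test* name

    cancer_sensitivity: float
    hr_polyp_sensitivity: float | AgeSchedule
    lr_polyp_sensitivity: float | AgeSchedule
    specificity: float
    is_colonoscopy: bool = False
    colo_cancer_detection_rate: float | None = None
    colo_interval_cancer_rate: float | None = None
    complication_prob: AgeSchedule | None = None

    def __post_init__(self) -> None:
        for name in ("cancer_sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("hr_polyp_sensitivity", "lr_polyp_sensitivity"):
            v = getattr(self, name)
            if isinstance(v, AgeSchedule):
                continue
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.is_colonoscopy:
            det, miss = self.colo_cancer_detection_rate, self.colo_interval_cancer_rate
            if det is None or miss is None or abs(det + miss - 1.0) > 1e-9:
                raise ValueError(
                    "colonoscopy detection and interval-cancer rates must sum to 1"
                )

    def hr_sens(self, age: int) -> float:
        v = self.hr_polyp_sensitivity
        return v(age) if isinstance(v, AgeSchedule) else v

    def lr_sens(self, age: int) -> float:
        v = self.lr_polyp_sensitivity
        return v(age) if isinstance(v, AgeSchedule) else v

    def cancer_detection(self, age: int) -> float:
        """Probability a cancer incident this cycle is screen-detected."""
        if self.is_colonoscopy:
            return self.colo_cancer_detection_rate
        return self.cancer_sensitivity


def _colonoscopy_polyp_sens(hi: float, mid: float, lo: float) -> AgeSchedule:
    # published-magnitude constants by age band; exact values not printed anywhere
    def f(a):
        if a < 65:
            return hi
        if a < 80:
            return mid
        return lo

    return schedule_from_fn(f)


def default_complication_prob() -> AgeSchedule:
    """Age-specific colonoscopy complication probability (rises with age)."""
    return schedule_from_fn(lambda a: min(0.0016 * np.exp(0.028 * (a - AGE_MIN)), 1.0))


def default_test_performance() -> dict[str, TestPerformance]:
    """Base-case test performance (Table-1 values, fractions)."""
    return {
        "colonoscopy": TestPerformance(
            cancer_sensitivity=0.928,
            hr_polyp_sensitivity=_colonoscopy_polyp_sens(0.95, 0.92, 0.89),
            lr_polyp_sensitivity=_colonoscopy_polyp_sens(0.85, 0.80, 0.75),
            specificity=1.0,
            is_colonoscopy=True,
            colo_cancer_detection_rate=0.928,
            colo_interval_cancer_rate=0.072,
            complication_prob=default_complication_prob(),
        ),
        "fit": TestPerformance(0.738, 0.238, 0.076, 0.964),
        "sdna": TestPerformance(0.923, 0.424, 0.172, 0.898),
        "lb": TestPerformance(0.820, 0.0, 0.0, 0.995),
    }


@dataclass(frozen=True)
class StrategySpec:
    """One screening arm: first-line modality/interval/adherence and the
    optional second-line modality offered to the non-adherent fraction."""

    name: str
    first_modality: str | None
    first_interval: int | None
    adherence: float
    second_modality: str | None = None
    second_interval: int | None = None
    start_age: int = 45
    stop_age: int = 75
    surveillance_stop_age: int = 85
    hr_surveillance_interval: int = 3
    lr_surveillance_interval: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.adherence <= 1.0:
            raise ValueError("adherence must be in [0, 1]")
        for iv in (self.first_interval, self.second_interval,
                   self.hr_surveillance_interval, self.lr_surveillance_interval):
            if iv is not None and iv < 1:
                raise ValueError("intervals must be >= 1 year")
        if self.start_age >= self.stop_age:
            raise ValueError("screen start age must be below stop age")

    def subcohorts(self) -> list[tuple[float, str | None, int | None]]:
        """Persistent (weight, modality, interval) decomposition of the arm."""
        parts = []
        if self.first_modality is not None and self.adherence > 0:
            parts.append((self.adherence, self.first_modality, self.first_interval))
        rest = 1.0 - (self.adherence if self.first_modality is not None else 0.0)
        if rest > 0:
            parts.append((rest, self.second_modality, self.second_interval))
        return parts

    def state_space(self) -> StateSpace:
        return StateSpace(self.lr_surveillance_interval, self.hr_surveillance_interval)


def build_strategy(
    name: str,
    adherence: float = 0.606,
    lb_adherence: float = 1.0,
    **overrides,
) -> StrategySpec:
    """Construct one of the six named strategies with base-case defaults."""
    base = dict(name=name)
    if name == "NH":
        base.update(first_modality=None, first_interval=None, adherence=0.0)
    elif name == "FIT":
        base.update(first_modality="fit", first_interval=1, adherence=adherence)
    elif name == "Colonoscopy":
        base.update(first_modality="colonoscopy", first_interval=10, adherence=adherence)
    elif name == "S-DNA":
        base.update(first_modality="sdna", first_interval=3, adherence=adherence)
    elif name == "LB":
        base.update(first_modality="lb", first_interval=3, adherence=lb_adherence)
    elif name == "C-LB":
        base.update(
            first_modality="colonoscopy",
            first_interval=10,
            adherence=adherence,
            second_modality="lb",
            second_interval=3,
        )
    else:
        raise ValueError(f"unknown strategy {name!r}; valid names: {STRATEGY_NAMES}")
    base.update(overrides)
    return StrategySpec(**base)


def screening_due(age: int, interval: int, start_age: int, stop_age: int) -> bool:
    """True when a screening round falls at ``age`` on the strategy's grid."""
    if age < start_age or age > stop_age:
        return False
    return (age - start_age) % interval == 0


@dataclass
class CycleEvents:
    """Person-fraction event ledger for one cycle (cost accounting input).

    ``stage_mix`` maps source states to the stage-at-diagnosis distribution
    that applies to their incident cancers this cycle (screen stage shift).
    """

    tests_performed: dict = field(default_factory=dict)
    colonoscopies: dict = field(default_factory=dict)
    false_positives: float = 0.0
    polypectomies: float = 0.0
    complications: float = 0.0
    stage_mix: dict = field(default_factory=dict)

    _COLO_KINDS = (
        "screening_plain",
        "screening_polypectomy",
        "followup_plain",
        "followup_polypectomy",
        "surveillance_plain",
        "surveillance_polypectomy",
    )

    def add_test(self, modality: str, fraction: float) -> None:
        if fraction < 0:
            raise ValueError("negative event fraction")
        self.tests_performed[modality] = self.tests_performed.get(modality, 0.0) + fraction

    def add_colonoscopy(self, kind: str, fraction: float) -> None:
        if kind not in self._COLO_KINDS:
            raise ValueError(f"unknown colonoscopy kind {kind!r}")
        if fraction < 0:
            raise ValueError("negative event fraction")
        self.colonoscopies[kind] = self.colonoscopies.get(kind, 0.0) + fraction

    def total_colonoscopies(self) -> float:
        return float(sum(self.colonoscopies.values()))

    def merge(self, other: "CycleEvents", weight: float = 1.0) -> None:
        for k, v in other.tests_performed.items():
            self.tests_performed[k] = self.tests_performed.get(k, 0.0) + weight * v
        for k, v in other.colonoscopies.items():
            self.colonoscopies[k] = self.colonoscopies.get(k, 0.0) + weight * v
        self.false_positives += weight * other.false_positives
        self.polypectomies += weight * other.polypectomies
        self.complications += weight * other.complications


def _screen_stage_mix(detect_prob: float, adherent: float, epi: EpiTables) -> np.ndarray:
    p = adherent * detect_prob
    return p * epi.stage_dist_screen + (1.0 - p) * epi.stage_dist_symptomatic


def apply_screening_cycle(
    state_vector: np.ndarray,
    age: int,
    spec: StrategySpec,
    tests: dict[str, TestPerformance],
    rates: NaturalHistoryRates,
    epi: EpiTables,
    space: StateSpace | None = None,
    modality: str | None = None,
    interval: int | None = None,
    adherence: float | None = None,
) -> tuple[np.ndarray, CycleEvents]:
    """Apply one round of screening to the cohort occupancy vector.

    By default uses the spec's first-line modality and adherence; the cohort
    engine overrides ``modality``/``interval``/``adherence`` to run each
    persistent sub-cohort at full adherence. Returns the post-screening
    occupancy and the event ledger (including the stage-shift mix for this
    cycle's incident cancers).
    """
    sp = space or spec.state_space()
    v = np.asarray(state_vector, dtype=float)
    if v.shape != (sp.n,) or np.any(v < -1e-12) or abs(v.sum() - 1.0) > 1e-9:
        raise ValueError("state vector must be a simplex point over the state space")
    events = CycleEvents()
    modality = spec.first_modality if modality is None else modality
    interval = spec.first_interval if interval is None else interval
    f = spec.adherence if adherence is None else adherence
    if modality is None or f == 0.0 or not screening_due(
        age, interval, spec.start_age, spec.stop_age
    ):
        return v.copy(), events

    perf = tests[modality]
    colo = tests["colonoscopy"]
    out = v.copy()
    n_colos = 0.0

    lesion_states = (sp.LR_POLYP, sp.LR_REFRACTORY, sp.HR_POLYP, sp.HR_REFRACTORY)
    screened = f * (v[sp.HEALTHY] + sum(v[s] for s in lesion_states))

    if perf.is_colonoscopy:
        # refractory occupants were missed by a prior colonoscopy and stay missed
        for state, refr, sens, dest in (
            (sp.LR_POLYP, sp.LR_REFRACTORY, perf.lr_sens(age), sp.LR_SURV[0]),
            (sp.HR_POLYP, sp.HR_REFRACTORY, perf.hr_sens(age), sp.HR_SURV[0]),
        ):
            tested = f * v[state]
            detected = tested * sens
            out[state] -= tested
            out[dest] += detected
            out[refr] += tested - detected
            events.add_colonoscopy("screening_polypectomy", detected)
            events.polypectomies += detected
        events.add_colonoscopy(
            "screening_plain", screened - events.colonoscopies.get("screening_polypectomy", 0.0)
        )
        n_colos = screened
    else:
        events.add_test(modality, screened)
        # lesion-free false positives -> follow-up colonoscopy, no state change
        fp = f * v[sp.HEALTHY] * (1.0 - perf.specificity)
        events.false_positives += fp
        events.add_colonoscopy("followup_plain", fp)
        n_colos += fp
        # polyp positives -> follow-up colonoscopy; confirmation per
        # colonoscopy polyp sensitivity -> polypectomy + surveillance;
        # test-negative lesions become refractory to this modality
        for state, refr, sens, csens, dest in (
            (sp.LR_POLYP, sp.LR_REFRACTORY, perf.lr_sens(age), colo.lr_sens(age), sp.LR_SURV[0]),
            (sp.HR_POLYP, sp.HR_REFRACTORY, perf.hr_sens(age), colo.hr_sens(age), sp.HR_SURV[0]),
        ):
            tested = f * v[state]
            pos = tested * sens
            confirmed = pos * csens
            out[state] -= confirmed + (tested - pos)
            out[dest] += confirmed
            out[refr] += tested - pos
            events.add_colonoscopy("followup_polypectomy", confirmed)
            events.add_colonoscopy("followup_plain", pos - confirmed)
            events.polypectomies += confirmed
            n_colos += pos

    events.complications += n_colos * colo.complication_prob(age)
    detect = perf.cancer_detection(age)
    for state in (sp.HEALTHY,) + lesion_states:
        events.stage_mix[state] = _screen_stage_mix(detect, f, epi)

    if np.any(out < -1e-12) or abs(out.sum() - 1.0) > 1e-9:
        raise AssertionError("screening produced an invalid occupancy vector")
    return np.clip(out, 0.0, None), events


def surveillance_cycle(
    state_vector: np.ndarray,
    age: int,
    spec: StrategySpec,
    perf_colonoscopy: TestPerformance,
    rates: NaturalHistoryRates | None = None,
    epi: EpiTables | None = None,
    space: StateSpace | None = None,
) -> tuple[np.ndarray, CycleEvents]:
    """Advance the post-polypectomy surveillance tunnels one year.

    Occupants of the final tunnel year receive a surveillance colonoscopy
    (100% adherence) and restart the tunnel; recurrent polyps (new onset
    accumulated over the interval) are re-detected with the colonoscopy
    polyp sensitivity, which determines the polypectomy cost share. After
    the surveillance stop age, tunnels keep cycling with no colonoscopies.
    """
    sp = space or spec.state_space()
    v = np.asarray(state_vector, dtype=float)
    out = v.copy()
    events = CycleEvents()
    for tunnel, interval, track_sens in (
        (sp.LR_SURV, spec.lr_surveillance_interval, "lr"),
        (sp.HR_SURV, spec.hr_surveillance_interval, "hr"),
    ):
        end_occ = v[tunnel[-1]]
        # advance year k -> k+1; final year wraps to year 1
        for k in range(len(tunnel) - 1, 0, -1):
            out[tunnel[k]] = v[tunnel[k - 1]]
        out[tunnel[0]] = end_occ
        if end_occ <= 0.0:
            continue
        if age <= spec.surveillance_stop_age:
            sens = (
                perf_colonoscopy.lr_sens(age)
                if track_sens == "lr"
                else perf_colonoscopy.hr_sens(age)
            )
            recur = 0.0
            if rates is not None:
                lo = max(age - interval, AGE_MIN)
                onset = rates.lr_onset.slice(lo, max(age - 1, lo))
                recur = 1.0 - float(np.prod(1.0 - onset))
            with_poly = end_occ * recur * sens
            events.add_colonoscopy("surveillance_polypectomy", with_poly)
            events.add_colonoscopy("surveillance_plain", end_occ - with_poly)
            events.polypectomies += with_poly
            if perf_colonoscopy.complication_prob is not None:
                events.complications += end_occ * perf_colonoscopy.complication_prob(age)
            if epi is not None:
                events.stage_mix[tunnel[0]] = _screen_stage_mix(
                    perf_colonoscopy.cancer_detection(age), 1.0, epi
                )
    if abs(out.sum() - v.sum()) > 1e-12:
        raise AssertionError("surveillance advancement lost mass (tunnel overflow)")
    return out, events
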