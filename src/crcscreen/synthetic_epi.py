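"""Synthetic epidemiological inputs.

The model needs age-specific other-cause mortality (CDC-life-table-like),
baseline colorectal-cancer incidence in an unscreened population
(pre-screening-era SEER-like), polyp onset/prevalence (CORI-like), a stage
distribution at diagnosis, and stage-specific cancer-death probabilities.
None of these tables are shipped; this module generates them from standard
parametric demographic forms so the whole model runs without downloads:

* other-cause mortality: Gompertz-Makeham hazard,
  ``h(a) = makeham + coef * exp(slope * (a - 45))``;
* baseline CRC incidence: log-linear in age with a plateau at old age;
* polyp prevalence: forward integration of a linear-in-age onset schedule
  with nominal progression/exit rates (logistic-shaped rise with age);
* stage inputs: fixed 3-simplex vectors (local/regional/distant), with the
  screen-detected vector shifted toward local stage.

All generators are pure, deterministic functions of their parameters.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schedules import AGE_MAX, AGE_MIN, AgeSchedule, schedule_from_fn

STAGES = ("local", "regional", "distant")

# Defaults emulate US magnitudes: life expectancy at 45 of ~36 years,
# lifetime CRC risk near 5%, any-adenoma prevalence in the tens of percent
# by the 70s with high-risk polyps the rarer subset.
DEFAULT_LIFE_TABLE = dict(makeham=8.0e-4, gompertz_coef=2.1e-3, gompertz_slope=0.088)
DEFAULT_INCIDENCE = dict(base_rate=1.55e-4, log_slope=0.082, plateau_age=85)
DEFAULT_POLYPS = dict(
    onset_base=0.0105,
    onset_slope=1.5e-4,
    nominal_lr_to_hr=0.020,
    nominal_hr_exit=0.030,
)
DEFAULT_STAGES = dict(
    symptomatic=(0.38, 0.36, 0.26),
    screen=(0.62, 0.28, 0.10),
    death_prob=(0.016, 0.065, 0.38),
)


@dataclass(frozen=True)
class EpiTables:
    """Bundle of the age-indexed epidemiological inputs.

    ``polyp_prevalence_lr``/``_hr`` are calibration reference curves, not
    transition inputs; ``cancer_death_prob`` is the annual probability of
    cancer death by stage (local, regional, distant).
    """

    all_cause_mortality: AgeSchedule
    crc_incidence_baseline: AgeSchedule
    lr_polyp_onset: AgeSchedule
    polyp_prevalence_lr: AgeSchedule
    polyp_prevalence_hr: AgeSchedule
    stage_dist_symptomatic: np.ndarray
    stage_dist_screen: np.ndarray
    cancer_death_prob: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sympt = np.asarray(self.stage_dist_symptomatic, dtype=float)
        screen = np.asarray(self.stage_dist_screen, dtype=float)
        death = np.asarray(self.cancer_death_prob, dtype=float)
        for name, vec in (("stage_dist_symptomatic", sympt), ("stage_dist_screen", screen)):
            if vec.shape != (3,) or np.any(vec < 0) or abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a 3-vector on the simplex")
        if screen[0] < sympt[0] - 1e-12:
            raise ValueError("screen-detected stage distribution must place >= mass on local")
        if death.shape != (3,) or np.any(death < 0) or np.any(death > 1):
            raise ValueError("cancer_death_prob must be three probabilities")
        if not (death[2] > death[1] > death[0]):
            raise ValueError("cancer death probability must order distant > regional > local")
        mort = self.all_cause_mortality.slice()
        if np.any(np.diff(mort) < -1e-15):
            raise ValueError("all_cause_mortality must be non-decreasing in age")
        object.__setattr__(self, "stage_dist_symptomatic", sympt)
        object.__setattr__(self, "stage_dist_screen", screen)
        object.__setattr__(self, "cancer_death_prob", death)


def generate_life_table(
    makeham: float = DEFAULT_LIFE_TABLE["makeham"],
    gompertz_coef: float = DEFAULT_LIFE_TABLE["gompertz_coef"],
    gompertz_slope: float = DEFAULT_LIFE_TABLE["gompertz_slope"],
    age_range: tuple[int, int] = (AGE_MIN, AGE_MAX),
) -> AgeSchedule:
    """Annual other-cause death probabilities from a Gompertz-Makeham hazard.

    ``p(a) = 1 - exp(-(makeham + coef * exp(slope * (a - 45))))``. With zero
    Makeham offset and zero slope the schedule is constant at
    ``1 - exp(-coef)``.
    """
    if age_range[0] > AGE_MIN or age_range[1] < AGE_MAX:
        raise ValueError(f"age_range must cover {AGE_MIN}..{AGE_MAX}")
    ages = np.arange(age_range[0], age_range[1] + 1)
    hazard = makeham + gompertz_coef * np.exp(gompertz_slope * (ages - AGE_MIN))
    if np.any(hazard <= 0) or not np.all(np.isfinite(hazard)):
        raise ValueError("hazard parameters produce probabilities outside (0, 1)")
    probs = 1.0 - np.exp(-hazard)
    if np.any(probs >= 1.0):
        raise ValueError("hazard parameters produce probabilities outside (0, 1)")
    return AgeSchedule(ages, probs, "probability")


def generate_crc_incidence(
    base_rate: float = DEFAULT_INCIDENCE["base_rate"],
    log_slope: float = DEFAULT_INCIDENCE["log_slope"],
    plateau_age: int = DEFAULT_INCIDENCE["plateau_age"],
    age_range: tuple[int, int] = (AGE_MIN, AGE_MAX),
) -> AgeSchedule:
    """Annual probability of clinical CRC onset in an unscreened population.

    Log-linear in age up to ``plateau_age``, flat after. ``base_rate = 0``
    gives the null (all-zero) schedule.
    """
    if base_rate < 0:
        raise ValueError("base_rate must be >= 0")
    ages = np.arange(age_range[0], age_range[1] + 1)
    capped = np.minimum(ages, plateau_age)
    probs = base_rate * np.exp(log_slope * (capped - AGE_MIN))
    if np.any(probs > 0.05):
        raise ValueError("annual CRC onset probability above 0.05 rejected")
    return AgeSchedule(ages, probs, "probability")


def generate_polyp_schedules(
    onset_base: float = DEFAULT_POLYPS["onset_base"],
    onset_slope: float = DEFAULT_POLYPS["onset_slope"],
    nominal_lr_to_hr: float = DEFAULT_POLYPS["nominal_lr_to_hr"],
    nominal_hr_exit: float = DEFAULT_POLYPS["nominal_hr_exit"],
) -> tuple[AgeSchedule, AgeSchedule, AgeSchedule]:
    """Low-risk polyp onset schedule plus LR/HR prevalence target curves.

    Onset is linear in age. The prevalence targets are what a cohort that is
    polyp-free at 45 accumulates under the onset schedule with nominal
    LR-to-HR progression and HR exit rates — the synthetic counterpart of
    cross-sectional registry prevalence, consistent by construction with the
    natural-history structure that is later calibrated against it.
    """
    onset = schedule_from_fn(
        lambda a: min(max(onset_base + onset_slope * (a - AGE_MIN), 0.0), 1.0)
    )
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    p_lr = np.zeros(ages.size)
    p_hr = np.zeros(ages.size)
    for i in range(ages.size - 1):
        free = max(1.0 - p_lr[i] - p_hr[i], 0.0)
        p_lr[i + 1] = p_lr[i] + onset.values[i] * free - nominal_lr_to_hr * p_lr[i]
        p_hr[i + 1] = p_hr[i] + nominal_lr_to_hr * p_lr[i] - nominal_hr_exit * p_hr[i]
    if np.any(p_lr < 0) or np.any(p_lr >= 1) or np.any(p_hr < 0) or np.any(p_hr >= 1):
        raise ValueError("prevalence targets outside [0, 1) rejected")
    return (
        onset,
        AgeSchedule(ages, p_lr, "probability"),
        AgeSchedule(ages, p_hr, "probability"),
    )


def generate_stage_inputs(
    symptomatic: tuple[float, float, float] = DEFAULT_STAGES["symptomatic"],
    screen: tuple[float, float, float] = DEFAULT_STAGES["screen"],
    death_prob: tuple[float, float, float] = DEFAULT_STAGES["death_prob"],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stage-at-diagnosis vectors and stage-specific annual death probabilities.

    Validates that both stage vectors lie on the 3-simplex, that the
    screen-detected vector is shifted toward local stage, and that death
    probabilities order distant > regional > local.
    """
    sympt = np.asarray(symptomatic, dtype=float)
    scr = np.asarray(screen, dtype=float)
    death = np.asarray(death_prob, dtype=float)
    for name, vec in (("symptomatic", sympt), ("screen", scr)):
        if vec.shape != (3,) or np.any(vec < 0) or abs(vec.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} stage distribution must be a 3-simplex vector")
    if scr[0] < sympt[0] - 1e-12:
        raise ValueError("screen-detected vector must not be later-stage than symptomatic")
    if not (death[2] > death[1] > death[0]) or np.any(death < 0) or np.any(death > 1):
        raise ValueError("death probabilities must satisfy distant > regional > local in [0,1]")
    return sympt, scr, death


def default_epi_tables(
    life_table: dict | None = None,
    incidence: dict | None = None,
    polyps: dict | None = None,
    stages: dict | None = None,
) -> EpiTables:
    """Assemble the default synthetic bundle (optionally overriding parameters)."""
    lt = {**DEFAULT_LIFE_TABLE, **(life_table or {})}
    inc = {**DEFAULT_INCIDENCE, **(incidence or {})}
    pol = {**DEFAULT_POLYPS, **(polyps or {})}
    stg = {**DEFAULT_STAGES, **(stages or {})}
    onset, prev_lr, prev_hr = generate_polyp_schedules(**pol)
    sympt, screen, death = generate_stage_inputs(**stg)
    return EpiTables(
        all_cause_mortality=generate_life_table(**lt),
        crc_incidence_baseline=generate_crc_incidence(**inc),
        lr_polyp_onset=onset,
        polyp_prevalence_lr=prev_lr,
        polyp_prevalence_hr=prev_hr,
        stage_dist_symptomatic=sympt,
        stage_dist_screen=screen,
        cancer_death_prob=death,
        params={"life_table": lt, "incidence": inc, "polyps": pol, "stages": stg},
    )


def life_expectancy(mortality: AgeSchedule, from_age: int = AGE_MIN) -> float:
    """Undiscounted life expectancy at ``from_age`` from the schedule alone.

    Full-year person-time at start-of-year survival, consistent with the
    cohort engine's accrual convention (no half-cycle correction).
    """
    probs = mortality.slice(from_age, AGE_MAX)
    surv = np.cumprod(np.concatenate([[1.0], 1.0 - probs[:-1]]))
    return float(surv.sum())
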