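"""Unscreened disease process and its calibration.

The health-state space is: healthy, undetected low-risk (LR) polyp,
undetected high-risk (HR) polyp, modality-refractory LR/HR polyp (a lesion
already missed once by the cohort's screening test, systematically
undetectable by that test until it progresses), post-polypectomy
surveillance tunnels (one state per year of the surveillance interval),
six diagnosed-cancer states (first-year and continuing, by SEER summary
stage), and two absorbing death states (cancer death, other-cause death).

Cancer onset follows the adenoma-carcinoma sequence: most incident cancers
arise from the HR-polyp compartment (annual probability = a calibrated
multiplier times the baseline incidence schedule), with a residual
``direct_cancer_fraction`` arising from healthy/LR states without a modeled
precursor dwell. Polypectomy therefore durably reduces subsequent incidence,
which is what gives colonoscopy-based strategies their incidence benefit.

Within a cycle, other-cause death is applied first, then disease
transitions; there is no half-cycle correction.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .schedules import AGE_MAX, AGE_MIN, AgeSchedule
from .synthetic_epi import EpiTables


class StateSpace:
    """Index layout of the Markov state space for given surveillance intervals."""

    def __init__(self, lr_tunnel: int = 5, hr_tunnel: int = 3):
        if lr_tunnel < 1 or hr_tunnel < 1:
            raise ValueError("tunnel lengths must be >= 1 year")
        self.lr_tunnel = int(lr_tunnel)
        self.hr_tunnel = int(hr_tunnel)
        self.HEALTHY = 0
        self.LR_POLYP = 1
        self.LR_REFRACTORY = 2
        self.HR_POLYP = 3
        self.HR_REFRACTORY = 4
        self.LR_SURV = list(range(5, 5 + self.lr_tunnel))
        self.HR_SURV = list(range(5 + self.lr_tunnel, 5 + self.lr_tunnel + self.hr_tunnel))
        base = 5 + self.lr_tunnel + self.hr_tunnel
        # cancer states ordered (local, regional, distant) x (year1, continuing)
        self.CANCER_Y1 = [base, base + 2, base + 4]
        self.CANCER_CONT = [base + 1, base + 3, base + 5]
        self.DEAD_CRC = base + 6
        self.DEAD_OTHER = base + 7
        self.n = base + 8
        self.ALIVE = [s for s in range(self.n) if s not in (self.DEAD_CRC, self.DEAD_OTHER)]

    def labels(self) -> list[str]:
        lab = [
            "healthy",
            "lr_polyp_undetected",
            "lr_polyp_refractory",
            "hr_polyp_undetected",
            "hr_polyp_refractory",
        ]
        lab += [f"lr_surveillance_{k}" for k in range(1, self.lr_tunnel + 1)]
        lab += [f"hr_surveillance_{k}" for k in range(1, self.hr_tunnel + 1)]
        for stage in ("local", "regional", "distant"):
            lab += [f"cancer_{stage}_y1", f"cancer_{stage}_cont"]
        lab += ["dead_crc", "dead_other"]
        return lab


DEFAULT_SPACE = StateSpace()


@dataclass(frozen=True)
class NaturalHistoryRates:
    """Free rates of the unscreened disease process.

    ``hr_to_cancer`` is a multiplier on the baseline incidence schedule
    (effective annual probability ``min(hr_to_cancer * incidence(age), 1)``),
    ``direct_cancer_fraction`` the share of baseline incidence arising
    without a modeled precursor dwell, and ``cancer_death_prob`` the
    (calibration-scaled) stage-specific annual cancer-death probabilities;
    when ``None`` the EpiTables values are used.
    """

    lr_onset: AgeSchedule
    lr_to_hr: float
    hr_to_cancer: float
    direct_cancer_fraction: float = 0.15
    cancer_death_prob: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.lr_to_hr <= 1.0:
            raise ValueError("lr_to_hr must be a probability")
        if self.hr_to_cancer < 0:
            raise ValueError("hr_to_cancer multiplier must be >= 0")
        if not 0.0 <= self.direct_cancer_fraction <= 1.0:
            raise ValueError("direct_cancer_fraction must be in [0, 1]")

    def death_probs(self, epi: EpiTables) -> np.ndarray:
        if self.cancer_death_prob is not None:
            return np.asarray(self.cancer_death_prob, dtype=float)
        return epi.cancer_death_prob


def default_rates(epi: EpiTables, direct_cancer_fraction: float = 0.15) -> NaturalHistoryRates:
    """Uncalibrated starting rates built from the synthetic bundle."""
    return NaturalHistoryRates(
        lr_onset=epi.lr_polyp_onset,
        lr_to_hr=0.02,
        hr_to_cancer=15.0,
        direct_cancer_fraction=direct_cancer_fraction,
    )


def transition_matrix(
    age: int,
    rates: NaturalHistoryRates,
    epi: EpiTables,
    space: StateSpace = DEFAULT_SPACE,
    stage_mix: dict[int, np.ndarray] | None = None,
) -> np.ndarray:
    """Row-stochastic annual transition matrix at ``age``.

    ``stage_mix`` optionally overrides, per source state, the stage-at-
    diagnosis distribution applied to that state's incident cancers this
    cycle (used by the screening layer to implement stage shift); the
    default is the symptomatic distribution everywhere. Tunnel advancement
    is handled by the screening layer, not here: surveillance rows stay in
    place apart from death and direct-pathway cancer onset.
    """
    if age < AGE_MIN or age > AGE_MAX:
        raise ValueError(f"age must be in {AGE_MIN}..{AGE_MAX}")
    sp = space
    M = np.zeros((sp.n, sp.n))
    m = epi.all_cause_mortality(age)
    inc = epi.crc_incidence_baseline(age)
    onset = rates.lr_onset(age)
    p_direct = min(rates.direct_cancer_fraction * inc, 1.0)
    p_hr = min(rates.hr_to_cancer * inc, 1.0)
    death = rates.death_probs(epi)
    sympt = epi.stage_dist_symptomatic
    mix = stage_mix or {}

    def onset_row(state: int, p_cancer: float, extra: dict[int, float]) -> None:
        stages = mix.get(state, sympt)
        M[state, sp.DEAD_OTHER] = m
        live = 1.0 - m
        for k in range(3):
            M[state, sp.CANCER_Y1[k]] = live * p_cancer * stages[k]
        rest = live * (1.0 - p_cancer)
        for dest, p in extra.items():
            M[state, dest] = rest * p
        M[state, state] = rest * (1.0 - sum(extra.values()))

    onset_row(sp.HEALTHY, p_direct, {sp.LR_POLYP: onset})
    onset_row(sp.LR_POLYP, p_direct, {sp.HR_POLYP: rates.lr_to_hr})
    # a lesion missed by screening stays biologically identical; progression
    # to high risk re-samples detectability (the lesion transforms)
    onset_row(sp.LR_REFRACTORY, p_direct, {sp.HR_POLYP: rates.lr_to_hr})
    onset_row(sp.HR_POLYP, p_hr, {})
    onset_row(sp.HR_REFRACTORY, p_hr, {})
    # post-polypectomy surveillance: precursor removed, direct pathway only
    for s in sp.LR_SURV + sp.HR_SURV:
        onset_row(s, p_direct, {})
    for k in range(3):
        for state, survivor_dest in (
            (sp.CANCER_Y1[k], sp.CANCER_CONT[k]),
            (sp.CANCER_CONT[k], sp.CANCER_CONT[k]),
        ):
            M[state, sp.DEAD_OTHER] = m
            M[state, sp.DEAD_CRC] = (1.0 - m) * death[k]
            M[state, survivor_dest] = (1.0 - m) * (1.0 - death[k])
    M[sp.DEAD_CRC, sp.DEAD_CRC] = 1.0
    M[sp.DEAD_OTHER, sp.DEAD_OTHER] = 1.0
    rowsum = M.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) > 1e-12):
        raise AssertionError(f"transition rows not stochastic at age {age}")
    return M


def nh_transition_matrix(
    age: int, rates: NaturalHistoryRates, epi: EpiTables, space: StateSpace = DEFAULT_SPACE
) -> np.ndarray:
    """Natural-history matrix: symptomatic stage distribution everywhere."""
    return transition_matrix(age, rates, epi, space)


def base_matrices(
    rates: NaturalHistoryRates, epi: EpiTables, space: StateSpace = DEFAULT_SPACE
) -> np.ndarray:
    """Stack of natural-history matrices for ages 45..100."""
    return np.stack(
        [nh_transition_matrix(a, rates, epi, space) for a in range(AGE_MIN, AGE_MAX + 1)]
    )


def simulate_natural_history(
    rates: NaturalHistoryRates, epi: EpiTables, space: StateSpace = DEFAULT_SPACE
) -> dict:
    """Run the unscreened cohort and summarize calibration-relevant outputs.

    Returns lifetime CRC incidence and mortality (fractions), per-age LR/HR
    polyp prevalence among the alive, and undiscounted life expectancy.
    """
    sp = space
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    v = np.zeros(sp.n)
    v[sp.HEALTHY] = 1.0
    prev_lr = np.zeros(ages.size)
    prev_hr = np.zeros(ages.size)
    life_years = 0.0
    incidence = 0.0
    for i, age in enumerate(ages):
        alive = 1.0 - v[sp.DEAD_CRC] - v[sp.DEAD_OTHER]
        if alive > 0:
            prev_lr[i] = (v[sp.LR_POLYP] + v[sp.LR_REFRACTORY]) / alive
            prev_hr[i] = (v[sp.HR_POLYP] + v[sp.HR_REFRACTORY]) / alive
        life_years += alive
        M = transition_matrix(age, rates, epi, sp)
        incidence += sum(v @ M[:, y1] for y1 in sp.CANCER_Y1)
        v = v @ M
    return {
        "lifetime_incidence": float(incidence),
        "crc_mortality": float(v[sp.DEAD_CRC]),
        "prevalence_lr": prev_lr,
        "prevalence_hr": prev_hr,
        "life_years": float(life_years),
        "ages": ages,
    }


class CalibrationError(RuntimeError):
    """Raised when the calibration targets cannot be met; carries residuals."""

    def __init__(self, message: str, report: pd.DataFrame | None = None):
        super().__init__(message)
        self.report = report


DEFAULT_TARGETS = {
    "lifetime_incidence": 0.052,
    "crc_mortality": 0.016,
    "prevalence_check_ages": (55, 65, 75, 85),
}
DEFAULT_TOLERANCES = {
    "lifetime_incidence": 0.003,
    "crc_mortality": 0.002,
    "prevalence": 0.05,
}


def calibrate_natural_history(
    epi: EpiTables,
    targets: dict | None = None,
    tolerances: dict | None = None,
    direct_cancer_fraction: float = 0.15,
    n_outer: int = 3,
) -> NaturalHistoryRates:
    """Fit the free natural-history rates to the synthetic targets.

    Deterministic nested solve with fixed starting points: a bounded
    least-squares fit of (onset scale, LR-to-HR rate) to the polyp
    prevalence curves, then bisection of the HR-to-cancer multiplier to the
    lifetime-incidence target and of the cancer-death scale to the
    CRC-mortality target, iterated a fixed number of outer rounds. Raises
    :class:`CalibrationError` with a residual report on failure.
    """
    tgt = {**DEFAULT_TARGETS, **(targets or {})}
    tol = {**DEFAULT_TOLERANCES, **(tolerances or {})}
    check_ages = [a - AGE_MIN for a in tgt["prevalence_check_ages"]]
    target_lr = epi.polyp_prevalence_lr.slice()[check_ages]
    target_hr = epi.polyp_prevalence_hr.slice()[check_ages]
    zero_polyps = np.all(epi.polyp_prevalence_lr.slice() == 0)
    zero_incidence = np.all(epi.crc_incidence_baseline.slice() == 0) or (
        tgt["lifetime_incidence"] == 0
    )

    onset_scale, lr_to_hr, hr_mult, death_scale = 1.0, 0.02, 15.0, 1.0
    if zero_polyps:
        onset_scale, lr_to_hr = 0.0, 0.0

    def make_rates(os_, l2h, mult, dscale):
        return NaturalHistoryRates(
            lr_onset=epi.lr_polyp_onset.scaled(os_),
            lr_to_hr=l2h,
            hr_to_cancer=mult,
            direct_cancer_fraction=direct_cancer_fraction,
            cancer_death_prob=np.clip(epi.cancer_death_prob * dscale, 0.0, 1.0),
        )

    if zero_incidence:
        hr_mult, death_scale = 0.0, 1.0
        tgt["crc_mortality"] = 0.0  # no cancers, so no cancer deaths

    for _ in range(n_outer):
        if not zero_polyps:
            def prev_residuals(x):
                sim = simulate_natural_history(make_rates(x[0], x[1], hr_mult, death_scale), epi)
                return np.concatenate(
                    [
                        sim["prevalence_lr"][check_ages] - target_lr,
                        sim["prevalence_hr"][check_ages] - target_hr,
                    ]
                )

            fit = optimize.least_squares(
                prev_residuals,
                x0=[onset_scale, lr_to_hr],
                bounds=([1e-4, 1e-5], [20.0, 0.5]),
                xtol=1e-10,
                ftol=1e-12,
            )
            onset_scale, lr_to_hr = float(fit.x[0]), float(fit.x[1])

        if not zero_incidence:
            def inc_gap(mult):
                sim = simulate_natural_history(
                    make_rates(onset_scale, lr_to_hr, mult, death_scale), epi
                )
                return sim["lifetime_incidence"] - tgt["lifetime_incidence"]

            lo, hi = 1e-3, 500.0
            if inc_gap(lo) > 0 or inc_gap(hi) < 0:
                raise CalibrationError("lifetime-incidence target outside reachable range")
            hr_mult = float(optimize.brentq(inc_gap, lo, hi, xtol=1e-6))

            def mort_gap(scale):
                sim = simulate_natural_history(
                    make_rates(onset_scale, lr_to_hr, hr_mult, scale), epi
                )
                return sim["crc_mortality"] - tgt["crc_mortality"]

            lo, hi = 1e-3, 10.0
            if mort_gap(lo) > 0 or mort_gap(hi) < 0:
                raise CalibrationError("CRC-mortality target outside reachable range")
            death_scale = float(optimize.brentq(mort_gap, lo, hi, xtol=1e-8))

    rates = make_rates(onset_scale, lr_to_hr, hr_mult, death_scale)
    report = calibration_report(rates, epi, tgt)
    bad = report[~report["within_tolerance"]]
    # tolerance check (prevalence only binds when polyp targets are nonzero)
    if len(bad) > 0:
        raise CalibrationError(
            f"calibration failed for: {', '.join(bad['target'])}", report=report
        )
    return rates


def calibration_report(
    rates: NaturalHistoryRates,
    epi: EpiTables,
    targets: dict | None = None,
    tolerances: dict | None = None,
) -> pd.DataFrame:
    """Target/achieved/residual table for a rate set (CSV-exportable)."""
    tgt = {**DEFAULT_TARGETS, **(targets or {})}
    tol = {**DEFAULT_TOLERANCES, **(tolerances or {})}
    sim = simulate_natural_history(rates, epi)
    rows = [
        (
            "lifetime_incidence",
            tgt["lifetime_incidence"],
            sim["lifetime_incidence"],
            tol["lifetime_incidence"],
        ),
        ("crc_mortality", tgt["crc_mortality"], sim["crc_mortality"], tol["crc_mortality"]),
    ]
    for a in tgt["prevalence_check_ages"]:
        i = a - AGE_MIN
        rows.append(
            (f"lr_prevalence_age_{a}", epi.polyp_prevalence_lr.slice()[i],
             sim["prevalence_lr"][i], tol["prevalence"])
        )
        rows.append(
            (f"hr_prevalence_age_{a}", epi.polyp_prevalence_hr.slice()[i],
             sim["prevalence_hr"][i], tol["prevalence"])
        )
    df = pd.DataFrame(rows, columns=["target", "target_value", "achieved", "tolerance"])
    df["residual"] = df["achieved"] - df["target_value"]
    df["within_tolerance"] = df["residual"].abs() <= df["tolerance"]
    return df
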