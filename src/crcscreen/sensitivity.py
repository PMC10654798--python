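"""One-way, threshold, scenario, and probabilistic sensitivity analyses.

Parameters are addressed by dotted path into the parameter bundle, e.g.
``costs.lb``, ``tests.lb.cancer_sensitivity``, ``tests.fit.specificity``,
``policy.adherence``. One-way analysis reruns the model at each bound;
threshold analysis bisects a (verified monotone) parameter to the
willingness-to-pay crossing; the probabilistic analysis samples beta
distributions for probabilities and gamma distributions for costs
(moment-matched to the base-case means) and builds cost-effectiveness
acceptability curves from per-iteration net monetary benefit.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import Outcomes, ParameterSet, run_all_strategies
from .frontier import FrontierResult, incremental_analysis

# ---------------------------------------------------------------- addressing


def get_param(params: ParameterSet, path: str) -> float:
    obj = params
    for part in path.split("."):
        if isinstance(obj, dict):
            if part not in obj:
                raise KeyError(f"unknown parameter path {path!r} (missing {part!r})")
            obj = obj[part]
        else:
            if not hasattr(obj, part):
                raise KeyError(f"unknown parameter path {path!r} (missing {part!r})")
            obj = getattr(obj, part)
    if not np.isscalar(obj):
        raise KeyError(f"parameter path {path!r} does not address a scalar")
    return float(obj)


def set_param(params: ParameterSet, path: str, value: float) -> ParameterSet:
    """Return a copy of the bundle with one scalar parameter replaced."""
    get_param(params, path)  # validate path
    new = copy.deepcopy(params)
    parts = path.split(".")
    obj = new
    for part in parts[:-1]:
        obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
    leaf = parts[-1]
    if isinstance(obj, dict):
        obj[leaf] = value
    else:
        object.__setattr__(obj, leaf, value)  # frozen dataclasses
    # keep the colonoscopy detection/miss pair complementary
    if leaf == "colo_cancer_detection_rate":
        object.__setattr__(obj, "colo_interval_cancer_rate", 1.0 - value)
    if leaf == "colo_interval_cancer_rate":
        object.__setattr__(obj, "colo_cancer_detection_rate", 1.0 - value)
    return new


# ---------------------------------------------------------------- one-way SA


@dataclass(frozen=True)
class OwsaEntry:
    parameter: str
    base_value: float
    low: float
    high: float
    icer_low: float
    icer_high: float
    comparison: tuple[str, str]

    @property
    def range_width(self) -> float:
        return abs(self.icer_high - self.icer_low)


def _icer(params: ParameterSet, comparison: tuple[str, str]) -> float:
    a, b = comparison
    outs = run_all_strategies(params, names=(a, b))
    dl = params.policy.discount_lyg
    de = outs[b].effectiveness(dl) - outs[a].effectiveness(dl)
    dc = outs[b].discounted_cost - outs[a].discounted_cost
    return dc / de


def one_way_sa(
    param_id: str,
    bounds: tuple[float, float],
    comparison: tuple[str, str],
    params: ParameterSet,
) -> OwsaEntry:
    """ICER of ``comparison[1]`` vs ``comparison[0]`` at each parameter bound.

    Negative lower bounds are clamped to 0.
    """
    base = get_param(params, param_id)
    lo, hi = sorted(bounds)
    lo = max(lo, 0.0)
    if not (lo <= base <= hi):
        raise ValueError(f"bounds {bounds} do not bracket base value {base} of {param_id!r}")
    return OwsaEntry(
        parameter=param_id,
        base_value=base,
        low=lo,
        high=hi,
        icer_low=_icer(set_param(params, param_id, lo), comparison),
        icer_high=_icer(set_param(params, param_id, hi), comparison),
        comparison=comparison,
    )


def tornado(
    entries: list[OwsaEntry],
) -> pd.DataFrame:
    """Tornado table sorted by descending ICER range width."""
    df = pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low,
                "high": e.high,
                "icer_low": e.icer_low,
                "icer_high": e.icer_high,
                "range": e.range_width,
            }
            for e in entries
        ]
    )
    return df.sort_values("range", ascending=False, ignore_index=True)


# ------------------------------------------------------------ threshold price


@dataclass(frozen=True)
class ThresholdResult:
    price: float
    crossed: bool
    message: str


def threshold_price(
    param_id: str,
    comparison: tuple[str, str],
    wtp: float,
    params: ParameterSet,
    search_interval: tuple[float, float],
    tol: float = 0.5,
    n_monotone_check: int = 5,
) -> ThresholdResult:
    """Largest parameter value at which the comparison is cost-effective.

    Verifies the ICER is monotone over the interval on a coarse grid
    (refusing with diagnostics otherwise), then bisects ``ICER(p) = wtp``
    to within ``tol`` on the parameter. When the ICER never crosses the
    threshold the relevant endpoint is returned with a flag.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    lo, hi = search_interval
    grid = np.linspace(lo, hi, n_monotone_check)
    icers = [_icer(set_param(params, param_id, float(p)), comparison) for p in grid]
    diffs = np.diff(icers)
    if not (np.all(diffs >= -1e-9) or np.all(diffs <= 1e-9)):
        raise ValueError(
            f"ICER not monotone in {param_id!r} over {search_interval}: samples {icers}"
        )
    increasing = icers[-1] >= icers[0]
    f_lo, f_hi = icers[0] - wtp, icers[-1] - wtp
    if increasing:
        if f_hi <= 0:
            return ThresholdResult(hi, False, "already cost-effective at upper bound")
        if f_lo >= 0:
            return ThresholdResult(lo, False, "not cost-effective anywhere in interval")
    else:
        if f_lo <= 0:
            return ThresholdResult(lo, False, "already cost-effective at lower bound")
        if f_hi >= 0:
            return ThresholdResult(hi, False, "not cost-effective anywhere in interval")
    a, b = lo, hi
    while b - a > tol:
        mid = 0.5 * (a + b)
        below = _icer(set_param(params, param_id, mid), comparison) - wtp <= 0
        if below == increasing:
            a = mid  # cost-effective side extends upward
        else:
            b = mid
    return ThresholdResult(0.5 * (a + b), True, "threshold found")


# ----------------------------------------------------------------- scenarios


def scenario_lb_polyp(
    hr_grid: list[float], lr_grid: list[float], params: ParameterSet
) -> pd.DataFrame:
    """Frontier results when the blood test is granted polyp sensitivity.

    Detected polyps are confirmed and removed at a follow-up colonoscopy and
    enter surveillance, exactly as for stool-test positives.
    """
    rows = []
    for hr in hr_grid:
        for lr in lr_grid:
            if not (0.0 <= hr <= 1.0 and 0.0 <= lr <= 1.0):
                raise ValueError("polyp sensitivity grids must lie in [0, 1]")
            p = set_param(params, "tests.lb.hr_polyp_sensitivity", hr)
            p = set_param(p, "tests.lb.lr_polyp_sensitivity", lr)
            fr = strategy_frontier(p)
            for name in ("LB", "C-LB"):
                row = fr[name]
                rows.append(
                    {
                        "hr_sensitivity": hr,
                        "lr_sensitivity": lr,
                        "strategy": name,
                        "cost": row.cost,
                        "lyg": row.effectiveness,
                        "icer": row.icer,
                        "status": row.status,
                    }
                )
    return pd.DataFrame(rows)


def scenario_intervals_and_endage(
    lr_intervals: tuple[int, ...],
    end_ages: tuple[int, ...],
    params: ParameterSet,
    wtp: float | None = None,
) -> pd.DataFrame:
    """Outcomes table over LR-surveillance-interval and screening-end-age grid.

    Flags whether the preferred strategy at the WTP threshold changes from
    the base configuration.
    """
    from .frontier import decide_cost_effective

    wtp = wtp or params.policy.wtp
    base_choice = decide_cost_effective(strategy_frontier(params), wtp)
    rows = []
    for lr_iv in lr_intervals:
        for end_age in end_ages:
            p = copy.deepcopy(params)
            object.__setattr__(p.policy, "lr_surveillance_interval", int(lr_iv))
            object.__setattr__(p.policy, "screen_stop_age", int(end_age))
            fr = strategy_frontier(p)
            choice = decide_cost_effective(fr, wtp)
            for row in fr.rows:
                rows.append(
                    {
                        "lr_interval": lr_iv,
                        "screen_end_age": end_age,
                        "strategy": row.name,
                        "cost": row.cost,
                        "lyg": row.effectiveness,
                        "status": row.status,
                        "preferred": choice,
                        "conclusion_unchanged": choice == base_choice,
                    }
                )
    return pd.DataFrame(rows)


def strategy_frontier(params: ParameterSet) -> FrontierResult:
    """Run all six strategies and perform the incremental analysis."""
    outs = run_all_strategies(params)
    dl = params.policy.discount_lyg
    pairs = [
        (name, o.discounted_cost, o.effectiveness(dl)) for name, o in outs.items()
    ]
    return incremental_analysis(pairs)


# ------------------------------------------------------------------------ PSA


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one parameter (moment-matched)."""

    family: str  # beta | gamma | degenerate
    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "degenerate"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "degenerate" or self.sd == 0.0:
            return self.mean
        if self.family == "beta":
            m, s2 = self.mean, self.sd**2
            if m <= 0.0 or m >= 1.0:
                return self.mean
            if m * (1.0 - m) <= s2:
                raise ValueError(
                    f"infeasible beta moments mean={m}, sd={self.sd}"
                )
            nu = m * (1.0 - m) / s2 - 1.0
            return float(rng.beta(m * nu, (1.0 - m) * nu))
        # gamma: shape = (mean/sd)^2, scale = sd^2/mean
        if self.mean <= 0.0:
            return self.mean
        shape = (self.mean / self.sd) ** 2
        scale = self.sd**2 / self.mean
        return float(rng.gamma(shape, scale))


# default SDs: 10% of the mean for probabilities; range-implied for costs
# (printed cost ranges are +/-25% of the mean, read as 95% intervals)
_PROB_CV = 0.10
_COST_RANGE_Z = 2.0 * 1.96


def default_psa_distributions(params: ParameterSet) -> dict[str, DistributionSpec]:
    dists: dict[str, DistributionSpec] = {}
    prob_paths = [
        "tests.fit.cancer_sensitivity",
        "tests.fit.hr_polyp_sensitivity",
        "tests.fit.lr_polyp_sensitivity",
        "tests.fit.specificity",
        "tests.sdna.cancer_sensitivity",
        "tests.sdna.hr_polyp_sensitivity",
        "tests.sdna.lr_polyp_sensitivity",
        "tests.sdna.specificity",
        "tests.lb.cancer_sensitivity",
        "tests.lb.specificity",
        "tests.colonoscopy.colo_cancer_detection_rate",
    ]
    for path in prob_paths:
        m = get_param(params, path)
        sd = min(_PROB_CV * m, 0.9 * np.sqrt(m * (1 - m))) if 0 < m < 1 else 0.0
        dists[path] = DistributionSpec("beta", m, sd)
    cost_paths = [
        "costs.colonoscopy_polypectomy",
        "costs.colonoscopy",
        "costs.fit",
        "costs.sdna",
        "costs.lb",
    ]
    for path in cost_paths:
        m = get_param(params, path)
        dists[path] = DistributionSpec("gamma", m, 0.5 * m / _COST_RANGE_Z)
    for stage_idx, stage in enumerate(("local", "regional", "distant")):
        for phase in ("first_year", "continuing", "final_year"):
            m = float(getattr(params.costs, f"cancer_{phase}")[stage_idx])
            dists[f"__cancer_cost__.{phase}.{stage_idx}"] = DistributionSpec(
                "gamma", m, 0.5 * m / _COST_RANGE_Z
            )
    return dists


def sample_psa_draw(
    distributions: dict[str, DistributionSpec],
    rng: np.random.Generator,
    params: ParameterSet,
) -> ParameterSet:
    """One coherent parameter set sampled from the distribution specs."""
    new = copy.deepcopy(params)
    for path, dist in distributions.items():
        value = dist.sample(rng)
        if path.startswith("__cancer_cost__"):
            _, phase, idx = path.split(".")
            getattr(new.costs, f"cancer_{phase}").setflags(write=True)
            getattr(new.costs, f"cancer_{phase}")[int(idx)] = value
        else:
            new = set_param(new, path, value)
    return new


@dataclass
class PsaResult:
    n_iterations: int
    seed: int
    draws: pd.DataFrame  # per-iteration, per-strategy cost and effect
    ceac: pd.DataFrame  # columns: wtp, strategy, probability

    def modal_strategy(self, wtp: float) -> str:
        sub = self.ceac[self.ceac["wtp"] == wtp]
        return sub.loc[sub["probability"].idxmax(), "strategy"]


def run_psa(
    n_iterations: int,
    seed: int,
    wtp_grid: list[float],
    params: ParameterSet,
    distributions: dict[str, DistributionSpec] | None = None,
) -> PsaResult:
    """Probabilistic sensitivity analysis with CEAC output.

    Natural-history rates stay at their calibrated base-case values; test
    performance and unit costs are resampled each iteration, all six
    strategies rerun, and the optimal strategy per willingness-to-pay value
    chosen by highest net monetary benefit. Reproducible for a fixed seed.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    dists = distributions if distributions is not None else default_psa_distributions(params)
    rng = np.random.default_rng(seed)
    dl = params.policy.discount_lyg
    records = []
    names = None
    for it in range(n_iterations):
        draw = sample_psa_draw(dists, rng, params)
        outs = run_all_strategies(draw)
        names = list(outs)
        for name, o in outs.items():
            records.append(
                {
                    "iteration": it,
                    "strategy": name,
                    "cost": o.discounted_cost,
                    "effect": o.effectiveness(dl),
                }
            )
    draws = pd.DataFrame(records)
    wide_c = draws.pivot(index="iteration", columns="strategy", values="cost")
    wide_e = draws.pivot(index="iteration", columns="strategy", values="effect")
    ceac_rows = []
    for wtp in wtp_grid:
        nmb = wide_e * wtp - wide_c
        best = nmb.idxmax(axis=1)
        frac = best.value_counts(normalize=True)
        for name in names:
            ceac_rows.append(
                {"wtp": wtp, "strategy": name, "probability": float(frac.get(name, 0.0))}
            )
    return PsaResult(
        n_iterations=n_iterations,
        seed=seed,
        draws=draws,
        ceac=pd.DataFrame(ceac_rows),
    )
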