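"""Configuration loading, validation, and the end-to-end pipeline.

A single structured YAML/JSON document is the only input surface. Every
base-case input is reachable and overridable under four top-level keys —
``policy``, ``epi`` (synthetic-generator shape parameters), ``tests``, and
``costs`` — plus a ``run`` block (strategies, seed, analysis selector,
output directory). Unspecified keys fall back to base-case defaults.
"""
from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    CostSet,
    ParameterSet,
    Policy,
    default_parameter_set,
    run_all_strategies,
)
from .natural_history import calibrate_natural_history, calibration_report
from .synthetic_epi import default_epi_tables
from .strategies import STRATEGY_NAMES, TestPerformance, default_test_performance
from .frontier import decide_cost_effective, incremental_analysis
from .sensitivity import (
    default_psa_distributions,
    one_way_sa,
    run_psa,
    scenario_intervals_and_endage,
    scenario_lb_polyp,
    threshold_price,
    tornado,
)

ANALYSES = ("base", "owsa", "threshold", "scenario", "psa")


@dataclass
class RunConfig:
    """Run-level settings (everything outside the parameter bundle)."""

    strategies: tuple[str, ...] = STRATEGY_NAMES
    seed: int = 1
    analysis: str = "base"
    output_dir: str = "results"
    psa_iterations: int = 500
    wtp_grid: tuple[float, ...] = (0.0, 25_000.0, 50_000.0, 100_000.0, 150_000.0, 200_000.0)

    def __post_init__(self) -> None:
        unknown = set(self.strategies) - set(STRATEGY_NAMES)
        if unknown:
            raise ValueError(f"run.strategies: unknown strategy names {sorted(unknown)}")
        if self.analysis not in ANALYSES:
            raise ValueError(f"run.analysis must be one of {ANALYSES}")


_TEST_FIELDS = (
    "cancer_sensitivity",
    "hr_polyp_sensitivity",
    "lr_polyp_sensitivity",
    "specificity",
    "colo_cancer_detection_rate",
)
_COST_FIELDS = ("colonoscopy_polypectomy", "colonoscopy", "fit", "sdna", "lb")
_POLICY_FIELDS = {f for f in Policy.__dataclass_fields__}


def _require(cond: bool, keypath: str, message: str) -> None:
    if not cond:
        raise ValueError(f"config error at {keypath}: {message}")


def load_config(path_or_dict) -> tuple[RunConfig, ParameterSet]:
    """Parse and validate a config document; apply defaults everywhere else.

    ``path_or_dict`` may be a YAML/JSON file path or an already-parsed
    mapping. Natural-history rates are calibrated to the (possibly
    overridden) synthetic epidemiology.
    """
    if isinstance(path_or_dict, (str, Path)):
        doc = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        doc = copy.deepcopy(path_or_dict) or {}
    _require(isinstance(doc, dict), "<root>", "document must be a mapping")

    policy_over = doc.get("policy", {}) or {}
    for key, val in policy_over.items():
        _require(key in _POLICY_FIELDS, f"policy.{key}", "unknown policy field")
    try:
        policy = Policy(**policy_over)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"config error at policy: {exc}") from exc

    epi_over = doc.get("epi", {}) or {}
    for key in epi_over:
        _require(
            key in ("life_table", "incidence", "polyps", "stages"),
            f"epi.{key}",
            "unknown epidemiology block",
        )
    epi = default_epi_tables(**epi_over)

    tests = default_test_performance()
    for modality, over in (doc.get("tests", {}) or {}).items():
        _require(modality in tests, f"tests.{modality}", "unknown modality")
        for key, val in (over or {}).items():
            _require(key in _TEST_FIELDS, f"tests.{modality}.{key}", "unknown field")
            _require(
                isinstance(val, (int, float)) and 0.0 <= val <= 1.0,
                f"tests.{modality}.{key}",
                "must be a probability in [0, 1]",
            )
        base = tests[modality]
        kwargs = {k: getattr(base, k) for k in base.__dataclass_fields__}
        kwargs.update(over or {})
        if "colo_cancer_detection_rate" in (over or {}):
            kwargs["colo_interval_cancer_rate"] = 1.0 - over["colo_cancer_detection_rate"]
        tests[modality] = TestPerformance(**kwargs)

    cost_over = doc.get("costs", {}) or {}
    for key, val in cost_over.items():
        _require(key in _COST_FIELDS, f"costs.{key}", "unknown cost field")
        _require(
            isinstance(val, (int, float)) and val >= 0,
            f"costs.{key}",
            "must be a non-negative number",
        )
    costs = CostSet(**cost_over)

    run_over = doc.get("run", {}) or {}
    known_run = set(RunConfig.__dataclass_fields__)
    for key in run_over:
        _require(key in known_run, f"run.{key}", "unknown run field")
    if "strategies" in run_over:
        run_over["strategies"] = tuple(run_over["strategies"])
    if "wtp_grid" in run_over:
        run_over["wtp_grid"] = tuple(run_over["wtp_grid"])
    run = RunConfig(**run_over)

    rates = calibrate_natural_history(
        epi, direct_cancer_fraction=policy.direct_cancer_fraction
    )
    params = ParameterSet(epi=epi, rates=rates, tests=tests, costs=costs, policy=policy)
    return run, params


def config_hash(doc) -> str:
    canonical = json.dumps(doc, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_pipeline(path_or_dict, output_dir: str | None = None) -> dict:
    """Run the analyses a config requests and write result tables to disk.

    Always writes the calibration report, per-strategy outcomes, and the
    incremental frontier; the ``run.analysis`` selector adds sensitivity
    outputs. Returns a manifest of written files. Deterministic for a fixed
    config (PSA is seeded from ``run.seed``).
    """
    if isinstance(path_or_dict, (str, Path)):
        doc = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        doc = copy.deepcopy(path_or_dict) or {}
    run, params = load_config(doc)
    out = Path(output_dir or run.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(doc)
    manifest = {"config_hash": chash, "seed": run.seed, "files": []}

    def write(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False)
        manifest["files"].append(str(p))

    write(calibration_report(params.rates, params.epi), "calibration_report.csv")

    outcomes = run_all_strategies(params, names=run.strategies)
    dl = params.policy.discount_lyg
    odf = pd.DataFrame(
        [
            {
                "strategy": n,
                "cost": o.discounted_cost,
                "lyg": o.effectiveness(dl),
                "undiscounted_lyg": o.undiscounted_lyg,
                "total_cancer_pct": o.lifetime_crc_incidence,
                "cancer_death_pct": o.crc_mortality,
            }
            for n, o in outcomes.items()
        ]
    )
    write(odf, "outcomes.csv")
    (out / "outcomes.json").write_text(odf.set_index("strategy").to_json(indent=1))
    manifest["files"].append(str(out / "outcomes.json"))

    frontier = incremental_analysis(
        [(n, o.discounted_cost, o.effectiveness(dl)) for n, o in outcomes.items()]
    )
    fdf = frontier.to_frame()
    fdf["config_hash"] = chash
    write(fdf, "frontier.csv")
    manifest["preferred_strategy"] = decide_cost_effective(frontier, params.policy.wtp)

    if run.analysis == "owsa":
        entries = []
        for path, lo, hi in (
            ("costs.lb", 0.0, 949.0),
            ("costs.colonoscopy", 1119.0 * 0.75, 1119.0 * 1.25),
            ("tests.lb.cancer_sensitivity", 0.50, 1.00),
        ):
            entries.append(one_way_sa(path, (lo, hi), ("NH", "LB"), params))
        write(tornado(entries), "tornado.csv")
    elif run.analysis == "threshold":
        res = threshold_price("costs.lb", ("NH", "LB"), params.policy.wtp, params, (0.0, 949.0))
        write(
            pd.DataFrame(
                [{"parameter": "costs.lb", "price": res.price, "crossed": res.crossed,
                  "message": res.message}]
            ),
            "threshold.csv",
        )
    elif run.analysis == "scenario":
        write(scenario_lb_polyp([0.0, 0.1, 0.2], [0.0, 0.05, 0.1], params), "scenario_lb_polyp.csv")
        write(
            scenario_intervals_and_endage((5, 7, 10), (75, 85), params),
            "scenario_intervals.csv",
        )
    elif run.analysis == "psa":
        res = run_psa(run.psa_iterations, run.seed, list(run.wtp_grid), params)
        ceac = res.ceac.copy()
        ceac["config_hash"] = chash
        write(ceac, "ceac.csv")
        write(res.draws, "psa_draws.csv")

    (out / "run_log.json").write_text(json.dumps(manifest, indent=1))
    return manifest
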