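"""Configuration parsing, cohort CSV reading and JSON report writing.

A run is described by a flat YAML or JSON config with a ``mode`` key:

``cohort``
    full pipeline on a subject-level CSV;
``calculator``
    summary equation on pre-computed analytic inputs (two treatment-effect
    estimates, two R² values, optional Introduced-Variable terms);
``example``
    one of the four built-in worked examples;
``simulate``
    draw a synthetic cohort, optionally export it and/or analyze it.

Reports are JSON with every intermediate of the summary equation named by
its conventional symbol (TEE_M1, TEE_M2, Conf_IntV_delta, Conf_IntV_M1,
Adj_delta_TEE, x, unconfounded_TEE) at full precision, plus a 4-decimal
worked chain for desk audit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, core
from .core import AcceInputs, AmplificationPair, BrossTerm, EffectEstimate, ProbeThresholds
from .exceptions import CohortValidationError, ConfigError
from .model import ACCE
from .propensity import Cohort, NestedModelSpec
from .simulate import SimScenario, example_fixture, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "read_cohort", "run_acce", "write_report"]

_COMMON_KEYS = {"mode", "output", "seed", "qualitative_thresholds"}
_MODE_KEYS = {
    "cohort": {"cohort_path", "treatment", "outcome", "model1_covariates",
               "introduced_variables", "n_strata", "withheld_marker",
               "iv_balance_m1", "min_per_arm", "bootstrap"},
    "calculator": {"tee_m1_rr", "tee_m1_beta", "tee_m2_rr", "tee_m2_beta",
                   "r2_m1", "r2_m2", "iv_rr_outcome",
                   "iv_prev_treated_m1", "iv_prev_comparison_m1",
                   "iv_prev_treated_m2", "iv_prev_comparison_m2"},
    "example": {"example_id"},
    "simulate": {"scenario", "export_cohort_path", "analyze", "n_strata"},
}
_REQUIRED = {
    "cohort": {"cohort_path", "treatment", "outcome", "model1_covariates",
               "introduced_variables"},
    "calculator": {"r2_m1", "r2_m2"},
    "example": {"example_id"},
    "simulate": {"scenario"},
}
_BOOTSTRAP_KEYS = {"B", "ci_level", "stratify_by_arm"}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """A validated run configuration (see module docstring for modes)."""

    mode: str
    options: dict
    output: str | None = None
    seed: int | None = None
    thresholds: ProbeThresholds | None = None


def _validate(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError(f"config must be a mapping, got {type(raw).__name__}")
    mode = raw.get("mode")
    if mode not in _MODE_KEYS:
        raise ConfigError(f"mode must be one of {sorted(_MODE_KEYS)}, got {mode!r}")
    allowed = _COMMON_KEYS | _MODE_KEYS[mode]
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown config keys for mode {mode!r}: {sorted(unknown)}")
    missing = _REQUIRED[mode] - set(raw)
    if mode == "calculator":
        for which in ("m1", "m2"):
            if f"tee_{which}_rr" not in raw and f"tee_{which}_beta" not in raw:
                missing.add(f"tee_{which}_rr|tee_{which}_beta")
    if missing:
        raise ConfigError(f"missing required keys for mode {mode!r}: {sorted(missing)}")
    boot = raw.get("bootstrap")
    if boot is not None:
        bad = set(boot) - _BOOTSTRAP_KEYS
        if bad:
            raise ConfigError(f"unknown bootstrap keys: {sorted(bad)}")
    thresholds = None
    qt = raw.get("qualitative_thresholds")
    if qt is not None:
        bad = set(qt) - {"negligible", "small"}
        if bad:
            raise ConfigError(f"unknown qualitative_thresholds keys: {sorted(bad)}")
        thresholds = ProbeThresholds(**qt)
    options = {k: v for k, v in raw.items() if k not in _COMMON_KEYS}
    return RunConfig(mode=mode, options=options, output=raw.get("output"),
                     seed=raw.get("seed"), thresholds=thresholds)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run config."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)  # YAML is a superset of JSON
    return _validate(raw)


def read_cohort(path: str | Path, treatment: str, outcome: str,
                covariates: list[str], iv_columns: list[str] = (),
                min_per_arm: int = 1) -> Cohort:
    """Read and validate a cohort CSV.

    Rows with missing values in any mapped column are rejected (dropped)
    with a logged count; non-binary treatment/outcome coding raises a
    validation error naming the offending values.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cols = [treatment, outcome, *covariates]
    absent = [c for c in cols if c not in df.columns]
    if absent:
        raise CohortValidationError(
            f"{path}: columns not found: {absent}; header is {list(df.columns)}")
    mask = df.loc[:, cols].isna().any(axis=1)
    if mask.any():
        logger.warning("%s: rejecting %d of %d rows with missing mapped values",
                       path, int(mask.sum()), len(df))
        df = df.loc[~mask]
    if len(df) == 0:
        raise CohortValidationError(f"{path}: no complete rows remain")
    return Cohort.from_dataframe(df, treatment=treatment, outcome=outcome,
                                 covariates=covariates, iv_columns=tuple(iv_columns),
                                 min_per_arm=min_per_arm)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Export a cohort to the standard CSV layout (round-trips exactly
    through :func:`read_cohort`)."""
    cohort.data.to_csv(path, index=False)


def _calculator_inputs(opts: dict) -> AcceInputs:
    def tee(which: str) -> EffectEstimate:
        if f"tee_{which}_beta" in opts:
            return EffectEstimate(float(opts[f"tee_{which}_beta"]))
        return EffectEstimate.from_rr(float(opts[f"tee_{which}_rr"]))

    amp = AmplificationPair(float(opts["r2_m1"]), float(opts["r2_m2"]))
    conf_delta = conf_m1 = 0.0
    if "iv_rr_outcome" in opts:
        rr = float(opts["iv_rr_outcome"])
        t1 = BrossTerm(float(opts["iv_prev_treated_m1"]),
                       float(opts["iv_prev_comparison_m1"]), rr)
        t2 = BrossTerm(float(opts["iv_prev_treated_m2"]),
                       float(opts["iv_prev_comparison_m2"]), rr)
        conf_m1 = core.bross_log_confounding(t1)
        conf_delta = core.delta_iv_confounding(t1, t2)
    return AcceInputs(tee("m1"), tee("m2"), amp,
                      conf_iv_delta=conf_delta, conf_iv_m1=conf_m1)


def _analytic_report(inputs: AcceInputs, thresholds: ProbeThresholds | None) -> dict:
    result = core.unconfounded_tee(inputs, thresholds)
    q = result.qualitative
    return {
        "terms": core.summary_equation_terms(result),
        "worked_chain_4dp": core.worked_chain(inputs),
        "qualitative": {"direction": q.direction, "magnitude": q.magnitude,
                        "delta_beta": q.delta_beta},
        "warnings": list(result.warnings),
    }


def run_acce(config: RunConfig) -> dict:
    """Execute a validated config end-to-end and return the report dict.

    The report echoes the inputs, names every intermediate of the summary
    equation, includes the qualitative classification and all warnings,
    and carries a tool/version/seed provenance block.  When
    ``config.output`` is set the report is also written as JSON.
    """
    opts = dict(config.options)
    if config.mode == "example":
        inputs = example_fixture(int(opts["example_id"]))
        report = _analytic_report(inputs, config.thresholds)
    elif config.mode == "calculator":
        report = _analytic_report(_calculator_inputs(opts), config.thresholds)
    elif config.mode == "cohort":
        cohort = read_cohort(
            opts["cohort_path"], treatment=opts["treatment"],
            outcome=opts["outcome"],
            covariates=[*opts["model1_covariates"], *opts["introduced_variables"],
                        *( [opts["withheld_marker"]] if opts.get("withheld_marker") else [] )],
            iv_columns=list(opts["introduced_variables"]),
            min_per_arm=int(opts.get("min_per_arm", 1)))
        spec = NestedModelSpec(
            model1_covariates=tuple(opts["model1_covariates"]),
            introduced_variables=tuple(opts["introduced_variables"]),
            n_strata=int(opts.get("n_strata", 10)),
            withheld_marker=opts.get("withheld_marker"),
            iv_balance_m1=opts.get("iv_balance_m1", "stratified"))
        results = ACCE(cohort, spec, thresholds=config.thresholds).fit()
        report = results.to_report()
        boot = opts.get("bootstrap")
        if boot:
            b = results.bootstrap_ci(
                B=int(boot.get("B", 500)),
                level=float(boot.get("ci_level", 0.95)),
                seed=config.seed,
                stratify_by_arm=bool(boot.get("stratify_by_arm", False)))
            report["bootstrap"] = dataclasses.asdict(b)
    elif config.mode == "simulate":
        scenario = SimScenario(**opts["scenario"])
        if config.seed is not None:
            scenario = dataclasses.replace(scenario, seed=config.seed)
        cohort = generate_cohort(scenario)
        report = {"scenario": dataclasses.asdict(scenario), "n": cohort.n}
        if opts.get("export_cohort_path"):
            write_cohort(cohort, opts["export_cohort_path"])
            report["exported_to"] = str(opts["export_cohort_path"])
        if opts.get("analyze", True):
            spec = NestedModelSpec(model1_covariates=("x",),
                                   introduced_variables=("z",),
                                   n_strata=int(opts.get("n_strata", 10)))
            report["analysis"] = ACCE(cohort, spec, thresholds=config.thresholds).fit().to_report()
    else:  # pragma: no cover - _validate guarantees the mode
        raise ConfigError(f"unhandled mode {config.mode!r}")

    report["provenance"] = {"tool": "acce", "version": __version__,
                            "mode": config.mode, "seed": config.seed}
    report["display_4dp"] = _rounded_block(report)
    if config.output:
        write_report(report, config.output)
    return report


def _rounded_block(report: dict) -> dict:
    terms = report.get("terms") or report.get("analysis", {}).get("terms")
    if not terms:
        return {}
    return {k: (round(v, 4) if isinstance(v, float) and math.isfinite(v) else v)
            for k, v in terms.items()}


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
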