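"""YAML configuration for the DGP, the scenario grid, and run options."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .defaults import default_params
from .engine import Scenario
from .params import DGPParams


class ConfigError(ValueError):
    pass


_DGP_KEYS = {"mu", "sigma", "binary_prevalences", "outcome_coefs",
             "missingness_coefs", "target_variable", "n_pop", "event_rate"}
_SCENARIO_KEYS = {"n_sample", "p_missing", "method", "target_variable",
                  "n_reps", "M", "donor_pool_k", "ridge"}
_RUN_KEYS = {"master_seed", "n_jobs", "out_dir"}
_TOP_KEYS = {"dgp", "scenarios", "run"}


def params_to_dict(params: DGPParams) -> dict:
    return {
        "mu": params.mu.tolist(),
        "sigma": params.sigma.tolist(),
        "binary_prevalences": params.binary_prevalences.tolist(),
        "outcome_coefs": params.outcome_coefs.tolist(),
        "missingness_coefs": params.missingness_coefs.tolist(),
        "target_variable": params.target_variable,
        "n_pop": int(params.n_pop),
        "event_rate": None if params.event_rate is None else float(params.event_rate),
    }


def params_from_dict(d: dict) -> DGPParams:
    unknown = set(d) - _DGP_KEYS
    if unknown:
        raise ConfigError(f"unknown dgp config keys: {sorted(unknown)}")
    base = params_to_dict(default_params(d.get("target_variable", "cholesterol")))
    base.update(d)
    try:
        return DGPParams(
            mu=np.asarray(base["mu"], dtype=float),
            sigma=np.asarray(base["sigma"], dtype=float),
            binary_prevalences=np.asarray(base["binary_prevalences"], dtype=float),
            outcome_coefs=np.asarray(base["outcome_coefs"], dtype=float),
            missingness_coefs=np.asarray(base["missingness_coefs"], dtype=float),
            target_variable=base["target_variable"],
            n_pop=int(base["n_pop"]),
            event_rate=base["event_rate"],
        )
    except ValueError as err:
        raise ConfigError(f"invalid dgp config: {err}") from err


def scenario_from_dict(d: dict) -> Scenario:
    unknown = set(d) - _SCENARIO_KEYS
    if unknown:
        raise ConfigError(f"unknown scenario config keys: {sorted(unknown)}")
    for key in ("n_sample", "p_missing", "method"):
        if key not in d:
            raise ConfigError(f"scenario config missing required key {key!r}")
    try:
        return Scenario(**d)
    except ValueError as err:
        raise ConfigError(f"invalid scenario config: {err}") from err


def load_config(path: str | Path) -> tuple[DGPParams, list[Scenario], dict]:
    """Read a YAML config into (DGPParams, scenario list, run options).

    Unknown keys at any level are rejected with the offending key named.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
    params = params_from_dict(raw.get("dgp", {}) or {})
    scenarios = [scenario_from_dict(s) for s in raw.get("scenarios", []) or []]
    run = raw.get("run", {}) or {}
    unknown = set(run) - _RUN_KEYS
    if unknown:
        raise ConfigError(f"unknown run config keys: {sorted(unknown)}")
    run.setdefault("master_seed", 20220718)
    run.setdefault("n_jobs", 1)
    run.setdefault("out_dir", "results")
    return params, scenarios, run


def save_config(path: str | Path, params: DGPParams,
                scenarios: list[Scenario] | None = None,
                run: dict | None = None) -> None:
    doc: dict = {"dgp": params_to_dict(params)}
    if scenarios:
        doc["scenarios"] = [
            {"n_sample": s.n_sample, "p_missing": s.p_missing, "method": s.method,
             "target_variable": s.target_variable, "n_reps": s.n_reps,
             "M": s.M, "donor_pool_k": s.donor_pool_k, "ridge": s.ridge}
            for s in scenarios]
    if run:
        doc["run"] = dict(run)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
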