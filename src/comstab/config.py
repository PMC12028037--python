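"""Run configuration: schema, defaults, validation and normalization.

Every stochastic stage must carry an explicit seed; defaults are filled in
and recorded in the run manifest so each run leaves an audit trail of every
parameter, including ones the user never set.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config", "DEFAULTS"]


class ConfigError(ValueError):
    """Raised with an itemized report of configuration problems."""


DEFAULTS: dict = {
    "inputs": {
        # either a simulation block or explicit paths
        "simulate": None,            # {"seed": int} -> synthetic study
        "feature_table": None,
        "metadata": None,
        "env": None,
        "orientation": "samples_as_rows",
    },
    "grouping": "soil_type",
    "filter": {"min_prevalence": 0.2, "min_mean_abundance": 0.0},
    "diversity": {"n_perm": 999, "seed": None},
    "network": {"rho_min": 0.6, "alpha": 0.05, "correction": "BH",
                "resolution": 1.0, "seed": None},
    "cohesion": {"corr_source": "network_edges", "null_model_correction": False,
                 "n_null": 200},
    "robustness": {"random_fraction": 0.5, "n_iterations": 999,
                   "hub_count": 5, "seed": None},
    "stability": {"n_iterations": 99, "seed": None},
    "drivers": {"correction": "none"},
    "plspm": {"scheme": "centroid", "n_boot": 500, "max_iter": 500,
              "tol": 1e-7, "seed": None},
    "output_dir": "comstab_run",
}

_SEEDED_STAGES = ("diversity", "network", "robustness", "stability", "plspm")


@dataclass(frozen=True)
class RunConfig:
    raw: dict = field(repr=False)
    filled_defaults: tuple[str, ...] = ()

    def __getitem__(self, key):
        return self.raw[key]

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.raw, sort_keys=True)


def _merge(defaults: dict, user: dict, path: str, errors: list, filled: list) -> dict:
    out = {}
    for key, dval in defaults.items():
        here = f"{path}.{key}" if path else key
        if key in user:
            uval = user[key]
            if isinstance(dval, dict) and dval and isinstance(uval, dict):
                out[key] = _merge(dval, uval, here, errors, filled)
            else:
                out[key] = uval
        else:
            out[key] = copy.deepcopy(dval)
            filled.append(here)
    for key in user:
        if key not in defaults:
            errors.append(f"unknown key: {f'{path}.{key}' if path else key}")
    return out


def validate_config(doc: dict) -> RunConfig:
    """Normalize a raw config dict: fill defaults, reject unknown keys and
    out-of-range thresholds, require a seed for every stochastic stage."""
    errors: list[str] = []
    filled: list[str] = []
    cfg = _merge(DEFAULTS, doc or {}, "", errors, filled)

    inputs = cfg["inputs"]
    if inputs["simulate"] is None and inputs["feature_table"] is None:
        errors.append("inputs: provide either a 'simulate' block or a 'feature_table' path")
    if inputs["simulate"] is not None and "seed" not in inputs["simulate"]:
        errors.append("inputs.simulate.seed: required")

    flt = cfg["filter"]
    for key in ("min_prevalence", "min_mean_abundance"):
        if not (0 <= flt[key] <= 1):
            errors.append(f"filter.{key}: must lie in [0, 1]")
    net = cfg["network"]
    if not (0 <= net["rho_min"] < 1):
        errors.append("network.rho_min: must lie in [0, 1)")
    if not (0 < net["alpha"] <= 1):
        errors.append("network.alpha: must lie in (0, 1]")
    if net["correction"] not in ("none", "BH"):
        errors.append("network.correction: must be 'none' or 'BH'")
    rb = cfg["robustness"]
    if not (0 < rb["random_fraction"] < 1):
        errors.append("robustness.random_fraction: must lie in (0, 1)")
    if cfg["plspm"]["scheme"] not in ("centroid", "factorial", "path"):
        errors.append("plspm.scheme: must be centroid, factorial or path")
    if cfg["plspm"]["n_boot"] is not None and cfg["plspm"]["n_boot"] < 100:
        errors.append("plspm.n_boot: must be >= 100 (or null to skip bootstrap)")
    if cfg["drivers"]["correction"] not in ("none", "BH"):
        errors.append("drivers.correction: must be 'none' or 'BH'")
    if cfg["cohesion"]["corr_source"] not in ("network_edges", "all_significant"):
        errors.append("cohesion.corr_source: must be 'network_edges' or 'all_significant'")
    for stage in _SEEDED_STAGES:
        if cfg[stage].get("seed") is None:
            errors.append(f"{stage}.seed: every stochastic stage needs an explicit seed")
    if errors:
        raise ConfigError("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))
    return RunConfig(cfg, tuple(filled))


def load_config(path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigError("config file must contain a mapping")
    return validate_config(doc)
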