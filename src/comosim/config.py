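"""Run configuration: a structured YAML document with fixed sections.

Sections: ``cohort`` (synthetic-cohort generation), ``models`` (QCS cut
points and categorizer bins), ``simulation`` (microsimulation grids and
cohort size), ``validation`` (calibration bins, comparison horizon),
``output`` (paths) and ``seed``.  Unknown keys anywhere are rejected, so
typos fail loudly instead of silently using a default.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigError
from .microsim import SimConfig
from .models import CovariateCategorizer
from .records import DCI_FLOOR, DCI_STEP

__all__ = ["RunConfig", "load_run_config", "DEFAULTS"]

DEFAULTS = {
    "cohort": {
        "n_individuals": 20_000,
        "n_regions": 6,
        "max_followup": 11,
        "annual_censor_prob": 0.02,
    },
    "models": {
        "cut_cci": 7.0,
        "cut_dci": 14.0,
        "cut_age": 100.0,
        "cci_edges": [1.0, 2.0, 3.0],
        "dci_edges": [0.0, 1.0, 3.0],
        "age_edges": [75.0, 85.0],
    },
    "simulation": {
        "n_individuals": 10_000,
        "max_age": 105,
        "start_ages": list(range(65, 91)),
        "start_cci": list(range(0, 11)),
        "start_dci": [round(DCI_FLOOR + DCI_STEP * k, 2)
                      for k in range(58)],
    },
    "validation": {
        "n_bins": 10,
        "horizon": 10,
        "replicates": 5,
    },
    "output": {
        "dir": ".",
    },
    "seed": None,
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {where}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{where} must be a mapping")
            out[key] = _merge(defaults[key], val, where)
        else:
            out[key] = val
    return out


@dataclass
class RunConfig:
    """Validated run configuration (see module docstring for sections)."""

    cohort: dict
    models: dict
    simulation: dict
    validation: dict
    output: dict
    seed: Optional[int]

    def require_seed(self) -> int:
        if self.seed is None:
            raise ConfigError(
                "a seed is mandatory for simulation commands; set it in "
                "the config file or with --seed")
        return int(self.seed)

    def categorizer(self) -> CovariateCategorizer:
        m = self.models
        return CovariateCategorizer(
            cci_edges=tuple(m["cci_edges"]),
            dci_edges=tuple(m["dci_edges"]),
            age_edges=tuple(m["age_edges"]))

    def sim_config(self, seed: Optional[int] = None,
                   n_individuals: Optional[int] = None,
                   start_ages=None, start_cci=None,
                   start_dci=None) -> SimConfig:
        s = self.simulation
        return SimConfig(
            n_individuals=int(n_individuals or s["n_individuals"]),
            max_age=int(s["max_age"]),
            start_ages=tuple(start_ages if start_ages is not None
                             else s["start_ages"]),
            start_cci=tuple(start_cci if start_cci is not None
                            else s["start_cci"]),
            start_dci=tuple(start_dci if start_dci is not None
                            else s["start_dci"]),
            seed=int(seed if seed is not None else self.require_seed()))


def load_run_config(path: Optional[str] = None,
                    overrides: Optional[dict] = None) -> RunConfig:
    """Load a YAML run configuration, applying defaults and overrides."""
    doc = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: configuration must be a mapping")
    merged = _merge(DEFAULTS, doc)
    if overrides:
        merged = _merge(merged, overrides)
    if merged["seed"] is not None and not float(
            merged["seed"]).is_integer():
        raise ConfigError("seed must be an integer")
    cfg = RunConfig(**merged)
    c = cfg.cohort
    if c["n_individuals"] < 1 or c["max_followup"] < 1:
        raise ConfigError("cohort sizes must be positive")
    if not 0 <= c["annual_censor_prob"] <= 1:
        raise ConfigError("annual_censor_prob must be a probability")
    if not np.all(np.diff(cfg.models["cci_edges"]) > 0):
        raise ConfigError("cci_edges must be strictly increasing")
    return cfg
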