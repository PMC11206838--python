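"""Pipeline configuration: one YAML file with per-stage blocks.

Unknown keys are rejected early so typos do not silently fall back to
defaults.  Every output directory gets a ``run_info.json`` embedding the
effective config hash and the seed.
"""

from __future__ import annotations

import copy
import hashlib
import json
from typing import Mapping, Optional

import yaml

DEFAULT_CONFIG = {
    "seed": 0,
    "log_level": "INFO",
    "synthetic": {
        "n_per_group": 20,
        "trials_per_level": 8,
        "levels": [1, 2, 3, 4],
        "noise_sd": 0.02,
        "tonic": 0.0,
        "step_prob": 0.0,
        "raw_emg": False,
        "gain_cv": 0.2,
    },
    "preprocess": {
        "band_hz": [10.0, 450.0],
        "lowpass_hz": 40.0,
        "sg_order": 5,
        "sg_window": 11,
        "analysis_rate_hz": 100.0,
        "window_s": [-0.6, 1.5],
        "resmooth_com": False,  # upstream 6 Hz smoothing toggle; off by default
    },
    "bins": {
        "emg_edges": [[0.0, 0.150], [0.150, 0.250], [0.250, 0.400]],
        "kin_edges": [[0.0, 0.050], [0.050, 0.150], [0.150, 0.300]],
    },
    "cci": {
        "window_short": [0.0, 0.400],
        "window_long": [-0.5, 1.5],
    },
    "model": {
        "tau_s": 0.100,
        "gain_bounds": [0.0, 10.0],
        "penalty_weight": 1.0e-4,
        "stiction_threshold_deg": 0.5,
        "fit_window_s": [-0.5, 1.5],
        "gof_window_s": [0.0, 1.5],
        "n_starts": 8,
        "per_trial_fit": False,
    },
    "stats": {
        "alpha": 0.05,
        # family name -> effect tested; family membership is per outcome type
        "families": {
            "emg_bin": "interaction",
            "kin_bin": "interaction",
            "cci": "group",
            "gain": "group",
            "improvement": "group",
            "gof": "group",
        },
    },
    "paths": {
        "data_dir": "data",
        "results_dir": "results",
    },
}


def _merge(base: dict, override: Mapping, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown config key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(val, Mapping):
                raise TypeError(f"config key {here} must be a mapping")
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: Optional[str] = None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, doc)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_run_info(path: str, cfg: dict, seed: int) -> None:
    with open(path, "w") as fh:
        json.dump({"config_hash": config_hash(cfg), "seed": seed, "config": cfg},
                  fh, indent=2, default=str)
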