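"""Structured configuration with pipeline defaults.

Every stage hyperparameter is exposed; a YAML file passed via the CLI's
``--config`` deep-merges over these defaults.
"""

from __future__ import annotations

import copy

import yaml

from .errors import ConfigError

DEFAULTS: dict = {
    "simulate": {
        "n_farms": 300,
        "n_instruments": 4,
        "date_start": "2018-01-01",
        "date_end": "2018-12-31",
        "monthly_volume": 5000,
        "atypical_prevalence": 0.001,
        "noise_sd": 6e-5,
        "n_latent_factors": 8,
        "fringe_amp_factor": 80.0,
    },
    "preprocess": {
        "bands": [[925, 1600], [1690, 1900], [2700, 2971]],
        "derivative": {"method": "finite_difference", "window": 7},
    },
    "screen": {
        "n_components": 16,
        "trim_fraction": 0.001,
        "n_iterations": 2,
        "freezing_point_lower_pct": 1.0,
        "freezing_point_upper_pct": 99.0,
        "prevalence": 0.001,
    },
    "cluster": {
        "n_components": 24,
        "k": 11,
        "k_min": 4,
        "k_max": 20,
        "n_init": 50,
        "merge_pairs": [],
        "train_fraction": 0.75,
    },
    "classify": {
        "cv_folds": 5,
        "c_grid": [0.1, 1.0, 10.0, 100.0],
        "gamma_factors": [0.1, 1.0, 10.0],
        "density_gate_pct": None,
    },
    "report": {
        "temporal_normalization": "max",  # or "sum"
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path=None) -> dict:
    """Defaults, optionally deep-merged with a YAML file."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path, "r", encoding="utf-8") as fh:
        loaded = yaml.safe_load(fh) or {}
    if not isinstance(loaded, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    unknown = set(loaded) - set(DEFAULTS)
    if unknown:
        raise ConfigError(f"{path}: unknown config section(s): {sorted(unknown)}")
    return _deep_merge(DEFAULTS, loaded)
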