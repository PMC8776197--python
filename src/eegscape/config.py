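"""Structured pipeline configuration.

A single YAML file drives every stage.  Unknown keys are rejected so typos
surface as configuration errors, and all defaults are materialized into the
resolved config that each run echoes to its output directory — every
study constant (250 Hz target rate, 0.5-70 Hz filter, 2 s windows, k=5,
500 trees, linear kernel, band edges) is therefore a visible diff when
changed.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from eegscape.errors import ConfigurationError
from eegscape.montage import Montage, default_montage, validate


DEFAULT_CONFIG: dict = {
    "synthetic_eeg": {
        "n_subjects": 20,
        "base_seed": 0,
        "rate_hz": 500.0,
        "effect_size": 1.0,
        "asymmetry": 0.1,
        "gain_jitter": 0.1,
        "band_rms_uv": {"delta": 5.0, "theta": 4.0, "alpha": 6.0, "beta": 3.0, "gamma": 2.0},
        "schedule": {"block_duration_s": 40.0, "rest_duration_s": 60.0, "lead_in_s": 5.0},
        "noise": {
            "alpha": 1.0,
            "background_power_uv2": 64.0,
            "line_freq_hz": 50.0,
            "line_amp_uv": 2.0,
            "blink_rate_per_min": 10.0,
            "blink_amp_uv": 150.0,
            "blink_duration_s": 0.4,
        },
    },
    "montage": "default",
    "preprocess": {
        "lo_hz": 0.5,
        "hi_hz": 70.0,
        "reject_uv": 100.0,
        "artifact_method": "ica",
    },
    "features": {
        "bands": {"delta": [1.0, 4.0], "theta": [4.0, 8.0], "alpha": [8.0, 13.0],
                  "beta": [13.0, 30.0], "gamma": [30.0, 70.0]},
        "de_backend": "projection",
    },
    "classify": {
        "classifiers": ["bp", "knn", "rf", "svm"],
        "families": None,   # None = all six
        "bands": None,      # None = five bands + total
        "protocol": "cv10",
        "seed": 0,
        "knn_k": 5,
        "rf_trees": 500,
        "svm_kernel": "linear",
        "svm_C": 1.0,
        "bp_hidden": 64,
        "bp_max_iter": 500,
    },
    "io": {
        "edf": True,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigurationError(f"unknown config key: {here}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = copy.deepcopy(val)
    return out


def resolve_config(user: dict | None = None) -> dict:
    """Merge a user mapping over the defaults, rejecting unknown keys."""
    return _merge(DEFAULT_CONFIG, user or {})


def load_config(path=None) -> dict:
    """Load and resolve a YAML config file (or the pure defaults when None)."""
    if path is None:
        return resolve_config()
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    user = yaml.safe_load(path.read_text()) or {}
    if not isinstance(user, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(user).__name__}")
    return resolve_config(user)


def dump_config(cfg: dict, path) -> Path:
    """Write the fully resolved config snapshot next to a run's outputs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return path


def montage_from_config(cfg: dict) -> Montage:
    """Build (and validate) the montage named by the config.

    ``montage: default`` selects the packaged 32-channel cap; a mapping with
    electrodes/coords/reference_labels/feature_channels/lr_pairs/fp_pairs
    builds a custom one, validated on load.
    """
    spec = cfg.get("montage", "default")
    if spec == "default":
        return default_montage()
    if not isinstance(spec, dict):
        raise ConfigurationError("montage must be 'default' or a mapping")
    try:
        m = Montage(
            electrodes=tuple(spec["electrodes"]),
            coords={k: tuple(v) for k, v in spec["coords"].items()},
            reference_labels=tuple(spec["reference_labels"]),
            feature_channels=tuple(spec["feature_channels"]),
            lr_pairs=tuple(tuple(p) for p in spec["lr_pairs"]),
            fp_pairs=tuple(tuple(p) for p in spec["fp_pairs"]),
        )
    except KeyError as e:
        raise ConfigurationError(f"montage config missing key {e}")
    problems = validate(m)
    if problems:
        raise ConfigurationError("invalid montage: " + "; ".join(problems))
    return m
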