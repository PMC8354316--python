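"""YAML pipeline configuration with study defaults and dotted overrides.

Every constant of the emulated study is a default here, never hard-coded
downstream: 50 Hz notch, 0.1 Hz high-pass, 400 μV artifact gate, 500 ms
windows at 250 ms steps, the five canonical bands, C3/Cz/C4 alpha
synchrony scaled ×100, and Bonferroni families of 8 (group) and 2
(individual) tests at family-wise α = 0.05.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Optional

import yaml

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "outdir": "eegsync_out",
    "log_level": "INFO",
    "simulate": {
        "n_subjects": 30,
        "n_stimuli": 24,
        "duration_s": 24.0,
        "fs": 256.0,
        "artifact_rate": 0.5,
        "beta0": 0.5,
        "beta_synch": 0.02,
        "beta_single": 0.75,
        "noise_sd": 0.3,
    },
    "preprocess": {
        "notch_hz": 50.0,
        "highpass_hz": 0.1,
        "artifact_uv": 400.0,
        "filter_order": 4,
        "notch_bandwidth_hz": 2.0,
        "guard_s": 0.25,
    },
    "spectral": {
        "window_s": 0.5,
        "step_s": 0.25,
    },
    "synchrony": {
        "electrodes": ["C3", "Cz", "C4"],
        "band": "alpha",
        "half_width_frames": 2,
        "scale": 100.0,
        "smooth_frames": 0,
    },
    "group": {
        "alpha_family": 0.05,
        "m_tests": 8,
        "normality_alpha": 0.05,
        "outlier_sd": 3.0,
        "diagnostic_alpha": 0.05,
    },
    "individual": {
        "alpha_family": 0.05,
        "m_tests": 2,
        "family": "linear",
        "logistic_cut": 4.0,
    },
}


def _deep_update(base: dict, extra: dict) -> dict:
    for key, val in extra.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], val)
        else:
            base[key] = val
    return base


def _coerce(text: str) -> Any:
    return yaml.safe_load(text)


def load_config(
    path: Optional[str] = None, overrides: Optional[list[str]] = None
) -> dict:
    """Merge defaults ← YAML file ← ``key.path=value`` overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a mapping")
        _deep_update(cfg, loaded)
    for item in overrides or []:
        if "=" not in item:
            raise ValueError(f"override {item!r} is not key=value")
        key, _, raw = item.partition("=")
        node = cfg
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = _coerce(raw)
    return cfg
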