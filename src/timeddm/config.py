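"""Run configuration: YAML loading, validation, and seed fan-out."""

from __future__ import annotations

import copy
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "load_config", "stage_seed", "DEFAULTS"]

DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "results",
    "log_level": "INFO",
    "stages": ["synth", "behavior", "ddm", "ephys", "decode"],
    "ddm": {
        "F": 1.0, "b": 0.52, "D": 0.135, "sigma": 0.052,
        "dt": 0.1, "t_max": 25.0, "n_sims": 500, "n_repeats": 10,
    },
    "grid": {
        "D_min": 0.05, "D_max": 0.25, "D_step": 0.002,
        "sigma_min": 0.02, "sigma_max": 0.10, "sigma_step": 0.002,
    },
    "synth": {
        "n_trials": 100, "gamma_shape": 6.08, "gamma_rate": 0.69,
        "p_long": 0.5, "n_units": 16, "n_ensemble_trials": 40,
    },
    "peth": {
        "window": [-4.0, 22.0], "bin_width": 0.2, "bandwidth": 1.0,
        "zscore": True, "analysis_interval": [0.0, 6.0],
    },
    "decoder": {
        "bin_width_s": 0.5, "window": [-6.0, 24.0],
        "min_trials_per_unit": 20, "rate_floor": 0.1,
    },
    "readout": {
        "kernel_w": 1.0, "grid_step": 0.1, "threshold": 0.5,
        "accuracy_window": 1.0, "ridge_c": 100.0, "horizon": 18.0,
    },
}


@dataclass
class RunConfig:
    """Validated configuration with defaults filled in."""

    data: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @property
    def out_dir(self) -> Path:
        return Path(self.data["out_dir"])


def _check_unknown(user: dict, ref: dict, prefix: str,
                   errors: list[str]) -> None:
    for key, val in user.items():
        path = f"{prefix}.{key}" if prefix else key
        if key not in ref:
            errors.append(f"unknown config key: {path}")
        elif isinstance(ref[key], dict):
            if not isinstance(val, dict):
                errors.append(f"config key {path} must be a mapping")
            else:
                _check_unknown(val, ref[key], path, errors)


def _merge(base: dict, user: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a YAML config, fill defaults, and reject unknown keys.

    All schema violations are reported together, not first-only.
    """
    user: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        loaded = yaml.safe_load(p.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a mapping")
        user = loaded
    if overrides:
        user = _merge(user, overrides)
    errors: list[str] = []
    _check_unknown(user, DEFAULTS, "", errors)
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(_merge(DEFAULTS, user))


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic child seed for a named pipeline stage.

    Uses a CRC of the stage name with the root seed so stage seeds are
    independent of execution order, and stay below 2**31.
    """
    tag = zlib.crc32(stage.encode())
    return int(np.random.SeedSequence([root_seed, tag]).generate_state(1)[0]
               % (2 ** 31))
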