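"""Run configuration: YAML loading, validation and echo.

A configuration file is a flat YAML mapping; every key has a documented
default (the standard simulation values of the model) and a validated
range.  Unknown keys are rejected so typos fail loudly.  Angles in the
config are degrees except ``sigma_i`` (radians, default 10*pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .dynamics import NetworkParams
from .kernel import KernelParams, SIGMA_E_BROAD_DEG, SIGMA_E_NARROW_DEG, SIGMA_I_RAD
from .stimulus import StimulusSpec


class ConfigError(ValueError):
    pass


#: key -> (default, lower bound, upper bound); None bound = unbounded.
_SCHEMA = {
    "n": (404, 8, 100_000),
    "mu": (16.0, 1e-9, None),
    "th": (3.0, 1e-9, None),
    "kappa_i": (0.1, 0.0, None),
    "tau_p": (1.0, 1e-9, None),
    "tau_l": (100.0, 1e-9, None),
    "noise_eps": (0.01, 0.0, None),
    "dt": (0.1, 1e-6, None),
    "ic_amp": (0.1, 0.0, None),
    "alpha": (0.0, 0.0, 1.0),
    "beta": (-10.0, -10.0, 15.0),
    "sigma_e_a": (SIGMA_E_NARROW_DEG, 1e-6, None),
    "sigma_e_b": (SIGMA_E_BROAD_DEG, 1e-6, None),
    "sigma_i": (SIGMA_I_RAD, 2 * np.pi, None),
    "ps": (120.0, 0.0, 180.0),
    "pw": (10.0, 1.0, 90.0),
    "pw_rds": (10.0, 1.0, 90.0),
    "pw_plaid": (25.0, 1.0, 90.0),
    "rel_strength": (1.0, 0.0, 1.0),
    "g_i_low": (0.0, None, None),
    "onset": (0.0, 0.0, None),
    "tol_ss": (1e-9, 0.0, None),
    "t_max": (2000.0, 0.0, None),
    "tol_dir": (20.0, 0.0, 90.0),
    "sb_frac": (0.1, 0.0, 1.0),
    "min_height_frac": (0.1, 0.0, 1.0),
    "min_prominence_frac": (0.05, 0.0, 1.0),
    "binarization_threshold": (0.5, 0.0, 1.0),
    "n_trials": (100, 1, None),
    "seed": (0, 0, 2**31 - 1),
    "area_normalized_input": (False, None, None),
    "out_dir": ("runs", None, None),
}


@dataclass(frozen=True)
class RunConfig:
    """Validated flat configuration with all model defaults."""

    values: dict = field(default_factory=dict)

    def __getattr__(self, key):
        try:
            return self.values[key]
        except KeyError:
            raise AttributeError(key)

    def network_params(self, **overrides) -> NetworkParams:
        kw = dict(mu=self.values["mu"], th=self.values["th"],
                  kappa_i=self.values["kappa_i"], tau_p=self.values["tau_p"],
                  noise_eps=self.values["noise_eps"], dt=self.values["dt"],
                  ic_amp=self.values["ic_amp"])
        kw.update(overrides)
        return NetworkParams(**kw)

    def kernel_params(self, **overrides) -> KernelParams:
        kw = dict(alpha=self.values["alpha"], beta=self.values["beta"],
                  sigma_e_a=self.values["sigma_e_a"],
                  sigma_e_b=self.values["sigma_e_b"],
                  sigma_i=self.values["sigma_i"])
        kw.update(overrides)
        return KernelParams(**kw)

    def stimulus_spec(self, **overrides) -> StimulusSpec:
        kw = dict(ps=self.values["ps"], pw=self.values["pw"],
                  rel_strength=self.values["rel_strength"],
                  area_normalized=self.values["area_normalized_input"])
        kw.update(overrides)
        return StimulusSpec(**kw)

    def echo(self, path) -> None:
        """Write the effective configuration next to the outputs."""
        Path(path).write_text(yaml.safe_dump(self.values, sort_keys=True))


def _validate(key: str, value):
    default, lo, hi = _SCHEMA[key]
    if isinstance(default, bool):
        if not isinstance(value, bool):
            raise ConfigError(f"config key {key!r} must be a boolean")
        return value
    if isinstance(default, int) and not isinstance(default, bool):
        if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
            raise ConfigError(f"config key {key!r} must be an integer")
    if isinstance(default, (int, float)) and isinstance(value, (int, float)):
        if lo is not None and value < lo:
            raise ConfigError(f"config key {key!r} = {value} below minimum {lo}")
        if hi is not None and value > hi:
            raise ConfigError(f"config key {key!r} = {value} above maximum {hi}")
        return type(default)(value) if not isinstance(default, str) else value
    if isinstance(default, str):
        return str(value)
    raise ConfigError(f"config key {key!r} has invalid value {value!r}")


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None,
                ) -> RunConfig:
    """Load a YAML config; missing keys fall back to the documented defaults.

    An empty (or absent) file yields all defaults.  Unknown keys and values
    outside their documented ranges raise :class:`ConfigError` naming the
    key.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        raw.update(loaded)
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    values = {k: default for k, (default, _, _) in _SCHEMA.items()}
    for k, v in raw.items():
        values[k] = _validate(k, v)
    return RunConfig(values=values)
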