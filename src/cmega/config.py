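"""Run configuration: flat key/value config files plus programmatic overrides.

A config file is a flat YAML mapping.  Keys that name :class:`RunConfig`
fields set those fields; any other key is passed through as a model rate
parameter (and validated by the model builder).  Command-line flags
override file values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Tuple

import yaml

from .networks import build_griffith, build_switch

METHODS = ("ga", "cmega", "oracle-check")
MODELS = ("switch", "griffith")


@dataclass
class RunConfig:
    model: str = "switch"
    method: str = "ga"
    params: Dict[str, float] = field(default_factory=dict)
    d: int = 10
    t_final: float = 500.0
    ensemble: int = 1
    record_dt: float = 5.0
    histogram_times: Tuple[float, ...] = ()
    seed: int = 0
    eps: float = 1e-3
    inverse_moment: str = "series"
    out_dir: str = "cmega-out"

    def validate(self) -> "RunConfig":
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r} (expected {MODELS})")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r} (expected {METHODS})")
        if not self.t_final > 0:
            raise ValueError("t_final must be positive")
        if self.ensemble < 1:
            raise ValueError("ensemble size must be >= 1")
        if not self.eps > 0:
            raise ValueError("eps must be positive")
        if not self.record_dt > 0:
            raise ValueError("record_dt must be positive")
        if self.inverse_moment not in ("exact", "series"):
            raise ValueError("inverse_moment must be 'exact' or 'series'")
        if self.d < 2:
            raise ValueError("d must be >= 2")
        self.build_network()  # validates the rate parameters
        return self

    def build_network(self):
        if self.model == "switch":
            return build_switch(self.params)
        return build_griffith(self.params, d=self.d)


_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def parse_config(path=None, overrides: Dict | None = None) -> RunConfig:
    """Build a validated RunConfig from an optional file plus overrides.

    Model defaults are those of the built-in models; the file and then the
    overrides refine them.  Unknown model parameters are rejected by the
    model builders with a descriptive error.
    """
    data: Dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must be a flat key: value mapping")
        data.update(loaded)
    for key, value in (overrides or {}).items():
        if value is not None:
            data[key] = value
    cfg = RunConfig()
    params: Dict[str, float] = {}
    for key, value in data.items():
        if key == "params":
            params.update(value)
        elif key in _FIELDS:
            current = getattr(cfg, key)
            if key == "histogram_times":
                value = tuple(float(v) for v in value)
            elif isinstance(current, int) and not isinstance(value, bool):
                value = int(value)
            elif isinstance(current, float):
                value = float(value)
            setattr(cfg, key, value)
        else:
            params[key] = float(value)
    cfg.params.update(params)
    return cfg.validate()
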