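"""Run configuration: YAML schema, validation, serialization.

A config file supplies any subset of the benchmark parameters (omitted
fields default to the benchmark values) plus output options.  Values
outside the benchmark's +-50% sensitivity ranges are accepted with a
warning, since the model is only characterized there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import ModelParams
from .sensitivity import DEFAULT_DELTAS
from .simulation import DEFAULT_SNAPSHOT_TIMES

#: keys accepted at the top level of a config file
_PARAM_KEYS = {
    "n_agents",
    "n_steps",
    "turning_point",
    "sigmoid_steepness",
    "influence_rate",
    "reward_rate",
    "mimicry_window",
}
_OTHER_KEYS = {"outputs", "snapshot_times", "thresholds", "master_seed", "report_format"}

#: offending-curve thresholds spanning the inter-group gap
DEFAULT_THRESHOLDS = (0.5, 0.6, 0.7)

REPORT_FORMATS = ("tabular", "structured-text")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one CLI invocation."""

    params: ModelParams = field(default_factory=ModelParams)
    outputs: str = "peercourse-output"
    snapshot_times: tuple = DEFAULT_SNAPSHOT_TIMES
    thresholds: tuple = DEFAULT_THRESHOLDS
    master_seed: int = 0
    report_format: str = "tabular"

    def __post_init__(self) -> None:
        if self.report_format not in REPORT_FORMATS:
            raise ValueError(
                f"report_format must be one of {REPORT_FORMATS}, "
                f"got {self.report_format!r}"
            )
        for t in self.snapshot_times:
            if not 0 <= t <= self.params.n_steps:
                raise ValueError(f"snapshot time {t} outside [0, T]")
        for th in self.thresholds:
            if not 0 < th <= 1:
                raise ValueError(f"threshold {th} outside (0, 1]")
        _warn_outside_benchmark(self.params)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self.params, k)
            for k in sorted(_PARAM_KEYS)
        }
        d.update(
            outputs=self.outputs,
            snapshot_times=list(self.snapshot_times),
            thresholds=list(self.thresholds),
            master_seed=self.master_seed,
            report_format=self.report_format,
        )
        return d

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _warn_outside_benchmark(params: ModelParams) -> None:
    """Warn (never error) when a parameter leaves its studied range."""
    benchmark = ModelParams()
    for name, delta in DEFAULT_DELTAS.items():
        value = getattr(params, name)
        lo = getattr(benchmark, name) - delta
        hi = getattr(benchmark, name) + delta
        if not lo <= value <= hi:
            warnings.warn(
                f"{name}={value} is outside the studied range "
                f"[{lo}, {hi}]; model behavior there is uncharacterized",
                UserWarning,
                stacklevel=3,
            )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; omitted fields get benchmark defaults."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _PARAM_KEYS - _OTHER_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    param_kwargs = {}
    for k in _PARAM_KEYS & set(raw):
        v = raw[k]
        if isinstance(v, bool) or not isinstance(v, (int, float)):
            raise ValueError(f"config key {k} must be numeric, got {v!r}")
        param_kwargs[k] = v
    master_seed = raw.get("master_seed", 0)
    if not isinstance(master_seed, int):
        raise ValueError(f"master_seed must be an integer, got {master_seed!r}")
    params = ModelParams(seed=master_seed, **param_kwargs)
    if "snapshot_times" in raw:
        snapshot_times = tuple(raw["snapshot_times"])
    else:  # default snapshot schedule, clipped to a shorter horizon
        snapshot_times = tuple(
            t for t in DEFAULT_SNAPSHOT_TIMES if t <= params.n_steps
        )
    return RunConfig(
        params=params,
        outputs=str(raw.get("outputs", "peercourse-output")),
        snapshot_times=snapshot_times,
        thresholds=tuple(raw.get("thresholds", DEFAULT_THRESHOLDS)),
        master_seed=master_seed,
        report_format=str(raw.get("report_format", "tabular")),
    )
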