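"""Run configuration: analysis windows, thresholds, permutation counts.

A ``RunConfig`` collects every knob the analysis pipeline honours and can
round-trip through YAML (the ``analyze`` CLI's ``--config``).  Validation
happens at construction, before any computation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Analysis settings.

    Windows are (start, end) offsets in seconds relative to tone onset,
    half-open.  ``rate_floor`` replaces smaller rates before logs or
    divisions; ``min_trials`` is the per-condition inclusion threshold for
    ratio and false-alarm analyses.
    """

    alpha: float = 0.05
    n_perm: int = 1000
    rate_floor: float = 0.1
    min_trials: int = 5
    during_spike_window: tuple[float, float] = (0.0, 0.250)
    before_spike_window: tuple[float, float] = (-0.250, 0.0)
    during_lfp_window: tuple[float, float] = (0.0, 0.500)
    before_lfp_window: tuple[float, float] = (-0.500, 0.0)
    bin_width: float = 0.010
    min_units_for_trace_test: int = 6
    lfp_per_trial_rms: bool = False
    frequencies: tuple[float, float] = (3000.0, 1000.0)
    require_responsive: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.n_perm < 100:
            raise ConfigError("n_perm must be >= 100")
        if self.rate_floor <= 0:
            raise ConfigError("rate_floor must be > 0")
        if self.min_trials < 2:
            raise ConfigError("min_trials must be >= 2")
        for name in ("during_spike_window", "before_spike_window",
                     "during_lfp_window", "before_lfp_window"):
            w0, w1 = getattr(self, name)
            if w1 <= w0:
                raise ConfigError(f"{name} must have positive length")
            setattr(self, name, (float(w0), float(w1)))
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be > 0")
        self.frequencies = tuple(float(f) for f in self.frequencies)

    def to_dict(self) -> dict:
        out = asdict(self)
        for key, value in out.items():
            if isinstance(value, tuple):
                out[key] = list(value)
        return out

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        for key in ("during_spike_window", "before_spike_window",
                    "during_lfp_window", "before_lfp_window", "frequencies"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        unknown = set(kwargs) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("run config YAML must be a mapping")
        return cls.from_dict(data)
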