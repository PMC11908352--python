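"""Run configuration for the command-line pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .piv import PivConfig
from .tfm import ElasticSubstrate


@dataclass
class RunConfig:
    """Validated settings for the analysis chains.

    Defaults mirror the standard acquisition/analysis settings:
    velocity profiles smoothed over 5 consecutive frames and fitted up to
    1.07x the peak position; spreading rates over the first 24 h gated at
    a 20% excess over the initial projection; 15 kPa incompressible
    substrate for traction reconstruction.
    """

    piv: PivConfig = field(default_factory=PivConfig)
    substrate: ElasticSubstrate = field(default_factory=ElasticSubstrate)
    window_factor: float = 1.07
    smoothing_window: int = 5
    profile_bin_width: float | None = None
    t_max_h: float = 24.0
    area_gate: float = 0.20
    tfm_lambda: float | str = 0.0       # a value, or "lcurve"
    tfm_grid_n: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_factor <= 0:
            raise ValueError("window_factor must be positive")
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")
        if self.t_max_h <= 0:
            raise ValueError("t_max_h must be positive")
        if not 0 <= self.area_gate:
            raise ValueError("area_gate must be nonnegative")
        if isinstance(self.tfm_lambda, str) and self.tfm_lambda != "lcurve":
            raise ValueError("tfm_lambda must be a number or 'lcurve'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        piv = PivConfig(**raw.pop("piv", {}))
        substrate = ElasticSubstrate(**raw.pop("substrate", {}))
        return cls(piv=piv, substrate=substrate, **raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
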