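"""Run configuration: every tunable of the pipeline in one tree.

Loadable from a TOML file with ``[spectral]``, ``[tremor]``,
``[posture]``, ``[brady]``, ``[dyskinesia]``, ``[wear]`` and
``[states]`` sections (nested ``[*.intensity]`` tables for the
intensity-map anchors).  Values not present fall back to the package
defaults, which were calibrated once against the synthetic generator
(``wristpd calibrate``).
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .detectors import (
    BradyConfig,
    DyskinesiaConfig,
    IntensityMap,
    PostureConfig,
    TremorConfig,
    WearConfig,
)
from .recording_io import ValidationError
from .spectral import SpectralConfig
from .states import StatesConfig

__all__ = ["PipelineConfig", "load_config"]

_SECTIONS = {
    "spectral": SpectralConfig,
    "tremor": TremorConfig,
    "posture": PostureConfig,
    "brady": BradyConfig,
    "dyskinesia": DyskinesiaConfig,
    "wear": WearConfig,
    "states": StatesConfig,
}


@dataclass
class PipelineConfig:
    epoch_s: float = 5.0
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    tremor: TremorConfig = field(default_factory=TremorConfig)
    posture: PostureConfig = field(default_factory=PostureConfig)
    brady: BradyConfig = field(default_factory=BradyConfig)
    dyskinesia: DyskinesiaConfig = field(default_factory=DyskinesiaConfig)
    wear: WearConfig = field(default_factory=WearConfig)
    states: StatesConfig = field(default_factory=StatesConfig)

    def validate(self) -> None:
        if self.epoch_s <= 0:
            raise ValidationError("epoch_s must be positive")
        self.spectral.validate()
        self.states.validate()
        for name, band in (
            ("tremor.band", self.tremor.band),
            ("tremor.search_band", self.tremor.search_band),
            ("brady.band", self.brady.band),
            ("dyskinesia.band_low", self.dyskinesia.band_low),
            ("dyskinesia.band_high", self.dyskinesia.band_high),
            ("dyskinesia.intensity_band", self.dyskinesia.intensity_band),
        ):
            lo, hi = band
            if not 0 <= lo < hi <= 25.0:
                raise ValidationError(
                    f"{name} must satisfy 0 <= lo < hi <= 25 Hz, got {band}"
                )
        if not 0 <= self.dyskinesia.majority_q <= 1:
            raise ValidationError("dyskinesia.majority_q must be in [0, 1]")
        if self.brady.theta_low >= self.brady.theta_high:
            raise ValidationError("brady thresholds misordered")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        def conv(obj):
            if isinstance(obj, IntensityMap):
                return dataclasses.asdict(obj)
            if dataclasses.is_dataclass(obj):
                return {
                    f.name: conv(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        out = {"epoch_s": self.epoch_s}
        for name in _SECTIONS:
            out[name] = conv(getattr(self, name))
        return out

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = {}
        if "epoch_s" in data:
            kwargs["epoch_s"] = float(data["epoch_s"])
        for name, section_cls in _SECTIONS.items():
            if name not in data:
                continue
            section = dict(data[name])
            for f in dataclasses.fields(section_cls):
                if f.name not in section:
                    continue
                v = section[f.name]
                if isinstance(v, dict):  # an intensity map
                    section[f.name] = IntensityMap(**v)
                elif isinstance(v, list):
                    section[f.name] = tuple(v)
            kwargs[name] = section_cls(**section)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a TOML run configuration (``None`` → package defaults)."""
    if path is None:
        cfg = PipelineConfig()
        cfg.validate()
        return cfg
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return PipelineConfig.from_dict(data)
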