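"""Pipeline configuration with the study's default constants.

Every threshold and constant of the analysis has its standard default
here (circularity 0.68, SDCH 0.3 nm, elliptic Fourier order 8, shrink
0.65, tip 0.5 nm / 5 degrees, low-pass cutoff 3 nm, 10 fps), and the
whole configuration round-trips losslessly through YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PreprocessingConfig:
    flatten: bool = True
    lowpass_cutoff_nm: float = 3.0


@dataclass
class ThresholdConfig:
    circularity: float = 0.68
    sdch_nm: float = 0.3


@dataclass
class SdchConfig:
    shrink: float = 0.65
    n_samples: int = 64


@dataclass
class DespikeConfig:
    k_mad: float = 6.0
    jump_nm: float = 0.4


@dataclass
class TipConfig:
    radius_nm: float = 0.5
    half_angle_deg: float = 5.0


@dataclass
class GeneratorConfig:
    pixel_nm: float = 0.5
    size_px: int = 128
    noise_sd: float = 0.1
    frame_rate: float = 10.0


@dataclass
class HistogramConfig:
    circularity_bin: float = 0.02
    sdch_bin_nm: float = 0.05


@dataclass
class PipelineConfig:
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    sdch: SdchConfig = field(default_factory=SdchConfig)
    despike: DespikeConfig = field(default_factory=DespikeConfig)
    tip: TipConfig = field(default_factory=TipConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    histograms: HistogramConfig = field(default_factory=HistogramConfig)
    efd_order: int = 8
    seed: int = 0
    outdir: str = "afmring_out"

    _SECTIONS = {
        "preprocessing": PreprocessingConfig,
        "thresholds": ThresholdConfig,
        "sdch": SdchConfig,
        "despike": DespikeConfig,
        "tip": TipConfig,
        "generator": GeneratorConfig,
        "histograms": HistogramConfig,
    }

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = {}
        valid = {f.name for f in fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key, value in data.items():
            if key in cls._SECTIONS:
                sect = cls._SECTIONS[key]
                names = {f.name for f in fields(sect)}
                bad = set(value) - names
                if bad:
                    raise ValueError(f"unknown key(s) {sorted(bad)} in section {key!r}")
                kwargs[key] = sect(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def digest(self) -> str:
        """Short stable hash of the full configuration, for provenance logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
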