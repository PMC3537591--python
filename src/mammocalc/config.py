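"""Layered pipeline configuration (defaults < file < flags).

Every tunable decision elsewhere in the package surfaces here as a named
key so whole experiments are declarative and reproducible from one file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detection import DetectionConfig
from .errors import ConfigError
from .synthetic import BackgroundParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunables of the pipeline with their defaults."""

    # synthetic dataset
    seed: int = 0
    roi_size: int = 128
    n_normal: int = 25
    n_abnormal: int = 25
    benign_fraction: float = 0.5
    background_mean: float = 120.0
    background_low_amplitude: float = 80.0
    background_mid_amplitude: float = 15.0
    background_noise_sigma: float = 4.0

    # detection
    edge_percentile: float = 97.0
    wavelet_method: str = "percentile"
    wavelet_percentile: float = 98.5
    dwt_wavelet: str = "db4"
    dwt_levels: int = 4
    zero_levels: tuple[int, ...] = (1, 4)
    zero_approx: bool = True
    min_spot_px: int = 2

    # features
    glcm_levels: int = 16
    glcm_distance: int = 1
    dtcwt_levels: int = 2
    first_stage_wavelet: str = "bior4.4"

    # classification
    pca_components: int = 4
    stage1_degree: int = 2
    stage2_degree: int = 3
    svm_C: float = 1.0
    svm_on_comprehensive: bool = False

    # evaluation
    match_tolerance_px: float = 5.0
    froc_sweep: tuple[float, ...] = (99.5, 99.0, 98.5, 98.0, 97.5, 97.0, 96.0)

    # ------------------------------------------------------------------
    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_dict(cls, values: dict) -> "PipelineConfig":
        unknown = set(values) - cls.field_names()
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        kwargs = dict(values)
        for key in ("zero_levels", "froc_sweep"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path, overrides: dict | None = None
                  ) -> "PipelineConfig":
        values = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(values, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        values.update(overrides or {})
        return cls.from_dict(values)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["zero_levels"] = list(self.zero_levels)
        out["froc_sweep"] = list(self.froc_sweep)
        return out

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    # views consumed by the submodules -------------------------------
    def detection_config(self) -> DetectionConfig:
        return DetectionConfig(edge_percentile=self.edge_percentile,
                               wavelet_method=self.wavelet_method,
                               wavelet_percentile=self.wavelet_percentile,
                               dwt_wavelet=self.dwt_wavelet,
                               dwt_levels=self.dwt_levels,
                               zero_levels=tuple(self.zero_levels),
                               zero_approx=self.zero_approx,
                               min_spot_px=self.min_spot_px)

    def background_params(self) -> BackgroundParams:
        return BackgroundParams(mean_level=self.background_mean,
                                low_amplitude=self.background_low_amplitude,
                                mid_amplitude=self.background_mid_amplitude,
                                noise_sigma=self.background_noise_sigma)
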