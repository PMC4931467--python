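"""Pipeline configuration: one flat, human-readable YAML mapping.

Every run resolves a full :class:`PipelineConfig`; its SHA-256 hash is
embedded in all outputs so results can be traced to the exact settings.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunables of the droplet-stress pipeline, with units.

    gamma defaults to the soybean-oil/medium interfacial tension of
    8.4 mN/m; the counting window to 700 um; the image chain to a 10x
    nearest-neighbour upscale with a 512-point snake and a 16-harmonic
    low-pass on 512 resampled contour points.
    """

    pixel_size_um: float = 0.1
    upscale: int = 10
    median_radius_px: int = 1
    snake_alpha: float = 0.015
    snake_beta: float = 10.0
    snake_n_iter: int = 500
    snake_convergence_tol_um: float = 0.01
    snake_smoothing_sigma_px: float = 1.5
    snake_n_points: int = 512
    resample_n: int = 512
    fft_harmonics: int = 16
    contact_window_rad: tuple[float, float] = (0.0, 3.141592653589793)
    gamma_mN_per_m: float = 8.4
    window_um: float = 700.0
    seed: int = 0

    def snake_params(self):
        from .segmentation import SnakeParams

        return SnakeParams(
            alpha=self.snake_alpha,
            beta=self.snake_beta,
            n_iter=self.snake_n_iter,
            convergence_tol_um=self.snake_convergence_tol_um,
            smoothing_sigma_px=self.snake_smoothing_sigma_px,
            n_points=self.snake_n_points,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["contact_window_rad"] = list(d["contact_window_rad"])
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "contact_window_rad" in data:
            data = dict(data)
            data["contact_window_rad"] = tuple(data["contact_window_rad"])
        return cls(**data)

    def sha256(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()
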