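"""Pipeline configuration.

All tunables of the three processing stages live in one flat dataclass so a
single YAML document (or CLI flag set) configures a run.  Defaults are the
values the algorithm was designed with: the shape-index weights
``lambda1 = 0.6`` / ``lambda2 = 0.4``, the 15 % projection-profile cut, and
the 1/20-of-long-side ROI expansion.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class AppConfig:
    """Tunables for the full locate pipeline.

    Attributes
    ----------
    smooth_window : int
        Width (odd) of the centered moving average applied to the gray
        histogram before valley detection.
    min_peak_frac : float
        A histogram local maximum counts as a significant peak when its
        smoothed count is at least this fraction of the total pixel count.
    fallback_quantile : float
        When no valley is found, threshold at the largest gray level whose
        cumulative histogram fraction stays at or below this value.
    projection_frac : float
        Fraction of a projection profile's maximum that delimits its main
        interval.
    expand_divisor : int
        The rough ROI is expanded on each side by ``long_side // divisor``
        pixels.
    opening_radius : int
        Radius (px) of the disc structuring element for morphological
        opening; 0 disables opening.
    min_area : int
        Connected components smaller than this (px) are never pupil
        candidates.
    lambda1, lambda2 : float
        Weights of the inertia-ratio and inverse-fitting-error terms of the
        pupil shape index; must sum to 1.
    sigma_max, z_max : float
        Defocus model: blur sigma grows linearly from 0 to ``sigma_max`` px
        as the defocus distance goes from 0 to ``z_max`` cm.
    log_level : str
        One of debug/info/warning/error.
    """

    smooth_window: int = 5
    min_peak_frac: float = 0.001
    fallback_quantile: float = 0.05
    projection_frac: float = 0.15
    expand_divisor: int = 20
    opening_radius: int = 1
    min_area: int = 15
    lambda1: float = 0.6
    lambda2: float = 0.4
    sigma_max: float = 6.0
    z_max: float = 20.0
    log_level: str = "info"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be a positive odd integer")
        if not 0.0 < self.projection_frac < 1.0:
            raise ValueError("projection_frac must lie in (0, 1)")
        if self.expand_divisor < 1:
            raise ValueError("expand_divisor must be >= 1")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("shape-index weights must be non-negative")
        if abs(self.lambda1 + self.lambda2 - 1.0) > 1e-9:
            raise ValueError("lambda1 + lambda2 must equal 1")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.opening_radius < 0:
            raise ValueError("opening_radius must be >= 0")

    @classmethod
    def load(cls, path: str | Path) -> "AppConfig":
        """Load a config from a flat YAML key/value document."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def replace(self, **kwargs) -> "AppConfig":
        return dataclasses.replace(self, **kwargs)
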