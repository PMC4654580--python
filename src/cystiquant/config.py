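"""Pipeline configuration.

All numeric defaults of the analysis live here: the per-marker IHC
positivity thresholds (mean DAB optical density per nucleus), the marker-area
threshold used for the cytokeratin epithelium measurement, the
lymphoplasmacytic inflammation cutoff (cells/mm^2), the kappa:lambda ratio
bounds defining light-chain restriction, and the light-chain density floor.
Every stage reads its parameters from a :class:`PipelineConfig` so a run is
fully described by one JSON document.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

#: Default IHC positivity threshold (mean DAB OD per nucleus) by marker.
DEFAULT_IHC_THRESHOLDS: dict[str, float] = {
    "CD3": 0.3,
    "CD20": 0.3,
    "CD138": 0.5,
    "kappa": 0.5,
    "lambda": 0.5,
    "cytokeratin": 0.4,
}

#: Default DAB OD threshold for marker-area (epithelium) detection.
DEFAULT_MARKER_AREA_THRESHOLD = 0.4

#: Lymphoplasmacytic density (cells/mm^2) at or above which a specimen is
#: called "inflamed".
DEFAULT_INFLAMMATION_CUTOFF = 200.0

#: kappa:lambda ratio outside (low, high) is an aberrant, clonal pattern.
DEFAULT_RATIO_LOW = 0.7
DEFAULT_RATIO_HIGH = 5.5

#: Minimum total light-chain-positive density (cells/mm^2, strict) for a
#: restriction call to be made.
DEFAULT_DENSITY_FLOOR = 50.0

#: Typical 20x whole-slide scan resolution.
DEFAULT_MICRONS_PER_PIXEL = 0.46

VALID_MARKERS = ("CD3", "CD20", "CD138", "kappa", "lambda", "cytokeratin")


class ConfigError(ValueError):
    """Raised when a pipeline configuration fails validation."""


@dataclass
class PipelineConfig:
    """Validated bundle of thresholds and run parameters.

    Parameters
    ----------
    ihc_thresholds
        Mean-DAB-OD positivity threshold per marker.
    marker_area_threshold
        DAB OD threshold for marker-area (epithelium) detection.
    inflammation_cutoff
        Lymphoplasmacytic density cutoff, cells/mm^2 (inclusive upper class).
    ratio_low, ratio_high
        kappa:lambda bounds; a ratio strictly outside [low, high] is aberrant.
    density_floor
        Strict minimum total light-chain density for a restriction call.
    microns_per_pixel
        Image calibration, um/px.
    seed
        Root seed for all stochastic stages.
    """

    ihc_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IHC_THRESHOLDS)
    )
    marker_area_threshold: float = DEFAULT_MARKER_AREA_THRESHOLD
    inflammation_cutoff: float = DEFAULT_INFLAMMATION_CUTOFF
    ratio_low: float = DEFAULT_RATIO_LOW
    ratio_high: float = DEFAULT_RATIO_HIGH
    density_floor: float = DEFAULT_DENSITY_FLOOR
    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.ihc_thresholds.items():
            if value < 0:
                raise ConfigError(f"IHC threshold for {name} must be >= 0, got {value}")
        for name in ("marker_area_threshold", "inflammation_cutoff",
                     "ratio_low", "ratio_high", "density_floor"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not self.ratio_low < self.ratio_high:
            raise ConfigError(
                f"ratio_low ({self.ratio_low}) must be < ratio_high ({self.ratio_high})"
            )
        if self.microns_per_pixel <= 0:
            raise ConfigError("microns_per_pixel must be > 0")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(d)
        if "ihc_thresholds" in merged:
            thr = dict(DEFAULT_IHC_THRESHOLDS)
            thr.update(merged["ihc_thresholds"])
            merged["ihc_thresholds"] = thr
        return cls(**merged)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
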