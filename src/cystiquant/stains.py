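"""Beer-Lambert color model for brightfield H-DAB slides.

Chromogen amounts on a brightfield slide act multiplicatively on transmitted
light, so the natural working space is optical density,
``OD = -log10(I / I0)``, which is linear in stain concentration.  A pixel's
OD vector is then a non-negative combination of per-stain unit OD vectors
(hematoxylin, DAB, and a residual channel), and unmixing is a 3x3 linear
solve followed by clipping of small negative concentrations.

The hematoxylin and DAB vectors are the standard Ruifrok-Johnston
calibration values used throughout digital pathology; the residual vector
completes an invertible basis via the cross product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Intensity guard added before the log so saturated (0) pixels stay finite.
OD_EPSILON = 1.0

#: White point of an 8-bit brightfield image.
WHITE_LEVEL = 255.0

# Ruifrok & Johnston H-DAB optical-density vectors (unnormalized).
_HEMATOXYLIN = (0.650, 0.704, 0.286)
_DAB = (0.269, 0.568, 0.778)


class StainError(ValueError):
    """Raised for invalid stain matrices."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0:
        raise StainError("zero-length stain vector")
    return v / n


@dataclass(frozen=True)
class StainVectors:
    """Invertible 3x3 matrix of unit OD vectors, rows = stains.

    Row order is (hematoxylin, DAB, residual).
    """

    matrix: np.ndarray

    @classmethod
    def hdab(cls) -> "StainVectors":
        """Standard H-DAB basis with a cross-product residual."""
        h = _unit(np.asarray(_HEMATOXYLIN, dtype=float))
        d = _unit(np.asarray(_DAB, dtype=float))
        r = _unit(np.cross(h, d))
        return cls(matrix=np.vstack([h, d, r]))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise StainError(f"stain matrix must be 3x3, got {m.shape}")
        norms = np.linalg.norm(m, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise StainError("stain vectors must have unit norm")
        if abs(np.linalg.det(m)) < 1e-8:
            raise StainError("stain matrix is singular")
        object.__setattr__(self, "matrix", m)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


def rgb_to_od(pixels: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB raster to per-channel optical density.

    ``OD = -log10((I + eps) / 255)`` with ``eps = 1`` so a fully saturated
    channel maps to a large finite OD rather than infinity.  White
    background maps to OD ~ 0 and OD is monotone decreasing in intensity.
    """
    arr = np.asarray(pixels)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an RGB raster (H, W, 3), got shape {arr.shape}")
    intensity = arr.astype(np.float64)
    od = -np.log10((intensity + OD_EPSILON) / WHITE_LEVEL)
    return np.maximum(od, 0.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`; returns a uint8 raster."""
    intensity = WHITE_LEVEL * np.power(10.0, -np.asarray(od, dtype=np.float64))
    return np.clip(np.rint(intensity - OD_EPSILON), 0, 255).astype(np.uint8)


def separate_stains(od: np.ndarray, vectors: StainVectors | None = None) -> np.ndarray:
    """Unmix an OD raster into per-stain concentration planes.

    Parameters
    ----------
    od
        (H, W, 3) optical-density raster.
    vectors
        Stain basis; the H-DAB default if omitted.

    Returns
    -------
    (H, W, 3) array of concentrations in the order of the stain rows
    (hematoxylin, DAB, residual), with negative solutions clipped to 0.
    """
    if vectors is None:
        vectors = StainVectors.hdab()
    od = np.asarray(od, dtype=np.float64)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError(f"expected an OD raster (H, W, 3), got shape {od.shape}")
    conc = od @ vectors.inverse
    return np.maximum(conc, 0.0)
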