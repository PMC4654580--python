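"""Positive-cell density and marker-area quantification on calibrated slides.

Mirrors the two analyses run on the digitized biopsies:

* **ROI-nuclei**: within a submucosal region of interest, detect nuclei on
  the combined nuclear signal (hematoxylin + DAB), score each nucleus
  positive when its mean DAB optical density reaches the marker's IHC
  threshold, and report the positive-cell density in cells/mm^2.
* **ROI-marker area**: within a whole-specimen mask, measure the area whose
  DAB OD reaches the marker-area threshold, and report it as a percent of
  the specimen area (the epithelium/specimen ratio for cytokeratin).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from cystiquant.config import (
    DEFAULT_IHC_THRESHOLDS,
    DEFAULT_MARKER_AREA_THRESHOLD,
    VALID_MARKERS,
)
from cystiquant.stains import StainVectors, rgb_to_od, separate_stains


class EmptyROIError(ValueError):
    """ROI mask contains no pixels; distinct from 'zero nuclei found'."""


@dataclass(frozen=True)
class SlideImage:
    """Calibrated 8-bit RGB slide raster for one marker."""

    pixels: np.ndarray
    microns_per_pixel: float
    marker_name: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 3 or arr.shape[2] != 3 or arr.size == 0:
            raise ValueError("pixels must be a non-empty (H, W, 3) raster")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")
        if self.marker_name not in VALID_MARKERS:
            raise ValueError(
                f"unknown marker {self.marker_name!r}; expected one of {VALID_MARKERS}"
            )


@dataclass
class Nucleus:
    label: int
    centroid: tuple[float, float]  # (x, y), 0-based pixel coordinates
    pixel_count: int
    mean_dab_od: float
    positive: bool = False


@dataclass
class NucleusSet:
    nuclei: list[Nucleus]
    labels: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.nuclei)

    @property
    def positive_count(self) -> int:
        return sum(1 for n in self.nuclei if n.positive)


@dataclass(frozen=True)
class DetectionParams:
    """Nucleus-detection defaults; all lengths/areas in physical units."""

    smoothing_sigma_um: float = 1.0
    min_area_um2: float = 10.0
    max_area_um2: float = 200.0
    #: Minimum separation of watershed seeds, as a fraction of the
    #: equivalent radius of min_area_um2 -- effectively ~1 nuclear radius.
    min_peak_distance_um: float = 2.5


@dataclass(frozen=True)
class DensityResult:
    marker_name: str
    positive_count: int
    roi_area_mm2: float
    density: float  # cells/mm^2


@dataclass(frozen=True)
class AreaResult:
    marker_area_mm2: float
    specimen_area_mm2: float
    ratio_percent: float


def roi_area_mm2(roi: np.ndarray, microns_per_pixel: float) -> float:
    """Mask area in mm^2: ``pixel_count * mpp^2 / 1e6``."""
    mask = np.asarray(roi, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise EmptyROIError("ROI mask is empty")
    return n * (microns_per_pixel**2) / 1e6


def compute_density(positive_count: int, area_mm2: float, marker_name: str = "") -> DensityResult:
    if area_mm2 <= 0:
        raise ValueError(f"ROI area must be > 0, got {area_mm2}")
    return DensityResult(
        marker_name=marker_name,
        positive_count=int(positive_count),
        roi_area_mm2=float(area_mm2),
        density=positive_count / area_mm2,
    )


def detect_nuclei(
    hema: np.ndarray,
    dab: np.ndarray,
    roi: np.ndarray,
    microns_per_pixel: float,
    params: DetectionParams | None = None,
) -> NucleusSet:
    """Segment nuclei inside an ROI from stain-concentration rasters.

    The combined nuclear signal (hematoxylin + DAB concentration) is
    Gaussian-smoothed, thresholded by Otsu within the ROI, and touching
    objects are split by a distance-transform watershed.  Objects outside
    the physical area window, or with centroid outside the ROI, are
    dropped.  Each retained nucleus carries its mean DAB OD for positivity
    scoring.
    """
    if params is None:
        params = DetectionParams()
    roi = np.asarray(roi, dtype=bool)
    if hema.shape != roi.shape or dab.shape != roi.shape:
        raise ValueError("rasters and ROI must be congruent")
    if not roi.any():
        raise EmptyROIError("ROI mask is empty")

    mpp = microns_per_pixel
    signal = gaussian(hema + dab, sigma=params.smoothing_sigma_um / mpp,
                      preserve_range=True)
    vals = signal[roi]
    # Otsu needs contrast; a blank ROI (all-background) yields no nuclei.
    if float(vals.max() - vals.min()) < 1e-6:
        return NucleusSet(nuclei=[], labels=np.zeros(roi.shape, dtype=np.int32))
    thr = threshold_otsu(vals)
    fg = (signal > thr) & roi

    min_area_px = params.min_area_um2 / (mpp * mpp)
    max_area_px = params.max_area_um2 / (mpp * mpp)
    if not fg.any():
        return NucleusSet(nuclei=[], labels=np.zeros(roi.shape, dtype=np.int32))

    distance = ndi.distance_transform_edt(fg)
    min_dist_px = max(1, int(round(params.min_peak_distance_um / mpp)))
    peaks = peak_local_max(
        distance, min_distance=min_dist_px, labels=fg, exclude_border=False
    )
    markers = np.zeros(fg.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=fg)

    nuclei: list[Nucleus] = []
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for rp in regionprops(labels, intensity_image=dab):
        if not (min_area_px <= rp.area <= max_area_px):
            continue
        cy, cx = rp.centroid
        iy, ix = int(round(cy)), int(round(cx))
        iy = min(max(iy, 0), roi.shape[0] - 1)
        ix = min(max(ix, 0), roi.shape[1] - 1)
        if not roi[iy, ix]:
            continue
        keep[rp.label] = True
        nuclei.append(
            Nucleus(
                label=rp.label,
                centroid=(cx, cy),
                pixel_count=int(rp.area),
                mean_dab_od=float(rp.intensity_mean),
            )
        )
    clean = np.where(keep[labels], labels, 0).astype(np.int32)
    return NucleusSet(nuclei=nuclei, labels=clean)


def score_positivity(
    nuclei: NucleusSet, ihc_threshold: float
) -> NucleusSet:
    """Mark each nucleus positive iff its mean DAB OD >= ``ihc_threshold``."""
    if ihc_threshold < 0:
        raise ValueError("ihc_threshold must be >= 0")
    scored = [
        replace(n, positive=bool(n.mean_dab_od >= ihc_threshold))
        for n in nuclei.nuclei
    ]
    return NucleusSet(nuclei=scored, labels=nuclei.labels)


def marker_area(
    dab: np.ndarray,
    specimen_mask: np.ndarray,
    microns_per_pixel: float,
    marker_threshold: float = DEFAULT_MARKER_AREA_THRESHOLD,
) -> AreaResult:
    """Marker-positive area inside a specimen mask, as mm^2 and percent.

    A pixel counts as marker-positive when its DAB OD (concentration)
    reaches ``marker_threshold``.  For cytokeratin this yields the
    epithelium/specimen ratio.
    """
    if marker_threshold < 0:
        raise ValueError("marker_threshold must be >= 0")
    mask = np.asarray(specimen_mask, dtype=bool)
    specimen_mm2 = roi_area_mm2(mask, microns_per_pixel)  # raises on empty
    px_mm2 = (microns_per_pixel**2) / 1e6
    marker_mm2 = float(((dab >= marker_threshold) & mask).sum()) * px_mm2
    return AreaResult(
        marker_area_mm2=marker_mm2,
        specimen_area_mm2=specimen_mm2,
        ratio_percent=100.0 * marker_mm2 / specimen_mm2,
    )


def quantify_slide(
    image: SlideImage,
    roi: np.ndarray,
    ihc_threshold: float | None = None,
    params: DetectionParams | None = None,
    vectors: StainVectors | None = None,
) -> tuple[DensityResult, NucleusSet]:
    """Full ROI-nuclei analysis: deconvolve, detect, score, compute density."""
    if ihc_threshold is None:
        ihc_threshold = DEFAULT_IHC_THRESHOLDS.get(image.marker_name, 0.3)
    od = rgb_to_od(image.pixels)
    conc = separate_stains(od, vectors)
    nuclei = detect_nuclei(
        conc[..., 0], conc[..., 1], roi, image.microns_per_pixel, params
    )
    nuclei = score_positivity(nuclei, ihc_threshold)
    area = roi_area_mm2(roi, image.microns_per_pixel)
    return compute_density(nuclei.positive_count, area, image.marker_name), nuclei


def quantify_marker_area(
    image: SlideImage,
    specimen_mask: np.ndarray,
    marker_threshold: float = DEFAULT_MARKER_AREA_THRESHOLD,
    vectors: StainVectors | None = None,
) -> AreaResult:
    """Full ROI-marker-area analysis on one slide."""
    od = rgb_to_od(image.pixels)
    conc = separate_stains(od, vectors)
    return marker_area(conc[..., 1], specimen_mask, image.microns_per_pixel,
                       marker_threshold)
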