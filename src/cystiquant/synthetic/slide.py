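"""Render synthetic brightfield IHC/ISH slides with exact ground truth.

The forward model is the same Beer-Lambert/H-DAB model the quantification
stage inverts: every nucleus receives a hematoxylin counterstain disk;
marker-positive cells additionally receive DAB at a configurable optical
density; an optional epithelium band receives DAB to emulate cytokeratin
staining.  The per-stain OD planes are combined through the
Ruifrok-Johnston stain vectors and exponentiated to an 8-bit RGB image.

Ground truth (cell centers and classes, tissue/epithelium masks, exact
planted density) is returned alongside the image, so segmentation and
density recovery can be scored without any manual annotation.

Two slide archetypes cover the study's assays:

* marker slides (CD3/CD20/CD138, kappa/lambda ISH): ``epithelium_fraction
  = 0``, positive and negative cells planted in the tissue;
* cytokeratin slides: a DAB epithelium band occupying a target fraction of
  the tissue area, used to validate the epithelium/specimen area ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cystiquant.stains import StainVectors, od_to_rgb
from cystiquant.config import DEFAULT_MICRONS_PER_PIXEL

#: Hematoxylin OD of a nucleus disk.
NUCLEUS_HEMA_OD = 0.6
#: Faint background counterstain over the tissue, hematoxylin channel.
TISSUE_HEMA_OD = 0.08


class PlacementError(RuntimeError):
    """Requested cell count cannot be placed in the available tissue."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could not place {requested} cells without excessive overlap; "
            f"achievable maximum under the current spec is about {achieved}"
        )


@dataclass(frozen=True)
class SlideSpec:
    """Parameters of one synthetic slide.

    ``stain_intensity_positive`` / ``stain_intensity_negative`` are the mean
    DAB optical densities of marker-positive and marker-negative cells; the
    defaults (0.8 vs 0.05) are well separated relative to the study's IHC
    thresholds of 0.3-0.5.
    """

    width_px: int = 1024
    height_px: int = 1024
    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL
    n_positive_cells: int = 100
    n_negative_cells: int = 100
    epithelium_fraction: float = 0.0
    stain_intensity_positive: float = 0.8
    stain_intensity_negative: float = 0.05
    cell_radius_px: float = 7.0
    background_level: float = 250.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("slide dimensions must be positive")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")
        if self.n_positive_cells < 0 or self.n_negative_cells < 0:
            raise ValueError("cell counts must be >= 0")
        if not 0.0 <= self.epithelium_fraction <= 1.0:
            raise ValueError("epithelium_fraction must be in [0, 1]")
        if self.stain_intensity_positive <= 0:
            raise ValueError("stain_intensity_positive must be > 0")
        if self.stain_intensity_negative < 0:
            raise ValueError("stain_intensity_negative must be >= 0")
        if self.cell_radius_px <= 0:
            raise ValueError("cell_radius_px must be > 0")


@dataclass
class SyntheticGroundTruth:
    """Exact planted truth for one rendered slide.

    ``cell_centers`` holds (x, y, class) with class in {"positive",
    "negative"}; coordinates are 0-based (column, row).
    """

    cell_centers: list[tuple[int, int, str]]
    tissue_mask: np.ndarray
    epithelium_mask: np.ndarray
    tissue_area_mm2: float
    true_positive_density: float
    true_epithelium_ratio: float
    submucosa_mask: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def _tissue_ellipse(height: int, width: int) -> np.ndarray:
    """Filled ellipse inscribed with a small margin: the tissue fragment."""
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    ry, rx = 0.46 * height, 0.46 * width
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _epithelium_band(tissue: np.ndarray, fraction: float) -> np.ndarray:
    """Top band of tissue rows whose cumulative area hits the target fraction."""
    band = np.zeros_like(tissue)
    if fraction <= 0:
        return band
    target = fraction * int(tissue.sum())
    per_row = tissue.sum(axis=1)
    cum = np.cumsum(per_row)
    n_rows = int(np.searchsorted(cum, target, side="left")) + 1
    band[:n_rows] = tissue[:n_rows]
    return band


def _place_cells(
    allowed: np.ndarray,
    n: int,
    min_dist: float,
    rng: np.random.Generator,
    existing: list[tuple[int, int]] | None = None,
) -> list[tuple[int, int]]:
    """Uniform rejection sampling of cell centers inside ``allowed``.

    Centers keep a minimum mutual distance from each other and from any
    ``existing`` centers (the overlap ceiling); neighbor queries go through
    a uniform grid.  Raises :class:`PlacementError` with the achieved count
    when the request is infeasible.
    """
    if n == 0:
        return []
    ys, xs = np.nonzero(allowed)
    n_existing = len(existing) if existing else 0
    if ys.size == 0:
        raise PlacementError(n, n_existing)
    cell = max(min_dist, 1.0)
    grid: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for x, y in existing or ():
        grid.setdefault((int(y // cell), int(x // cell)), []).append((y, x))
    placed: list[tuple[int, int]] = []
    min_d2 = min_dist * min_dist
    attempts = 0
    max_attempts = 200 * n
    while len(placed) < n and attempts < max_attempts:
        attempts += 1
        i = int(rng.integers(0, ys.size))
        y, x = int(ys[i]), int(xs[i])
        gy, gx = int(y // cell), int(x // cell)
        ok = True
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                for (py, px) in grid.get((gy + dy, gx + dx), ()):
                    if (py - y) ** 2 + (px - x) ** 2 < min_d2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            placed.append((x, y))
            grid.setdefault((gy, gx), []).append((y, x))
    if len(placed) < n:
        raise PlacementError(n, n_existing + len(placed))
    return placed


def _stamp_disks(
    plane: np.ndarray,
    centers: list[tuple[int, int]],
    radius: float,
    amplitude: float,
) -> None:
    """Add ``amplitude`` on a disk of ``radius`` around each (x, y) center."""
    if not centers or amplitude == 0:
        return
    h, w = plane.shape
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (yy**2 + xx**2) <= radius * radius
    for x, y in centers:
        y0, y1 = max(0, y - r), min(h, y + r + 1)
        x0, x1 = max(0, x - r), min(w, x + r + 1)
        sub = disk[y0 - (y - r) : y1 - (y - r), x0 - (x - r) : x1 - (x - r)]
        plane[y0:y1, x0:x1][sub] += amplitude


def render_slide(spec: SlideSpec) -> tuple[np.ndarray, SyntheticGroundTruth]:
    """Render one slide; deterministic given ``spec.seed``.

    Returns
    -------
    image : (H, W, 3) uint8 RGB raster.
    truth : :class:`SyntheticGroundTruth` with exact planted quantities.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    tissue = _tissue_ellipse(h, w)
    epithelium = _epithelium_band(tissue, spec.epithelium_fraction)
    submucosa = tissue & ~epithelium

    # Cells sit in the submucosa, clear of the image border, so every
    # planted disk lies fully inside the tissue fragment.
    margin = int(np.ceil(spec.cell_radius_px))
    interior = submucosa.copy()
    interior[:margin] = interior[-margin:] = False
    interior[:, :margin] = interior[:, -margin:] = False

    min_dist = 1.5 * spec.cell_radius_px  # overlap depth ceiling: half a radius
    # Draw order is fixed (positives first) so a seed fully determines layout.
    pos = _place_cells(interior, spec.n_positive_cells, min_dist, rng)
    neg = _place_cells(interior, spec.n_negative_cells, min_dist, rng, existing=pos)

    bg_od = max(0.0, -np.log10((spec.background_level + 1.0) / 255.0))
    hema = np.full((h, w), bg_od, dtype=np.float64)
    dab = np.full((h, w), bg_od, dtype=np.float64)
    hema[tissue] += TISSUE_HEMA_OD
    _stamp_disks(hema, pos + neg, spec.cell_radius_px, NUCLEUS_HEMA_OD)
    _stamp_disks(dab, pos, spec.cell_radius_px, spec.stain_intensity_positive)
    _stamp_disks(dab, neg, spec.cell_radius_px, spec.stain_intensity_negative)
    dab[epithelium] += spec.stain_intensity_positive

    vectors = StainVectors.hdab().matrix
    od_rgb = hema[..., None] * vectors[0] + dab[..., None] * vectors[1]
    image = od_to_rgb(od_rgb)

    px_area_mm2 = (spec.microns_per_pixel**2) / 1e6
    tissue_area_mm2 = float(tissue.sum()) * px_area_mm2
    truth = SyntheticGroundTruth(
        cell_centers=[(x, y, "positive") for x, y in pos]
        + [(x, y, "negative") for x, y in neg],
        tissue_mask=tissue,
        epithelium_mask=epithelium,
        tissue_area_mm2=tissue_area_mm2,
        true_positive_density=len(pos) / tissue_area_mm2,
        true_epithelium_ratio=100.0 * float(epithelium.sum()) / float(tissue.sum()),
        submucosa_mask=submucosa,
    )
    return image, truth
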