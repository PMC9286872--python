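"""Reporter-cell detection and tissue-area measurement on calibrated 2D sections.

The quantification chain mirrors standard whole-slide fluorescence counting:
channels are reduced to 8-bit grayscale, the reporter channel is flattened by
median background subtraction, binarized with Otsu's method, and connected
components with an equivalent-circle diameter of at least ``min_diameter``
(default 10 µm) are counted as reporter-positive cells.  Tissue area is taken
from the nuclear (DAPI) channel by Gaussian smoothing, Otsu binarization and a
morphological close that merges the section into one region.

Conventions
-----------
* pixel coordinates are 0-based ``(row, col)``; physical position is
  ``index * pixel_size`` in µm
* component areas are reported in µm², tissue areas in mm²
* "diameter" of a component is the equivalent-circle diameter
  ``2 * sqrt(area / pi)`` computed from its physical area
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import rank
from skimage.morphology import disk

__all__ = [
    "ImageStack",
    "DetectionParams",
    "CellDetection",
    "DetectionResult",
    "TissueMask",
    "DegenerateHistogramError",
    "to_8bit",
    "otsu_threshold",
    "subtract_background",
    "detect_cells",
    "compute_tissue_mask",
]


class DegenerateHistogramError(ValueError):
    """Raised when a histogram has no separable classes (all mass in one bin)."""


@dataclass
class ImageStack:
    """Calibrated multi-channel 2D image.

    channels maps a role name (``nuclei``, ``autofluorescence``, ``reporter``,
    ``marker`` — any subset) to a 2D intensity array; all channels share one
    shape.  ``pixel_size`` is the edge length of a pixel in µm.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels have mismatched shapes: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the cell-detection and tissue-mask operators.

    min_diameter
        equivalent-circle diameter cutoff in µm; components at least this
        large are counted as cells (inclusive).
    background_radius
        radius in µm of the median background estimate subtracted from the
        reporter channel before thresholding.
    connectivity
        pixel connectivity for component labelling, 4 or 8.
    gaussian_sigma, close_radius
        Gaussian smoothing sigma and morphological-close radius in µm used by
        the tissue mask.
    """

    min_diameter: float = 10.0
    background_radius: float = 50.0
    connectivity: int = 8
    gaussian_sigma: float = 10.0
    close_radius: float = 20.0

    def __post_init__(self) -> None:
        if self.min_diameter <= 0:
            raise ValueError("min_diameter must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class CellDetection:
    """One detected reporter-positive cell (a connected component)."""

    id: int
    centroid_px: tuple[float, float]  # (row, col)
    centroid_um: tuple[float, float]  # (row, col) * pixel_size
    area_um2: float
    equivalent_diameter_um: float
    pixel_rows: np.ndarray
    pixel_cols: np.ndarray
    zone: str | None = None
    marker_positive: bool | None = None


@dataclass
class DetectionResult:
    cells: list[CellDetection]
    threshold: int | None
    pixel_size: float
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)


@dataclass
class TissueMask:
    mask: np.ndarray  # bool
    area_mm2: float
    pixel_size: float
    warnings: list[str] = field(default_factory=list)


def to_8bit(channel: np.ndarray) -> np.ndarray:
    """Min–max rescale an intensity array to uint8 [0, 255].

    Rounds half up; a constant channel maps to all zeros.
    """
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("empty channel")
    lo = float(channel.min())
    hi = float(channel.max())
    if hi == lo:
        return np.zeros(channel.shape, dtype=np.uint8)
    scaled = (channel.astype(np.float64) - lo) * (255.0 / (hi - lo))
    return np.floor(scaled + 0.5).clip(0, 255).astype(np.uint8)


def otsu_threshold(histogram: Sequence[int] | np.ndarray) -> int:
    """Otsu threshold of a 256-bin grayscale histogram.

    Returns the level ``t`` maximizing the between-class variance of the split
    ``{<= t, > t}``; foreground is the ``> t`` class.  Ties are broken toward
    the smallest maximizing ``t``.  Computed in exact integer arithmetic, so
    the result equals exhaustive search over all 255 splits by construction.
    """
    hist = np.asarray(histogram)
    if hist.shape != (256,):
        raise ValueError("histogram must have exactly 256 bins")
    if np.any(hist < 0):
        raise ValueError("histogram counts must be non-negative")
    counts = [int(c) for c in hist]
    n_total = sum(counts)
    if n_total == 0 or sum(1 for c in counts if c > 0) < 2:
        raise DegenerateHistogramError("no separable classes")
    s_total = sum(i * c for i, c in enumerate(counts))

    # between-class variance at split t is (s0*N - n0*S)^2 / (N^2 * n0 * (N - n0));
    # the N^2 factor is constant, so compare (s0*N - n0*S)^2 * denom' ratios
    # exactly by cross-multiplication.
    best_t = -1
    best_num = 0  # numerator (s0*N - n0*S)^2
    best_den = 1  # denominator n0*(N - n0)
    n0 = 0
    s0 = 0
    for t in range(255):
        n0 += counts[t]
        s0 += t * counts[t]
        if n0 == 0 or n0 == n_total:
            continue
        num = (s0 * n_total - n0 * s_total) ** 2
        den = n0 * (n_total - n0)
        if best_t < 0 or num * best_den > best_num * den:
            best_t, best_num, best_den = t, num, den
    return best_t


def subtract_background(
    channel: np.ndarray, background_radius: float, pixel_size: float
) -> np.ndarray:
    """Subtract a large-scale median background estimate from an 8-bit channel.

    The background is the sliding median over a disk of ``background_radius``
    µm; the difference is clipped at zero.  The radius must correspond to at
    least 3 pixels.
    """
    if channel.dtype != np.uint8:
        raise ValueError("subtract_background expects an 8-bit (uint8) channel")
    radius_px = int(round(background_radius / pixel_size))
    if radius_px < 3:
        raise ValueError(
            f"background_radius {background_radius} µm is {radius_px} px at "
            f"{pixel_size} µm/px; at least 3 px required"
        )
    background = rank.median(channel, footprint=disk(radius_px))
    out = channel.astype(np.int16) - background.astype(np.int16)
    return np.clip(out, 0, 255).astype(np.uint8)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)


def _components_to_detections(
    mask: np.ndarray, pixel_size: float, connectivity: int, min_diameter: float
) -> list[CellDetection]:
    labels, n = ndimage.label(mask, structure=_connectivity_structure(connectivity))
    cells: list[CellDetection] = []
    if n == 0:
        return cells
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        sub = labels[sl] == lab
        rows, cols = np.nonzero(sub)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        area_um2 = rows.size * pixel_size**2
        eq_d = 2.0 * np.sqrt(area_um2 / np.pi)
        if eq_d < min_diameter:
            continue
        r_c = float(rows.mean())
        c_c = float(cols.mean())
        cells.append(
            CellDetection(
                id=-1,
                centroid_px=(r_c, c_c),
                centroid_um=(r_c * pixel_size, c_c * pixel_size),
                area_um2=float(area_um2),
                equivalent_diameter_um=float(eq_d),
                pixel_rows=rows,
                pixel_cols=cols,
            )
        )
    cells.sort(key=lambda c: c.centroid_px)
    return [replace(c, id=i) for i, c in enumerate(cells)]


def detect_cells(
    reporter: np.ndarray, pixel_size: float, params: DetectionParams | None = None
) -> DetectionResult:
    """Detect reporter-positive cells in a calibrated reporter channel.

    Pipeline: 8-bit conversion → median background subtraction → Otsu
    binarization → connected components → discard components whose
    equivalent-circle diameter is below ``params.min_diameter``.  Detections
    are returned sorted by centroid (row, col).  A degenerate histogram (no
    separable classes, e.g. a blank frame) yields an empty result with a
    warning flag rather than an error.
    """
    params = params or DetectionParams()
    flat = subtract_background(
        to_8bit(reporter), params.background_radius, pixel_size
    )
    hist = np.bincount(flat.ravel(), minlength=256)
    try:
        t = otsu_threshold(hist)
    except DegenerateHistogramError:
        return DetectionResult(
            cells=[], threshold=None, pixel_size=pixel_size,
            warnings=["no detectable signal"],
        )
    mask = flat > t
    cells = _components_to_detections(
        mask, pixel_size, params.connectivity, params.min_diameter
    )
    return DetectionResult(cells=cells, threshold=t, pixel_size=pixel_size)


def compute_tissue_mask(
    nuclei: np.ndarray, pixel_size: float, params: DetectionParams | None = None
) -> TissueMask:
    """Tissue mask and area (mm²) from the nuclear (DAPI) channel.

    Gaussian smooth → Otsu binarize → morphological close (disk) → keep the
    largest connected component → fill holes.  An empty foreground yields a
    zero-area mask with a warning.
    """
    params = params or DetectionParams()
    u8 = to_8bit(nuclei)
    sigma_px = params.gaussian_sigma / pixel_size
    smoothed = ndimage.gaussian_filter(u8.astype(np.float64), sigma=sigma_px)
    smoothed_u8 = np.floor(smoothed + 0.5).clip(0, 255).astype(np.uint8)
    hist = np.bincount(smoothed_u8.ravel(), minlength=256)
    warnings: list[str] = []
    try:
        t = otsu_threshold(hist)
    except DegenerateHistogramError:
        return TissueMask(
            mask=np.zeros(nuclei.shape, dtype=bool), area_mm2=0.0,
            pixel_size=pixel_size, warnings=["empty tissue foreground"],
        )
    mask = smoothed_u8 > t
    close_px = max(1, int(round(params.close_radius / pixel_size)))
    mask = ndimage.binary_closing(mask, structure=disk(close_px).astype(bool))
    labels, n = ndimage.label(mask, structure=_connectivity_structure(8))
    if n == 0:
        return TissueMask(
            mask=np.zeros(nuclei.shape, dtype=bool), area_mm2=0.0,
            pixel_size=pixel_size, warnings=["empty tissue foreground"],
        )
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    area_mm2 = float(mask.sum()) * (pixel_size / 1000.0) ** 2
    return TissueMask(mask=mask, area_mm2=area_mm2, pixel_size=pixel_size,
                      warnings=warnings)
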