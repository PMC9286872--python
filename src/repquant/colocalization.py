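"""Marker-positive area and reporter/marker double-positive calling.

Immunofluorescence marker channels are binarized at a fixed, experiment-wide
grayscale threshold (a required input, never auto-chosen), and a detected
reporter cell is called double-positive when its component pixel set overlaps
the marker mask by at least ``min_overlap_px`` pixels (default 10, inclusive).
The overlap rule is deliberately kept in pixels, with the pixel size recorded
alongside so reports can expose the physical meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .detection import CellDetection, TissueMask, to_8bit

__all__ = [
    "MarkerMask",
    "OverlapParams",
    "ColocalizationSummary",
    "marker_mask",
    "positive_area_fraction",
    "call_double_positives",
]


@dataclass
class MarkerMask:
    mask: np.ndarray  # bool
    threshold_used: int
    marker_name: str = ""


@dataclass(frozen=True)
class OverlapParams:
    """Pixel-overlap rule for double-positive calling (inclusive cutoff)."""

    min_overlap_px: int = 10

    def __post_init__(self) -> None:
        if self.min_overlap_px < 1:
            raise ValueError("min_overlap_px must be >= 1")


@dataclass
class ColocalizationSummary:
    marker_name: str
    threshold_used: int
    min_overlap_px: int
    n_cells: int
    n_double_positive: int
    percent_double_positive: float | None  # None when there are no cells


def marker_mask(
    marker_channel: np.ndarray, threshold: int, marker_name: str = ""
) -> MarkerMask:
    """Binarize a marker channel at a fixed 8-bit grayscale threshold.

    The channel is first reduced to 8-bit; pixels strictly above the threshold
    are positive.  The threshold is recorded for provenance.
    """
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    u8 = to_8bit(marker_channel)
    return MarkerMask(mask=u8 > threshold, threshold_used=int(threshold),
                      marker_name=marker_name)


def positive_area_fraction(mask: MarkerMask, tissue: TissueMask) -> float:
    """Fraction of the tissue area that is marker-positive, in [0, 1]."""
    if mask.mask.shape != tissue.mask.shape:
        raise ValueError("marker mask and tissue mask shapes differ")
    n_tissue = int(tissue.mask.sum())
    if n_tissue == 0:
        raise ValueError("empty tissue mask")
    return float(np.logical_and(mask.mask, tissue.mask).sum()) / n_tissue


def call_double_positives(
    detections: list[CellDetection],
    mask: MarkerMask,
    params: OverlapParams | None = None,
) -> tuple[list[CellDetection], ColocalizationSummary]:
    """Flag detections overlapping the marker mask by >= min_overlap_px pixels.

    Returns new detection records with ``marker_positive`` set, plus a summary
    with the double-positive count and percentage.
    """
    params = params or OverlapParams()
    flagged: list[CellDetection] = []
    n_pos = 0
    for d in detections:
        overlap = int(mask.mask[d.pixel_rows, d.pixel_cols].sum())
        positive = overlap >= params.min_overlap_px
        n_pos += positive
        flagged.append(replace(d, marker_positive=positive))
    pct = 100.0 * n_pos / len(detections) if detections else None
    return flagged, ColocalizationSummary(
        marker_name=mask.marker_name, threshold_used=mask.threshold_used,
        min_overlap_px=params.min_overlap_px, n_cells=len(detections),
        n_double_positive=n_pos, percent_double_positive=pct,
    )
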