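"""Recovery metrics against planted ground truth.

Detections are matched to planted cells by minimum-cost assignment
(Hungarian) with a maximum matching distance; precision/recall follow from
the match.  Also provides the serial-section → whole-kidney recovery helper
used by the extrapolation benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .detection import DetectionParams, DetectionResult, compute_tissue_mask, detect_cells
from .synthetic import SectionedKidney
from .zonation import ExtrapolationResult, estimate_total_cells

__all__ = [
    "DetectionMetrics",
    "match_detections",
    "detection_metrics",
    "recover_total_from_sections",
]


@dataclass
class DetectionMetrics:
    n_truth: int
    n_detected: int
    n_matched: int
    precision: float
    recall: float
    matches: list[tuple[int, int]]  # (truth index, detection index)


def match_detections(
    truth_um: np.ndarray, detected_um: np.ndarray, max_dist_um: float
) -> list[tuple[int, int]]:
    """One-to-one matching of planted and detected centroids.

    Minimum-cost assignment on Euclidean distance; pairs farther than
    ``max_dist_um`` are not matched.  Coordinates are (row_um, col_um) or any
    consistent 2D frame.
    """
    truth_um = np.asarray(truth_um, dtype=float).reshape(-1, 2)
    detected_um = np.asarray(detected_um, dtype=float).reshape(-1, 2)
    if len(truth_um) == 0 or len(detected_um) == 0:
        return []
    cost = np.linalg.norm(truth_um[:, None, :] - detected_um[None, :, :], axis=2)
    big = cost.max() + 2 * max_dist_um + 1.0
    rows, cols = linear_sum_assignment(np.where(cost > max_dist_um, big, cost))
    return [(int(i), int(j)) for i, j in zip(rows, cols)
            if cost[i, j] <= max_dist_um]


def detection_metrics(
    truth_cells: pd.DataFrame, result: DetectionResult, max_dist_um: float = 5.0
) -> DetectionMetrics:
    """Precision/recall of a detection run against planted cells."""
    truth_xy = truth_cells[["y_um", "x_um"]].to_numpy()
    det_xy = np.array([d.centroid_um for d in result.cells]).reshape(-1, 2)
    matches = match_detections(truth_xy, det_xy, max_dist_um)
    n_t, n_d, n_m = len(truth_xy), len(det_xy), len(matches)
    return DetectionMetrics(
        n_truth=n_t, n_detected=n_d, n_matched=n_m,
        precision=n_m / n_d if n_d else 1.0,
        recall=n_m / n_t if n_t else 1.0,
        matches=matches,
    )


def recover_total_from_sections(
    kidney: SectionedKidney, params: DetectionParams | None = None
) -> tuple[ExtrapolationResult, pd.DataFrame]:
    """Detect cells on each serial section, average the areal densities and
    extrapolate to the whole-kidney total via the ellipsoid volume.

    Returns the extrapolation plus a per-section table (detected count,
    tissue area, density, planted count) for auditing.
    """
    params = params or DetectionParams()
    rows = []
    densities = []
    for k, stack in enumerate(kidney.sections):
        result = detect_cells(stack.channels["reporter"], stack.pixel_size, params)
        tissue = compute_tissue_mask(stack.channels["nuclei"], stack.pixel_size,
                                     params)
        density = len(result.cells) / tissue.area_mm2 if tissue.area_mm2 > 0 else 0.0
        densities.append(density)
        rows.append({
            "section": k, "z_mm": kidney.section_z_mm[k],
            "n_detected": len(result.cells),
            "n_planted": kidney.section_truth_counts[k],
            "tissue_area_mm2": tissue.area_mm2,
            "density_per_mm2": density,
        })
    mean_density = float(np.mean(densities))
    extrap = estimate_total_cells(mean_density, kidney.geometry)
    return extrap, pd.DataFrame(rows)
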