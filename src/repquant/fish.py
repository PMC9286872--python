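"""Single-molecule FISH dot clustering and transcript-contribution statistics.

Each fluorescent dot is one mRNA molecule.  Dots lying within a chain of
pairwise distances of at most ``cluster_radius`` (default 5 µm, inclusive —
single-linkage) are considered to originate from the same cell; per-cluster
dot counts are the per-cell transcript counts.  FISH cells are co-labelled
("tagged") with reporter detections by containment of the cluster centroid in
a detection's pixel set, falling back to proximity of detection centroids.

Manually annotated dot tables (CSV with x_um, y_um[, channel]) are the
canonical input; an automated blob detector is provided only so synthetic
end-to-end runs need no manual step.

Contribution statistics rank cells by transcript count (descending) and trace
the Lorenz-type cumulative curve of transcript share versus cell fraction,
from which the share carried by the top x% of cells ("high contributors") is
read off by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .detection import CellDetection

__all__ = [
    "DotTable",
    "FishCell",
    "FishCellSet",
    "CompositionStats",
    "ContributionCurve",
    "detect_dots",
    "cluster_dots",
    "tag_fish_cells",
    "composition_stats",
    "contribution_curve",
    "contributor_slices",
]


@dataclass
class DotTable:
    """FISH dot coordinates in µm; ``source`` records manual vs detector origin."""

    x_um: np.ndarray
    y_um: np.ndarray
    channel: np.ndarray | None = None
    source: str = "manual"

    def __post_init__(self) -> None:
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if self.x_um.shape != self.y_um.shape:
            raise ValueError("x_um and y_um must have equal length")

    def __len__(self) -> int:
        return self.x_um.size

    @classmethod
    def from_csv(cls, path: str | Path, source: str = "manual") -> "DotTable":
        df = pd.read_csv(path)
        channel = df["channel"].to_numpy() if "channel" in df else None
        return cls(df["x_um"].to_numpy(), df["y_um"].to_numpy(), channel, source)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"x_um": self.x_um, "y_um": self.y_um})
        if self.channel is not None:
            df["channel"] = self.channel
        df.to_csv(path, index=False)


@dataclass
class FishCell:
    id: int
    member_dot_ids: np.ndarray
    dot_count: int
    centroid_um: tuple[float, float]  # (x, y)
    tagged: bool | None = None
    matched_detection_id: int | None = None


@dataclass
class FishCellSet:
    cells: list[FishCell]
    cluster_radius: float
    dot_cluster_ids: np.ndarray  # per-dot cluster assignment

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def counts(self) -> np.ndarray:
        return np.array([c.dot_count for c in self.cells], dtype=int)


@dataclass
class CompositionStats:
    """Both directions of the reporter/FISH double-positive composition."""

    percent_tagged_cells_fish_positive: float | None
    percent_fish_cells_tagged: float | None
    n_detections: int
    n_detections_fish_positive: int
    n_fish_cells: int
    n_fish_cells_tagged: int
    undefined: list[str] = field(default_factory=list)


@dataclass
class ContributionCurve:
    counts_sorted: np.ndarray  # descending
    cell_fraction: np.ndarray  # cumulative, ends at 1
    transcript_fraction: np.ndarray  # cumulative, ends at 1


def detect_dots(fish_channel: np.ndarray, pixel_size: float) -> DotTable:
    """Automated FISH dot detection (local-maximum blob finder).

    Smooths with a small Gaussian, finds local maxima above an Otsu-like cut
    of the smoothed image, and refines each to sub-pixel precision by the
    intensity centroid of its 3x3 neighbourhood.  Dots closer than the
    detector scale may merge — a documented resolution bound; the ``source``
    field marks the table as detector-derived.
    """
    from .detection import DegenerateHistogramError, otsu_threshold, to_8bit

    u8 = to_8bit(fish_channel)
    smoothed = ndimage.gaussian_filter(u8.astype(float), sigma=1.0)
    hist = np.bincount(np.floor(smoothed + 0.5).astype(int).clip(0, 255).ravel(),
                       minlength=256)
    try:
        t = otsu_threshold(hist)
    except DegenerateHistogramError:
        return DotTable(np.empty(0), np.empty(0), source="detector")
    maxima = (smoothed == ndimage.maximum_filter(smoothed, size=3)) & (smoothed > t)
    rows, cols = np.nonzero(maxima)
    xs, ys = [], []
    h, w = u8.shape
    img = smoothed
    for r, c in zip(rows, cols):
        r0, r1 = max(r - 1, 0), min(r + 2, h)
        c0, c1 = max(c - 1, 0), min(c + 2, w)
        patch = img[r0:r1, c0:c1]
        total = patch.sum()
        if total > 0:
            rr, cc = np.mgrid[r0:r1, c0:c1]
            r_ref = float((patch * rr).sum() / total)
            c_ref = float((patch * cc).sum() / total)
        else:
            r_ref, c_ref = float(r), float(c)
        xs.append(c_ref * pixel_size)
        ys.append(r_ref * pixel_size)
    return DotTable(np.array(xs), np.array(ys), source="detector")


def cluster_dots(dots: DotTable, cluster_radius: float = 5.0) -> FishCellSet:
    """Single-linkage clustering of dots at an inclusive distance radius.

    Two dots belong to one cluster iff they are connected by a chain of
    pairwise Euclidean distances <= ``cluster_radius``.  Implemented with a
    KD-tree neighbour query and union-find; per-cluster centroid is the mean
    of member coordinates.  Cluster ids follow the order of first appearance
    in the dot table.
    """
    if cluster_radius <= 0:
        raise ValueError("cluster_radius must be positive")
    n = len(dots)
    if n == 0:
        return FishCellSet(cells=[], cluster_radius=cluster_radius,
                           dot_cluster_ids=np.empty(0, dtype=int))
    pts = np.column_stack([dots.x_um, dots.y_um])
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(pts)
    for i, j in tree.query_pairs(r=cluster_radius):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    roots = np.array([find(i) for i in range(n)])
    # relabel clusters by first appearance
    order: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        if r not in order:
            order[r] = len(order)
        labels[i] = order[r]
    cells = []
    for cid in range(len(order)):
        members = np.nonzero(labels == cid)[0]
        cells.append(FishCell(
            id=cid, member_dot_ids=members, dot_count=members.size,
            centroid_um=(float(pts[members, 0].mean()),
                         float(pts[members, 1].mean())),
        ))
    return FishCellSet(cells=cells, cluster_radius=cluster_radius,
                       dot_cluster_ids=labels)


def tag_fish_cells(
    fish_cells: FishCellSet,
    detections: list[CellDetection],
    pixel_size: float,
    detection_pixel_size: float | None = None,
    match_radius: float = 5.0,
) -> FishCellSet:
    """Co-label FISH cells with reporter detections.

    A FISH cell is tagged iff its centroid pixel lies inside a detection's
    component pixel set, else iff it is within ``match_radius`` µm of a
    detection centroid.  Both inputs must share one coordinate frame; a
    mismatched pixel calibration raises.
    """
    if detection_pixel_size is not None and not np.isclose(
        detection_pixel_size, pixel_size
    ):
        raise ValueError(
            f"calibration mismatch: FISH frame {pixel_size} µm/px vs "
            f"detections {detection_pixel_size} µm/px"
        )
    pixel_owner: dict[tuple[int, int], int] = {}
    for d in detections:
        for r, c in zip(d.pixel_rows, d.pixel_cols):
            pixel_owner[(int(r), int(c))] = d.id
    det_centroids = np.array(
        [[d.centroid_um[1], d.centroid_um[0]] for d in detections]
    )  # (x, y) µm
    det_tree = cKDTree(det_centroids) if len(detections) else None
    tagged_cells = []
    for cell in fish_cells.cells:
        x, y = cell.centroid_um
        px = (int(round(y / pixel_size)), int(round(x / pixel_size)))
        match = pixel_owner.get(px)
        if match is None and det_tree is not None:
            dist, idx = det_tree.query([x, y])
            if dist <= match_radius:
                match = detections[int(idx)].id
        tagged_cells.append(replace(
            cell, tagged=match is not None, matched_detection_id=match
        ))
    return FishCellSet(cells=tagged_cells, cluster_radius=fish_cells.cluster_radius,
                       dot_cluster_ids=fish_cells.dot_cluster_ids)


def composition_stats(
    fish_cells: FishCellSet, detections: list[CellDetection]
) -> CompositionStats:
    """Percent of tagged (reporter) cells that are FISH-positive, and percent
    of FISH cells that are tagged; numerators and denominators are reported
    for auditability.  Zero denominators yield undefined (None), never 0.
    """
    for c in fish_cells.cells:
        if c.tagged is None:
            raise ValueError("fish cells must be tagged first (tag_fish_cells)")
    n_fish = len(fish_cells)
    n_fish_tagged = sum(1 for c in fish_cells.cells if c.tagged)
    fish_positive_dets = {
        c.matched_detection_id for c in fish_cells.cells
        if c.matched_detection_id is not None
    }
    n_det = len(detections)
    n_det_fish = len(fish_positive_dets)
    undefined = []
    pct_det = 100.0 * n_det_fish / n_det if n_det else None
    if n_det == 0:
        undefined.append("no reporter detections")
    pct_fish = 100.0 * n_fish_tagged / n_fish if n_fish else None
    if n_fish == 0:
        undefined.append("no FISH cells")
    return CompositionStats(
        percent_tagged_cells_fish_positive=pct_det,
        percent_fish_cells_tagged=pct_fish,
        n_detections=n_det, n_detections_fish_positive=n_det_fish,
        n_fish_cells=n_fish, n_fish_cells_tagged=n_fish_tagged,
        undefined=undefined,
    )


def contribution_curve(counts) -> ContributionCurve:
    """Lorenz-type cumulative contribution curve of per-cell transcript counts.

    Counts are sorted descending; the curve gives, after each cell rank, the
    cumulative fraction of cells and of transcripts.  With the descending
    sort the transcript fraction dominates the cell fraction pointwise.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("no counts")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("all counts are zero; contribution undefined")
    srt = np.sort(counts)[::-1]
    n = srt.size
    return ContributionCurve(
        counts_sorted=srt,
        cell_fraction=np.arange(1, n + 1) / n,
        transcript_fraction=np.cumsum(srt) / total,
    )


def contributor_slices(curve: ContributionCurve, cell_fraction_cutoffs) -> np.ndarray:
    """Cumulative transcript share at given cell-fraction cutoffs.

    Cutoffs must lie in (0, 1] and be strictly increasing; shares between
    cell ranks are linearly interpolated on the cumulative curve (which also
    resolves ties at the cutoff rank).
    """
    cutoffs = np.atleast_1d(np.asarray(cell_fraction_cutoffs, dtype=float))
    if np.any(cutoffs <= 0) or np.any(cutoffs > 1):
        raise ValueError("cutoffs must lie in (0, 1]")
    if cutoffs.size > 1 and np.any(np.diff(cutoffs) <= 0):
        raise ValueError("cutoffs must be strictly increasing")
    x = np.concatenate([[0.0], curve.cell_fraction])
    y = np.concatenate([[0.0], curve.transcript_fraction])
    return np.interp(cutoffs, x, y)
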