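"""Renal-compartment assignment, zonal densities and whole-kidney extrapolation.

Detections are assigned to one of five renal compartments — cortex, outer and
inner stripes of the outer medulla (OSOM, ISOM), inner medulla (IM) and
papilla — by looking up the zone label at the detection centroid.  Zone maps
are curated inputs (a label image), not computed: anatomical zoning of real
sections is manual, and the synthetic generator supplies procedurally defined
maps with the same vocabulary.

Whole-kidney totals are extrapolated stereologically: the areal density of a
2D section of known thickness is converted to a volumetric density and scaled
by the kidney volume from the ellipsoid equation V = (π/6)·L·W·D.  No
over-projection (Abercrombie) correction is applied; cells thicker than the
section are over-counted, a known bias of the plain extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import pi

import numpy as np

from .detection import CellDetection

__all__ = [
    "ZONES",
    "UNASSIGNED",
    "ZoneMap",
    "KidneyGeometry",
    "ZoneStats",
    "DensityReport",
    "ExtrapolationResult",
    "assign_zones",
    "zone_density_report",
    "ellipsoid_volume",
    "estimate_total_cells",
]

#: fixed zone vocabulary, outermost compartment first; label image uses
#: 0 = background, 1..5 = this order
ZONES: tuple[str, ...] = ("cortex", "OSOM", "ISOM", "IM", "papilla")
UNASSIGNED = "unassigned"


@dataclass
class ZoneMap:
    """Label image over {background, cortex, OSOM, ISOM, IM, papilla}."""

    labels: np.ndarray  # int image, 0 = background, 1..5 = ZONES order
    pixel_size: float

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        bad = set(np.unique(self.labels)) - set(range(len(ZONES) + 1))
        if bad:
            raise ValueError(f"zone labels outside vocabulary: {sorted(bad)}")

    def zone_at(self, row: float, col: float) -> str:
        r = int(round(row))
        c = int(round(col))
        if not (0 <= r < self.labels.shape[0] and 0 <= c < self.labels.shape[1]):
            return UNASSIGNED
        lab = int(self.labels[r, c])
        return UNASSIGNED if lab == 0 else ZONES[lab - 1]

    def zone_area_mm2(self, zone: str) -> float:
        idx = ZONES.index(zone) + 1
        return float((self.labels == idx).sum()) * (self.pixel_size / 1000.0) ** 2


@dataclass(frozen=True)
class KidneyGeometry:
    """Kidney axes (mm) and section thickness (µm) for extrapolation.

    length is the maximum longitudinal diameter; width and depth are measured
    on centric transverse sections; sections default to 12 µm cryosections.
    """

    length_mm: float
    width_mm: float
    depth_mm: float
    section_thickness_um: float = 12.0

    def __post_init__(self) -> None:
        for name in ("length_mm", "width_mm", "depth_mm", "section_thickness_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ZoneStats:
    zone: str
    count: int
    area_mm2: float
    density_per_mm2: float | None  # None when the zone has zero area
    percent: float | None  # None when no cells were assigned at all


@dataclass
class DensityReport:
    zones: dict[str, ZoneStats]
    n_assigned: int
    n_unassigned: int
    whole_slice_density_per_mm2: float | None
    total_zone_area_mm2: float
    slice_id: str | None = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class ExtrapolationResult:
    total_cells: float
    areal_density_per_mm2: float
    volumetric_density_per_mm3: float
    kidney_volume_mm3: float


def assign_zones(
    detections: list[CellDetection], zone_map: ZoneMap, image_shape=None
) -> list[CellDetection]:
    """Label each detection with the compartment at its centroid pixel.

    Centroids falling on background are labelled ``unassigned`` and are later
    excluded from per-zone statistics (but counted separately).  Returns new
    detection records; the inputs are not mutated.
    """
    if image_shape is not None and tuple(image_shape) != zone_map.labels.shape:
        raise ValueError(
            f"zone map shape {zone_map.labels.shape} does not match "
            f"image shape {tuple(image_shape)}"
        )
    return [replace(d, zone=zone_map.zone_at(*d.centroid_px)) for d in detections]


def zone_density_report(
    detections: list[CellDetection], zone_map: ZoneMap, slice_id: str | None = None
) -> DensityReport:
    """Per-zone counts, densities (cells/mm²) and percentage distribution.

    Percentages are over zone-assigned cells; zones with zero area are flagged
    (density None), never reported as density zero.
    """
    if zone_map.labels.size == 0 or not np.any(zone_map.labels > 0):
        raise ValueError("empty zone map")
    for d in detections:
        if d.zone is None:
            raise ValueError("detections must be zone-assigned first")
    counts = {z: 0 for z in ZONES}
    n_unassigned = 0
    for d in detections:
        if d.zone == UNASSIGNED:
            n_unassigned += 1
        else:
            counts[d.zone] += 1
    n_assigned = sum(counts.values())
    warnings: list[str] = []
    zones: dict[str, ZoneStats] = {}
    total_area = 0.0
    for z in ZONES:
        area = zone_map.zone_area_mm2(z)
        total_area += area
        if area > 0:
            density = counts[z] / area
        else:
            density = None
            warnings.append(f"zone {z} has zero area; density undefined")
        percent = 100.0 * counts[z] / n_assigned if n_assigned > 0 else None
        zones[z] = ZoneStats(z, counts[z], area, density, percent)
    whole = n_assigned / total_area if total_area > 0 else None
    if n_assigned == 0:
        warnings.append("no zone-assigned cells; percentages undefined")
    return DensityReport(
        zones=zones, n_assigned=n_assigned, n_unassigned=n_unassigned,
        whole_slice_density_per_mm2=whole, total_zone_area_mm2=total_area,
        slice_id=slice_id, warnings=warnings,
    )


def ellipsoid_volume(geometry: KidneyGeometry) -> float:
    """Kidney volume in mm³ from the ellipsoid equation V = (π/6)·L·W·D."""
    return (pi / 6.0) * geometry.length_mm * geometry.width_mm * geometry.depth_mm


def estimate_total_cells(
    areal_density_per_mm2: float, geometry: KidneyGeometry
) -> ExtrapolationResult:
    """Extrapolate a 2D areal density to a whole-kidney cell total.

    The section of thickness t (µm) samples a slab of volume area·t, so the
    volumetric density is areal density / (t in mm); the total is that times
    the ellipsoid volume.
    """
    if areal_density_per_mm2 < 0:
        raise ValueError("areal density must be non-negative")
    t_mm = geometry.section_thickness_um / 1000.0
    volumetric = areal_density_per_mm2 / t_mm
    volume = ellipsoid_volume(geometry)
    return ExtrapolationResult(
        total_cells=volumetric * volume,
        areal_density_per_mm2=areal_density_per_mm2,
        volumetric_density_per_mm3=volumetric,
        kidney_volume_mm3=volume,
    )
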