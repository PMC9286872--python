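"""Standard-format I/O: multi-page TIFF image stacks, zone-map label images
with JSON legends, and CSV tables for detections and dots."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .detection import CellDetection, DetectionResult, ImageStack
from .zonation import ZONES, ZoneMap

__all__ = [
    "write_stack",
    "read_stack",
    "write_zone_map",
    "read_zone_map",
    "detections_to_frame",
    "write_detections_csv",
]


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an image stack as a multi-page TIFF (one page per channel).

    Channel names and the pixel size (µm/px) are recorded in the TIFF
    description; resolution tags carry pixels-per-µm.
    """
    path = Path(path)
    meta = {"pixel_size_um": stack.pixel_size,
            "channels": list(stack.channels.keys())}
    pages = np.stack([stack.channels[c] for c in stack.channels])
    tifffile.imwrite(
        path, pages, description=json.dumps(meta),
        photometric="minisblack", planarconfig="separate",
        resolution=(1.0 / stack.pixel_size, 1.0 / stack.pixel_size),
        resolutionunit="MICROMETER",
    )


def read_stack(path: str | Path) -> ImageStack:
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc)
    names = meta["channels"]
    if pages.ndim == 2:
        pages = pages[None]
    channels = {name: pages[i] for i, name in enumerate(names)}
    return ImageStack(channels=channels, pixel_size=float(meta["pixel_size_um"]))


def write_zone_map(zone_map: ZoneMap, path: str | Path) -> None:
    """Indexed label TIFF plus a sidecar JSON legend mapping index → zone."""
    path = Path(path)
    tifffile.imwrite(path, zone_map.labels.astype(np.uint8))
    legend = {"0": "background",
              **{str(i + 1): z for i, z in enumerate(ZONES)},
              "pixel_size_um": zone_map.pixel_size}
    path.with_suffix(".json").write_text(json.dumps(legend, indent=1))


def read_zone_map(path: str | Path) -> ZoneMap:
    path = Path(path)
    labels = tifffile.imread(path)
    legend = json.loads(path.with_suffix(".json").read_text())
    for i, z in enumerate(ZONES):
        if legend.get(str(i + 1)) != z:
            raise ValueError(f"zone legend mismatch at index {i + 1}: "
                             f"{legend.get(str(i + 1))!r} != {z!r}")
    return ZoneMap(labels=labels, pixel_size=float(legend["pixel_size_um"]))


def detections_to_frame(result: DetectionResult) -> pd.DataFrame:
    rows = []
    for d in result.cells:
        rows.append({
            "id": d.id,
            "row_px": d.centroid_px[0], "col_px": d.centroid_px[1],
            "x_um": d.centroid_um[1], "y_um": d.centroid_um[0],
            "area_um2": d.area_um2,
            "eq_diameter_um": d.equivalent_diameter_um,
            "zone": d.zone, "marker_positive": d.marker_positive,
        })
    return pd.DataFrame(rows, columns=[
        "id", "row_px", "col_px", "x_um", "y_um", "area_um2",
        "eq_diameter_um", "zone", "marker_positive",
    ])


def write_detections_csv(result: DetectionResult, path: str | Path) -> None:
    detections_to_frame(result).to_csv(path, index=False)
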