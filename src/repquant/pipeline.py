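"""Stage orchestration: simulate, quantify, benchmark.

Every reported number is a pure function of (inputs, config, seed); all
thresholds and defaults are echoed into the run report so a quantification is
auditable and reproducible.  Warnings (empty detections, undefined densities)
are machine-readable report fields, not just log text.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .colocalization import OverlapParams, call_double_positives, marker_mask, positive_area_fraction
from .detection import DetectionParams, compute_tissue_mask, detect_cells
from .fish import DotTable, cluster_dots, composition_stats, contribution_curve, contributor_slices, tag_fish_cells
from .io import detections_to_frame, read_stack, read_zone_map, write_stack, write_zone_map
from .metrics import detection_metrics
from .synthetic import SyntheticSpec, generate_fish_field, generate_section
from .zonation import ZONES, KidneyGeometry, assign_zones, estimate_total_cells, zone_density_report

__all__ = ["RunConfig", "run_simulate", "run_quantify", "run_benchmark"]


@dataclass
class RunConfig:
    """Configuration of a quantification run (one JSON document).

    Channel roles default to the canonical names; any stage whose inputs are
    missing (no marker threshold, no dot table) is skipped with a warning.
    """

    image_path: str | None = None
    zone_map_path: str | None = None
    dot_table_path: str | None = None
    output_dir: str = "results"
    detection: DetectionParams = field(default_factory=DetectionParams)
    overlap: OverlapParams = field(default_factory=OverlapParams)
    marker_threshold: int | None = None
    marker_name: str = "marker"
    cluster_radius_um: float = 5.0
    match_radius_um: float = 5.0
    geometry: KidneyGeometry | None = None
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        if "detection" in raw:
            raw["detection"] = DetectionParams(**raw["detection"])
        if "overlap" in raw:
            raw["overlap"] = OverlapParams(**raw["overlap"])
        if raw.get("geometry"):
            raw["geometry"] = KidneyGeometry(**raw["geometry"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _ensure_dir(path: str | Path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p


def run_simulate(spec: SyntheticSpec, output_dir: str | Path) -> dict:
    """Generate a synthetic section + FISH field and write it to disk.

    Writes the multi-channel TIFF, zone-map label image + legend, ground
    truth CSVs (cells, dots), and an echo of the generator parameters as
    JSON.  Deterministic per seed.
    """
    out = _ensure_dir(output_dir)
    stack, truth = generate_section(spec)
    dots, fish_truth = generate_fish_field(spec)
    write_stack(stack, out / "section.tiff")
    write_zone_map(truth.zone_map, out / "zones.tiff")
    truth.cells.to_csv(out / "truth_cells.csv", index=False)
    fish_truth.cells.to_csv(out / "truth_fish_cells.csv", index=False)
    fish_truth.dots.to_csv(out / "truth_dots.csv", index=False)
    dots.to_csv(out / "dots.csv")
    spec_dict = dataclasses.asdict(spec)
    (out / "spec.json").write_text(json.dumps(spec_dict, indent=1))
    return {"output_dir": str(out), "n_cells": int(len(truth.cells)),
            "n_dots": int(len(dots)), "spec": spec_dict}


def run_quantify(config: RunConfig, blinded: bool = False) -> dict:
    """Full quantification: detection → zonation → colocalization → FISH.

    Stages without configured inputs are skipped with a machine-readable
    warning.  Returns the run report (also written to the output directory as
    JSON, with stage CSVs alongside).
    """
    if config.image_path is None:
        raise ValueError("quantify requires image_path")
    out = _ensure_dir(config.output_dir)
    report: dict = {
        "version": __version__, "seed": config.seed,
        "config": config.to_dict(), "warnings": [], "stages": {},
    }
    t0 = time.perf_counter()
    stack = read_stack(config.image_path)
    if "reporter" not in stack.channels:
        raise ValueError("stage detection failed: no reporter channel")
    result = detect_cells(stack.channels["reporter"], stack.pixel_size,
                          config.detection)
    report["warnings"].extend(result.warnings)
    tissue = None
    if "nuclei" in stack.channels:
        tissue = compute_tissue_mask(stack.channels["nuclei"], stack.pixel_size,
                                     config.detection)
        report["warnings"].extend(tissue.warnings)
    report["stages"]["detection"] = {
        "n_cells": len(result.cells), "otsu_threshold": result.threshold,
        "tissue_area_mm2": tissue.area_mm2 if tissue else None,
        "seconds": round(time.perf_counter() - t0, 3),
    }

    if config.zone_map_path:
        zone_map = read_zone_map(config.zone_map_path)
        result.cells = assign_zones(result.cells, zone_map, stack.shape)
        dens = zone_density_report(result.cells, zone_map)
        report["warnings"].extend(dens.warnings)
        zone_rows = [{
            "zone": z, "count": s.count, "area_mm2": s.area_mm2,
            "density_per_mm2": s.density_per_mm2, "percent": s.percent,
        } for z, s in dens.zones.items()]
        pd.DataFrame(zone_rows).to_csv(out / "zone_report.csv", index=False)
        report["stages"]["zonation"] = {
            "per_zone_counts": {z: dens.zones[z].count for z in ZONES},
            "n_unassigned": dens.n_unassigned,
            "whole_slice_density_per_mm2": dens.whole_slice_density_per_mm2,
        }
        if config.geometry is not None and dens.whole_slice_density_per_mm2:
            extrap = estimate_total_cells(dens.whole_slice_density_per_mm2,
                                          config.geometry)
            report["stages"]["extrapolation"] = dataclasses.asdict(extrap)
    else:
        report["warnings"].append("no zone map configured; zonation skipped")

    if config.marker_threshold is not None and "marker" in stack.channels:
        mmask = marker_mask(stack.channels["marker"], config.marker_threshold,
                            config.marker_name)
        result.cells, summary = call_double_positives(result.cells, mmask,
                                                      config.overlap)
        coloc: dict = dataclasses.asdict(summary)
        if tissue is not None and tissue.area_mm2 > 0:
            coloc["positive_area_fraction"] = positive_area_fraction(mmask, tissue)
        report["stages"]["colocalization"] = coloc
    else:
        report["warnings"].append(
            "no marker threshold/channel configured; colocalization skipped")

    if config.dot_table_path:
        dots = DotTable.from_csv(config.dot_table_path)
        fish_cells = cluster_dots(dots, config.cluster_radius_um)
        fish_cells = tag_fish_cells(fish_cells, result.cells, stack.pixel_size,
                                    match_radius=config.match_radius_um)
        comp = composition_stats(fish_cells, result.cells)
        counts = fish_cells.counts
        fish_report: dict = {
            "n_fish_cells": len(fish_cells),
            "composition": dataclasses.asdict(comp),
        }
        if counts.size and counts.sum() > 0:
            curve = contribution_curve(counts)
            fish_report["top_decile_transcript_share"] = float(
                contributor_slices(curve, [0.1])[0])
        pd.DataFrame({
            "cell_id": [c.id for c in fish_cells.cells],
            "n_dots": [c.dot_count for c in fish_cells.cells],
            "x_um": [c.centroid_um[0] for c in fish_cells.cells],
            "y_um": [c.centroid_um[1] for c in fish_cells.cells],
            "tagged": [c.tagged for c in fish_cells.cells],
        }).to_csv(out / "fish_cells.csv", index=False)
        report["stages"]["fish"] = fish_report
    else:
        report["warnings"].append("no dot table configured; FISH stage skipped")

    frame = detections_to_frame(result)
    if blinded:
        report["blinded"] = True
    frame.to_csv(out / "detections.csv", index=False)
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report


def run_benchmark(
    seeds: list[int],
    spec: SyntheticSpec | None = None,
    match_radius_um: float = 5.0,
) -> pd.DataFrame:
    """Detection precision/recall, zone-assignment accuracy and top-decile
    contribution share across seeds, on freshly generated synthetic sections.
    """
    if not seeds:
        raise ValueError("benchmark requires at least one seed")
    base = spec or SyntheticSpec()
    rows = []
    for seed in seeds:
        sp = dataclasses.replace(base, seed=int(seed))
        stack, truth = generate_section(sp)
        result = detect_cells(stack.channels["reporter"], sp.pixel_size)
        m = detection_metrics(truth.cells, result, match_radius_um)
        cells = assign_zones(result.cells, truth.zone_map, stack.shape)
        correct = 0
        for ti, di in m.matches:
            if cells[di].zone == truth.cells.iloc[ti]["zone"]:
                correct += 1
        zone_acc = correct / len(m.matches) if m.matches else float("nan")
        dots, fish_truth = generate_fish_field(sp)
        fish_cells = cluster_dots(dots)
        counts = fish_cells.counts
        share = float(contributor_slices(contribution_curve(counts), [0.1])[0]) \
            if counts.size and counts.sum() else float("nan")
        rows.append({
            "seed": seed, "n_truth": m.n_truth, "n_detected": m.n_detected,
            "precision": m.precision, "recall": m.recall,
            "zone_accuracy": zone_acc,
            "top_decile_share": share,
        })
    return pd.DataFrame(rows)
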