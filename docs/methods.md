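# Methods

## Detection model

Reporter-cell counting treats a whole-slice fluorescence image as a mixture
of a dark, noisy background and bright, roughly disk-shaped cells. The chain
is: min–max rescale to 8-bit (rounding half up; a constant channel maps to
all zeros) → median background subtraction → Otsu binarization → connected
components → size filter.

* **Background subtraction before thresholding.** The two operations only
  both matter in this order: a global Otsu threshold on an image with
  low-frequency background variation either clips cells or admits background,
  whereas thresholding the flattened image separates the two classes cleanly.
  The background estimate is the sliding median over a disk of radius 50 µm —
  large against the 10–25 µm cells, so cells do not contaminate their own
  background — computed with the 8-bit sliding-histogram median
  (`skimage.filters.rank.median`); the radius must be ≥ 3 px.
* **Otsu threshold.** Computed in exact integer arithmetic (cross-multiplied
  rational comparison of the between-class variance over all 255 splits of
  the 256-bin histogram), so the result equals exhaustive search by
  construction and ties resolve deterministically to the smallest maximizing
  level. Foreground is strictly above the threshold. A histogram with fewer
  than two populated bins has no separable classes and raises; `detect_cells`
  converts that into an empty result with a `no detectable signal` warning.
* **Size filter.** A component is a cell when its equivalent-circle diameter
  `2·sqrt(area/π)` (from the physical area in µm²) is ≥ `min_diameter`
  (default 10 µm, inclusive). Components are not split: touching cells count
  as one, a deliberate simplification (see limitations). Connectivity
  defaults to 8-neighbour; border-touching components are kept, since whole
  slide frames border slide background, not truncated tissue. Detections are
  reported sorted by centroid (row, col), 0-based pixel coordinates, physical
  position = index · pixel size.
* **Tissue mask.** DAPI channel → Gaussian smooth (default σ 10 µm) → Otsu →
  morphological close (disk, default 20 µm) → largest connected component →
  fill holes. Area is reported in mm².

**Operating regime.** A global Otsu threshold needs the cell class to carry
non-negligible between-class weight. With cells at ≥ 5× the noise SD and cell
pixels ≳ 1% of the frame the split lands between noise and signal and
recovery is essentially perfect (the benchmark measures precision = recall =
1.0 at defaults). At much sparser cell fractions or lower contrast, the
maximizing split can fall inside the noise distribution and precision
collapses — the classic small-foreground failure of Otsu's method. The
serial-section simulation therefore plants a dense field (50,000 cells,
noise SD 10 at cell intensity 150); the behaviour at the regime boundary is a
property of the method, not of the implementation.

## Zonation and extrapolation

Zone maps are curated label images (background + cortex, OSOM, ISOM, IM,
papilla), not computed: anatomical zoning of real sections is manual, and the
synthetic generator supplies procedural maps. Zone membership is decided by
the detection's centroid pixel only — the simplest rule consistent with point
counting; centroids on background are "unassigned", excluded from per-zone
percentages but reported, so totals stay auditable. Zones with zero area are
flagged (density undefined), never reported as density 0.

Whole-kidney totals assume the kidney is an ellipsoid
(`V = (π/6)·L·W·D`, axes in mm measured on centric sections) and that a
section of thickness `t` samples a slab of volume `area·t`, so
`N = (ρ_A/t)·V`. No over-projection (Abercrombie) correction is applied:
cells thicker than the default 12 µm section are over-counted, and in
projection two cells closer than the sum of their radii merge into one
component and are under-counted. On the synthetic 3D field these biases
partially cancel and recovery is within ~3–7% of the planted total; both
biases are properties of plain 2D→3D extrapolation. Multiple slices are
combined as the mean of per-slice densities.

## Colocalization

Marker thresholds are required configuration inputs, fixed per experiment —
never auto-chosen — because IF marker intensity scales are arbitrary and the
meaningful contract is that one threshold is maintained across all compared
images. The double-positive rule is kept in pixels (≥ 10 px overlap of the
detection's component pixel set with the marker mask, inclusive) exactly as
practised, with the pixel size recorded so reports expose the physical
meaning; at the default 1.5 µm/px, 10 px ≈ 22.5 µm².

## FISH clustering and contribution statistics

"Dots within a maximal proximity of 5 µm share one cell of origin" is
implemented as single-linkage clustering with inclusive 5 µm edges — the only
reading under which dots chained through intermediate dots form one cluster.
The implementation (KD-tree pair query + union-find) is verified against an
independent transitive-closure oracle on the full distance matrix; increasing
the radius can only merge clusters.

Manually annotated dot tables (CSV: `x_um, y_um[, channel]`) are the
canonical input. An automated local-maximum blob detector exists only so
synthetic end-to-end runs need no manual step; dots closer than the detector
scale may merge (flagged via the table's `source` field) and detector-derived
tables are excluded from recovery statistics.

FISH cells are co-labelled with reporter detections by containment of the
cluster centroid in a detection's pixel set, falling back to a 5 µm
centroid-distance match — mirroring visual double-positive counting on the
same section. Composition statistics report both directions (percent of
reporter cells that are FISH⁺, percent of FISH cells that are tagged) with
numerators and denominators; zero denominators yield "undefined", never 0.

The contribution curve sorts per-cell counts descending and accumulates cell
and transcript fractions; shares at arbitrary cell-fraction cutoffs are read
off by linear interpolation, which also resolves ties at the cutoff rank.
High/low contributor cutoffs are explicit arguments — the analysis does not
guess a count threshold.

## Washout kinetics

CO-Hb saturation declines linearly after exposure ends, clamped at the
endogenous baseline. The fit is OLS on points strictly above
`baseline + baseline_sd` (clamped points would bias the slope), requiring ≥ 3
usable points and a negative slope. The half-life is defined on the
above-baseline saturation under the linear model:
`(S₀ − baseline)/(2·|slope|)`, with `S₀` the fitted value at the series'
first time point — this makes the quantity invariant to relabelling the time
origin and coincides with the fitted intercept when the series starts at
t = 0. Per-series fits are averaged across animals rather than pooled.

## Synthetic generator

The generator emulates the statistical structure the pipeline assumes:

* **Geometry.** Tissue is an ellipse (~64% of the frame); zones are five
  concentric elliptical bands whose radial widths are the generator's
  `zone_band_fractions` (outermost = cortex). Default frame 768×1024 px at
  1.5 µm/px ≈ 1.15×1.5 mm.
* **Cells.** Disks of 12–20 µm diameter at 8-bit intensity 150 over Gaussian
  noise (SD 20, i.e. 7.5× contrast), placed per zone by rejection sampling
  that forbids overlap with tubules and other cells (bounded attempts;
  explicit shortfall error) — reporter cells are strictly peritubular and
  interstitial. Default per-zone counts (60, 100, 50, 20, 10) concentrate
  cells at the corticomedullary bands, chosen for testability; real per-zone
  abundances vary.
* **Tubules and channels.** Autofluorescent tubule texture is stamped as
  random disks to a 30% tissue coverage. The reporter channel's background
  offset is frame-wide (no tissue step), as a camera offset is — a step at
  the tissue rim would otherwise ring under median subtraction.
* **Marker.** Each cell is marker-positive with probability 0.25 (Bernoulli);
  positive cells' disks are painted into the marker channel, plus extra
  marker area (5% of tissue) kept clear of all cells so the planted Bernoulli
  truth is exact.
* **FISH counts.** Per-cell transcript counts are negative binomial
  (mean 8, dispersion 1.5; variance = mean + mean²/dispersion;
  dispersion → ∞ recovers Poisson). The dispersion was calibrated once by
  Monte-Carlo so the expected top-decile transcript share is 0.30,
  reproducing the observed burst heterogeneity in which ~9–10% of cells carry
  ~29–30% of transcripts. With `separable=True`, dots are confined within
  radius/2 of their cell centroid and centroids are kept > 2.5 radii apart,
  so single-linkage clustering provably recovers one cluster per dot-bearing
  cell; cells drawing zero counts leave no dots and are invisible to
  dot-based statistics (contribution shares computed from clustered dots
  therefore condition on expressing cells).
* **Serial sections.** `simulate_sectioned_kidney` plants cells uniformly in
  the kidney ellipsoid and renders every cell whose centre falls in a 12 µm
  slab at 7 evenly spaced depths (within ±45% of the half-depth, where
  cross-sections remain large).
* **Randomness.** One seed feeds counter-based Philox streams split per
  purpose (placement, tubules, marker, per-channel noise, FISH), so outputs
  are bitwise reproducible and stages stay independently perturbable.

What the generator does **not** emulate: optical PSF beyond Gaussian dot
jitter, nucleus-scale texture, uneven illumination, anatomically realistic
zone shapes, 3D stacks, or cell-shape variation (cells are disks). Passing
recovery tests therefore demonstrates correctness of the operators under the
model's assumptions, not segmentation performance on real histology.

## Problem sizes and numerical choices

The recovery benchmarks use 300-cell frames across 10 seeds, 400-cell frames
for the double-positive rate, a 50,000-cell ellipsoid for extrapolation and
20 seeds × 400 cells for contribution statistics — sizes at which binomial
and Poisson sampling errors are a few percent, matched to the tolerances the
checks assert. Degenerate inputs are contracts, not accidents: blank frames
warn and return empty, zero denominators return "undefined", zero-area zones
are flagged, all-zero count vectors raise. Floating-point summation order is
fixed throughout, so reruns reproduce results bitwise.

## Known limitations

* Touching reporter cells are counted as one component (no watershed split).
* Plain 2D→3D extrapolation over-counts thick cells and under-counts
  projection-merged ones; no Abercrombie correction.
* Global Otsu fails when the foreground class is a vanishing fraction of the
  frame (documented operating regime above).
* The automated dot detector merges dots below its resolution scale; manual
  tables remain canonical.
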