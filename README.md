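# repquant

Whole-slide fluorescence quantification of renal erythropoietin-producing
(REP) reporter cells.

REP cells are fibroblast-like interstitial cells of the kidney that switch
erythropoietin (Epo) transcription on under hypoxia. Fate-mapping experiments
permanently tag active REP cells with a red fluorescent reporter (tdTomato)
and then ask, on whole kidney sections: how many tagged cells are there,
where do they sit across the renal compartments, how many per whole kidney,
which of them co-express injury or myofibroblast markers, and how unevenly is
Epo transcription distributed across cells. `repquant` implements that
quantification chain as a tested, reusable package, together with a
synthetic-section generator with exhaustive ground truth so every stage can
be validated without microscope data.

## The quantification chain

* **Detection** — channels are reduced to 8-bit grayscale; the reporter
  channel is flattened by median background subtraction (default radius
  50 µm), binarized with Otsu's method (threshold `t` maximizing the
  between-class variance of the split `{≤t, >t}`, computed exactly over all
  255 splits), and connected components with equivalent-circle diameter
  `2·sqrt(area/π) ≥ 10 µm` are counted as reporter⁺ cells. Tissue area comes
  from the DAPI channel (Gaussian smooth → Otsu → morphological close →
  largest component → fill holes).
* **Zonation** — each detection is assigned the renal compartment (cortex,
  OSOM, ISOM, IM, papilla) at its centroid pixel of a curated zone label
  image; per-zone densities (cells/mm²) and percentage distributions follow.
* **Extrapolation** — kidney volume from the ellipsoid equation
  `V = (π/6)·L·W·D`; a section of thickness `t` converts areal density `ρ_A`
  to the whole-kidney total `N = (ρ_A / t) · V`.
* **Colocalization** — marker channels are binarized at fixed, experiment-wide
  grayscale thresholds; a cell is double-positive when its pixel set overlaps
  the marker mask by ≥ 10 pixels (inclusive).
* **FISH quantification** — single-molecule FISH dots (1 dot ≈ 1 mRNA) are
  clustered by single linkage at an inclusive 5 µm radius; per-cluster counts
  feed a Lorenz-type cumulative contribution curve, from which the transcript
  share of the top x% of cells ("high contributors") is interpolated.
* **Kinetics** — carboxyhaemoglobin washout is fitted by OLS on the
  above-baseline points; the half-life is
  `(S₀ − baseline) / (2·|slope|)`, the time for the above-baseline
  saturation to halve under the linear decline.

## Worked example

The numbered drivers under `analysis/` run the whole chain on a synthetic
section (240 planted cells, seed 1):

```bash
python analysis/01_simulate_section.py
python analysis/02_detect_and_zone.py
```

```
detected 240 cells (240 planted); per-zone detected vs planted:
  cortex     60 vs   60
  OSOM      100 vs  100
  ISOM       50 vs   50
  IM         20 vs   20
  papilla    10 vs   10
whole-slice density: 213.3 cells/mm²
extrapolated total for a 12x7x6 mm kidney: 4,691,107 cells (V = 264 mm³)
```

All 240 planted cells are recovered and assigned to the correct compartment;
the extrapolated total is the whole-slice density converted to a volumetric
density (12 µm sections) times the ellipsoid volume. `03_colocalization.py`
reproduces the planted 25.4% marker-positive fraction with the 10-pixel
overlap rule, and `04_fish_contribution.py` summarizes the burst structure of
the planted transcript counts:

```
1895 dots -> 217 cells (mean 8.7 dots/cell, max 54)
top 9.4% of cells carry 28.6 % of transcripts
top decile of cells carries 29.9 % of transcripts
```

i.e. a small minority of cells carries ~30% of all transcripts, the hallmark
of bursty Epo transcription. `05_washout_kinetics.py` fits a noisy washout
series generated at the published physiology (54.8% → 4.57% CO-Hb) and
recovers a ~35 min half-life.

A `repquant` console command exposes the same stages
(`simulate`, `quantify`, `fish`, `washout`, `benchmark`) for use on real
TIFF stacks and manually annotated dot CSVs.

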