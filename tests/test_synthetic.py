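import dataclasses
from math import inf

import numpy as np
import pandas as pd
import pytest

from repquant import (
    KidneyGeometry,
    PlacementError,
    SyntheticSpec,
    generate_fish_field,
    generate_section,
    generate_washout_series,
    simulate_sectioned_kidney,
)
from conftest import brute_force_clusters


class TestSpecValidation:
    def test_zone_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticSpec(zone_band_fractions=(0.3, 0.2, 0.2, 0.2, 0.2))

    def test_probabilities_bounded(self):
        with pytest.raises(ValueError):
            SyntheticSpec(marker_overlap_prob=1.5)

    def test_negative_cell_counts_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(n_cells_per_zone=(-1, 0, 0, 0, 0))


class TestGenerateSection:
    def test_same_seed_bitwise_identical(self, small_spec):
        stack_a, truth_a = generate_section(small_spec)
        stack_b, truth_b = generate_section(small_spec)
        for name in stack_a.channels:
            assert np.array_equal(stack_a.channels[name], stack_b.channels[name])
        pd.testing.assert_frame_equal(truth_a.cells, truth_b.cells)
        assert np.array_equal(truth_a.zone_map.labels, truth_b.zone_map.labels)

    def test_different_seed_differs(self, small_spec):
        other = dataclasses.replace(small_spec, seed=small_spec.seed + 1)
        stack_a, _ = generate_section(small_spec)
        stack_b, _ = generate_section(other)
        assert not np.array_equal(stack_a.channels["reporter"],
                                  stack_b.channels["reporter"])

    def test_no_cells_gives_pure_noise_reporter(self):
        spec = SyntheticSpec(image_shape=(256, 256),
                             n_cells_per_zone=(0, 0, 0, 0, 0), seed=1)
        stack, truth = generate_section(spec)
        assert len(truth.cells) == 0
        # background 20 plus noise never reaches the planted cell intensity
        assert stack.channels["reporter"].max() < spec.cell_intensity

    def test_cells_only_in_requested_zone(self):
        spec = SyntheticSpec(image_shape=(512, 512),
                             n_cells_per_zone=(0, 50, 0, 0, 0), seed=3)
        _, truth = generate_section(spec)
        assert len(truth.cells) == 50
        assert set(truth.cells.zone) == {"OSOM"}
        labels = truth.zone_map.labels
        for _, cell in truth.cells.iterrows():
            assert labels[cell.row_px, cell.col_px] == 2  # OSOM index

    def test_per_zone_counts_match_spec(self, small_spec, small_section):
        _, truth = small_section
        counts = truth.cells.zone.value_counts()
        from repquant.zonation import ZONES
        for zone, expected in zip(ZONES, small_spec.n_cells_per_zone):
            assert counts.get(zone, 0) == expected

    def test_centroids_inside_tissue_and_outside_tubules(self, small_section):
        _, truth = small_section
        r = truth.cells.row_px.to_numpy()
        c = truth.cells.col_px.to_numpy()
        assert truth.tissue_mask[r, c].all()
        assert not truth.tubule_mask[r, c].any()

    def test_impossible_placement_reports_shortfall(self):
        spec = SyntheticSpec(image_shape=(96, 96), pixel_size=1.5,
                             n_cells_per_zone=(500, 0, 0, 0, 0), seed=0)
        with pytest.raises(PlacementError, match="shortfall"):
            generate_section(spec)


class TestGenerateFishField:
    def test_poisson_limit_mean_within_3_se(self):
        spec = SyntheticSpec(fish_count_distribution=(5.0, inf), seed=11)
        _, truth = generate_fish_field(spec, n_cells=1000)
        counts = truth.cells.fish_count.to_numpy()
        se = np.sqrt(5.0 / 1000)
        assert abs(counts.mean() - 5.0) <= 3 * se

    def test_zero_cells_empty_table(self):
        spec = SyntheticSpec(seed=2)
        dots, truth = generate_fish_field(spec, n_cells=0)
        assert len(dots) == 0
        assert len(truth.cells) == 0

    def test_dot_counts_equal_ground_truth_counts(self):
        spec = SyntheticSpec(seed=4)
        dots, truth = generate_fish_field(spec, n_cells=60)
        per_parent = truth.dots.groupby("parent_cell_id").size()
        for _, cell in truth.cells.iterrows():
            assert per_parent.get(cell.id, 0) == cell.fish_count
        assert len(dots) == truth.cells.fish_count.sum()

    def test_separable_placement_one_cluster_per_cell(self):
        spec = SyntheticSpec(seed=5)
        _, truth = generate_fish_field(spec, n_cells=40, separable=True,
                                       cluster_radius=5.0)
        pts = truth.dots[["x_um", "y_um"]].to_numpy()
        clusters = brute_force_clusters(pts, 5.0)
        n_cells_with_dots = (truth.cells.fish_count > 0).sum()
        assert len(clusters) == n_cells_with_dots
        # each brute-force cluster maps to exactly one parent cell
        parents = truth.dots.parent_cell_id.to_numpy()
        for members in clusters:
            assert len({parents[i] for i in members}) == 1

    def test_overcrowded_separable_request_fails(self):
        spec = SyntheticSpec(image_shape=(64, 64), pixel_size=1.0, seed=6)
        with pytest.raises(PlacementError):
            generate_fish_field(spec, n_cells=500, separable=True)

    def test_deterministic_per_seed(self):
        spec = SyntheticSpec(seed=9)
        dots_a, _ = generate_fish_field(spec, n_cells=30)
        dots_b, _ = generate_fish_field(spec, n_cells=30)
        assert np.array_equal(dots_a.x_um, dots_b.x_um)
        assert np.array_equal(dots_a.y_um, dots_b.y_um)


class TestWashoutSeries:
    def test_noiseless_line_exact(self):
        s = generate_washout_series(54.8, 4.57, -1.0, np.array([0.0, 10.0]))
        assert s.saturations_pct[1] == pytest.approx(44.8)

    def test_clamps_at_baseline_for_large_t(self):
        s = generate_washout_series(54.8, 4.57, -1.0,
                                    np.array([0.0, 100.0, 200.0]))
        assert s.saturations_pct[-1] == pytest.approx(4.57)

    def test_nonnegative_slope_rejected(self):
        with pytest.raises(ValueError):
            generate_washout_series(54.8, 4.57, 0.5, np.array([0.0, 1.0]))

    def test_start_must_exceed_baseline(self):
        with pytest.raises(ValueError):
            generate_washout_series(4.0, 4.57, -1.0, np.array([0.0, 1.0]))

    def test_noise_deterministic_per_seed(self):
        t = np.arange(0, 60, 5.0)
        a = generate_washout_series(54.8, 4.57, -0.7, t, noise_sd=2.0, seed=3)
        b = generate_washout_series(54.8, 4.57, -0.7, t, noise_sd=2.0, seed=3)
        assert np.array_equal(a.saturations_pct, b.saturations_pct)


class TestSectionedKidney:
    def test_truth_counts_and_determinism(self):
        geom = KidneyGeometry(2.0, 1.4, 1.4)
        kid_a = simulate_sectioned_kidney(geom, 2000, n_sections=3,
                                          image_shape=(760, 1060), seed=8)
        kid_b = simulate_sectioned_kidney(geom, 2000, n_sections=3,
                                          image_shape=(760, 1060), seed=8)
        assert kid_a.planted_total == 2000
        assert kid_a.section_truth_counts == kid_b.section_truth_counts
        assert np.array_equal(kid_a.sections[0].channels["reporter"],
                              kid_b.sections[0].channels["reporter"])
        # a 12 µm slab of a ~1.4 mm kidney holds a tiny fraction of the cells
        assert 0 < sum(kid_a.section_truth_counts) < 200
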