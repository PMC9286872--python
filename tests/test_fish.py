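import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repquant.detection import CellDetection
from repquant.fish import (
    DotTable,
    cluster_dots,
    composition_stats,
    contribution_curve,
    contributor_slices,
    detect_dots,
    tag_fish_cells,
)
from conftest import brute_force_clusters


def _table(xy):
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    return DotTable(xy[:, 0], xy[:, 1])


def _partition(cell_set):
    return {frozenset(int(i) for i in c.member_dot_ids)
            for c in cell_set.cells}


class TestClusterDots:
    def test_three_dot_chain_is_one_cluster(self):
        # links of 4 and 5 µm chain the three dots into one cell
        cells = cluster_dots(_table([(0, 0), (0, 4), (0, 9)]), 5.0)
        assert len(cells) == 1
        assert cells.cells[0].dot_count == 3

    def test_grid_beyond_radius_stays_singletons(self):
        xs, ys = np.meshgrid(np.arange(0, 30, 6.0), np.arange(0, 30, 6.0))
        table = DotTable(xs.ravel(), ys.ravel())
        cells = cluster_dots(table, 5.0)
        assert len(cells) == len(table)
        assert all(c.dot_count == 1 for c in cells.cells)

    def test_radius_is_inclusive(self):
        cells = cluster_dots(_table([(0, 0), (5.0, 0)]), 5.0)
        assert len(cells) == 1

    def test_empty_table(self):
        cells = cluster_dots(_table(np.empty((0, 2))), 5.0)
        assert len(cells) == 0

    def test_centroid_is_member_mean(self):
        cells = cluster_dots(_table([(0, 0), (4, 0)]), 5.0)
        assert cells.cells[0].centroid_um == pytest.approx((2.0, 0.0))

    def test_matches_brute_force_on_random_geometries(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(1, 80))
            pts = rng.uniform(0, 60, size=(n, 2))
            ours = _partition(cluster_dots(DotTable(pts[:, 0], pts[:, 1]), 5.0))
            brute = set(brute_force_clusters(pts, 5.0))
            assert ours == brute

    def test_cluster_count_non_increasing_in_radius(self):
        rng = np.random.default_rng(23)
        pts = rng.uniform(0, 100, size=(120, 2))
        table = DotTable(pts[:, 0], pts[:, 1])
        counts = [len(cluster_dots(table, r)) for r in (1, 2, 5, 10, 25)]
        assert counts == sorted(counts, reverse=True)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            cluster_dots(_table([(0, 0)]), 0.0)


def _detection(id_, rows, cols, pixel_size=1.0):
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    return CellDetection(
        id=id_, centroid_px=(float(rows.mean()), float(cols.mean())),
        centroid_um=(float(rows.mean()) * pixel_size,
                     float(cols.mean()) * pixel_size),
        area_um2=float(rows.size) * pixel_size**2,
        equivalent_diameter_um=12.0, pixel_rows=rows, pixel_cols=cols,
    )


class TestTagFishCells:
    def _fish_at(self, x, y):
        return cluster_dots(_table([(x, y)]), 5.0)

    def test_centroid_inside_component_is_tagged(self):
        det = _detection(3, np.repeat(np.arange(10, 20), 10),
                         np.tile(np.arange(10, 20), 10))
        tagged = tag_fish_cells(self._fish_at(15.0, 15.0), [det], 1.0)
        assert tagged.cells[0].tagged is True
        assert tagged.cells[0].matched_detection_id == 3

    def test_nearby_centroid_within_match_radius_tagged(self):
        det = _detection(1, np.array([10]), np.array([10]))
        tagged = tag_fish_cells(self._fish_at(13.0, 10.0), [det], 1.0,
                                match_radius=5.0)
        assert tagged.cells[0].tagged is True

    def test_detection_20um_away_untagged(self):
        det = _detection(1, np.array([10]), np.array([10]))
        tagged = tag_fish_cells(self._fish_at(30.0, 10.0), [det], 1.0)
        assert tagged.cells[0].tagged is False

    def test_calibration_mismatch_raises(self):
        det = _detection(1, np.array([10]), np.array([10]))
        with pytest.raises(ValueError, match="calibration"):
            tag_fish_cells(self._fish_at(0, 0), [det], 1.0,
                           detection_pixel_size=2.0)

    def test_synthetic_coplacement_fraction_recovered(self, small_section):
        # place FISH cells on a known 30% subset of planted reporter cells
        stack, truth = small_section
        rng = np.random.default_rng(5)
        chosen = rng.random(len(truth.cells)) < 0.30
        dets = []
        for _, cell in truth.cells.iterrows():
            rr = np.arange(cell.row_px - 2, cell.row_px + 3)
            dets.append(_detection(
                int(cell.id), np.repeat(rr, 5),
                np.tile(np.arange(cell.col_px - 2, cell.col_px + 3), 5),
                stack.pixel_size))
        xy = truth.cells[["x_um", "y_um"]].to_numpy()[chosen]
        fish = cluster_dots(DotTable(xy[:, 0], xy[:, 1]), 5.0)
        tagged = tag_fish_cells(fish, dets, stack.pixel_size)
        assert all(c.tagged for c in tagged.cells)
        frac = sum(c.tagged for c in tagged.cells) / len(truth.cells)
        se = np.sqrt(0.3 * 0.7 / len(truth.cells))
        assert abs(chosen.mean() - 0.30) <= 3 * se
        assert frac == pytest.approx(chosen.mean())


class TestCompositionStats:
    def _fish_set(self, n, tagged_ids):
        pts = np.arange(n, dtype=float) * 100.0
        cells = cluster_dots(DotTable(pts, np.zeros(n)), 5.0)
        for i, c in enumerate(cells.cells):
            c.tagged = i in tagged_ids
            c.matched_detection_id = i if i in tagged_ids else None
        return cells

    def test_worked_example_25_and_5_percent(self):
        # 40 reporter cells, 10 of them FISH-positive; 200 FISH cells
        dets = [_detection(i, np.array([i]), np.array([0])) for i in range(40)]
        fish = self._fish_set(200, set(range(10)))
        stats = composition_stats(fish, dets)
        assert stats.percent_tagged_cells_fish_positive == pytest.approx(25.0)
        assert stats.percent_fish_cells_tagged == pytest.approx(5.0)

    def test_full_overlap_both_100(self):
        dets = [_detection(i, np.array([i]), np.array([0])) for i in range(5)]
        stats = composition_stats(self._fish_set(5, set(range(5))), dets)
        assert stats.percent_tagged_cells_fish_positive == 100.0
        assert stats.percent_fish_cells_tagged == 100.0

    def test_disjoint_sets_both_0(self):
        dets = [_detection(i, np.array([i]), np.array([0])) for i in range(5)]
        stats = composition_stats(self._fish_set(5, set()), dets)
        assert stats.percent_tagged_cells_fish_positive == 0.0
        assert stats.percent_fish_cells_tagged == 0.0

    def test_zero_denominators_flagged_undefined(self):
        stats = composition_stats(self._fish_set(0, set()), [])
        assert stats.percent_tagged_cells_fish_positive is None
        assert stats.percent_fish_cells_tagged is None
        assert len(stats.undefined) == 2

    def test_untagged_input_rejected(self):
        pts = np.array([0.0])
        fish = cluster_dots(DotTable(pts, pts), 5.0)
        with pytest.raises(ValueError, match="tagged first"):
            composition_stats(fish, [])


class TestContributionCurve:
    def test_hand_example_top20_carries_71_percent(self):
        curve = contribution_curve([10, 1, 1, 1, 1])
        share = contributor_slices(curve, [0.2])[0]
        assert share == pytest.approx(10 / 14, abs=1e-9)

    def test_uniform_counts_on_diagonal(self):
        curve = contribution_curve([3, 3, 3, 3])
        assert np.allclose(curve.transcript_fraction, curve.cell_fraction)
        assert contributor_slices(curve, [0.5])[0] == pytest.approx(0.5)

    def test_single_cell_is_point_1_1(self):
        curve = contribution_curve([7])
        assert curve.cell_fraction[-1] == 1.0
        assert curve.transcript_fraction[-1] == 1.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            contribution_curve([0, 0, 0])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            contribution_curve([1, -1])

    def test_cutoff_outside_unit_interval_rejected(self):
        curve = contribution_curve([1, 2])
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                contributor_slices(curve, [bad])

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=1,
                    max_size=60).filter(lambda c: sum(c) > 0))
    def test_dominance_and_endpoints(self, counts):
        curve = contribution_curve(counts)
        assert np.all(curve.transcript_fraction >= curve.cell_fraction - 1e-12)
        assert curve.cell_fraction[-1] == pytest.approx(1.0)
        assert curve.transcript_fraction[-1] == pytest.approx(1.0)
        assert np.all(np.diff(curve.transcript_fraction) >= -1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 30, 50)
        counts[0] = 5
        a = contributor_slices(contribution_curve(counts), [0.1, 0.5])
        b = contributor_slices(
            contribution_curve(rng.permutation(counts)), [0.1, 0.5])
        assert np.allclose(a, b)


class TestDetectDots:
    def test_planted_isolated_dots_recovered(self):
        rng = np.random.default_rng(8)
        img = np.zeros((200, 200))
        centers = [(20 + 40 * i, 20 + 40 * j) for i in range(5) for j in range(4)]
        for r, c in centers:
            img[r, c] = 255.0
        table = detect_dots(img + rng.normal(0, 2, img.shape), pixel_size=1.0)
        assert len(table) == 20
        assert table.source == "detector"
        found = np.sort(np.column_stack([table.y_um, table.x_um]), axis=0)
        planted = np.sort(np.array(centers, dtype=float), axis=0)
        assert np.all(np.abs(found - planted) <= 1.0)

    def test_blank_channel_empty(self):
        assert len(detect_dots(np.zeros((50, 50)), 1.0)) == 0


class TestDotTableIO:
    def test_csv_round_trip(self, tmp_path):
        table = _table([(1.5, 2.5), (3.0, 4.0)])
        p = tmp_path / "dots.csv"
        table.to_csv(p)
        back = DotTable.from_csv(p)
        assert np.allclose(back.x_um, table.x_um)
        assert np.allclose(back.y_um, table.y_um)
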