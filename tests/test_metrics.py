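import numpy as np
import pytest

from lysoscreen import (
    aggregate_colocalization,
    circle_mask,
    clustering_ratio,
    clustering_value,
    fraction_pixels_above_threshold,
    peripheral_cell_fraction,
)
from lysoscreen.errors import DataError, ValidationError
from lysoscreen.metrics import normalize_to_control
from lysoscreen.mtoc import MtocCall
from lysoscreen.segmentation import LabelMask, central_region

PX = 0.325


def _call(pos, label=1):
    return MtocCall(label, pos, 1.0, True)


class TestCircleMask:
    def test_matches_bruteforce_distance_oracle(self, rng):
        """100+ random centres/diameters vs a per-pixel distance loop."""
        shape = (40, 40)
        for _ in range(120):
            center = tuple(rng.uniform(0, 39, 2))
            diameter = float(rng.uniform(0.5, 20)) * PX
            mask = circle_mask(center, diameter, PX, shape)
            radius_px = diameter / 2 / PX
            oracle = np.zeros(shape, bool)
            for i in range(shape[0]):
                for j in range(shape[1]):
                    if np.hypot(i - center[0], j - center[1]) <= radius_px:
                        oracle[i, j] = True
            if not oracle.any():
                oracle[int(round(center[0])), int(round(center[1]))] = True
            np.testing.assert_array_equal(mask, oracle)

    def test_area_close_to_analytic_disk(self):
        mask = circle_mask((100.0, 100.0), 40 * PX, PX, (200, 200))
        assert mask.sum() == pytest.approx(np.pi * 20**2, rel=0.02)

    def test_corner_centre_quarter_disk(self):
        full = circle_mask((100.0, 100.0), 30 * PX, PX, (200, 200)).sum()
        quarter = circle_mask((0.0, 0.0), 30 * PX, PX, (200, 200)).sum()
        # the corner quarter keeps both boundary half-axes (~r pixels each
        # shared between adjacent quarters): full/4 + r + 3/4 on the grid
        assert quarter == pytest.approx(full / 4 + 15 + 0.75, rel=0.03)

    def test_subpixel_diameter_keeps_centre_pixel(self):
        mask = circle_mask((10.6, 10.2), 0.3 * PX, PX, (20, 20))
        assert mask.sum() == 1
        assert mask[11, 10]

    def test_centre_outside_image_warns_and_empty(self):
        with pytest.warns(UserWarning, match="outside"):
            mask = circle_mask((-5.0, 3.0), 7.0, PX, (20, 20))
        assert not mask.any()


class TestClusteringRatio:
    def _uniform_cell(self, size=64):
        cell = np.zeros((size, size), bool)
        rr = np.arange(size)[:, None] - size / 2
        cc = np.arange(size)[None, :] - size / 2
        cell[rr**2 + cc**2 <= (size / 2 - 2) ** 2] = True
        return cell

    def test_all_intensity_inside_circle_gives_one(self, config):
        cell = self._uniform_cell()
        lys = np.zeros((64, 64))
        lys[30:34, 30:34] = 50.0
        m = clustering_ratio(lys, cell, _call((32.0, 32.0)), config, PX)
        assert m.raw_ratio == pytest.approx(1.0)

    def test_uniform_intensity_equals_area_fraction(self, config):
        cell = self._uniform_cell()
        lys = np.where(cell, 7.0, 0.0)
        m = clustering_ratio(lys, cell, _call((32.0, 32.0)), config, PX)
        circ = circle_mask((32.0, 32.0), config.circle_diameter_um, PX, cell.shape)
        expected = (circ & cell).sum() / cell.sum()
        assert m.raw_ratio == pytest.approx(expected, abs=1e-9)

    def test_two_equal_puncta_split_gives_half(self, config):
        """One punctum inside the circle, one outside: brute-force 0.5."""
        cell = self._uniform_cell()
        lys = np.zeros((64, 64))
        lys[32, 32] = 120.0  # at the MTOC
        lys[10, 52] = 120.0  # far corner of the cell
        assert cell[10, 52]
        m = clustering_ratio(lys, cell, _call((32.0, 32.0)), config, PX)
        circ = circle_mask((32.0, 32.0), config.circle_diameter_um, PX, cell.shape)
        brute = lys[circ & cell].sum() / lys[cell].sum()
        assert brute == pytest.approx(0.5)
        assert m.raw_ratio == pytest.approx(brute, abs=1e-12)

    def test_matches_bruteforce_on_random_instances(self, config, rng):
        cell = self._uniform_cell()
        for _ in range(100):
            lys = rng.gamma(1.0, 30.0, (64, 64)) * cell
            pos = tuple(rng.uniform(20, 44, 2))
            m = clustering_ratio(lys, cell, _call(pos), config, PX)
            circ = circle_mask(pos, config.circle_diameter_um, PX, cell.shape)
            brute = lys[circ & cell].sum() / lys[cell].sum()
            assert m.raw_ratio == pytest.approx(brute, abs=1e-12)
            assert 0.0 <= m.raw_ratio <= 1.0

    def test_scale_invariance(self, config, rng):
        cell = self._uniform_cell()
        lys = rng.random((64, 64)) * cell
        a = clustering_ratio(lys, cell, _call((32.0, 32.0)), config, PX)
        b = clustering_ratio(lys * 137.0, cell, _call((32.0, 32.0)), config, PX)
        assert a.raw_ratio == pytest.approx(b.raw_ratio, rel=1e-12)

    def test_moving_punctum_into_circle_never_decreases_ratio(self, config):
        cell = self._uniform_cell()
        base = np.zeros((64, 64))
        base[32, 32] = 10.0
        outside = base.copy()
        outside[10, 52] = 40.0
        inside = base.copy()
        inside[33, 33] = 40.0
        r_out = clustering_ratio(outside, cell, _call((32.0, 32.0)), config, PX)
        r_in = clustering_ratio(inside, cell, _call((32.0, 32.0)), config, PX)
        assert r_in.raw_ratio >= r_out.raw_ratio

    def test_undetected_mtoc_excluded(self, config):
        cell = self._uniform_cell()
        m = clustering_ratio(
            np.ones((64, 64)), cell, MtocCall(1, None, 0.0, False), config, PX
        )
        assert m.excluded and "MTOC" in m.reason

    def test_zero_lysosome_signal_excluded(self, config):
        cell = self._uniform_cell()
        m = clustering_ratio(np.zeros((64, 64)), cell, _call((32.0, 32.0)), config, PX)
        assert m.excluded and m.reason == "empty lysosome signal"


class TestClusteringValue:
    def test_identical_groups_give_one(self, rng):
        ratios = rng.random(50).tolist()
        assert clustering_value(ratios, ratios) == pytest.approx(1.0)

    def test_boundary_arithmetic(self):
        # a treated mean of 0.33 against a control mean of 0.30 sits at
        # the 1.1-fold hit boundary
        assert clustering_value([0.33], [0.30]) == pytest.approx(1.1)

    def test_fifty_wells_match_independent_oracle(self, rng):
        control = rng.uniform(0.1, 0.5, 200)
        for _ in range(50):
            treated = rng.uniform(0.1, 0.9, rng.integers(5, 40))
            got = clustering_value(treated.tolist(), control.tolist(), "mean")
            oracle = (sum(treated) / len(treated)) / (sum(control) / len(control))
            assert got == pytest.approx(oracle, abs=1e-12)
            got_med = clustering_value(treated.tolist(), control.tolist(), "median")
            oracle_med = float(np.sort(treated)[len(treated) // 2]) if len(treated) % 2 else float(np.sort(treated)[len(treated) // 2 - 1 : len(treated) // 2 + 1].mean())
            oracle_med /= float(np.median(control))
            assert got_med == pytest.approx(oracle_med, abs=1e-12)

    def test_empty_control_rejected(self):
        with pytest.raises(DataError):
            normalize_to_control([0.5], [])

    def test_empty_treated_gives_nan(self):
        assert np.isnan(normalize_to_control([], [0.5]))


class TestPeripheralCellFraction:
    def _cells_with_central(self):
        labels = np.zeros((40, 80), np.int32)
        labels[4:36, 4:36] = 1
        labels[4:36, 44:76] = 2
        cells = LabelMask(labels, "cell")
        central = central_region(cells, 0.5)
        return cells, central

    def test_all_central_gives_zero_percent(self):
        cells, central = self._cells_with_central()
        lys = np.where(central.labels > 0, 10.0, 0.0)
        pct, flags = peripheral_cell_fraction(lys, cells, central)
        assert pct == 0.0 and not any(flags.values())

    def test_all_peripheral_gives_hundred_percent(self):
        cells, central = self._cells_with_central()
        lys = np.where((cells.labels > 0) & (central.labels == 0), 10.0, 0.0)
        pct, flags = peripheral_cell_fraction(lys, cells, central)
        assert pct == 100.0 and all(flags.values())

    def test_mixed_population_matches_construction(self):
        cells, central = self._cells_with_central()
        lys = np.zeros((40, 80))
        lys[central.labels == 1] = 10.0  # cell 1 fully central
        lys[(cells.labels == 2) & (central.labels == 0)] = 10.0  # cell 2 peripheral
        pct, flags = peripheral_cell_fraction(lys, cells, central)
        assert flags == {1: False, 2: True}
        assert pct == 50.0

    def test_no_cells_raises(self):
        empty = LabelMask(np.zeros((8, 8), np.int32), "cell")
        with pytest.raises(DataError, match="no cells"):
            peripheral_cell_fraction(np.zeros((8, 8)), empty, empty)


class TestAggregateColocalization:
    def _setup(self):
        labels = np.zeros((48, 48), np.int32)
        labels[4:44, 4:44] = 1
        cells = LabelMask(labels, "cell")
        aggregate = np.zeros((48, 48))
        aggregate[20:30, 20:30] = 200.0
        return cells, aggregate

    def test_zero_lysosome_inside_aggregates_scores_zero(self):
        cells, aggregate = self._setup()
        scores = aggregate_colocalization(np.zeros((48, 48)), aggregate, cells)
        assert scores[0].aggregate_area_px > 0
        assert scores[0].lysosome_intensity_in_aggregate == 0.0

    def test_partial_overlap_matches_masked_sum_oracle(self, rng):
        cells, aggregate = self._setup()
        lys = np.zeros((48, 48))
        lys[18:24, 18:24] = rng.uniform(5, 50, (6, 6))  # straddles the edge
        scores = aggregate_colocalization(lys, aggregate, cells)
        agg_mask = (aggregate > 0) & (cells.labels == 1)
        oracle = lys[agg_mask].sum()
        assert scores[0].lysosome_intensity_in_aggregate == pytest.approx(oracle)
        assert scores[0].mean_intensity_in_aggregate == pytest.approx(
            oracle / agg_mask.sum()
        )

    def test_no_aggregate_gives_zero_record(self):
        labels = np.zeros((16, 16), np.int32)
        labels[2:14, 2:14] = 1
        cells = LabelMask(labels, "cell")
        scores = aggregate_colocalization(
            np.ones((16, 16)), np.zeros((16, 16)), cells
        )
        assert scores[0].aggregate_area_px == 0
        assert scores[0].lysosome_intensity_in_aggregate == 0.0
        assert scores[0].mean_intensity_in_aggregate == 0.0


class TestFractionPixelsAboveThreshold:
    def test_bounds(self):
        assert fraction_pixels_above_threshold(np.zeros((8, 8)), 1.0) == 0.0
        assert fraction_pixels_above_threshold(np.full((8, 8), 5.0), 1.0) == 1.0

    def test_matches_counting_loop(self, rng):
        img = rng.normal(0, 1, (32, 32))
        thr = 0.3
        count = sum(
            1 for i in range(32) for j in range(32) if img[i, j] > thr
        )
        assert fraction_pixels_above_threshold(img, thr) == count / img.size

    def test_empty_raster_rejected(self):
        with pytest.raises(ValidationError):
            fraction_pixels_above_threshold(np.zeros((0,)), 1.0)
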