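import numpy as np
import pytest
from scipy import ndimage as ndi

from lysoscreen import (
    SyntheticCellSpec,
    detect_mtoc,
    generate_fields,
    normalize_intensity,
    segment_cells,
    segment_nuclei,
    subtract_background,
)
from lysoscreen.errors import ValidationError
from lysoscreen.segmentation import LabelMask

PX = 0.325


class TestNormalizeIntensity:
    def test_constant_image_maps_to_zeros(self):
        out = normalize_intensity(np.full((16, 16), 42.0))
        np.testing.assert_array_equal(out, 0.0)

    def test_two_level_image_full_percentiles(self):
        img = np.where(np.arange(64).reshape(8, 8) % 2 == 0, 10.0, 100.0)
        out = normalize_intensity(img, 0, 100)
        np.testing.assert_array_equal(np.unique(out), [0.0, 1.0])

    def test_matches_elementwise_clip_rescale_oracle(self, rng):
        img = rng.gamma(2.0, 50.0, (48, 48))
        out = normalize_intensity(img, 5, 95)
        lo, hi = np.percentile(img, 5), np.percentile(img, 95)
        oracle = np.empty_like(img)
        for i in range(img.shape[0]):
            for j in range(img.shape[1]):
                v = min(max(img[i, j], lo), hi)
                oracle[i, j] = (v - lo) / (hi - lo)
        np.testing.assert_allclose(out, oracle, atol=1e-12)

    def test_preserves_ordering_of_unclipped_pixels(self, rng):
        img = rng.random((32, 32)) * 100
        out = normalize_intensity(img, 1, 99)
        lo, hi = np.percentile(img, 1), np.percentile(img, 99)
        sel = (img > lo) & (img < hi)
        order_in = np.argsort(img[sel], kind="stable")
        order_out = np.argsort(out[sel], kind="stable")
        np.testing.assert_array_equal(order_in, order_out)


class TestSubtractBackground:
    def test_flat_image_maps_to_zero(self):
        out = subtract_background(np.full((32, 32), 50.0), 2.0, PX)
        np.testing.assert_allclose(out, 0.0)

    def test_impulse_preserved_against_grey_opening_oracle(self):
        img = np.zeros((64, 64))
        img[30, 30] = 100.0
        out = subtract_background(img, 5.0, PX)
        assert out[30, 30] >= 99.0
        # independent oracle: scipy grey opening with a disk footprint
        r = int(round(5.0 / PX))
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        footprint = yy**2 + xx**2 <= r**2
        oracle = img - ndi.grey_opening(img, footprint=footprint)
        np.testing.assert_allclose(out, oracle, atol=1e-9)

    def test_nonnegative_on_random_input(self, rng):
        img = rng.poisson(20.0, (48, 48)).astype(float)
        assert (subtract_background(img, 3.0, PX) >= 0).all()

    def test_subpixel_radius_rejected(self):
        with pytest.raises(ValidationError):
            subtract_background(np.zeros((8, 8)), 0.1, PX)


def _one_cell_mask(shape):
    return LabelMask(np.ones(shape, np.int32), "cell")


class TestDetectMtoc:
    def test_single_spot_recovered_within_one_pixel(self, config):
        img = np.zeros((80, 80))
        rr = np.arange(80)[:, None] - 40.0
        cc = np.arange(80)[None, :] - 40.0
        img += 500 * np.exp(-(rr**2 + cc**2) / (2 * 1.5**2))
        calls = detect_mtoc(img, _one_cell_mask(img.shape), config, PX)
        assert len(calls) == 1 and calls[0].detected
        assert np.hypot(calls[0].position[0] - 40, calls[0].position[1] - 40) < 1.0

    def test_brighter_of_two_spots_wins(self, config):
        """Exhaustive check against per-component integrated intensities."""
        img = np.zeros((80, 80))
        for center, amp in (((20.0, 20.0), 200.0), ((60.0, 60.0), 100.0)):
            rr = np.arange(80)[:, None] - center[0]
            cc = np.arange(80)[None, :] - center[1]
            img += amp * np.exp(-(rr**2 + cc**2) / (2 * 1.5**2))
        calls = detect_mtoc(
            img, _one_cell_mask(img.shape), config, PX, preprocessed=True
        )
        assert calls[0].detected
        # oracle: enumerate suprathreshold components, integrate, pick max
        from skimage.filters import threshold_otsu

        fg = img > threshold_otsu(img)
        comp, n = ndi.label(fg, np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        integrals = [img[comp == k].sum() for k in range(1, n + 1)]
        best = int(np.argmax(integrals)) + 1
        rr, cc = np.nonzero(comp == best)
        w = img[comp == best]
        oracle_pos = ((rr * w).sum() / w.sum(), (cc * w).sum() / w.sum())
        np.testing.assert_allclose(calls[0].position, oracle_pos, atol=1e-9)
        assert np.hypot(calls[0].position[0] - 20, calls[0].position[1] - 20) < 1

    def test_all_zero_tubulin_not_detected(self, config):
        calls = detect_mtoc(np.zeros((32, 32)), _one_cell_mask((32, 32)), config, PX)
        assert len(calls) == 1
        assert not calls[0].detected
        assert calls[0].position is None

    def test_empty_cells_mask_gives_empty_list(self, config):
        empty = LabelMask(np.zeros((32, 32), np.int32), "cell")
        assert detect_mtoc(np.ones((32, 32)), empty, config, PX) == []

    def test_position_lies_inside_owning_cell(self, config, clustered_field):
        field, _ = clustered_field
        nuclei = segment_nuclei(field.channels["nuclear"], config, field.pixel_size_um)
        composite = field.channels["tubulin"].astype(float)
        cells = segment_cells(nuclei, composite, config)
        for call in detect_mtoc(
            field.channels["tubulin"], cells, config, field.pixel_size_um
        ):
            assert call.detected
            r, c = int(round(call.position[0])), int(round(call.position[1]))
            assert cells.labels[r, c] == call.cell_label

    def test_determinism(self, config, clustered_field):
        field, _ = clustered_field
        nuclei = segment_nuclei(field.channels["nuclear"], config, field.pixel_size_um)
        cells = segment_cells(nuclei, field.channels["tubulin"].astype(float), config)
        a = detect_mtoc(field.channels["tubulin"], cells, config, field.pixel_size_um)
        b = detect_mtoc(field.channels["tubulin"], cells, config, field.pixel_size_um)
        assert a == b


def test_median_localization_error_below_one_pixel(config):
    """~100 synthetic cells at high SNR: median MTOC error < 1 px."""
    spec = SyntheticCellSpec(seed=77, clustered_fraction=0.5)
    errors = []
    for field, truth in generate_fields(spec, 12):
        nuclei = segment_nuclei(field.channels["nuclear"], config, field.pixel_size_um)
        composite = field.channels["tubulin"].astype(float) + field.channels[
            "lysosome"
        ].astype(float)
        cells = segment_cells(nuclei, composite, config)
        calls = {
            c.cell_label: c
            for c in detect_mtoc(
                field.channels["tubulin"], cells, config, field.pixel_size_um
            )
        }
        mapping = truth.match_labels(cells.labels)
        for cell in truth.cells:
            call = calls.get(mapping[cell.label])
            if call is not None and call.detected:
                errors.append(
                    np.hypot(
                        call.position[0] - cell.mtoc_position[0],
                        call.position[1] - cell.mtoc_position[1],
                    )
                )
    assert len(errors) >= 100
    assert np.median(errors) < 1.0
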