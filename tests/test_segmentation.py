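"""Masking threshold, segment partition, mean extraction, absorbance, oven arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hsimoist as hm
from hsimoist.segmentation import Mask


def _uniform_cube(value, wavelengths, shape=(4, 6)):
    return hm.Hypercube(
        np.full(shape + (len(wavelengths),), float(value)), wavelengths,
        kind="reflectance",
    )


class TestThresholdMask:
    def test_uniform_above_threshold_all_true(self, wavelengths):
        mask = hm.threshold_mask(_uniform_cube(0.5, wavelengths))
        assert mask.n_foreground == mask.grid.size

    def test_exactly_at_threshold_all_false(self, wavelengths):
        # strict inequality: 0.075 itself is background
        with pytest.warns(UserWarning, match="empty"):
            mask = hm.threshold_mask(_uniform_cube(0.075, wavelengths))
        assert mask.n_foreground == 0

    def test_noiseless_scene_mask_exact(self, clean_scene):
        refl = hm.calibrate(clean_scene.raw, clean_scene.refs)
        mask = hm.threshold_mask(refl)
        assert np.array_equal(mask.grid, clean_scene.truth_mask.grid)

    def test_invariant_to_other_bands(self, wavelengths):
        cube = _uniform_cube(0.5, wavelengths)
        other = cube.data.copy()
        idx695 = cube.band_index(695.0)
        other[:, :, np.arange(len(wavelengths)) != idx695] = 0.0
        cube2 = hm.Hypercube(other, wavelengths, kind="reflectance")
        m1 = hm.threshold_mask(cube)
        m2 = hm.threshold_mask(cube2)
        assert np.array_equal(m1.grid, m2.grid)

    def test_band_outside_grid_rejected(self, wavelengths):
        with pytest.raises(ValueError, match="grid"):
            hm.threshold_mask(_uniform_cube(0.5, wavelengths), band_nm=2000.0)


class TestPartitionSegments:
    def test_exact_divisibility_equal_widths(self):
        grid = np.zeros((20, 160), dtype=bool)
        grid[5:15, 5:155] = True  # 150-column extent
        labels = hm.partition_segments(Mask(grid), 15)
        widths = [
            np.unique(np.nonzero(labels == s)[1]).size for s in range(1, 16)
        ]
        assert widths == [10] * 15

    def test_off_by_one_extent_widths_differ_by_at_most_one(self):
        grid = np.zeros((20, 170), dtype=bool)
        grid[5:15, 5:156] = True  # 151-column extent
        labels = hm.partition_segments(Mask(grid), 15)
        widths = np.array(
            [np.unique(np.nonzero(labels == s)[1]).size for s in range(1, 16)]
        )
        assert widths.min() >= 10 and widths.max() <= 11
        assert widths.sum() == 151

    @given(st.integers(15, 300), st.integers(1, 14))
    @settings(max_examples=30, deadline=None)
    def test_partition_covers_and_is_disjoint(self, extent, rows):
        grid = np.zeros((rows + 2, extent + 4), dtype=bool)
        grid[1 : rows + 1, 2 : extent + 2] = True
        labels = hm.partition_segments(Mask(grid), 15)
        assert np.array_equal(labels > 0, grid)  # cover exactly the mask
        assert set(np.unique(labels[grid])) == set(range(1, 16))

    def test_long_axis_is_rows_when_taller_than_wide(self):
        grid = np.zeros((60, 20), dtype=bool)
        grid[5:50, 5:15] = True  # 45 rows x 10 cols -> slice along rows
        labels = hm.partition_segments(Mask(grid), 15)
        rows_of_seg1 = np.unique(np.nonzero(labels == 1)[0])
        assert rows_of_seg1.size == 3  # 45 / 15

    def test_extent_smaller_than_segments_rejected(self):
        grid = np.zeros((5, 10), dtype=bool)
        grid[1:4, 1:9] = True
        with pytest.raises(ValueError, match="extent"):
            hm.partition_segments(Mask(grid), 15)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hm.partition_segments(Mask(np.zeros((4, 4), dtype=bool)), 15)


class TestExtractMeanSpectra:
    def test_uniform_cube_every_segment_equals_pixel_spectrum(self, wavelengths):
        cube = _uniform_cube(0.3, wavelengths, shape=(10, 40))
        labels = hm.partition_segments(Mask(np.ones((10, 40), dtype=bool)), 5)
        out = hm.extract_mean_spectra(cube, labels, "p1")
        assert np.allclose(out.spectra, 0.3)
        assert out.sample_ids == [f"p1:s{i:02d}" for i in range(1, 6)]

    def test_two_pixel_segment_mean(self, wavelengths):
        n = len(wavelengths)
        data = np.zeros((1, 2, n))
        a, b = np.linspace(0, 1, n), np.linspace(1, 0, n)
        data[0, 0], data[0, 1] = a, b
        cube = hm.Hypercube(data, wavelengths, kind="reflectance")
        labels = np.array([[1, 1]])
        out = hm.extract_mean_spectra(cube, labels, "p")
        assert np.allclose(out.spectra[0], (a + b) / 2)

    def test_matches_brute_force_accumulation(self, rng, wavelengths):
        n = len(wavelengths)
        data = rng.random((20, 20, n))
        cube = hm.Hypercube(data, wavelengths, kind="reflectance")
        labels = rng.integers(0, 4, size=(20, 20))
        out = hm.extract_mean_spectra(cube, labels, "p")
        for row, s in zip(out.spectra, (1, 2, 3)):
            acc = np.zeros(n)
            cnt = 0
            for i in range(20):
                for j in range(20):
                    if labels[i, j] == s:
                        acc += data[i, j]
                        cnt += 1
            assert np.allclose(row, acc / cnt)


class TestAbsorbance:
    @pytest.mark.parametrize("r, a", [(1.0, 0.0), (0.1, 1.0), (0.01, 2.0)])
    def test_log_identities(self, wavelengths, r, a):
        cube = _uniform_cube(r, wavelengths)
        out = hm.to_absorbance(cube)
        assert np.allclose(out.data, a)
        assert out.kind == "absorbance"

    def test_clamps_nonpositive_and_warns(self, wavelengths):
        n = len(wavelengths)
        data = np.full((2, 2, n), 0.5)
        data[0, 0, 0] = -0.01
        cube = hm.Hypercube(data, wavelengths, kind="reflectance")
        with pytest.warns(UserWarning, match="clamped"):
            out = hm.to_absorbance(cube)
        assert out.data[0, 0, 0] == pytest.approx(6.0)  # -log10(1e-6)

    def test_spectrum_set_domain_flip(self, clean_samples):
        data, _, _ = clean_samples
        out = hm.to_absorbance(data)
        assert out.domain == "absorbance"
        assert np.allclose(out.spectra, -np.log10(data.spectra))
        assert out.sample_ids == data.sample_ids

    def test_rejects_absorbance_input(self, clean_samples):
        data, _, _ = clean_samples
        with pytest.raises(ValueError, match="reflectance"):
            hm.to_absorbance(hm.to_absorbance(data))

    def test_mean_then_log_equals_log_then_mean_on_uniform_segments(self, wavelengths):
        # only guaranteed when spectra are constant within a segment
        cube = _uniform_cube(0.2, wavelengths, shape=(6, 30))
        labels = hm.partition_segments(Mask(np.ones((6, 30), dtype=bool)), 3)
        mean_then_log = hm.to_absorbance(hm.extract_mean_spectra(cube, labels, "p"))
        log_then_mean = hm.extract_mean_spectra(hm.to_absorbance(cube), labels, "p")
        assert np.allclose(mean_then_log.spectra, log_then_mean.spectra)


class TestMoistureFromWeights:
    @pytest.mark.parametrize("w1, w2, expected", [(5, 2.5, 50.0), (5, 5, 0.0), (5, 0, 100.0)])
    def test_oven_drying_arithmetic(self, w1, w2, expected):
        assert hm.moisture_from_weights(w1, w2) == pytest.approx(expected)

    def test_mass_gain_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            hm.moisture_from_weights(5.0, 5.1)

    def test_nonpositive_wet_mass_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            hm.moisture_from_weights(0.0, 0.0)


def test_spectrum_set_rejects_more_than_15_segments_per_block(wavelengths):
    n = 16
    with pytest.raises(ValueError, match="15"):
        hm.SpectrumSet(
            np.ones((n, len(wavelengths))), wavelengths,
            [f"s{i}" for i in range(n)], ["blk"] * n,
        )


def test_spectrum_set_rejects_out_of_range_moisture(wavelengths):
    with pytest.raises(ValueError, match="0, 100"):
        hm.SpectrumSet(
            np.ones((2, len(wavelengths))), wavelengths,
            ["a", "b"], ["p", "p"], np.array([50.0, 120.0]),
        )
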