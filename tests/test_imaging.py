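"""Ion-image peak picking, grouping, TIC normalization and ROI statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lipidkit.imaging import (
    MarkerWindow,
    ROIMask,
    SpectrumGrid,
    detect_peaks,
    group_peaks,
    marker_image,
    roi_summary,
    tic_normalize,
)
from lipidkit.simulate import SimConfig, simulate_ion_image


def _grid(cube, mz=None, px=60.0):
    cube = np.asarray(cube, dtype=float)
    if mz is None:
        mz = 700.0 + 0.1 * np.arange(cube.shape[2])
    return SpectrumGrid(np.asarray(mz, float), cube, px)


class TestDetectPeaks:
    def test_flat_zero_spectrum_no_peaks(self):
        mzs, _ = detect_peaks(_grid(np.zeros((2, 2, 50))))
        assert mzs.size == 0

    def test_single_gaussian_peak_at_apex_bin(self):
        rng = np.random.default_rng(0)
        bins = 200
        noise = rng.uniform(0.5, 1.5, size=(4, 4, bins))
        apex = 100
        profile = 40.0 * np.exp(-0.5 * ((np.arange(bins) - apex) / 2.0) ** 2)
        cube = noise + profile[None, None, :]
        grid = _grid(cube)
        mzs, intens = detect_peaks(grid, snr=3.0)
        # brute-force oracle: local maxima of the mean spectrum above threshold
        spec = grid.mean_spectrum()
        noise_est = 1.4826 * np.median(np.abs(spec - np.median(spec)))
        oracle = [
            i for i in range(1, bins - 1)
            if spec[i] > spec[i - 1] and spec[i] > spec[i + 1]
            and spec[i] - np.median(spec) >= 3.0 * noise_est
        ]
        assert mzs.tolist() == grid.mz[oracle].tolist()
        assert grid.mz[apex] in mzs

    def test_peak_below_snr_threshold_not_detected(self):
        rng = np.random.default_rng(1)
        cube = rng.uniform(0.5, 1.5, size=(4, 4, 100))
        spec_noise = 1.4826 * np.median(
            np.abs(cube.mean((0, 1)) - np.median(cube.mean((0, 1))))
        )
        apex = 50
        # plant a local maximum ~2x the noise above the baseline (SNR < 3)
        cube[:, :, apex] = np.median(cube.mean((0, 1))) + 2.0 * spec_noise
        mzs, _ = detect_peaks(_grid(cube), snr=3.0)
        assert _grid(cube).mz[apex] not in mzs

    def test_band_noise_estimator_selectable(self):
        cube = np.zeros((2, 2, 100))
        cube[:, :, 50] = 100.0
        cube[:, :, :20] = 1.0  # flat signal-free band
        grid = _grid(cube)
        mzs, _ = detect_peaks(grid, noise_estimator="band",
                              noise_band=(grid.mz[0], grid.mz[19]))
        assert grid.mz[50] in mzs


class TestGroupPeaks:
    @pytest.mark.parametrize(
        "cands, expected_n",
        [([700.10, 700.40], 1), ([700.10, 700.80], 2), ([700.1, 700.5, 700.9], 1)],
    )
    def test_single_linkage_chains(self, cands, expected_n):
        assert group_peaks(cands, window=0.5).size == expected_n

    def test_intensity_weighted_centers(self):
        centers = group_peaks([700.0, 700.4], [3.0, 1.0], window=0.5)
        assert centers[0] == pytest.approx(700.1)

    @given(seed=st.integers(min_value=0, max_value=500))
    def test_matches_pairwise_grouping_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cands = np.sort(rng.uniform(700, 710, size=rng.integers(1, 20)))
        groups = group_peaks(cands, window=0.5)
        # oracle: number of connected components of the <0.5 Da chain graph
        n_components = 1 + int(np.sum(np.diff(cands) >= 0.5))
        assert groups.size == n_components


class TestTicNormalize:
    def test_percent_arithmetic(self):
        cube = np.array([[[2.0, 3.0, 5.0]]])
        norm, n_missing = tic_normalize(_grid(cube))
        assert norm.intensities[0, 0].tolist() == [20.0, 30.0, 50.0]
        assert n_missing == 0

    def test_scale_invariance(self):
        cube = np.array([[[2.0, 3.0, 5.0]]])
        n1, _ = tic_normalize(_grid(cube))
        n2, _ = tic_normalize(_grid(cube * 17.0))
        np.testing.assert_allclose(n1.intensities, n2.intensities)

    def test_zero_pixel_missing_and_counted(self):
        cube = np.array([[[1.0, 1.0], [0.0, 0.0]]])
        norm, n_missing = tic_normalize(_grid(cube))
        assert n_missing == 1
        assert np.isnan(norm.intensities[0, 1]).all()

    @given(seed=st.integers(min_value=0, max_value=200))
    def test_rows_sum_to_100(self, seed):
        rng = np.random.default_rng(seed)
        cube = rng.uniform(0.01, 5.0, size=(3, 4, 20))
        norm, _ = tic_normalize(_grid(cube))
        sums = norm.intensities.sum(axis=2)
        np.testing.assert_allclose(sums, 100.0, atol=1e-9)


class TestMarkerImage:
    def test_max_within_range(self):
        mz = np.array([733.99, 734.02, 734.06])
        cube = np.array([[[5.0, 9.0, 4.0]]])
        img = marker_image(_grid(cube, mz), MarkerWindow(734.00, 0.05))
        assert img[0, 0] == 9.0

    def test_window_outside_axis_rejected_with_bounds(self):
        grid = _grid(np.ones((1, 1, 3)), mz=[700.0, 700.1, 700.2])
        with pytest.raises(ValueError, match=r"700\.0"):
            marker_image(grid, MarkerWindow(900.0, 0.05))

    def test_widening_never_decreases(self):
        rng = np.random.default_rng(3)
        cube = rng.uniform(size=(2, 2, 50))
        grid = _grid(cube)
        narrow = marker_image(grid, MarkerWindow(702.0, 0.1))
        wide = marker_image(grid, MarkerWindow(702.0, 1.0))
        assert np.all(wide >= narrow)

    def test_invariant_to_out_of_window_bins(self):
        mz = np.array([700.0, 734.0, 760.0])
        c1 = np.array([[[1.0, 9.0, 2.0]]])
        c2 = np.array([[[5.0, 9.0, 7.0]]])
        w = MarkerWindow(734.0, 0.05)
        assert marker_image(_grid(c1, mz), w) == marker_image(_grid(c2, mz), w)


class TestRoiSummary:
    def test_single_pixel_degenerate_stats(self):
        marker = np.array([[7.5]])
        s = roi_summary(marker, ROIMask("T", np.array([[True]])), 60.0)
        assert s.total == s.mean_per_pixel == s.median == s.minimum == s.maximum == 7.5
        assert s.sd_per_pixel == 0.0 and s.n_pixels == 1

    def test_two_by_two_arithmetic(self):
        marker = np.array([[1.0, 2.0], [3.0, 4.0]])
        s = roi_summary(marker, ROIMask("T", np.ones((2, 2), bool)), 60.0)
        assert s.mean_per_pixel == 2.5
        assert s.mean_per_mm2 == pytest.approx(10.0 / (4 * 0.0036))

    @given(seed=st.integers(min_value=0, max_value=300))
    def test_quartile_ordering_and_sum_identity(self, seed):
        rng = np.random.default_rng(seed)
        marker = rng.uniform(0, 100, size=(6, 6))
        mask = ROIMask("T", rng.uniform(size=(6, 6)) > 0.3)
        if not mask.mask.any():
            return
        s = roi_summary(marker, mask, 60.0)
        assert s.q1 <= s.median <= s.q3
        assert s.minimum <= s.mean_per_pixel <= s.maximum
        assert s.total == pytest.approx(s.mean_per_pixel * s.n_pixels)
        if s.mean_per_pixel > 0:
            assert s.rsd == pytest.approx(s.sd_per_pixel / s.mean_per_pixel)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            roi_summary(np.ones((2, 2)), ROIMask("T", np.zeros((2, 2), bool)), 60.0)

    def test_planted_tumor_stroma_contrast_signs(self):
        grid, masks, truth = simulate_ion_image(SimConfig(seed=8))
        t_mask, s_mask = masks
        for name, info in truth.marker_contrast.items():
            img = marker_image(grid, MarkerWindow(info["mz"]))
            mean_t = roi_summary(img, t_mask, 60.0).mean_per_pixel
            mean_s = roi_summary(img, s_mask, 60.0).mean_per_pixel
            if info["kind"] == "tumor":
                assert mean_t > mean_s
            else:
                assert mean_s > mean_t


class TestGridIO:
    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        grid = _grid(rng.uniform(size=(3, 4, 6)))
        grid.save(tmp_path / "g")
        back = SpectrumGrid.load(tmp_path / "g")
        np.testing.assert_allclose(back.intensities, grid.intensities)
        np.testing.assert_allclose(back.mz, grid.mz)

    def test_imzml_round_trip(self, tmp_path):
        pytest.importorskip("pyimzml")
        from pyimzml.ImzMLWriter import ImzMLWriter

        from lipidkit.imaging import grid_from_imzml

        mz = np.array([700.0, 734.6, 760.6])
        rng = np.random.default_rng(9)
        cube = rng.uniform(1, 10, size=(2, 3, 3))
        path = tmp_path / "img.imzML"
        with ImzMLWriter(str(path), mode="continuous") as w:
            for y in range(2):
                for x in range(3):
                    w.addSpectrum(mz, cube[y, x], (x + 1, y + 1, 1))
        grid = grid_from_imzml(path)
        np.testing.assert_allclose(grid.mz, mz)
        np.testing.assert_allclose(grid.intensities, cube, rtol=1e-6)
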