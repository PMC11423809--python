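"""Density windows, live/fixed matching, normalization, correlation, maps."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nucmorph.image_io import DEFAULT_BINNED_CALIBRATION as CAL
from nucmorph.population import (
    DEFAULT_DENSITY_WINDOW_UM,
    binned_mean_map,
    local_density,
    match_live_fixed,
    normalize_table,
    normalize_timeseries,
    spearman_correlation,
)
from nucmorph.segmentation import LabelVolume
from nucmorph.synthetic_data import ChannelModel, SceneSpec, simulate_scene


class TestLocalDensity:
    def test_window_side_matches_binned_pixel_convention(self):
        # 200 binned pixels of 0.5652 µm
        assert DEFAULT_DENSITY_WINDOW_UM == pytest.approx(113.04, abs=0.01)
        assert DEFAULT_DENSITY_WINDOW_UM == pytest.approx(113.03, abs=0.02)

    def test_single_nucleus_counts_itself(self):
        table = local_density(np.array([[50.0, 50.0]]))
        assert table.density.tolist() == [1]

    def test_grid_against_brute_force_point_in_square(self):
        spacing = 30.0
        pts = np.array(
            [(100 + i * spacing, 100 + j * spacing) for i in range(3) for j in range(3)]
        )
        table = local_density(pts, window_side_um=113.03)
        half = 113.03 / 2
        for k, (x, y) in enumerate(pts):
            expected = sum(
                (abs(px - x) <= half) and (abs(py - y) <= half) for px, py in pts
            )
            assert table.density.iloc[k] == expected
        assert table.density.iloc[4] == 9  # central nucleus sees the full grid

    def test_pairwise_symmetry(self):
        table = local_density(np.array([[0.0, 0.0], [40.0, 30.0]]), window_side_um=113.0)
        assert table.density.tolist() == [2, 2]

    def test_exclusive_counting_flag(self):
        table = local_density(
            np.array([[0.0, 0.0], [10.0, 10.0]]), include_focal=False
        )
        assert table.density.tolist() == [1, 1]

    def test_per_mm2_conversion(self):
        table = local_density(np.array([[0.0, 0.0]]), window_side_um=100.0)
        assert table.density_per_mm2.iloc[0] == pytest.approx(100.0)  # 1 per 0.01 mm²

    def test_edge_window_flagged(self):
        table = local_density(
            np.array([[10.0, 100.0], [150.0, 100.0]]),
            window_side_um=113.0,
            field_size_um=(300.0, 200.0),
        )
        # first window clips the x=0 field edge; second is fully interior
        assert table.edge_window.tolist() == [True, False]


class TestMatchLiveFixed:
    @pytest.fixture(scope="class")
    def scene_labels(self):
        spec = SceneSpec(
            n_nuclei=9, seed=17, channels=ChannelModel(gaussian_sigma_frac=0.0)
        )
        return simulate_scene(spec).labels

    def test_identity_match(self, scene_labels):
        result = match_live_fixed(scene_labels, scene_labels)
        assert result.shift_yx_px == (0, 0)
        assert len(result.pairs) == scene_labels.n_nuclei
        assert (result.pairs.live_id == result.pairs.fixed_id).all()
        assert (result.pairs.overlap_fraction == 1.0).all()

    def test_translation_recovered_and_pairs_preserved(self, scene_labels):
        shifted = LabelVolume(
            np.roll(scene_labels.labels, (7, -4), axis=(1, 2)), CAL
        )
        result = match_live_fixed(scene_labels, shifted)
        assert (abs(result.shift_yx_px[0]), abs(result.shift_yx_px[1])) == (7, 4)
        assert len(result.pairs) == scene_labels.n_nuclei
        assert (result.pairs.live_id == result.pairs.fixed_id).all()
        assert (result.pairs.overlap_fraction == 1.0).all()

    def test_disjoint_fields_no_matches(self):
        # content so far apart that the implied shift is implausible as
        # stage drift: registration falls back to identity, nothing overlaps
        a = np.zeros((4, 80, 80), dtype=np.int32)
        b = np.zeros((4, 80, 80), dtype=np.int32)
        a[1:3, 2:6, 2:6] = 1
        b[1:3, 70:74, 70:74] = 1
        result = match_live_fixed(LabelVolume(a, CAL), LabelVolume(b, CAL))
        assert result.pairs.empty

    def test_empty_fixed_volume_warns_identity(self, scene_labels):
        empty = LabelVolume(np.zeros(scene_labels.shape, dtype=np.int32), CAL)
        with pytest.warns(UserWarning, match="identity"):
            result = match_live_fixed(scene_labels, empty)
        assert result.pairs.empty
        assert not result.registered


class TestNormalizeTimeseries:
    def test_constant_series_becomes_ones(self):
        np.testing.assert_allclose(normalize_timeseries(np.full(8, 3.0)), 1.0)

    def test_step_series(self):
        series = np.array([10.0, 10, 10, 10, 10, 20])
        np.testing.assert_allclose(
            normalize_timeseries(series), [1, 1, 1, 1, 1, 2]
        )

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="timepoints"):
            normalize_timeseries(np.array([1.0, 2.0, 3.0]))

    def test_zero_baseline_flagged_as_nan(self):
        with pytest.warns(UserWarning, match="baseline"):
            out = normalize_timeseries(np.array([0.0, 0, 0, 0, 0, 5.0]))
        assert np.isnan(out).all()

    def test_table_normalization_per_nucleus(self):
        frames = []
        for nucleus, base in ((1, 10.0), (2, 40.0)):
            frames.append(
                pd.DataFrame(
                    {
                        "nucleus_id": nucleus,
                        "timepoint": np.arange(6),
                        "volume_um3": [base] * 5 + [2 * base],
                    }
                )
            )
        table = pd.concat(frames, ignore_index=True)
        out = normalize_table(table, ["volume_um3"])
        for nucleus in (1, 2):
            series = out[out.nucleus_id == nucleus].sort_values("timepoint")
            np.testing.assert_allclose(series.volume_um3_norm, [1, 1, 1, 1, 1, 2])


def _brute_force_spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Independent oracle: rho from ranks, exact p by full enumeration."""
    rank_x = stats.rankdata(x)
    rank_y = stats.rankdata(y)
    rho = stats.pearsonr(rank_x, rank_y).statistic
    count = total = 0
    for perm in itertools.permutations(rank_y):
        r = stats.pearsonr(rank_x, np.asarray(perm)).statistic
        count += abs(r) >= abs(rho) - 1e-12
        total += 1
    return rho, count / total


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(12.0)
        assert spearman_correlation(x, x**3).rho == pytest.approx(1.0)
        assert spearman_correlation(x, -x).rho == pytest.approx(-1.0)

    def test_exact_small_sample_matches_enumeration_with_tie(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])  # one tie
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0, 6.0])
        result = spearman_correlation(x, y)
        rho_ref, p_ref = _brute_force_spearman(x, y)
        assert result.method == "exact"
        assert result.rho == pytest.approx(rho_ref, abs=1e-12)
        assert result.pvalue == pytest.approx(p_ref, abs=1e-12)

    def test_exact_p_second_case(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        result = spearman_correlation(x, y)
        rho_ref, p_ref = _brute_force_spearman(x, y)
        assert result.rho == pytest.approx(rho_ref, abs=1e-12)
        assert result.pvalue == pytest.approx(p_ref, abs=1e-12)

    def test_large_sample_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        result = spearman_correlation(x, y)
        reference = stats.spearmanr(x, y)
        assert result.rho == pytest.approx(reference.statistic, abs=1e-12)
        assert result.pvalue == pytest.approx(reference.pvalue, rel=1e-9)

    def test_zero_variance_undefined(self):
        with pytest.warns(UserWarning, match="zero variance"):
            result = spearman_correlation(np.ones(6), np.arange(6.0))
        assert math.isnan(result.rho)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            spearman_correlation([1.0, 2.0], [2.0, 1.0])


class TestBinnedMeanMap:
    def test_single_bin_holds_overall_mean(self):
        x = np.array([0.1, 0.2, 0.3])
        v = np.array([1.0, 2.0, 6.0])
        mean, count = binned_mean_map(x, x, v, [0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        assert mean[0, 0] == pytest.approx(3.0)
        assert count[0, 0] == 3
        assert np.isnan(mean[1, 1])

    def test_two_cells_in_two_bins(self):
        mean, count = binned_mean_map(
            np.array([0.5, 1.5]), np.array([0.5, 1.5]), np.array([1.0, 3.0]),
            [0.0, 1.0, 2.0], [0.0, 1.0, 2.0],
        )
        assert mean[0, 0] == 1.0
        assert mean[1, 1] == 3.0
        assert count.sum() == 2

    def test_empty_input_all_undefined(self):
        mean, count = binned_mean_map([], [], [], [0.0, 1.0], [0.0, 1.0])
        assert np.isnan(mean).all()
        assert count.sum() == 0
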