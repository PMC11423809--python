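"""Measurement regions, background estimation, N/C indices and QC."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucmorph.image_io import DEFAULT_BINNED_CALIBRATION as CAL, ImageStack
from nucmorph.intensity import (
    BackgroundError,
    BackgroundEstimate,
    CellIntensity,
    ChannelMap,
    QCThresholds,
    UndefinedIndexError,
    apply_qc_filters,
    compute_nc_index,
    define_regions,
    estimate_background,
    measure_scene,
)
from nucmorph.segmentation import LabelVolume
from nucmorph.synthetic_data import ChannelModel, SceneSpec, simulate_scene


def _square_nucleus(side: int, at: tuple[int, int] = (20, 20), plane: int = 2) -> LabelVolume:
    labels = np.zeros((5, 60, 60), dtype=np.int32)
    y, x = at
    labels[plane, y : y + side, x : x + side] = 1
    return LabelVolume(labels, CAL)


class TestDefineRegions:
    def test_square_nucleus_oracle(self):
        # brute-force set arithmetic on a 20x20 square with Chebyshev
        # (3x3 structuring element) morphology
        volume = _square_nucleus(20)
        regions = define_regions(volume, 1)
        assert regions.plane == 2

        inside = {(y, x) for y in range(20, 40) for x in range(20, 40)}
        eroded = {(y, x) for y in range(21, 39) for x in range(21, 39)}

        def dilate(pixels, k):
            return {
                (y + dy, x + dx)
                for y, x in pixels
                for dy in range(-k, k + 1)
                for dx in range(-k, k + 1)
            }

        ring = dilate(inside, 3) - dilate(inside, 1)
        assert set(map(tuple, np.argwhere(regions.nuclear))) == eroded
        assert set(map(tuple, np.argwhere(regions.ring))) == ring
        assert regions.nuclear.sum() == 18 * 18

    def test_neighbor_pixels_excluded_from_ring(self):
        labels = np.zeros((3, 40, 40), dtype=np.int32)
        labels[1, 10:20, 10:20] = 1
        labels[1, 10:20, 22:32] = 2  # 2 px gap: ring of 1 would reach into 2
        volume = LabelVolume(labels, CAL)
        regions = define_regions(volume, 1)
        neighbour = labels[1] == 2
        assert not (regions.ring & neighbour).any()
        # without the neighbour the ring would cover those pixels
        alone = LabelVolume((labels == 1).astype(np.int32), CAL)
        regions_alone = define_regions(alone, 1)
        assert (regions_alone.ring & neighbour).any()

    def test_tiny_nucleus_flagged_when_erosion_empties(self):
        regions = define_regions(_square_nucleus(2), 1)
        assert regions.flag == "empty_nuclear_region"

    def test_fully_occluded_ring_flagged(self):
        labels = np.zeros((3, 30, 30), dtype=np.int32)
        labels[1, 10:20, 10:20] = 1
        labels[1] = np.where(labels[1] == 0, 2, labels[1])  # neighbour everywhere
        regions = define_regions(LabelVolume(labels, CAL), 1)
        assert regions.flag == "occluded_ring"


class TestEstimateBackground:
    def _scene(self, noise_sigma: float, rng=None):
        labels = np.zeros((3, 80, 80), dtype=np.int32)
        labels[1, 35:45, 35:45] = 1
        image = np.full((3, 80, 80), 50.0)
        image[1, 30:50, 30:50] = 400.0  # foreground block around nucleus
        if noise_sigma:
            image = image + rng.normal(0, noise_sigma, image.shape)
        return ImageStack({"sensor": np.clip(image, 0, None)}, CAL), LabelVolume(labels, CAL)

    def test_uniform_background_recovered_exactly(self):
        stack, labels = self._scene(0.0)
        estimate = estimate_background(stack, labels, "sensor", plane=1)
        assert estimate.mean == 50.0

    def test_noisy_background_within_standard_error(self):
        rng = np.random.default_rng(8)
        stack, labels = self._scene(5.0, rng)
        estimate = estimate_background(stack, labels, "sensor", plane=1)
        assert estimate.n_pixels > 1000
        sem = 5.0 / math.sqrt(estimate.n_pixels)
        assert estimate.mean == pytest.approx(50.0, abs=5 * sem)
        assert estimate.std == pytest.approx(5.0, rel=0.15)

    def test_confluent_plane_raises(self):
        labels = np.zeros((3, 40, 40), dtype=np.int32)
        labels[1] = 1  # nuclei footprint covers everything
        stack = ImageStack({"sensor": np.full((3, 40, 40), 50.0)}, CAL)
        with pytest.raises(BackgroundError, match="plane 1"):
            estimate_background(stack, LabelVolume(labels, CAL), "sensor", plane=1)


class TestComputeIndex:
    @pytest.mark.parametrize(
        "f_nuc, f_cyt, f_bg, expected",
        [
            (120.0, 120.0, 30.0, 0.0),
            (200.0, 100.0, 0.0, 1.0),
            (300.0, 150.0, 50.0, math.log2(250.0 / 100.0)),  # 1.3219
        ],
    )
    def test_reference_values(self, f_nuc, f_cyt, f_bg, expected):
        assert compute_nc_index(f_nuc, f_cyt, f_bg) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_numerator_or_denominator_flagged(self):
        with pytest.raises(UndefinedIndexError):
            compute_nc_index(40.0, 100.0, 50.0)
        with pytest.raises(UndefinedIndexError):
            compute_nc_index(100.0, 50.0, 50.0)

    @given(
        f_nuc=st.floats(1.0, 1e4),
        f_cyt=st.floats(1.0, 1e4),
        f_bg=st.floats(0.0, 0.99),
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric_under_compartment_swap(self, f_nuc, f_cyt, f_bg):
        forward = compute_nc_index(f_nuc, f_cyt, f_bg)
        backward = compute_nc_index(f_cyt, f_nuc, f_bg)
        assert forward == pytest.approx(-backward, abs=1e-9)


def _record(**overrides) -> CellIntensity:
    base = dict(
        nucleus_id=1, plane=2, sencyt_index=0.5, hoechst_nc_ratio=8.0,
        snr=20.0, cv_nuc=0.2, cv_cyt=0.2,
    )
    base.update(overrides)
    return CellIntensity(**base)


class TestQCFilters:
    def test_clean_record_passes(self):
        assert apply_qc_filters(_record()).qc_pass

    def test_high_cv_discarded_with_reason(self):
        filtered = apply_qc_filters(_record(cv_cyt=0.9))
        assert not filtered.qc_pass
        assert filtered.qc_reasons == ("cv",)

    def test_low_hoechst_ratio_discarded_with_reason(self):
        filtered = apply_qc_filters(_record(hoechst_nc_ratio=3.0))
        assert not filtered.qc_pass
        assert filtered.qc_reasons == ("hoechst_nc",)

    def test_low_snr_discarded_with_reason(self):
        filtered = apply_qc_filters(_record(snr=1.0))
        assert filtered.qc_reasons == ("snr",)

    def test_rules_accumulate_and_are_idempotent(self):
        bad = _record(cv_nuc=0.95, hoechst_nc_ratio=2.0, snr=0.5)
        once = apply_qc_filters(bad)
        assert set(once.qc_reasons) == {"snr", "cv", "hoechst_nc"}
        twice = apply_qc_filters(once)
        assert twice.qc_reasons == once.qc_reasons  # order-independent, stable

    def test_thresholds_configurable(self):
        lax = QCThresholds(snr_min=0.0, cv_max=2.0, hoechst_nc_min=0.0)
        assert apply_qc_filters(_record(cv_nuc=1.5, hoechst_nc_ratio=1.0), lax).qc_pass

    def test_each_rule_only_shrinks_passing_set(self):
        records = [
            _record(), _record(cv_nuc=0.9), _record(snr=0.1),
            _record(hoechst_nc_ratio=1.0),
        ]
        strict = QCThresholds()
        lax = QCThresholds(snr_min=-math.inf, cv_max=math.inf, hoechst_nc_min=-math.inf)
        n_strict = sum(apply_qc_filters(r, strict).qc_pass for r in records)
        n_lax = sum(apply_qc_filters(r, lax).qc_pass for r in records)
        assert n_strict <= n_lax


class TestSceneRecovery:
    def test_noise_free_index_matches_truth(self, quiet_scene):
        table = measure_scene(quiet_scene.stack, quiet_scene.labels)
        merged = table.merge(quiet_scene.truth, on="nucleus_id")
        clean = merged[merged.qc_pass]
        assert len(clean) == len(merged) == 9
        assert np.abs(clean.sencyt_index - clean.true_log2_nc).max() <= 0.05

    def test_uniform_control_channel_index_near_zero(self, quiet_scene):
        table = measure_scene(
            quiet_scene.stack,
            quiet_scene.labels,
            channels=ChannelMap(dna="dna", sensor="uniform"),
        )
        assert abs(table.sencyt_index.mean()) <= 0.1
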