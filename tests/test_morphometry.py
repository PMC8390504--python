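"""Compartment areas, normalized intensity, positivity, coverage index."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embryoquant.core import BinaryMask
from embryoquant.morphometry import (
    PositivityThresholds,
    classify_reporter_positive,
    compute_compartment_areas,
    coverage_index,
    measure_frame,
    normalized_mean_intensity,
)
from embryoquant.synthetic import GeneratorParams, generate_embryoid_image


def _mask_from_box(shape, r0, r1, c0, c1, ps=1.0):
    support = np.zeros(shape, dtype=bool)
    support[r0:r1, c0:c1] = True
    return BinaryMask(support, ps)


class TestCompartmentAreas:
    def test_nested_masks(self):
        shape = (60, 60)
        bf = _mask_from_box(shape, 5, 45, 5, 30)  # 1000 px
        gfp = _mask_from_box(shape, 5, 25, 5, 20)  # 300 px inside bf
        mch = BinaryMask(np.zeros(shape, dtype=bool), 1.0)
        areas = compute_compartment_areas(bf, gfp, mch)
        assert areas.area_total == 1000.0
        assert areas.area_epi == 700.0
        assert areas.area_anterior_epi == 700.0
        assert areas.area_reporter == 0.0

    def test_partial_overlap_uses_set_difference(self):
        shape = (60, 80)
        bf = _mask_from_box(shape, 5, 45, 5, 30)  # 1000 px
        gfp_support = np.zeros(shape, dtype=bool)
        gfp_support[5:25, 25:30] = True  # 100 px inside bf
        gfp_support[5:25, 40:50] = True  # 200 px outside bf
        areas = compute_compartment_areas(
            bf, BinaryMask(gfp_support, 1.0), BinaryMask(np.zeros(shape, bool), 1.0)
        )
        assert areas.area_epi == 900.0  # only the overlapping 100 px removed

    def test_empty_brightfield_is_flagged_zero(self):
        shape = (20, 20)
        empty = BinaryMask(np.zeros(shape, dtype=bool), 1.0)
        areas = compute_compartment_areas(empty, empty, empty)
        assert areas.area_total == 0.0
        assert "no-object" in areas.flags

    def test_noiseless_synthetic_matches_truth_exactly(self):
        params = GeneratorParams(seed=6, noise_sd=0.0)
        _, truth = generate_embryoid_image(params)
        ps = params.pixel_size
        areas = compute_compartment_areas(
            BinaryMask(truth.bf_mask, ps),
            BinaryMask(truth.ts_mask, ps),
            BinaryMask(truth.reporter_mask, ps),
        )
        assert areas.area_total == truth.area_total_um2
        assert areas.area_ts == truth.area_ts_um2
        assert areas.area_epi == truth.area_epi_um2
        assert areas.area_reporter == truth.area_reporter_um2
        assert areas.area_anterior_epi == truth.area_anterior_epi_um2

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_area_conservation_for_random_triples(self, seed):
        """anterior + reporter = EPI and EPI + (GFP∩BF) = total, always."""
        rng = np.random.default_rng(seed)
        shape = (32, 32)
        bf, gfp, mch = (
            BinaryMask(rng.random(shape) < p, 1.0) for p in (0.5, 0.3, 0.3)
        )
        areas = compute_compartment_areas(bf, gfp, mch)
        overlap = (gfp.support & bf.support).sum()
        assert areas.area_anterior_epi + areas.area_reporter == areas.area_epi
        assert areas.area_epi + overlap == areas.area_total
        assert min(areas.area_epi, areas.area_reporter, areas.area_anterior_epi) >= 0

    def test_scale_equivariance(self):
        shape = (40, 40)
        bf = _mask_from_box(shape, 5, 35, 5, 35, ps=1.0)
        gfp = _mask_from_box(shape, 5, 15, 5, 35, ps=1.0)
        mch = _mask_from_box(shape, 20, 35, 5, 35, ps=1.0)
        a1 = compute_compartment_areas(bf, gfp, mch)
        bf2, gfp2, mch2 = (
            BinaryMask(m.support, 2.0) for m in (bf, gfp, mch)
        )
        a2 = compute_compartment_areas(bf2, gfp2, mch2)
        assert a2.area_epi == 4 * a1.area_epi
        assert a2.area_total == 4 * a1.area_total
        epi1 = BinaryMask(a1.epi_support, 1.0)
        epi2 = BinaryMask(a2.epi_support, 2.0)
        assert coverage_index(mch, epi1) == coverage_index(mch2, epi2)

    def test_mismatched_masks_rejected(self):
        a = BinaryMask(np.zeros((10, 10), bool), 1.0)
        b = BinaryMask(np.zeros((12, 10), bool), 1.0)
        with pytest.raises(ValueError):
            compute_compartment_areas(a, b, a)


class TestNormalizedIntensity:
    def test_uniform_signal(self):
        mask = _mask_from_box((20, 20), 5, 15, 5, 15)
        channel = np.full((20, 20), 26.0)
        assert normalized_mean_intensity(channel, mask, 20.0) == pytest.approx(1.3)

    def test_channel_at_background_gives_unity(self):
        mask = _mask_from_box((20, 20), 5, 15, 5, 15)
        assert normalized_mean_intensity(np.full((20, 20), 20.0), mask, 20.0) == 1.0

    def test_empty_mask_is_nan(self):
        empty = BinaryMask(np.zeros((20, 20), bool), 1.0)
        assert math.isnan(normalized_mean_intensity(np.ones((20, 20)), empty, 1.0))

    def test_nonpositive_background_raises(self):
        mask = _mask_from_box((20, 20), 5, 15, 5, 15)
        with pytest.raises(ValueError):
            normalized_mean_intensity(np.ones((20, 20)), mask, 0.0)

    def test_recovers_truth_factor_under_noise(self):
        params = GeneratorParams(seed=5, noise_sd=5.0, reporter_intensity_factor=2.0)
        image, truth = generate_embryoid_image(params)
        mask = BinaryMask(truth.reporter_mask, params.pixel_size)
        ratio = normalized_mean_intensity(
            image.mcherry, mask, params.background_level
        )
        assert 1.9 <= ratio <= 2.1


class TestPositivity:
    @pytest.mark.parametrize(
        "ratio,area,expected",
        [
            (1.30, 1500.0, True),  # both boundaries inclusive
            (1.29, 2000.0, False),
            (2.00, 1499.0, False),
            (2.00, 1500.0, True),
            (1.30, 1499.9, False),
        ],
    )
    def test_criterion_boundaries(self, ratio, area, expected):
        positive, record = classify_reporter_positive(ratio, area)
        assert positive is expected
        assert record["intensity_ratio_min"] == 1.3
        assert record["area_min_um2"] == 1500.0

    def test_undefined_ratio_is_negative_with_flag(self):
        positive, record = classify_reporter_positive(math.nan, 5000.0)
        assert positive is False
        assert "ratio-undefined" in record["flags"]

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            PositivityThresholds(intensity_ratio_min=0.9)


class TestCoverageIndex:
    def test_empty_reporter_is_zero(self):
        epi = _mask_from_box((30, 30), 5, 25, 5, 25)
        empty = BinaryMask(np.zeros((30, 30), bool), 1.0)
        assert coverage_index(empty, epi) == 0.0

    def test_superset_reporter_is_one(self):
        epi = _mask_from_box((30, 30), 5, 25, 5, 25)
        full = BinaryMask(np.ones((30, 30), bool), 1.0)
        assert coverage_index(full, epi) == 1.0

    def test_empty_epi_is_nan(self):
        empty = BinaryMask(np.zeros((30, 30), bool), 1.0)
        assert math.isnan(coverage_index(empty, empty))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_growing_reporter_never_decreases_coverage(self, seed):
        rng = np.random.default_rng(seed)
        shape = (32, 32)
        epi = BinaryMask(rng.random(shape) < 0.5, 1.0)
        if epi.is_empty:
            return
        small = rng.random(shape) < 0.3
        grown = small | (rng.random(shape) < 0.2)
        assert coverage_index(BinaryMask(grown, 1.0), epi) >= coverage_index(
            BinaryMask(small, 1.0), epi
        )

    def test_synthetic_cap_recovered(self):
        params = GeneratorParams(seed=9, noise_sd=5.0, reporter_coverage=0.40,
                                 reporter_intensity_factor=2.0)
        image, truth = generate_embryoid_image(params)
        meas = measure_frame(image)
        assert abs(meas.coverage_index - truth.coverage) <= 0.03


class TestParameterRecovery:
    def test_coverage_and_positivity_recovered_across_conditions(self, rng):
        """Random q and f with 5% noise: coverage within ±0.05 in ≥90% of
        embryoids, and positivity calls match the ground-truth rule
        (f ≥ 1.3 and truth reporter area ≥ 1500 µm²) in ≥95%."""
        n = 50
        cov_ok = pos_ok = 0
        for i in range(n):
            q = float(rng.uniform(0, 1))
            f = float(rng.uniform(1, 3))
            params = GeneratorParams(
                seed=3000 + i, reporter_coverage=q,
                reporter_intensity_factor=f, noise_sd=5.0,
            )
            image, truth = generate_embryoid_image(params)
            meas = measure_frame(image)
            cov_ok += abs(meas.coverage_index - truth.coverage) <= 0.05
            truth_positive = f >= 1.3 and truth.area_reporter_um2 >= 1500.0
            pos_ok += meas.positive == truth_positive
        assert cov_ok >= 0.9 * n
        assert pos_ok >= 0.95 * n
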