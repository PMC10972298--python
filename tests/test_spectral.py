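import numpy as np
import pytest

from urinmr import spectral
from urinmr.io import Spectrum
from urinmr.simulate import CohortConfig, default_library, simulate_cohort
from urinmr.spectral import (
    AlignmentParams,
    align_rspa,
    dynamic_adaptive_bins,
    exclude_regions,
    integrate_bins,
    mean_spectrum,
    reference_to_tsp,
    select_reference_spectrum,
)

from conftest import make_spectrum


class TestReferencing:
    def test_apex_already_at_zero_unchanged(self):
        # 9501 points over (-0.5, 9.0) puts 0.000 exactly on the grid
        s = make_spectrum([0.0, 3.0], window=(-0.5, 9.0), points=9501)
        out = reference_to_tsp(s, (-0.2, 0.2))
        np.testing.assert_allclose(out.ppm, s.ppm, atol=1e-9)

    def test_apex_offset_translates_axis(self):
        s = make_spectrum([0.1, 3.0], window=(-0.5, 9.0), points=9501)
        out = reference_to_tsp(s, (-0.2, 0.2))
        apex = out.ppm[np.argmax(out.intensity * (np.abs(out.ppm) < 0.3))]
        assert apex == pytest.approx(0.0, abs=1e-6)
        # intensities untouched, axis rigidly shifted by -0.1
        np.testing.assert_array_equal(out.intensity, s.intensity)
        assert out.ppm[0] - s.ppm[0] == pytest.approx(-0.1, abs=1e-3)

    def test_planted_tsp_lands_at_zero(self):
        s = make_spectrum([-0.010, 5.0], heights=[5.0, 1.0], window=(-0.5, 9.0))
        out = reference_to_tsp(s, (-0.2, 0.2))
        assert abs(out.ppm[np.argmax(out.intensity)]) < 1e-9

    def test_empty_window_rejected(self):
        s = make_spectrum([3.0], window=(0.0, 9.0))
        with pytest.raises(ValueError):
            reference_to_tsp(s, (-0.9, -0.5))


class TestReferenceSelection:
    def test_identical_pair_plus_shifted_picks_lowest_identical(self):
        base = make_spectrum([2.0, 5.0])
        shifted = Spectrum(base.ppm.copy(), np.roll(base.intensity, 40))
        idx = select_reference_spectrum([base, Spectrum(base.ppm.copy(),
                                                        base.intensity.copy()), shifted])
        assert idx == 0

    def test_all_identical_ties_to_zero(self):
        s = make_spectrum([2.0])
        copies = [Spectrum(s.ppm.copy(), s.intensity.copy()) for _ in range(3)]
        assert select_reference_spectrum(copies) == 0

    def test_mismatched_grids_rejected(self):
        a = make_spectrum([2.0], points=100)
        b = make_spectrum([2.0], points=101)
        with pytest.raises(ValueError, match="common"):
            select_reference_spectrum([a, b])


class TestAlignment:
    def test_identical_spectrum_unchanged(self):
        s = make_spectrum([1.0, 4.0, 7.0])
        out = align_rspa([s, Spectrum(s.ppm.copy(), s.intensity.copy())], 0)
        np.testing.assert_array_equal(out[1].intensity, s.intensity)

    def test_uniform_translation_recovered(self):
        ref = make_spectrum([1.5, 3.2, 5.1, 7.4])
        moved = Spectrum(ref.ppm.copy(), np.roll(ref.intensity, 5))
        out = align_rspa([ref, moved], 0)
        assert np.argmax(out[1].intensity) == np.argmax(ref.intensity)
        assert np.max(np.abs(out[1].intensity - ref.intensity)) < 1e-4

    def test_alignment_reduces_apex_error_on_jittered_cohorts(self, library):
        # Monte-Carlo improvement property over several seeds
        before_err, after_err = [], []
        for seed in range(6):
            cfg = CohortConfig(seed=seed, points=4096, jitter_sd=0.005,
                               noise_sd=0.001, dilution_sd=0.0)
            cohort = simulate_cohort(cfg, library)
            specs = list(cohort.spectra.values())
            ref_idx = select_reference_spectrum(specs)
            aligned = align_rspa(specs, ref_idx)
            ref = specs[ref_idx]
            anchors = [2.157, 6.494, 8.219]
            for anchor in anchors:
                m = (ref.ppm < anchor + 0.1) & (ref.ppm > anchor - 0.1)
                ref_apex = ref.ppm[m][np.argmax(ref.intensity[m])]
                for s_b, s_a in zip(specs, aligned):
                    b = s_b.ppm[m][np.argmax(s_b.intensity[m])]
                    a = s_a.ppm[m][np.argmax(s_a.intensity[m])]
                    before_err.append(abs(b - ref_apex))
                    after_err.append(abs(a - ref_apex))
        assert np.mean(after_err) < np.mean(before_err)

    def test_total_integral_preserved_up_to_padding(self):
        ref = make_spectrum([1.5, 3.2, 5.1, 7.4])
        moved = Spectrum(ref.ppm.copy(), np.roll(ref.intensity, 7))
        out = align_rspa([ref, moved], 0)
        total = lambda s: -np.trapezoid(s.intensity, s.ppm)  # noqa: E731
        assert total(out[1]) == pytest.approx(total(moved), rel=0.005)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AlignmentParams(max_shift=-1.0)
        with pytest.raises(ValueError):
            AlignmentParams(min_segment_points=4)


class TestBinning:
    def test_separated_lorentzians_get_one_bin_each(self):
        # peaks >= 10 linewidths apart: troughs are unambiguous
        s = make_spectrum([2.0, 4.0, 6.0], hwhm=0.05)
        bins = dynamic_adaptive_bins(s, min_bin_width=0.1,
                                     noise_floor=0.02, smoothing_points=3)
        for apex in [2.0, 4.0, 6.0]:
            hits = [b for b in bins if b.right < apex < b.left
                    and s.intensity[np.argmin(np.abs(s.ppm - b.center))] > 0.02]
            assert len(hits) == 1

    def test_flat_spectrum_below_floor_single_bin(self):
        s = Spectrum(np.linspace(9, 0, 500), np.full(500, 0.001))
        bins = dynamic_adaptive_bins(s, 0.05, noise_floor=0.01)
        assert len(bins) == 1
        assert bins[0].left == pytest.approx(9.0)
        assert bins[0].right == pytest.approx(0.0)

    def test_wider_min_width_never_increases_bin_count(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            centers = rng.uniform(0.5, 8.5, size=rng.integers(3, 12))
            s = make_spectrum(centers, hwhm=0.05)
            n_narrow = len(dynamic_adaptive_bins(s, 0.05, 0.0, 3))
            n_wide = len(dynamic_adaptive_bins(s, 0.10, 0.0, 3))
            assert n_wide <= n_narrow

    def test_bins_partition_window_and_sum_to_total(self):
        s = make_spectrum([1.0, 2.5, 5.5, 8.0], hwhm=0.05)
        bins = dynamic_adaptive_bins(s, 0.05, 0.0, 3)
        lefts = [b.left for b in bins]
        rights = [b.right for b in bins]
        assert lefts[0] == pytest.approx(s.ppm[0])
        assert rights[-1] == pytest.approx(s.ppm[-1])
        np.testing.assert_allclose(lefts[1:], rights[:-1])
        fm = integrate_bins({"x": s}, bins)
        total = -np.trapezoid(s.intensity, s.ppm)
        assert fm.values.sum(axis=1).iloc[0] == pytest.approx(total, rel=1e-9)

    def test_min_width_exceeding_window_rejected(self):
        s = make_spectrum([2.0], window=(0.0, 1.0))
        with pytest.raises(ValueError):
            dynamic_adaptive_bins(s, min_bin_width=5.0)


class TestExclusionAndIntegration:
    def test_overlapping_bin_marked_excluded(self):
        s = make_spectrum([4.85], hwhm=0.05)
        bins = dynamic_adaptive_bins(s, 0.05, 0.0, 3)
        out = exclude_regions(bins, [(4.70, 5.00)])
        overlapping = [b for b in out if b.right < 5.0 and b.left > 4.7]
        assert overlapping and all(b.excluded for b in overlapping)

    def test_empty_region_list_no_change(self):
        s = make_spectrum([3.0])
        bins = dynamic_adaptive_bins(s, 0.05, 0.0, 3)
        assert exclude_regions(bins, []) == bins

    def test_whole_window_excluded_then_integration_errors(self):
        s = make_spectrum([3.0], window=(0.0, 9.0))
        bins = dynamic_adaptive_bins(s, 0.05, 0.0, 3)
        out = exclude_regions(bins, [(-1.0, 10.0)])
        assert all(b.excluded for b in out)
        with pytest.raises(ValueError, match="non-excluded"):
            integrate_bins({"x": s}, out)

    def test_unit_rectangle_integrates_to_width(self):
        ppm = np.linspace(9, 0, 9001)
        y = ((ppm <= 5.0) & (ppm >= 4.9)).astype(float)
        s = Spectrum(ppm, y)
        bins = [spectral.BinDefinition(left=5.0, right=4.9, center=4.95)]
        fm = integrate_bins({"x": s}, bins)
        assert fm.values.iloc[0, 0] == pytest.approx(0.1, rel=1e-3)

    def test_zero_spectrum_gives_zero_row(self):
        s = Spectrum(np.linspace(9, 0, 100), np.zeros(100))
        bins = [spectral.BinDefinition(left=8.0, right=1.0, center=4.0)]
        fm = integrate_bins({"x": s}, bins)
        assert (fm.values.to_numpy() == 0).all()

    def test_lorentzian_in_one_bin_matches_closed_form(self):
        s = make_spectrum([4.0], heights=[2.0], hwhm=0.01, points=40000)
        bins = [spectral.BinDefinition(left=4.5, right=3.5, center=4.0)]
        fm = integrate_bins({"x": s}, bins)
        assert fm.values.iloc[0, 0] == pytest.approx(2.0 * np.pi * 0.01, rel=0.02)


def test_pipeline_processing_is_deterministic(library):
    cfg = CohortConfig(seed=11, points=2048)
    runs = []
    for _ in range(2):
        cohort = simulate_cohort(cfg, library)
        specs = list(cohort.spectra.values())
        aligned = align_rspa(specs, select_reference_spectrum(specs))
        ms = mean_spectrum(aligned)
        bins = exclude_regions(dynamic_adaptive_bins(ms, 0.02, 0.01, 5))
        runs.append(integrate_bins(dict(zip(cohort.spectra, aligned)), bins).values)
    np.testing.assert_array_equal(runs[0].to_numpy(), runs[1].to_numpy())
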