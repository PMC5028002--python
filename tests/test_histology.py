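"""Profiles, robust smoothing, KS comparison, lengths, areas, Table stats."""

import numpy as np
import pytest

from corticomap import errors
from corticomap.datasets import macaque_area_table, macaque_method_pairs
from corticomap.histology import (
    IntensityProfile,
    aggregate_area,
    compare_profiles,
    extract_profile,
    method_agreement,
    section_myelin_length,
    smooth_profile,
    summarize_areas,
)
from corticomap.phantom import (
    make_phantom,
    render_histology,
    histology_pial_trace,
)


def _profile(values, step=15.0):
    values = np.asarray(values, float)
    return IntensityProfile(np.arange(len(values)) * step, values,
                            np.zeros(len(values)), np.full(len(values), 6))


class TestExtractProfile:
    def test_constant_image_flat_profile(self):
        img = np.full((60, 60), 5.0)
        path = np.array([[5.0, 5.0], [50.0, 5.0]])
        prof = extract_profile(img, path, pixel_size_mm=0.015)
        np.testing.assert_allclose(prof.mean, 5.0)
        np.testing.assert_allclose(prof.sd, 0.0)
        assert np.all(prof.n == 6)

    def test_linear_field_linear_profile(self):
        img = np.tile(np.arange(80.0)[:, None], (1, 40))
        path = np.array([[5.0, 20.0], [70.0, 20.0]])
        prof = extract_profile(img, path, pixel_size_mm=0.015)
        diffs = np.diff(prof.mean)
        np.testing.assert_allclose(diffs, diffs[0], rtol=1e-6)

    def test_path_exiting_image_rejected(self):
        img = np.zeros((20, 20))
        path = np.array([[5.0, 5.0], [40.0, 5.0]])
        with pytest.raises(errors.ProfileError):
            extract_profile(img, path, pixel_size_mm=0.015)

    def test_phantom_profile_darkest_at_myelin_band(self, slab_spec):
        surface, truth = make_phantom(slab_spec)
        series = render_histology(surface, truth, slab_spec)
        mid = len(series) // 2
        img = series.images[mid]
        # pial-to-white path through the patch centre
        px = series.pixel_size
        col = slab_spec.extent[1] / 2 / px
        zmax = slab_spec.fold_amplitude + slab_spec.thickness / 2 + 0.5
        pial_row = (zmax - slab_spec.thickness / 2) / px
        white_row = (zmax + slab_spec.thickness / 2) / px
        path = np.array([[pial_row, col], [white_row, col]])
        prof = extract_profile(img, path, pixel_size_mm=px)
        # darkest point sits at the configured depth (0.6 from white =
        # 0.4 of the way down from the pial surface in this geometry)
        frac = np.argmin(prof.mean) / (len(prof) - 1)
        assert abs(frac - (1 - slab_spec.peak_depth)) < 0.1


class TestSmoothProfile:
    def test_constant_unchanged(self):
        prof = _profile(np.full(20, 3.0))
        sm = smooth_profile(prof)
        np.testing.assert_allclose(sm.mean, 3.0)

    def test_quadratic_reproduced_exactly(self):
        x = np.arange(30) * 15.0
        prof = _profile(0.002 * x ** 2 - 0.3 * x + 7.0)
        sm = smooth_profile(prof, span=0.4)
        np.testing.assert_allclose(sm.mean, prof.mean, rtol=1e-6)

    def test_outlier_downweighted(self):
        x = np.arange(25) * 15.0
        clean = 0.5 * x + 10.0
        dirty = clean.copy()
        dirty[12] += 50 * clean.mean()  # gross outlier
        sm = smooth_profile(_profile(dirty), span=0.4)
        assert abs(sm.mean[12] - clean[12]) / clean[12] < 0.05

    def test_too_few_points(self):
        with pytest.raises(errors.ProfileError):
            smooth_profile(_profile([1, 2, 3]))


class TestCompareProfiles:
    def test_identical_zero_d(self):
        a = _profile([1, 2, 3, 4])
        d, p = compare_profiles(a, a)
        assert d == 0.0

    def test_fully_separated(self):
        d, _ = compare_profiles(_profile([1, 2, 3]), _profile([4, 5, 6]))
        assert d == 1.0

    def test_hand_computed_quarter(self):
        d, _ = compare_profiles(_profile([1, 2, 3, 4]),
                                _profile([2, 3, 4, 5]))
        assert d == pytest.approx(0.25)

    def test_matches_ecdf_oracle(self, rng):
        def ks_oracle(a, b):
            pooled = np.concatenate([a, b])
            fa = np.array([(a <= t).mean() for t in pooled])
            fb = np.array([(b <= t).mean() for t in pooled])
            return np.abs(fa - fb).max()

        for _ in range(500):
            a = rng.normal(size=rng.integers(2, 12))
            b = rng.normal(rng.uniform(-1, 1), size=rng.integers(2, 12))
            d, _ = compare_profiles(_profile(a), _profile(b))
            assert d == pytest.approx(ks_oracle(a, b))

    def test_single_point_rejected(self):
        with pytest.raises(errors.ProfileError):
            compare_profiles(_profile([1.0]), _profile([1, 2, 3]))


class TestSectionLength:
    def test_no_dark_pixels_zero(self):
        img = np.full((40, 100), 200.0)
        trace = np.array([[10.0, 0.0], [10.0, 99.0]])
        total, runs = section_myelin_length(img, 100.0, trace, 0.05, 0.5)
        assert total == 0.0 and runs == []

    def test_two_disjoint_runs(self):
        img = np.full((40, 200), 200.0)
        img[15:25, 40:80] = 50.0    # 2 mm run at 0.05 mm pixels
        img[15:25, 120:140] = 50.0  # 1 mm run
        trace = np.array([[10.0, 0.0], [10.0, 199.0]])
        total, runs = section_myelin_length(img, 100.0, trace, 0.05, 0.5)
        assert len(runs) == 2
        assert total == pytest.approx(3.0, abs=0.15)

    def test_phantom_chord_recovered(self, slab_spec):
        surface, truth = make_phantom(slab_spec)
        series = render_histology(surface, truth, slab_spec)
        probe = (1 - slab_spec.peak_depth) * slab_spec.thickness
        for i in range(len(series)):
            trace = histology_pial_trace(slab_spec, series, i)
            total, _ = section_myelin_length(series.images[i], 90.0, trace,
                                             series.pixel_size, probe)
            assert total == pytest.approx(truth.section_lengths_mm[i],
                                          abs=2 * series.pixel_size + 0.05)


class TestAggregateArea:
    def test_constant_lengths(self):
        assert aggregate_area([2, 2, 2], 0.5) == pytest.approx(2.0)

    def test_tapered(self):
        assert aggregate_area([0, 4, 0], 1.0) == pytest.approx(4.0)

    def test_single_section_padded(self):
        assert aggregate_area([0, 3, 0], 0.5) == pytest.approx(3 * 0.5)

    def test_too_few_sections(self):
        with pytest.raises(errors.DegenerateInputError):
            aggregate_area([2.0], 0.5)

    def test_linear_in_spacing_and_lengths(self, rng):
        lengths = rng.uniform(0, 5, 9)
        a1 = aggregate_area(lengths, 0.5)
        assert aggregate_area(2 * lengths, 0.5) == pytest.approx(2 * a1)
        assert aggregate_area(lengths, 1.0) == pytest.approx(2 * a1)

    def test_refinement_stability(self):
        # halving spacing with interpolated lengths barely moves the result
        x = np.linspace(0, 4, 9)
        lengths = np.sqrt(np.clip(4 - (x - 2) ** 2, 0, None))
        coarse = aggregate_area(lengths, 0.5)
        xf = np.linspace(0, 4, 17)
        fine = aggregate_area(np.interp(xf, x, lengths), 0.25)
        assert abs(fine - coarse) / coarse < 0.01


class TestSummarizeAreas:
    def test_reproduces_published_cells(self):
        table = macaque_area_table()
        summ = summarize_areas(table, pooled={"mri_both": ["mri_lh",
                                                           "mri_rh"]})
        assert round(summ.loc["mean", "mri_lh"], 1) == 83.6
        assert round(summ.loc["sd", "mri_lh"], 1) == 12.4
        assert round(summ.loc["mean", "hist_lh"], 1) == 78.0
        assert round(summ.loc["sd", "hist_lh"], 1) == 10.6
        assert round(summ.loc["mean", "mri_rh"], 1) == 81.2
        assert round(summ.loc["sd", "mri_rh"], 1) == 4.5
        assert round(summ.loc["mean", "mri_both"], 1) == 82.4
        assert round(summ.loc["sd", "mri_both"], 1) == 8.9
        assert summ.loc["n", "mri_both"] == 10

    def test_single_value_sd_missing(self):
        import pandas as pd

        summ = summarize_areas(pd.DataFrame({"a": [65.1]}))
        assert summ.loc["mean", "a"] == 65.1
        assert np.isnan(summ.loc["sd", "a"])


class TestMethodAgreement:
    def test_proportional_pairs(self):
        r, _, n = method_agreement([(1, 2), (2, 4), (3, 6), (4, 8)])
        assert r == pytest.approx(1.0)

    def test_anti_proportional(self):
        r, _, _ = method_agreement([(1, 8), (2, 6), (3, 4), (4, 2)])
        assert r == pytest.approx(-1.0)

    def test_published_pairs(self):
        pairs = macaque_method_pairs()
        assert len(pairs) == 4
        r, p, n = method_agreement(pairs)
        assert r == pytest.approx(0.996, abs=0.001)
        assert p < 0.05

    def test_incomplete_pairs_dropped(self):
        r, _, n = method_agreement([(1, 2), (2, 4), (3, 6), (np.nan, 5),
                                    (4, None)])
        assert n == 3

    def test_too_few_pairs(self):
        with pytest.raises(errors.DegenerateInputError):
            method_agreement([(1, 2), (2, 4)])

    def test_zero_variance(self):
        with pytest.raises(errors.DegenerateInputError):
            method_agreement([(1, 2), (1, 4), (1, 6)])
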