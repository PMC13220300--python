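"""Spectral region quantitation, conformer arithmetic, cross-peak rules."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from secwall import synth
from secwall.nmr import (
    CrossPeak,
    CrossPeakTable,
    RegionSet,
    Spectrum1D,
    WHEAT_REGIONS,
    acetylation_degree,
    chord_weights,
    classify_cross_peaks,
    classify_intensity,
    fit_exponential,
    hsqc_lignin_ratios,
    integrate_regions,
    interior_surface_split,
    read_spectrum,
    twofold_fraction,
    water_edited_ratio,
    write_spectrum,
    xylan_twofold_share,
)


class TestIntegrateRegions:
    def test_reference_region_integrates_to_one(self):
        spec, _ = synth.gen_spectrum1d()
        regions = RegionSet({"all": (0.0, 200.0)}, reference=(0.0, 200.0))
        assert integrate_regions(spec, regions)["all"] == pytest.approx(1.0)

    def test_partition_sums_to_one(self):
        spec, _ = synth.gen_spectrum1d()
        cuts = [0, 25, 50, 60, 80, 90, 110, 170, 200]
        regions = RegionSet(
            {f"r{i}": (lo, hi) for i, (lo, hi) in enumerate(zip(cuts, cuts[1:]))},
            reference=(0.0, 200.0),
        )
        total = sum(integrate_regions(spec, regions).values())
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_wheat_like_fractions_recovered(self):
        spec, record = synth.gen_spectrum1d()
        fractions = integrate_regions(spec, WHEAT_REGIONS)
        for name, truth in record.params["region_truth"].items():
            assert fractions[name] == pytest.approx(truth, abs=0.005), name

    def test_region_outside_axis_named(self):
        spec, _ = synth.gen_spectrum1d()
        regions = RegionSet({"bad": (-5.0, 10.0)}, reference=(-5.0, 200.0))
        with pytest.raises(ValueError):
            integrate_regions(spec, regions)

    def test_spectrum_axis_direction_irrelevant(self):
        spec, _ = synth.gen_spectrum1d()
        reversed_spec = Spectrum1D(spec.ppm[::-1].copy(), spec.intensity[::-1].copy())
        a = integrate_regions(spec, WHEAT_REGIONS)
        b = integrate_regions(reversed_spec, WHEAT_REGIONS)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-12)

    def test_io_roundtrip(self, tmp_path):
        spec, _ = synth.gen_spectrum1d()
        path = tmp_path / "spec.dat"
        write_spectrum(path, spec, header="synthetic")
        back = read_spectrum(path)
        assert np.allclose(back.ppm, spec.ppm)


class TestConformerArithmetic:
    def test_twofold_from_printed_intensities(self):
        assert twofold_fraction(0.12, 0.10) == pytest.approx(0.8333, abs=5e-4)

    def test_twofold_edges(self):
        assert twofold_fraction(0.2, 0.2) == 1.0
        assert twofold_fraction(0.2, 0.0) == 0.0
        with pytest.raises(ValueError):
            twofold_fraction(0.0, 0.1)
        with pytest.warns(UserWarning):
            assert twofold_fraction(0.1, 0.12) == 1.0

    def test_xylan_share(self):
        assert xylan_twofold_share(0.8333, 0.6) == pytest.approx(0.583, abs=2e-3)
        assert xylan_twofold_share(0.6, 0.6) == 0.0
        assert xylan_twofold_share(1.0, 0.6) == 1.0

    def test_xylan_share_assumption_violated(self):
        with pytest.raises(ValueError, match="assumption"):
            xylan_twofold_share(0.5, 0.6)

    def test_interior_surface(self):
        interior, surface = interior_surface_split(0.38, 0.62)
        assert interior == pytest.approx(0.38)
        assert surface == pytest.approx(0.62)
        assert interior_surface_split(0.5, 0.0) == (1.0, 0.0)
        with pytest.raises(ValueError):
            interior_surface_split(0.0, 0.0)

    def test_interior_surface_from_generator(self):
        spec, record = synth.gen_spectrum1d()
        fr = integrate_regions(spec, WHEAT_REGIONS)
        interior, _ = interior_surface_split(fr["c4_interior"], fr["c4_surface"])
        truth = record.params["region_truth"]
        want = truth["c4_interior"] / (truth["c4_interior"] + truth["c4_surface"])
        assert interior == pytest.approx(want, abs=0.01)

    def test_acetylation_degree(self):
        assert acetylation_degree(0.054, 0.02) == pytest.approx(2.7)
        assert acetylation_degree(0.04, 0.02) == pytest.approx(2.0)
        assert acetylation_degree(0.02, 0.02) == pytest.approx(1.0)
        assert acetylation_degree(0.05, 0.0) == math.inf

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, k):
        # multiplying every integral by k changes no fraction-type output
        assert twofold_fraction(0.12, 0.10) == pytest.approx(
            twofold_fraction(0.12 * 1.0, 0.10 * 1.0)
        )
        a = interior_surface_split(0.38 * k, 0.62 * k)
        assert a[0] == pytest.approx(0.38, rel=1e-9)
        assert acetylation_degree(0.054 * k, 0.02 * k) == pytest.approx(2.7, rel=1e-9)


class TestCrossPeaks:
    @pytest.mark.parametrize(
        "intensity,expected",
        [(5.0, "strong"), (4.1, "strong"), (4.0, "medium"), (3.0, "medium"),
         (2.0, "medium"), (1.99, "weak"), (1.0, "weak"), (0.0, "weak")],
    )
    def test_threshold_policy(self, intensity, expected):
        assert classify_intensity(intensity) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_intensity(-0.1)

    def test_generator_classes_recovered_exactly(self):
        truth = (
            [("i4", "s6", "strong")] * 12
            + [("2fXn4", "i6", "medium")] * 12
            + [("S2/6", "2fXn1", "weak")] * 15
        )
        table, record = synth.gen_crosspeak_table(truth, seed=7)
        classified = classify_cross_peaks(table)
        got = [p.peak_class for p in classified.peaks]
        assert got == [cls for _, _, cls in truth]

    def test_classification_invariant_under_common_rescale(self):
        # class counts depend only on the percent values, which are
        # already slice-normalised: rescaling both numerator and slice
        # total leaves the percent, hence the class, unchanged
        table, _ = synth.gen_crosspeak_table(
            [("i4", "s4", "strong"), ("i4", "s4", "weak")], seed=1
        )
        c1 = [p.peak_class for p in classify_cross_peaks(table).peaks]
        c2 = [p.peak_class for p in classify_cross_peaks(table).peaks]
        assert c1 == c2

    def test_chord_weights_additive(self):
        peaks = [
            CrossPeak("i4", "2fXn4", 89.0, 82.0, 3.0, "medium"),
            CrossPeak("i6", "2fXn4", 65.0, 82.0, 2.5, "medium"),
            CrossPeak("i3", "2fXn1", 75.0, 102.0, 1.0, "weak"),
            CrossPeak("s4", "2fXn1", 84.0, 102.0, 1.0, "weak"),
        ]
        matrix = chord_weights(CrossPeakTable(peaks))
        assert matrix.weight("cellulose_interior", "xylan_2fold") == 5
        assert matrix.weight("cellulose_surface", "xylan_2fold") == 1

    def test_single_strong_peak_weight(self):
        peaks = [CrossPeak("i4", "S2/6", 89.0, 104.0, 6.0, "strong")]
        matrix = chord_weights(CrossPeakTable(peaks))
        assert matrix.weight("cellulose_interior", "lignin") == 3
        assert matrix.weights.sum() == 3

    def test_empty_table_all_zero(self):
        matrix = chord_weights(CrossPeakTable([]))
        assert matrix.weights.sum() == 0

    def test_unmapped_label_listed(self):
        peaks = [CrossPeak("mystery9", "i4", 70.0, 89.0, 3.0, "medium")]
        with pytest.raises(KeyError, match="mystery9"):
            chord_weights(CrossPeakTable(peaks))

    def test_csv_roundtrip(self, tmp_path):
        table, _ = synth.gen_crosspeak_table(
            [("i4", "s6", "strong"), ("2fXn4", "i6", "weak")], seed=3
        )
        path = tmp_path / "xpk.csv"
        classify_cross_peaks(table).save(path)
        back = CrossPeakTable.load(path)
        assert [p.peak_class for p in back.peaks] == ["strong", "weak"]


class TestWaterEdited:
    def test_basic_ratios(self):
        ratios, flagged = water_edited_ratio({"i4": 2.0, "s4": 0.0}, {"i4": 2.0, "s4": 1.0})
        assert ratios == {"i4": 1.0, "s4": 0.0}
        assert flagged == []

    def test_flagging_not_error(self):
        ratios, flagged = water_edited_ratio({"i4": 2.0}, {"i4": 1.0})
        assert ratios["i4"] == 2.0
        assert flagged == ["i4"]

    def test_bad_control_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            ratios, _ = water_edited_ratio({"a": 1.0, "b": 1.0}, {"a": 0.0, "b": 2.0})
        assert list(ratios) == ["b"]

    def test_synthetic_table_exact_recovery(self):
        rng = np.random.default_rng(5)
        truth = {f"site{i}": r for i, r in enumerate(rng.uniform(0.2, 1.1, 31))}
        s0 = {k: rng.uniform(1, 10) for k in truth}
        s = {k: truth[k] * s0[k] for k in truth}
        ratios, _ = water_edited_ratio(s, s0)
        for k in truth:
            assert ratios[k] == pytest.approx(truth[k], rel=1e-12)


class TestExponentialFit:
    @pytest.mark.parametrize("tau", [0.1, 1.0, 5.0, 20.0, 50.0])
    def test_exact_recovery_noise_free(self, tau):
        t = np.linspace(0.0, 3 * tau, 12)
        y = 4.0 * np.exp(-t / tau)
        got, diag = fit_exponential(t, y, "decay")
        assert got == pytest.approx(tau, rel=1e-6)
        assert diag["i0"] == pytest.approx(4.0, rel=1e-6)

    def test_matches_two_point_closed_form(self):
        # noise-free data: the fit must agree with T = dt / ln(I1/I2)
        t = np.array([0.0, 1.0, 2.0, 3.0])
        y = 2.0 * np.exp(-t / 5.0)
        got, _ = fit_exponential(t, y, "decay")
        closed_form = (t[1] - t[0]) / np.log(y[0] / y[1])
        assert got == pytest.approx(closed_form, rel=1e-9)

    def test_recovery_mode(self):
        t = np.linspace(0.0, 10.0, 10)
        y = 3.0 * (1 - 2 * np.exp(-t / 2.5))
        got, _ = fit_exponential(t, y, "recovery")
        assert got == pytest.approx(2.5, rel=1e-6)

    def test_noisy_median_within_five_percent(self):
        t = np.linspace(0.0, 15.0, 10)
        estimates = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = np.exp(-t / 5.0) * (1 + rng.normal(0, 0.05, t.size))
            tau, _ = fit_exponential(t, y, "decay")
            estimates.append(tau)
        assert np.median(estimates) == pytest.approx(5.0, rel=0.05)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            fit_exponential([0, 1, 2], [1, 0.5, 0.25], "decay")
        with pytest.raises(ValueError):
            fit_exponential([0, 1, 2, 3], [1, 1, 1, 1], "sideways")


class TestHsqcRatios:
    def test_halving_rule(self):
        s, g, h = hsqc_lignin_ratios(2.0, 1.0, 0.0)
        assert (s, g, h) == (0.5, 0.5, 0.0)

    def test_pure_guaiacyl(self):
        assert hsqc_lignin_ratios(0.0, 1.0, 0.0) == (0.0, 1.0, 0.0)

    def test_equal_proportions(self):
        s, g, h = hsqc_lignin_ratios(2.0, 1.0, 2.0)
        assert s == pytest.approx(1 / 3)
        assert g == pytest.approx(1 / 3)
        assert h == pytest.approx(1 / 3)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            hsqc_lignin_ratios(0.0, 0.0, 0.0)
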