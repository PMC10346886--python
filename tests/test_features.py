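"""Spectral features against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from eegselect.features import (
    BANDS,
    FEATURE_NAMES,
    LOG_FLOOR,
    PSD,
    REDUCED_FEATURES,
    FeatureError,
    apply_out_of_range,
    compute_psd,
    extract_features,
    fit_out_of_range_ranges,
    out_of_range_count,
    relative_band_power,
    root_total_power,
    spectral_edge_frequency,
    spectral_entropy,
    spectral_moment,
    spectral_slope_intercept,
)

from conftest import FS, flat_psd, make_psd, random_psds


def single_bin_psd(freq=10.0, value=100.0):
    freqs = np.arange(1.0, 50.25, 0.5)
    power = np.zeros(len(freqs))
    power[np.argmin(np.abs(freqs - freq))] = value
    return PSD(freqs, power)


class TestComputePSD:
    def test_sinusoid_peaks_at_its_frequency(self):
        t = np.arange(int(20 * FS)) / FS
        psd = compute_psd(np.sin(2 * np.pi * 10 * t), FS)
        assert psd.frequencies[np.argmax(psd.power)] == pytest.approx(10.0, abs=psd.resolution)

    def test_nonnegative_everywhere(self):
        rng = np.random.default_rng(0)
        psd = compute_psd(rng.standard_normal(int(20 * FS)), FS)
        assert np.all(psd.power >= 0)

    def test_parseval_integral_matches_variance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(20 * FS))
        psd = compute_psd(x, FS)
        integral = np.trapezoid(psd.power, psd.frequencies)
        assert integral == pytest.approx(np.var(x), rel=0.05)

    def test_all_zero_input_gives_zero_psd(self):
        psd = compute_psd(np.zeros(int(4 * FS)), FS)
        assert np.all(psd.power == 0)


class TestRootTotalPower:
    def test_sinusoid_rms(self):
        t = np.arange(int(20 * FS)) / FS
        x = 3.0 * np.sin(2 * np.pi * 10 * t)
        psd = compute_psd(x, FS)
        assert root_total_power(psd) == pytest.approx(3.0 / np.sqrt(2), rel=0.05)

    def test_zero_signal(self):
        assert root_total_power(make_psd(np.zeros(99))) == 0.0

    def test_matches_temporal_std_of_bandlimited_noise(self):
        from eegselect.preprocess import filter_signal
        from eegselect.synthetic import Recording
        from eegselect.montage import CHANNELS_1020

        rng = np.random.default_rng(3)
        sig = rng.standard_normal((19, int(60 * FS)))
        rec = filter_signal(
            Recording("p", CHANNELS_1020, FS, sig), (1.0, 40.0), notch=None
        )
        x = rec.signal[0]
        psd = compute_psd(x, FS)
        assert root_total_power(psd) == pytest.approx(x.std(), rel=0.05)

    def test_empty_band_raises(self):
        with pytest.raises(FeatureError):
            root_total_power(flat_psd(), band=(40.0, 40.0))


class TestRelativeBandPower:
    def test_flat_psd_delta_is_bandwidth_ratio(self):
        assert relative_band_power(flat_psd(), BANDS["delta"]) == pytest.approx(3 / 39)

    def test_pure_alpha_tone(self):
        t = np.arange(int(20 * FS)) / FS
        psd = compute_psd(np.sin(2 * np.pi * 10 * t), FS)
        assert relative_band_power(psd, BANDS["alpha"]) >= 0.95

    def test_one_over_f_matches_analytic_integral(self):
        """For PSD = 1/f the band power is log(high/low) exactly; compare the
        discrete estimate against the closed form."""
        freqs = np.arange(1.0, 50.0005, 0.001)  # fine grid: discretization -> 0
        psd = PSD(freqs, 1.0 / freqs)
        for name, (lo, hi) in BANDS.items():
            got = relative_band_power(psd, (lo, hi))
            expected = np.log(hi / lo) / np.log(40.0 / 1.0)
            assert got == pytest.approx(expected, rel=1e-3), name

    def test_log_mode_matches_log_of_linear_mode(self):
        for psd in random_psds(5, seed=4):
            lin = relative_band_power(psd, BANDS["theta"])
            log = relative_band_power(psd, BANDS["theta"], log=True)
            assert log == pytest.approx(np.log(lin))

    def test_zero_total_power_raises(self):
        with pytest.raises(FeatureError):
            relative_band_power(make_psd(np.zeros(99)), BANDS["delta"])

    def test_linear_band_powers_tile_unity(self):
        for psd in random_psds(10, seed=5):
            total = sum(
                relative_band_power(psd, b) for b in BANDS.values()
            )
            # bands tile 1-50 Hz while the denominator is 1-40 Hz, so the sum
            # is >= 1; for near-band-limited spectra it stays close to 1
            assert total >= 1.0


class TestSpectralMoment:
    def test_point_mass(self):
        assert spectral_moment(single_bin_psd(10.0)) == pytest.approx(10.0)

    def test_flat_psd_midpoint(self):
        assert spectral_moment(flat_psd(), (1.0, 40.0)) == pytest.approx(20.5)

    def test_matches_weighted_sum_oracle(self):
        for psd in random_psds(100, seed=6):
            mask = (psd.frequencies >= 1.0) & (psd.frequencies <= 40.0)
            f, p = psd.frequencies[mask], psd.power[mask]
            w = np.full(len(f), 0.5)
            w[0] = w[-1] = 0.25
            expected = (f * w * p).sum() / (w * p).sum()
            assert spectral_moment(psd) == pytest.approx(expected, rel=1e-10)


class TestSpectralEdgeFrequency:
    def test_flat_psd_uniform_quantile(self):
        assert spectral_edge_frequency(flat_psd(), (1.0, 40.0)) == pytest.approx(36.1)

    def test_point_mass_within_one_bin(self):
        sef = spectral_edge_frequency(single_bin_psd(10.0))
        assert abs(sef - 10.0) <= 0.5

    @staticmethod
    def dense_sef_oracle(psd, band=(1.0, 40.0), fraction=0.9, n_grid=20001):
        """Brute-force cumulative oracle: interpolate the PSD onto a dense
        frequency grid, accumulate, and scan for the first crossing."""
        mask = (psd.frequencies >= band[0]) & (psd.frequencies <= band[1])
        f, p = psd.frequencies[mask], psd.power[mask]
        grid = np.linspace(f[0], f[-1], n_grid)
        dense = np.interp(grid, f, p)
        cum = np.cumsum((dense[1:] + dense[:-1]) / 2) * (grid[1] - grid[0])
        return grid[1:][np.searchsorted(cum, fraction * cum[-1])]

    def test_matches_cumulative_sum_oracle_within_one_bin(self):
        freqs = np.arange(1.0, 50.25, 0.5)
        cases = [PSD(freqs, freqs**-2.0)] + random_psds(50, seed=7)
        for psd in cases:
            brute = self.dense_sef_oracle(psd)
            assert abs(spectral_edge_frequency(psd) - brute) <= 0.5


class TestSpectralEntropy:
    def test_flat_psd_is_maximal(self):
        assert spectral_entropy(flat_psd()) == pytest.approx(1.0)

    def test_point_mass_is_zero(self):
        assert spectral_entropy(single_bin_psd()) == 0.0

    def test_two_equal_bins_closed_form(self):
        freqs = np.arange(1.0, 40.25, 0.5)
        power = np.zeros(len(freqs))
        power[[4, 30]] = 7.0
        got = spectral_entropy(PSD(freqs, power), (1.0, 40.0))
        assert got == pytest.approx(np.log(2) / np.log(len(freqs)))


class TestSpectralSlopeIntercept:
    def test_power_law_slope(self):
        freqs = np.arange(1.0, 50.25, 0.5)
        slope, _ = spectral_slope_intercept(PSD(freqs, freqs**-2.0))
        assert slope == pytest.approx(-2.0, rel=0.01)

    def test_flat_psd(self):
        slope, intercept = spectral_slope_intercept(flat_psd(3.0))
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert intercept == pytest.approx(np.log(3.0))

    def test_matches_normal_equations_oracle(self):
        for psd in random_psds(100, seed=8):
            mask = (psd.frequencies >= 1.0) & (psd.frequencies <= 40.0)
            x = np.log(psd.frequencies[mask])
            y = np.log(np.maximum(psd.power[mask], LOG_FLOOR * psd.power[mask].sum()))
            n = len(x)
            denom = n * (x**2).sum() - x.sum() ** 2
            slope_o = (n * (x * y).sum() - x.sum() * y.sum()) / denom
            inter_o = (y.sum() - slope_o * x.sum()) / n
            slope, inter = spectral_slope_intercept(psd)
            assert slope == pytest.approx(slope_o, rel=1e-10, abs=1e-10)
            assert inter == pytest.approx(inter_o, rel=1e-10, abs=1e-10)

    def test_too_few_bins_raises(self):
        with pytest.raises(FeatureError):
            spectral_slope_intercept(flat_psd(), band=(10.0, 10.6))


class TestOutOfRange:
    RANGES = {
        "root_total_power": (1.0, 10.0),
        "spectral_slope": (-3.0, 0.0),
        "spectral_intercept": (0.0, 5.0),
        "sef90": (5.0, 30.0),
    }

    def test_all_inside_is_zero(self):
        vals = {"root_total_power": 5, "spectral_slope": -1, "spectral_intercept": 2, "sef90": 10}
        assert out_of_range_count(vals, self.RANGES) == 0

    def test_all_outside_is_four(self):
        vals = {"root_total_power": 50, "spectral_slope": 1, "spectral_intercept": -1, "sef90": 40}
        assert out_of_range_count(vals, self.RANGES) == 4

    def test_two_outside(self):
        vals = {"root_total_power": 5, "spectral_slope": 1, "spectral_intercept": 2, "sef90": 40}
        assert out_of_range_count(vals, self.RANGES) == 2

    def test_missing_range_raises(self):
        with pytest.raises(FeatureError):
            out_of_range_count({}, {"spectral_slope": (0, 1)})


class TestExtractFeatures:
    def test_full_mode_is_306_columns(self, feature_table):
        feature_cols = [c for c in feature_table.columns if "__" in c]
        assert len(feature_cols) == 18 * 17 == 306
        assert len(FEATURE_NAMES) == 17

    def test_reduced_mode_is_90_columns(self, segments):
        from eegselect.preprocess import accepted

        table = extract_features(accepted(segments)[:10], mode="reduced")
        feature_cols = [c for c in table.columns if "__" in c]
        assert len(feature_cols) == 18 * 5 == 90
        assert {c.split("__")[1] for c in feature_cols} == set(REDUCED_FEATURES)

    def test_rejected_segment_raises(self, segments):
        bad = segments[0]
        import copy

        bad = copy.copy(bad)
        bad.rejected = True
        with pytest.raises(ValueError, match="rejected"):
            extract_features([bad])

    def test_rel_powers_in_unit_interval_and_oor_in_0_4(self, feature_table):
        rel_cols = [c for c in feature_table.columns if "__rel_power_" in c]
        assert ((feature_table[rel_cols] >= 0) & (feature_table[rel_cols] <= 1)).all().all()
        oor = [c for c in feature_table.columns if c.endswith("__out_of_range")]
        assert feature_table[oor].isin([0, 1, 2, 3, 4]).all().all()

    def test_vectorized_path_matches_scalar_ops(self, segments):
        """The table values equal the scalar reference operations applied to
        the same Welch spectra, channel by channel."""
        from eegselect.preprocess import accepted

        seg = accepted(segments)[5]
        table = extract_features([seg], mode="full")
        psd_all = compute_psd(seg.data, seg.sampling_rate)
        for i, ch in enumerate(seg.channel_labels):
            psd = PSD(psd_all.frequencies, psd_all.power[i])
            row = table.iloc[0]
            assert row[f"{ch}__root_total_power"] == pytest.approx(root_total_power(psd), rel=1e-9)
            for bname, b in BANDS.items():
                assert row[f"{ch}__rel_power_{bname}"] == pytest.approx(
                    relative_band_power(psd, b), rel=1e-9
                )
                assert row[f"{ch}__rel_log_power_{bname}"] == pytest.approx(
                    relative_band_power(psd, b, log=True), rel=1e-9
                )
            assert row[f"{ch}__spectral_moment"] == pytest.approx(spectral_moment(psd), rel=1e-9)
            assert row[f"{ch}__sef90"] == pytest.approx(spectral_edge_frequency(psd), rel=1e-9)
            assert row[f"{ch}__spectral_entropy"] == pytest.approx(spectral_entropy(psd), rel=1e-9)
            slope, inter = spectral_slope_intercept(psd)
            assert row[f"{ch}__spectral_slope"] == pytest.approx(slope, rel=1e-9)
            assert row[f"{ch}__spectral_intercept"] == pytest.approx(inter, rel=1e-9, abs=1e-9)

    def test_band_power_sum_near_unity_for_bandlimited_signals(self, feature_table):
        """After 1-40 Hz filtering the five relative band powers sum to ~1."""
        for ch in ("T3", "O1", "Fz"):
            total = sum(
                feature_table[f"{ch}__rel_power_{b}"] for b in BANDS
            )
            assert ((total > 0.95) & (total < 1.05)).all()

    def test_amplitude_scaling_behaviour(self, segments):
        """Scaling the signal x10: relative/normalized features invariant,
        root power scales x10, intercept and log powers shift."""
        from eegselect.preprocess import accepted
        import copy

        seg = accepted(segments)[3]
        scaled = copy.copy(seg)
        scaled.data = seg.data * 10.0
        a = extract_features([seg], mode="full").iloc[0]
        b = extract_features([scaled], mode="full").iloc[0]
        for ch in ("T3", "O2"):
            for name in ("rel_power_alpha", "spectral_entropy", "sef90", "spectral_moment", "spectral_slope"):
                assert b[f"{ch}__{name}"] == pytest.approx(a[f"{ch}__{name}"], rel=1e-8)
            assert b[f"{ch}__root_total_power"] == pytest.approx(
                10 * a[f"{ch}__root_total_power"], rel=1e-8
            )
            assert b[f"{ch}__spectral_intercept"] == pytest.approx(
                a[f"{ch}__spectral_intercept"] + np.log(100.0), rel=1e-6
            )
            assert b[f"{ch}__rel_log_power_delta"] == pytest.approx(
                a[f"{ch}__rel_log_power_delta"], rel=1e-8
            )

    def test_out_of_range_ranges_roundtrip(self, feature_table):
        ranges = fit_out_of_range_ranges(feature_table[feature_table["label"] == 0])
        redone = apply_out_of_range(feature_table.drop(
            columns=[c for c in feature_table.columns if c.endswith("__out_of_range")]
        ), ranges)
        manual = feature_table.copy()
        # recomputing with the same ranges used at extraction changes nothing
        got = apply_out_of_range(manual, ranges)
        pd.testing.assert_frame_equal(
            got[sorted(got.columns)], redone[sorted(redone.columns)], check_like=True
        )
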