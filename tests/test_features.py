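import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import windows

from eegaffect import features as ft
from eegaffect.core import EpochSet, default_montage, segment

FS = 128.0


def sine(freq, n=128, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / FS)


ALPHA, BETA, DELTA, GAMMA, THETA = ((8, 12), (12, 30), (0.5, 4), (30, 45),
                                    (4, 8))


class TestShannonEntropy:
    def test_constant_is_zero(self):
        assert ft.shannon_entropy(np.full(128, 3.3)) == 0.0

    def test_uniform_fill_reaches_log_m(self):
        m = 8
        x = np.repeat(np.arange(m, dtype=float), 16)
        assert ft.shannon_entropy(x, n_bins=m) == pytest.approx(math.log(m))

    def test_matches_histogram_oracle(self, rng):
        x = rng.normal(size=128)
        counts, _ = np.histogram(x, bins=32, range=(x.min(), x.max()))
        p = counts[counts > 0] / 128
        assert ft.shannon_entropy(x, 32) == pytest.approx(-(p * np.log(p)).sum())

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 64))
    def test_bounded_by_log_bins(self, seed, n_bins):
        x = np.random.default_rng(seed).normal(size=128)
        h = ft.shannon_entropy(x, n_bins)
        assert 0.0 <= h <= math.log(n_bins) + 1e-12


class TestSubbandInformationQuantity:
    def test_compositional_identity(self, rng):
        x = rng.normal(size=128)
        expected = ft.shannon_entropy(ft._band_filter(x, ALPHA, FS), 32)
        assert ft.subband_information_quantity(x, ALPHA, FS, 32) == expected

    def test_constant_zero_for_every_band(self):
        for band in (ALPHA, BETA, DELTA, GAMMA, THETA):
            assert ft.subband_information_quantity(np.full(128, 2.0), band,
                                                   FS) == 0.0

    def test_tone_matches_two_step_oracle(self):
        x = sine(10) + 0.01 * np.random.default_rng(3).normal(size=128)
        for band in (ALPHA, GAMMA):
            oracle = ft.shannon_entropy(ft._band_filter(x, band, FS), 32)
            assert ft.subband_information_quantity(x, band, FS) == oracle


class TestHjorth:
    def test_mobility_sine_closed_form(self):
        # first difference of a sinusoid scales variance by (2 sin(pi f/fs))^2
        assert ft.hjorth_mobility(sine(10)) == pytest.approx(
            2 * math.sin(math.pi * 10 / FS), rel=0.02)

    def test_complexity_sine_near_one(self):
        assert ft.hjorth_complexity(sine(10)) == pytest.approx(1.0, rel=0.02)

    def test_noise_exceeds_sine(self, rng):
        noise = rng.normal(size=128)
        assert ft.hjorth_mobility(noise) > ft.hjorth_mobility(sine(10))
        assert ft.hjorth_complexity(noise) > 1.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.1, 100.0), st.integers(0, 2**31 - 1))
    def test_amplitude_scale_invariance(self, scale, seed):
        x = np.random.default_rng(seed).normal(size=128)
        assert ft.hjorth_mobility(scale * x) == pytest.approx(
            ft.hjorth_mobility(x))
        assert ft.hjorth_complexity(scale * x) == pytest.approx(
            ft.hjorth_complexity(x))

    def test_flat_window_rejected(self):
        with pytest.raises(ValueError):
            ft.hjorth_mobility(np.zeros(128))


class TestFalseNearestNeighbor:
    def test_sine_saturates_at_dim_two(self):
        assert ft.false_nearest_neighbor(sine(10, n=256), dim=2) < 0.1

    def test_noise_exceeds_sine(self, rng):
        s = ft.false_nearest_neighbor(sine(10, n=256), dim=2)
        n = ft.false_nearest_neighbor(rng.normal(size=256), dim=2)
        assert n > s

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            ft.false_nearest_neighbor(np.arange(3.0), dim=4, delay=1)


class TestDifferentialEntropy:
    def test_unit_variance_closed_form(self):
        x = np.array([-1.0, 1.0])  # population variance exactly 1
        assert ft.differential_entropy(x) == pytest.approx(
            0.5 * math.log(2 * math.pi * math.e))

    def test_analytic_root(self):
        sigma = math.sqrt(1 / (2 * math.pi * math.e))
        x = np.array([-sigma, sigma])
        assert ft.differential_entropy(x) == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_sample(self, rng):
        x = rng.normal(0, 2, size=4096)
        assert ft.differential_entropy(x) == pytest.approx(
            0.5 * math.log(2 * math.pi * math.e * 4), abs=0.05)


class TestAsymmetry:
    def test_identical_sides_give_zero_and_one(self, rng):
        x = rng.normal(0, 5, size=256)
        assert ft.dasm(x, x, ALPHA, FS) == pytest.approx(0.0, abs=1e-12)
        assert ft.rasm(x, x, ALPHA, FS) == pytest.approx(1.0)

    def test_antisymmetry_and_reciprocal(self, rng):
        l, r = rng.normal(0, 5, size=(2, 256))
        assert ft.dasm(l, r, BETA, FS) == pytest.approx(
            -ft.dasm(r, l, BETA, FS))
        assert ft.rasm(l, r, BETA, FS) == pytest.approx(
            1.0 / ft.rasm(r, l, BETA, FS))

    def test_double_amplitude_closed_form(self, rng):
        r = rng.normal(0, 5, size=1024)
        assert ft.dasm(2 * r, r, ALPHA, FS) == pytest.approx(
            0.5 * math.log(4))

    def test_dasm_rasm_algebraic_identity(self, rng):
        l, r = rng.normal(0, 5, size=(2, 256))
        hr = ft.differential_entropy(ft._band_filter(r, ALPHA, FS))
        assert ft.dasm(l, r, ALPHA, FS) == pytest.approx(
            hr * (ft.rasm(l, r, ALPHA, FS) - 1.0))


class TestSpectralFeatures:
    def test_median_frequency_tone(self):
        assert ft.median_frequency(sine(10), FS) == pytest.approx(10.0, abs=1.0)

    def test_median_frequency_between_two_tones(self):
        x = sine(6, n=512) + sine(20, n=512)
        assert 6.0 <= ft.median_frequency(x, FS) <= 20.0

    def test_median_frequency_white_noise_half_nyquist(self, rng):
        x = rng.standard_normal(8192)
        assert ft.median_frequency(x, FS) == pytest.approx(32.0, abs=3.0)

    def test_band_power_zero_signal(self):
        assert ft.band_power(np.zeros(128), ALPHA, FS) == 0.0

    def test_band_power_concentrates_on_tone(self):
        x = sine(10)
        alpha = ft.band_power(x, ALPHA, FS)
        for band in (BETA, DELTA, GAMMA, THETA):
            assert alpha >= 20 * ft.band_power(x, band, FS)

    def test_band_powers_bounded_by_total(self, rng):
        x = rng.normal(size=128)
        _, p = __import__("scipy.signal", fromlist=["periodogram"]).periodogram(x, fs=FS)
        total = p.mean()
        band_sum = sum(ft.band_power(x, b, FS)
                       for b in (ALPHA, BETA, DELTA, GAMMA, THETA))
        assert band_sum <= total * 1.05


class TestAmplitudeFeatures:
    def test_std_dev_population_convention(self):
        assert ft.std_dev(np.array([0.0, 2.0])) == 1.0
        assert ft.std_dev(np.full(16, 5.0)) == 0.0

    def test_std_dev_matches_oracle(self, rng):
        x = rng.normal(size=128)
        assert ft.std_dev(x) == pytest.approx(np.sqrt(np.var(x)))

    def test_spikes_planted(self, rng):
        x = rng.normal(0, 1, size=128)
        for p in (20, 60, 100):
            x[p] += 10.0
        assert ft.spikes(x) == 3

    def test_spikes_distance_rule(self, rng):
        x = rng.normal(0, 1, size=128)
        x[50] += 10.0
        x[53] += 10.0
        assert ft.spikes(x) == 1

    def test_spikes_constant_zero(self):
        assert ft.spikes(np.zeros(128) + 1.0) == 0

    def test_sharp_spike_width_rule(self, rng):
        x = rng.normal(0, 0.1, size=512)
        x[40:44] += 12 * windows.hann(4)      # narrow: < 9 samples above thr
        x[200:240] += 12 * windows.hann(40)   # broad excursion
        assert ft.spikes(x) == 2
        assert ft.sharp_spike(x, fs=FS) == 1

    def test_all_narrow_spikes_saturate(self, rng):
        x = rng.normal(0, 0.3, size=256)
        for p in (40, 90, 140):
            x[p:p + 3] += 12 * windows.hann(3)
        assert ft.sharp_spike(x, fs=FS) == ft.spikes(x) == 3

    def test_no_spikes_zero(self, rng):
        assert ft.sharp_spike(rng.normal(size=128), fs=FS) >= 0
        assert ft.sharp_spike(np.zeros(128), fs=FS) == 0


class TestDeltaBurstAfterSpike:
    def test_no_spikes_zero(self, rng):
        assert ft.delta_burst_after_spike(rng.normal(0, 1, 128), fs=FS) == 0.0

    def test_flat_delta_near_zero(self, rng):
        x = rng.normal(0, 0.2, size=256)
        x[128] += 15.0
        assert abs(ft.delta_burst_after_spike(x, fs=FS)) < 0.5

    def test_step_matches_two_step_oracle_and_is_positive(self, rng):
        x = rng.normal(0, 0.2, size=256)
        x[128:] += 5.0
        x[128] += 15.0
        got = ft.delta_burst_after_spike(x, fs=FS)
        # independent oracle: delta-filter, then windowed means per spike
        delta = ft._band_filter(x, (0.5, 4.0), FS)
        peaks = ft._spike_indices(x, 3.0, 7)
        expected = sum(delta[p + 1:p + 8].mean() - delta[p - 7:p].mean()
                       for p in peaks if 7 <= p <= x.size - 8)
        assert got == pytest.approx(expected)
        assert got > 0.5

    def test_sum_mode_switch(self, rng):
        x = rng.normal(0, 0.2, size=256)
        x[128:] += 5.0
        x[128] += 15.0
        assert (ft.delta_burst_after_spike(x, fs=FS, mode="sum")
                != ft.delta_burst_after_spike(x, fs=FS, mode="diff"))


class TestBurstsAndSuppressions:
    def test_flat_signal_no_bursts(self):
        assert ft.bursts(np.zeros(128), fs=FS) == (0, 0.0, 0.0)

    def test_planted_runs_counted(self, rng):
        x = rng.normal(0, 1, size=256)
        x[30:40] = 15.0
        x[100:120] = 15.0
        nb, blm, bls = ft.bursts(x, fs=FS)
        assert nb == 2
        assert blm == pytest.approx(15 / FS, rel=0.01)

    def test_single_run_has_zero_length_sd(self, rng):
        x = rng.normal(0, 1, size=256)
        x[100:115] = 15.0
        nb, _, bls = ft.bursts(x, fs=FS)
        assert nb == 1 and bls == 0.0

    def test_all_zero_window_one_suppression(self):
        assert ft.suppressions(np.zeros(128), fs=FS) == (1, 1.0, 0.0)

    def test_square_wave_no_suppression(self):
        sq = 50 * np.sign(np.sin(2 * np.pi * 8 * np.arange(128) / FS))
        assert ft.suppressions(sq, fs=FS)[0] == 0

    def test_planted_gaps_counted(self):
        x = 50 * np.sin(2 * np.pi * 10 * np.arange(640) / FS)
        x[100:132] = 0.5
        x[400:432] = 0.5
        assert ft.suppressions(x, fs=FS)[0] == 2


class TestDiffuseSlowing:
    @pytest.mark.parametrize("freq,expected", [(2.0, 1), (10.0, 0)])
    def test_pure_tones(self, freq, expected):
        assert ft.diffuse_slowing(sine(freq), fs=FS) == expected

    def test_mixed_tones_follow_band_power_oracle(self):
        x = sine(2, amp=1.0) + sine(20, amp=3.0)
        assert ft.diffuse_slowing(x, fs=FS) == 0


class TestExtractFeatures:
    def test_default_battery_column_count(self, clean_campaign):
        epochs, _, _, _ = clean_campaign
        seg = segment(epochs, 1.0)
        fm = ft.extract_features(seg)
        # 15 per-channel codes x 14 channels + 10 pair codes x 7 pairs
        assert fm.values.shape == (seg.n_trials, 15 * 14 + 10 * 7)
        assert len(fm.codes) == 25

    def test_single_channel_std_battery(self, rng):
        ep = EpochSet(data=rng.normal(0, 5, size=(6, 1, 128)), fs=FS,
                      channel_names=("F3",))
        fm = ft.extract_features(ep, battery=["S.D."])
        expected = [ft.std_dev(ep.data[i, 0]) for i in range(6)]
        np.testing.assert_allclose(fm.values[:, 0], expected)

    def test_channel_permutation_permutes_columns_not_values(self, rng,
                                                             montage):
        ep = EpochSet(data=rng.normal(0, 5, size=(4, 14, 128)), fs=FS,
                      channel_names=montage.channels)
        perm = tuple(reversed(montage.channels))
        from eegaffect.core import select_channels

        fm1 = ft.extract_features(ep, battery=["H.M.", "S.D."])
        fm2 = ft.extract_features(select_channels(ep, perm),
                                  battery=["H.M.", "S.D."])
        for ch in montage.channels:
            c1 = fm1.columns_for_channel(ch)
            c2 = fm2.columns_for_channel(ch)
            np.testing.assert_allclose(fm1.values[:, c1], fm2.values[:, c2])

    def test_vectorised_path_matches_scalar_ops(self, rng):
        ep = EpochSet(data=rng.normal(0, 5, size=(3, 4, 128)), fs=FS,
                      channel_names=("F3", "F4", "T7", "T8"))
        fm = ft.extract_features(ep)
        scalar = {
            "S.E.A.": lambda w: ft.subband_information_quantity(w, ALPHA, FS),
            "H.M.": ft.hjorth_mobility,
            "H.C.": ft.hjorth_complexity,
            "M.F.": lambda w: ft.median_frequency(w, FS),
            "B.P.G.": lambda w: ft.band_power(w, GAMMA, FS),
            "S.D.": ft.std_dev,
            "S.S.N.": lambda w: ft.sharp_spike(w, fs=FS),
        }
        for code, fn in scalar.items():
            cols = fm.columns_for_code(code)
            for i in range(3):
                for j, c in enumerate(cols):
                    assert fm.values[i, c] == pytest.approx(
                        fn(ep.data[i, j]), rel=1e-9), code
        # pair features against scalar dasm/rasm
        d_cols = fm.columns_for_code("D.A.")
        r_cols = fm.columns_for_code("R.A.")
        for i in range(3):
            assert fm.values[i, d_cols[0]] == pytest.approx(
                ft.dasm(ep.data[i, 0], ep.data[i, 1], ALPHA, FS))
            assert fm.values[i, r_cols[1]] == pytest.approx(
                ft.rasm(ep.data[i, 2], ep.data[i, 3], ALPHA, FS))

    def test_flat_windows_imputed_as_zero(self):
        ep = EpochSet(data=np.zeros((2, 2, 128)), fs=FS,
                      channel_names=("F3", "F4"))
        fm = ft.extract_features(ep, battery=["H.M.", "S.D.", "R.A."])
        assert np.isfinite(fm.values).all()
        np.testing.assert_array_equal(fm.values, 0.0)

    def test_empty_battery_rejected(self, rng):
        ep = EpochSet(data=rng.normal(size=(2, 2, 128)), fs=FS,
                      channel_names=("A", "B"))
        with pytest.raises(ValueError):
            ft.extract_features(ep, battery=[])

    def test_trial_order_invariance(self, rng):
        ep = EpochSet(data=rng.normal(0, 5, size=(4, 2, 128)), fs=FS,
                      channel_names=("F3", "F4"))
        fm = ft.extract_features(ep, battery=["S.D.", "H.M."])
        rev = ft.extract_features(ep.copy_with(data=ep.data[::-1]),
                                  battery=["S.D.", "H.M."])
        np.testing.assert_allclose(rev.values[::-1], fm.values)
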