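import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import periodogram
from statsmodels.regression.linear_model import burg as sm_burg

from pedalbci.preprocessing import EpochSet
from pedalbci.spectral import (
    DEFAULT_FREQS,
    DegenerateSignalError,
    InsufficientClassesError,
    OptimalFrequencyMap,
    PowerTable,
    burg_ar,
    burg_psd,
    compute_power_table,
    extract_features,
    normalize_powers,
    periodogram_psd,
    select_optimal_frequencies,
)
from pedalbci.workflows import session_frequency_map

FS = 500.0
FREQS = list(range(6, 31))


def tone(freq, n=500, amp=1.0, phase=0.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / FS + phase)


class TestBurgAR:
    @pytest.mark.parametrize("order", [1, 2, 8, 16])
    def test_matches_statsmodels_burg(self, order):
        rng = np.random.default_rng(0)
        for _ in range(3):
            x = rng.standard_normal(300)
            a, _ = burg_ar(x - x.mean(), order)
            rho, _ = sm_burg(x, order=order, demean=True)
            assert np.allclose(a, -rho, atol=1e-10)

    def test_recovers_known_ar2_process(self):
        # x_t = 1.3 x_{t-1} - 0.6 x_{t-2} + e_t
        rng = np.random.default_rng(1)
        n = 20000
        x = np.zeros(n)
        e = rng.standard_normal(n)
        for t in range(2, n):
            x[t] = 1.3 * x[t - 1] - 0.6 * x[t - 2] + e[t]
        a, sigma2 = burg_ar(x[100:] - x[100:].mean(), 2)
        assert np.allclose(a, [-1.3, 0.6], atol=0.02)
        assert sigma2 == pytest.approx(1.0, rel=0.05)

    def test_batch_equals_scalar(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((5, 4, 200))
        A, S = burg_ar(X, 8)
        for i in range(5):
            for j in range(4):
                a, s = burg_ar(X[i, j], 8)
                assert np.allclose(A[i, j], a) and S[i, j] == pytest.approx(s)

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateSignalError):
            burg_ar(np.zeros(100), 4)


class TestBurgPSD:
    def test_peak_matches_periodogram_single_tone(self):
        rng = np.random.default_rng(3)
        x = tone(10.0) + 0.1 * rng.standard_normal(500)
        p = burg_psd(x, 16, FREQS, FS)
        f_burg = FREQS[int(np.argmax(p))]
        f, pg = periodogram(x, FS)
        f_oracle = f[np.argmax(pg)]
        assert abs(f_burg - f_oracle) <= 1.0
        assert f_burg == 10

    def test_two_tones_give_two_local_maxima(self):
        rng = np.random.default_rng(4)
        x = tone(10.0) + tone(22.0) + 0.1 * rng.standard_normal(500)
        p = burg_psd(x, 16, FREQS, FS)
        local_max = [FREQS[i] for i in range(1, len(FREQS) - 1)
                     if p[i] > p[i - 1] and p[i] > p[i + 1]]
        assert any(abs(f - 10) <= 1 for f in local_max)
        assert any(abs(f - 22) <= 1 for f in local_max)

    def test_white_noise_spectrum_flat(self):
        rng = np.random.default_rng(5)
        p = burg_psd(rng.standard_normal((300, 500)), 16, FREQS, FS).mean(axis=0)
        assert p.max() / p.min() < 1.2

    def test_rejects_frequencies_above_nyquist(self):
        with pytest.raises(ValueError):
            burg_psd(tone(10.0), 16, [300.0], FS)

    def test_powers_nonnegative(self):
        rng = np.random.default_rng(6)
        p = burg_psd(rng.standard_normal((10, 500)), 16, FREQS, FS)
        assert np.all(p >= 0)


def make_table(values, labels):
    values = np.asarray(values, dtype=float)
    electrodes = [f"E{i}" for i in range(values.shape[1])]
    return PowerTable(values, np.arange(6, 6 + values.shape[2]), electrodes,
                      np.asarray(labels))


class TestNormalization:
    def test_uniform_slice(self):
        t = make_table(np.ones((1, 1, 25)), ["RELAX"])
        out = normalize_powers(t)
        assert np.allclose(out.values, 0.04)

    def test_single_bin(self):
        vals = np.zeros((1, 1, 25))
        vals[0, 0, 0] = 2.0
        out = normalize_powers(make_table(vals, ["RELAX"]))
        assert out.values[0, 0, 0] == 1.0 and np.all(out.values[0, 0, 1:] == 0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_sums_to_one_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        t = make_table(rng.uniform(0.01, 5.0, (3, 2, 25)), ["RELAX", "IMAGINE", "RELAX"])
        out = normalize_powers(t)
        assert np.allclose(out.values.sum(axis=-1), 1.0, atol=1e-12)
        again = normalize_powers(out)
        assert np.allclose(again.values, out.values)

    def test_zero_slice_raises(self):
        with pytest.raises(DegenerateSignalError):
            normalize_powers(make_table(np.zeros((1, 1, 25)), ["RELAX"]))


class TestOptimalFrequencies:
    def test_tie_break_lowest_frequency(self):
        vals = np.ones((4, 9, 25))
        labels = ["RELAX", "IMAGINE"] * 2
        fmap = select_optimal_frequencies(make_table(vals, labels))
        assert all(f == 6 for f in fmap.frequencies.values())

    def test_known_argmax(self):
        vals = np.ones((2, 1, 25))
        vals[0, 0, 4] = 2.0   # RELAX has extra power at 10 Hz
        fmap = select_optimal_frequencies(make_table(vals, ["RELAX", "IMAGINE"]))
        assert fmap.frequencies["E0"] == 10
        assert fmap.separations["E0"] > 0

    def test_scale_invariance_of_selection(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0.1, 2.0, (20, 3, 25))
        labels = ["RELAX", "IMAGINE"] * 10
        f1 = select_optimal_frequencies(make_table(vals, labels))
        f2 = select_optimal_frequencies(make_table(vals * 37.5, labels))
        assert f1.frequencies == f2.frequencies

    def test_single_class_raises(self):
        with pytest.raises(InsufficientClassesError):
            select_optimal_frequencies(make_table(np.ones((2, 1, 25)),
                                                  ["RELAX", "RELAX"]))

    def test_recovers_generator_ground_truth(self, clean_small_session,
                                             small_spec):
        # noise-free ERD injected at 10 Hz: every electrode selects 10 Hz
        fmap = session_frequency_map(clean_small_session, small_spec)
        assert list(fmap.frequencies.values()) == [10] * 9


class TestExtractFeatures:
    def test_length_matches_montage(self):
        vals = np.random.default_rng(8).uniform(0.1, 1, (5, 9, 25))
        t = normalize_powers(make_table(vals, ["RELAX"] * 5))
        fmap = OptimalFrequencyMap({f"E{i}": 10 for i in range(9)}, {})
        X = extract_features(t, fmap)
        assert X.shape == (5, 9)

    def test_all_six_hz_map_returns_first_column(self):
        vals = np.random.default_rng(9).uniform(0.1, 1, (3, 4, 25))
        t = make_table(vals, ["RELAX"] * 3)
        fmap = OptimalFrequencyMap({f"E{i}": 6 for i in range(4)}, {})
        assert np.allclose(extract_features(t, fmap), vals[:, :, 0])

    def test_uniform_slice_gives_uniform_features(self):
        t = normalize_powers(make_table(np.ones((1, 9, 25)), ["RELAX"]))
        fmap = OptimalFrequencyMap({f"E{i}": 17 for i in range(9)}, {})
        assert np.allclose(extract_features(t, fmap), 0.04)

    def test_missing_electrode_raises(self):
        t = make_table(np.ones((1, 2, 25)), ["RELAX"])
        with pytest.raises(KeyError):
            extract_features(t, OptimalFrequencyMap({"E0": 6}, {}))


class TestPeriodogramTable:
    def test_matches_band_power_for_pure_tone(self):
        x = tone(10.0)
        p = periodogram_psd(x, FREQS, FS)
        # all power concentrates in the 10 Hz bin
        assert FREQS[int(np.argmax(p))] == 10
        assert p[4] / p.sum() > 0.99

    def test_table_shapes_agree_across_methods(self, clean_small_session,
                                               small_spec):
        from pedalbci.preprocessing import preprocess

        es = preprocess(clean_small_session, small_spec)
        sub = es.subset(np.arange(es.n_epochs) < 10)
        tb = compute_power_table(sub, method="burg")
        tp = compute_power_table(sub, method="periodogram")
        assert tb.values.shape == tp.values.shape == (10, 9, 25)
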