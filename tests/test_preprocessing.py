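import dataclasses

import numpy as np
import pytest

from pedalbci.montage import CHANNELS_30, MOTOR_9, coordinate_array
from pedalbci.preprocessing import (
    EpochSet,
    FilterChainConfig,
    FilterConfigError,
    apply_filter_chain,
    filter_recording_causal,
    laplacian_reference,
    laplacian_weights,
    select_electrodes,
    slice_epochs,
)
from pedalbci.protocol import IMAGINE, RELAX, ProtocolSpec, ScheduleEvent
from pedalbci.synthetic import SessionRecording

FS = 500.0


def make_epochset(data, labels=None, fs=FS, channels=None):
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    channels = channels or [f"ch{i}" for i in range(data.shape[1])]
    labels = labels if labels is not None else np.array([RELAX] * n)
    return EpochSet(data, labels, np.arange(n, dtype=float), channels, fs)


class TestSliceEpochs:
    def test_default_session_epoch_count(self, zeros_session, default_spec):
        es = slice_epochs(zeros_session, default_spec)
        assert es.n_epochs == 10 * 20 * 15 == 3000
        assert es.epochs.shape == (3000, 30, 500)
        assert np.sum(es.labels == RELAX) == np.sum(es.labels == IMAGINE) == 1500
        assert sorted(np.unique(es.trials)) == list(range(1, 11))
        # every epoch lies inside its task minus the 2 s lead-in
        assert es.epoch_start_s.min() >= 2.0

    def test_single_event(self, default_spec):
        rec = SessionRecording(np.zeros((2, 3000)), FS, ["CZ", "C1"],
                               [ScheduleEvent(RELAX, 0.0, 5.8, trial=1)])
        es = slice_epochs(rec, default_spec)
        assert es.n_epochs == 15
        assert set(es.labels) == {RELAX}
        assert es.epoch_start_s[0] == pytest.approx(2.0)
        assert es.epoch_start_s[-1] == pytest.approx(4.8)

    def test_single_window_spec(self, default_spec):
        spec = dataclasses.replace(default_spec, discard_initial_s=4.8)
        rec = SessionRecording(np.zeros((1, 3000)), FS, ["CZ"],
                               [ScheduleEvent(IMAGINE, 0.0, 5.8, trial=1)])
        assert slice_epochs(rec, spec).n_epochs == 1

    def test_event_past_end_raises(self, default_spec):
        rec = SessionRecording.__new__(SessionRecording)
        rec.samples = np.zeros((1, 1000))
        rec.sampling_rate_hz = FS
        rec.channel_labels = ["CZ"]
        rec.events = [ScheduleEvent(RELAX, 0.0, 5.8, trial=1)]
        with pytest.raises(ValueError, match="past end"):
            slice_epochs(rec, default_spec)


class TestFilterChain:
    def tone(self, freq, n=500, amp=1.0):
        t = np.arange(n) / FS
        return amp * np.sin(2 * np.pi * freq * t)

    def test_dc_removed(self):
        es = make_epochset(np.full((1, 1, 500), 7.3))
        out = apply_filter_chain(es)
        assert np.max(np.abs(out.epochs)) < 1e-6

    def test_line_frequency_notched(self):
        es = make_epochset(self.tone(50.0)[None, None, :])
        out = apply_filter_chain(es)
        rms_in = np.sqrt(np.mean(es.epochs**2))
        rms_out = np.sqrt(np.mean(out.epochs**2))
        assert rms_out < 0.1                       # residual on unit tone
        assert rms_out / rms_in < 0.1              # >= 20 dB attenuation

    def test_passband_preserved(self):
        es = make_epochset(self.tone(10.0)[None, None, :])
        out = apply_filter_chain(es)
        # compare RMS over the central region, away from edge transients
        sl = slice(100, 400)
        ratio = (np.sqrt(np.mean(out.epochs[..., sl] ** 2))
                 / np.sqrt(np.mean(es.epochs[..., sl] ** 2)))
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 1, 500))
        y = rng.standard_normal((1, 1, 500))
        a, b = 2.5, -1.3
        lhs = apply_filter_chain(make_epochset(a * x + b * y)).epochs
        rhs = (a * apply_filter_chain(make_epochset(x)).epochs
               + b * apply_filter_chain(make_epochset(y)).epochs)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_bad_cutoffs_rejected(self):
        es = make_epochset(np.zeros((1, 1, 500)))
        with pytest.raises(FilterConfigError):
            apply_filter_chain(es, FilterChainConfig(lp_cutoff_hz=300.0))
        with pytest.raises(FilterConfigError):
            apply_filter_chain(es, FilterChainConfig(hp_cutoff_hz=46.0))

    def test_causal_mode_removes_dc(self):
        rec = SessionRecording(np.full((2, 60 * 500), 3.0), FS, ["CZ", "C1"], [])
        out = filter_recording_causal(rec)
        assert out.samples.shape == rec.samples.shape
        # 0.05 Hz high-pass settles over tens of seconds; check the tail
        assert np.max(np.abs(out.samples[:, -1000:])) < 0.5


class TestLaplacian:
    def test_common_mode_rejected(self):
        rng = np.random.default_rng(1)
        frame = rng.standard_normal(500)
        data = np.tile(frame, (1, 30, 1))
        es = make_epochset(data, channels=list(CHANNELS_30))
        out = laplacian_reference(es)
        assert np.max(np.abs(out.epochs)) < 1e-10

    def test_single_source_weights(self):
        # signal on CZ only: CZ passes through, channel j sees -w_j * signal
        sig = np.sin(2 * np.pi * 10 * np.arange(500) / FS)
        data = np.zeros((1, 30, 500))
        cz = list(CHANNELS_30).index("CZ")
        data[0, cz] = sig
        es = make_epochset(data, channels=list(CHANNELS_30))
        out = laplacian_reference(es)
        assert np.allclose(out.epochs[0, cz], sig)
        # independent recomputation of the 1/d weights
        xy = coordinate_array(list(CHANNELS_30))
        for j in range(30):
            if j == cz:
                continue
            d = np.linalg.norm(xy[j] - xy, axis=1)
            d[j] = np.inf
            w_cz = (1 / d[cz]) / np.sum(1 / d[np.arange(30) != j])
            assert np.allclose(out.epochs[0, j], -w_cz * sig, atol=1e-12)

    def test_two_channel_difference(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0]])
        x = np.arange(10, dtype=float)
        data = np.stack([x, -x])[None, :, :]
        es = make_epochset(data, channels=["A", "B"])
        out = laplacian_reference(es, coords=coords)
        assert np.allclose(out.epochs[0, 0], x - (-x))
        assert np.allclose(out.epochs[0, 1], -x - x)

    def test_duplicate_coordinates_rejected(self):
        coords = np.zeros((2, 2))
        with pytest.raises(FilterConfigError):
            laplacian_weights(["A", "B"], coords)

    def test_row_sums_zero(self):
        L = laplacian_weights(list(CHANNELS_30))
        assert np.allclose(L.sum(axis=1), 0.0, atol=1e-12)


class TestSelectElectrodes:
    def test_default_nine(self, zeros_session, default_spec):
        es = slice_epochs(zeros_session, default_spec).subset(
            np.arange(3000) < 3)
        out = select_electrodes(es, MOTOR_9)
        assert out.epochs.shape[1] == 9
        assert out.channel_labels == list(MOTOR_9)

    def test_identity_and_single(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((2, 30, 50))
        es = make_epochset(data, channels=list(CHANNELS_30))
        assert np.array_equal(select_electrodes(es, CHANNELS_30).epochs, data)
        cz = list(CHANNELS_30).index("CZ")
        one = select_electrodes(es, ["Cz"])
        assert np.array_equal(one.epochs[:, 0, :], data[:, cz, :])

    def test_unknown_name_raises(self):
        es = make_epochset(np.zeros((1, 2, 10)), channels=["CZ", "C1"])
        with pytest.raises(KeyError):
            select_electrodes(es, ["CZ", "XX"])
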