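"""Synthetic cue-locked EEG sessions with ground-truth mu/beta ERD.

The generator emulates what the classification pipeline needs from a real
motor-imagery session: a sensorimotor (mu, ~10 Hz) rhythm radiating from the
vertex whose band power drops by a known fraction rho during pedaling-imagery
tasks (event-related desynchronization), on top of 1/f background noise,
a common-mode component, and optional 50 Hz line interference.

The suppression is parameterized on the POWER scale: during IMAGINE the
rhythm amplitude is scaled by sqrt(1 - rho * day_curve[day-1]) so that band
power drops by exactly rho * day_curve[day-1], making the ERD statistic
(-100 * rho) the analytic ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .montage import CHANNELS_30, coordinate_array, median_neighbor_spacing
from .protocol import (
    IMAGINE,
    ProtocolSpec,
    ScheduleEvent,
    build_session_schedule,
)

SHAM = "SHAM"
TDCS = "TDCS"


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one simulated subject.

    Amplitudes are peak amplitudes in microvolts at the source (the vertex
    electrode sees nearly the full amplitude; it falls off with scalp
    distance). ``erd_power_fraction`` (rho) is the fraction of mu/beta band
    power suppressed during imagery at day_curve = 1; ``day_curve`` scales
    rho per day to model practice or stimulation effects.
    """

    mu_center_hz: float = 10.0
    mu_amplitude: float = 5.0
    beta_center_hz: float | None = 20.0
    beta_amplitude: float = 1.0
    erd_power_fraction: float = 0.3
    noise_amplitude: float = 3.0
    line_noise_amplitude: float = 1.0
    day_curve: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.erd_power_fraction <= 1.0):
            raise ValueError("erd_power_fraction must lie in [0, 1]")
        if min(self.mu_amplitude, self.beta_amplitude, self.noise_amplitude,
               self.line_noise_amplitude) < 0:
            raise ValueError("amplitudes must be non-negative")
        if any(d < 0 for d in self.day_curve):
            raise ValueError("day_curve entries must be non-negative")


@dataclass
class SessionRecording:
    """Continuous multichannel EEG plus its cue annotations."""

    samples: np.ndarray  # (n_channels, n_samples), microvolts
    sampling_rate_hz: float
    channel_labels: list[str]
    events: list[ScheduleEvent]

    def __post_init__(self) -> None:
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("samples/labels shape mismatch")
        dur = self.duration_s
        for e in self.events:
            if e.onset_s < 0 or e.end_s > dur + 1e-6:
                raise ValueError(f"event {e} outside recording of {dur:.1f} s")

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.sampling_rate_hz

    def channel_index(self, label: str) -> int:
        labels = [l.upper() for l in self.channel_labels]
        try:
            return labels.index(label.upper())
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], fs: float,
                rms: float) -> np.ndarray:
    """1/f-power background noise, RMS-normalized per row."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    # amplitude ~ f^-1/2 (power ~ 1/f); floor at 1 Hz, kill DC
    scale = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    std = x.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return x / std * rms


def _slow_modulation(rng: np.random.Generator, n: int, fs: float,
                     std: float) -> np.ndarray:
    """Zero-mean random process with ~1 s correlation length and given std."""
    x = gaussian_filter1d(rng.standard_normal(n), sigma=fs, mode="reflect")
    s = x.std()
    return x / s * std if s > 0 else x


def _suppression_envelope(n: int, fs: float, events: Sequence[ScheduleEvent],
                          target: float, ramp_s: float = 0.1) -> np.ndarray:
    """Amplitude envelope: 1 outside imagery, ``target`` inside, cosine ramps.

    The 100 ms ramps at task boundaries avoid step discontinuities that would
    leak broadband power into the spectra.
    """
    env = np.ones(n)
    r = max(int(round(ramp_s * fs)), 1)
    half = 0.5 * (1.0 - np.cos(np.pi * np.arange(r) / r))  # 0 -> 1
    for e in events:
        if e.label != IMAGINE:
            continue
        i0 = int(round(e.onset_s * fs))
        i1 = min(int(round(e.end_s * fs)), n)
        if i1 - i0 <= 2 * r:
            env[i0:i1] = target
            continue
        env[i0:i0 + r] = 1.0 + (target - 1.0) * half
        env[i0 + r:i1 - r] = target
        env[i1 - r:i1] = target + (1.0 - target) * half
    return env


def _rhythm(rng: np.random.Generator, t: np.ndarray, fs: float,
            center_hz: float, amplitude: float, envelope: np.ndarray) -> np.ndarray:
    """Narrowband oscillation: sinusoid with random phase, slow amplitude
    jitter (~5%) and a slight (<0.3 Hz) frequency wander."""
    n = t.size
    phase0 = rng.uniform(0, 2 * np.pi)
    wander = _slow_modulation(rng, n, fs, std=0.2)
    phase = 2 * np.pi * (center_hz * t + np.cumsum(wander) / fs) + phase0
    amp = amplitude * (1.0 + _slow_modulation(rng, n, fs, std=0.05))
    return amp * envelope * np.sin(phase)


def motor_projection_weights(channel_labels: Sequence[str]) -> np.ndarray:
    """Gaussian spatial weights of the vertex source onto each electrode.

    Scale = one median electrode spacing, so the rhythm is strong on Cz and
    its immediate ring (C1/C2/FC1/FC2/CP1/CP2, then C3/C4) and weak elsewhere
    -- mirroring why those nine electrodes carry the discriminative signal.
    """
    xy = coordinate_array(list(channel_labels))
    cz = coordinate_array(["CZ"])[0]
    d = np.linalg.norm(xy - cz, axis=1)
    sigma = 1.6 * median_neighbor_spacing()
    return np.exp(-(d**2) / (2 * sigma**2))


def generate_session(
    profile: SubjectProfile,
    spec: ProtocolSpec | None = None,
    day: int = 1,
    seed: int = 0,
    channel_labels: Sequence[str] = CHANNELS_30,
) -> SessionRecording:
    """Simulate one full session (all trials) for one subject and day.

    Deterministic per (seed, day). Raises if the effective suppression
    ``rho * day_curve[day-1]`` exceeds 1 (power cannot drop below zero).
    """
    spec = spec or ProtocolSpec()
    if not (1 <= day <= len(profile.day_curve)):
        raise ValueError(f"day must lie in 1..{len(profile.day_curve)}")
    depth = profile.erd_power_fraction * profile.day_curve[day - 1]
    if depth > 1.0 + 1e-12:
        raise ValueError("rho * day_curve[day] exceeds 1")

    fs = spec.sampling_rate_hz
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(day,))
    rng_sched, rng_sig = [np.random.default_rng(s) for s in ss.spawn(2)]
    sched_seed = int(rng_sched.integers(2**31))
    events = build_session_schedule(spec, sched_seed)

    n = int(round(spec.session_duration_s * fs))
    t = np.arange(n) / fs
    env = _suppression_envelope(n, fs, events, target=float(np.sqrt(1.0 - depth)))

    source = _rhythm(rng_sig, t, fs, profile.mu_center_hz, profile.mu_amplitude, env)
    if profile.beta_center_hz is not None and profile.beta_amplitude > 0:
        source = source + _rhythm(rng_sig, t, fs, profile.beta_center_hz,
                                  profile.beta_amplitude, env)

    w = motor_projection_weights(channel_labels)
    data = w[:, None] * source[None, :]

    n_ch = len(channel_labels)
    if profile.noise_amplitude > 0:
        data += _pink_noise(rng_sig, (n_ch, n), fs, profile.noise_amplitude)
        # common-mode drift seen identically by every electrode; the
        # Laplacian reference should reject it
        data += _pink_noise(rng_sig, (1, n), fs, 0.5 * profile.noise_amplitude)
    if profile.line_noise_amplitude > 0:
        line = profile.line_noise_amplitude * np.sin(
            2 * np.pi * 50.0 * t + rng_sig.uniform(0, 2 * np.pi))
        gains = rng_sig.uniform(0.8, 1.2, size=n_ch)
        data += gains[:, None] * line[None, :]

    return SessionRecording(
        samples=data,
        sampling_rate_hz=fs,
        channel_labels=[c.upper() for c in channel_labels],
        events=events,
    )


def _preset_day_curve(group: str, n_days: int) -> tuple[float, ...]:
    """Per-day multipliers on rho.

    The stimulation preset expresses the full suppression from day 1; the
    sham preset ramps up over days, emulating slow unassisted learning of
    the imagery task.
    """
    if group == TDCS:
        return tuple(np.ones(n_days))
    if group == SHAM:
        return tuple(np.linspace(0.35, 1.0, n_days))
    raise ValueError(f"unknown group {group!r}; expected {SHAM!r} or {TDCS!r}")


def draw_profile(group: str, rng: np.random.Generator,
                 n_days: int = 5) -> SubjectProfile:
    """Randomized subject profile from the cohort ranges."""
    return SubjectProfile(
        mu_center_hz=float(rng.uniform(8.5, 11.5)),
        mu_amplitude=float(rng.uniform(4.0, 6.0)),
        beta_center_hz=float(rng.uniform(18.0, 24.0)),
        beta_amplitude=float(rng.uniform(0.5, 1.5)),
        erd_power_fraction=float(rng.uniform(0.3, 0.45)),
        noise_amplitude=float(rng.uniform(2.5, 3.5)),
        line_noise_amplitude=float(rng.uniform(0.5, 1.5)),
        day_curve=_preset_day_curve(group, n_days),
    )


def iter_cohort(
    group: str,
    n_subjects: int,
    spec: ProtocolSpec | None = None,
    seed: int = 0,
) -> Iterator[tuple[int, int, SessionRecording]]:
    """Lazily yield (subject, day, recording) for a whole group.

    Lazy because a full 30-channel session is ~200 MB; callers stream
    sessions one at a time. Fully reproducible per seed.
    """
    spec = spec or ProtocolSpec()
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    group_key = {SHAM: 1, TDCS: 2}.get(group)
    if group_key is None:
        raise ValueError(f"unknown group {group!r}; expected {SHAM!r} or {TDCS!r}")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(group_key,))
    for subj, child in enumerate(ss.spawn(n_subjects), start=1):
        rng = np.random.default_rng(child)
        profile = draw_profile(group, rng, n_days=spec.n_days)
        subj_seed = int(rng.integers(2**31))
        for day in range(1, spec.n_days + 1):
            yield subj, day, generate_session(profile, spec, day=day, seed=subj_seed)


def generate_cohort(group, n_subjects, spec=None, seed=0):
    """Materialized cohort: {(subject, day): SessionRecording}.

    Convenience for small specs; prefer :func:`iter_cohort` at full size.
    """
    return {(s, d): rec for s, d, rec in iter_cohort(group, n_subjects, spec, seed)}
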