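"""End-to-end experiment drivers built from the pipeline stages.

These functions wire generator -> preprocessing -> spectral features ->
classifier -> analysis into the study-shaped computations the analysis
scripts and the acceptance checks run: per-session online accuracy, cohort
accuracy tables, per-group-day optimal-frequency maps, ERD recovery.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import (
    PredictionStream,
    TrainedModel,
    realtime_accuracy,
    run_online_session,
    train_from_recording,
)
from .montage import MOTOR_9
from .preprocessing import FilterChainConfig, preprocess, slice_epochs
from .protocol import ProtocolSpec, task_events
from .spectral import (
    DEFAULT_AR_ORDER,
    OptimalFrequencyMap,
    compute_power_table,
    normalize_powers,
    select_optimal_frequencies,
)
from .synthetic import (
    SessionRecording,
    SubjectProfile,
    draw_profile,
    generate_session,
)


def training_only_spec(spec: ProtocolSpec | None = None) -> ProtocolSpec:
    """A spec truncated to the training trials plus one evaluation trial.

    Feature selection and model fitting use only the first
    ``training_trials`` trials, so sessions generated under this spec give
    identical training-stage results at a fraction of the cost.
    """
    spec = spec or ProtocolSpec()
    return dataclasses.replace(spec,
                               trials_per_session=spec.training_trials + 1)


def session_frequency_map(rec: SessionRecording,
                          spec: ProtocolSpec | None = None,
                          cfg: FilterChainConfig | None = None,
                          electrodes: Sequence[str] = MOTOR_9,
                          ar_order: int = DEFAULT_AR_ORDER,
                          ) -> OptimalFrequencyMap:
    """Optimal-frequency map from the training trials of one session."""
    spec = spec or ProtocolSpec()
    es = preprocess(rec, spec, cfg, electrodes)
    train = es.subset(es.trials <= spec.training_trials)
    table = normalize_powers(compute_power_table(train, ar_order))
    return select_optimal_frequencies(table)


def evaluate_session(
    profile: SubjectProfile,
    spec: ProtocolSpec | None = None,
    day: int = 1,
    seed: int = 0,
    cfg: FilterChainConfig | None = None,
) -> tuple[TrainedModel, PredictionStream, float]:
    """Simulate one session, train on its first trials, evaluate the rest.

    Returns (model, prediction stream, real-time accuracy in percent).
    """
    spec = spec or ProtocolSpec()
    rec = generate_session(profile, spec, day=day, seed=seed)
    model = train_from_recording(rec, spec, cfg)
    stream = run_online_session(rec, model, spec, cfg)
    return model, stream, realtime_accuracy(stream)


def cohort_accuracy_table(
    groups: Sequence[str],
    n_subjects: int,
    spec: ProtocolSpec | None = None,
    seed: int = 0,
    days: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Real-time accuracy per (group, subject, day) over synthetic cohorts.

    Streams sessions one at a time (a full 30-channel session is large);
    reproducible per seed.
    """
    spec = spec or ProtocolSpec()
    days = list(days) if days is not None else list(range(1, spec.n_days + 1))
    rows = []
    for group in groups:
        for subj, day, profile, subj_seed in iter_cohort_profiles(
                group, n_subjects, spec, seed, days):
            _, _, acc = evaluate_session(profile, spec, day=day, seed=subj_seed)
            rows.append({"group": group, "subject": subj, "day": day,
                         "accuracy": acc})
    return pd.DataFrame(rows)


def iter_cohort_profiles(group: str, n_subjects: int, spec: ProtocolSpec,
                         seed: int, days: Sequence[int]):
    """(subject, day, profile, session_seed) tuples matching iter_cohort's
    randomization, without materializing the recordings."""
    from .synthetic import SHAM, TDCS  # local to avoid cycle noise

    group_key = {SHAM: 1, TDCS: 2}[group]
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(group_key,))
    for subj, child in enumerate(ss.spawn(n_subjects), start=1):
        rng = np.random.default_rng(child)
        profile = draw_profile(group, rng, n_days=spec.n_days)
        subj_seed = int(rng.integers(2**31))
        for day in days:
            yield subj, day, profile, subj_seed


def cohort_frequency_maps(
    group: str,
    n_subjects: int,
    day: int = 1,
    spec: ProtocolSpec | None = None,
    seed: int = 0,
) -> list[OptimalFrequencyMap]:
    """One optimal-frequency map per subject for a given group and day.

    Uses training-only sessions (see :func:`training_only_spec`): the map is
    a training-stage quantity.
    """
    full = spec or ProtocolSpec()
    short = training_only_spec(full)
    maps = []
    for _, _, profile, subj_seed in iter_cohort_profiles(
            group, n_subjects, full, seed, [day]):
        rec = generate_session(profile, short, day=day, seed=subj_seed)
        maps.append(session_frequency_map(rec, short))
    return maps


def coin_flip_stream(rec: SessionRecording, spec: ProtocolSpec,
                     seed: int) -> PredictionStream:
    """A coin-flip 'classifier' over the evaluation epochs of a session.

    Bypasses signal processing entirely (labels come from the schedule);
    establishes the empirical chance level of the real-time accuracy.
    """
    es = slice_epochs(rec, spec)
    ev = es.subset(es.trials > spec.training_trials)
    rng = np.random.default_rng(seed)
    pred = rng.choice(["RELAX", "IMAGINE"], size=ev.n_epochs)
    onsets = np.array([e.onset_s for e in task_events(rec.events)])
    task_idx = np.searchsorted(onsets, ev.epoch_start_s + 1e-9) - 1
    df = pd.DataFrame({
        "epoch_start_s": ev.epoch_start_s,
        "trial": ev.trials,
        "task_index": task_idx,
        "true_label": ev.labels,
        "predicted_label": pred,
    })
    df["correct"] = df.true_label == df.predicted_label
    bars = df.groupby("task_index")["correct"].sum().astype(int).to_dict()
    return PredictionStream(df, bars)


def erd_recovery(profile: SubjectProfile, spec: ProtocolSpec | None = None,
                 day: int = 1, seed: int = 0,
                 cfg: FilterChainConfig | None = None,
                 method: str = "periodogram"):
    """ERD matrix of a simulated session through the preprocessing chain.

    Returns (ERDMatrix, mu-band motor-cortex ERD). Uses all epochs of the
    session and raw (unnormalized) spectra; the default periodogram
    estimator is linear in band power, which a ratio statistic needs.
    """
    from .analysis import erd_matrix, mu_motor_erd

    spec = spec or ProtocolSpec()
    rec = generate_session(profile, spec, day=day, seed=seed)
    es = preprocess(rec, spec, cfg)
    table = compute_power_table(es, method=method)
    m = erd_matrix(table)
    return m, mu_motor_erd(m)
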