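"""RBF-SVM training on the first trials and streaming per-epoch classification.

The model is trained on the features of the first four trials of a session
(features = per-electrode normalized power at the electrode's optimal
frequency) and then classifies every sliding epoch of the remaining trials,
one prediction per 200 ms shift. Real-time accuracy is the percentage of
correct predictions among all predictions. The on-screen feedback is modeled
as a counter per task occurrence: the "green bar" grows by one for every
correct prediction within that task.

Features are standardized (train-set mean/scale) before the RBF kernel --
relative powers live on very different scales across electrodes and an
unscaled RBF is badly conditioned. The fitted machine is stored as plain
arrays (support vectors, dual coefficients, bias) so models serialize to
JSON and prediction does not depend on the training library at run time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .montage import MOTOR_9
from .preprocessing import EpochSet, FilterChainConfig, preprocess
from .protocol import ProtocolSpec, task_events
from .spectral import (
    DEFAULT_AR_ORDER,
    DEFAULT_FREQS,
    InsufficientClassesError,
    OptimalFrequencyMap,
    compute_power_table,
    extract_features,
    normalize_powers,
    select_optimal_frequencies,
)
from .synthetic import SessionRecording


@dataclass
class TrainedModel:
    """Standardizer + RBF-SVM decision function + optimal-frequency map."""

    feature_mean: np.ndarray
    feature_scale: np.ndarray
    support_vectors: np.ndarray     # (n_sv, n_features), standardized space
    dual_coef: np.ndarray           # (n_sv,)
    intercept: float
    gamma: float
    C: float
    classes: list[str]              # [negative, positive] per decision sign
    frequency_map: OptimalFrequencyMap | None = None
    electrode_labels: list[str] | None = None
    ar_order: int = DEFAULT_AR_ORDER
    training_accuracy: float | None = None

    # -- prediction -------------------------------------------------------

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.feature_mean) / self.feature_scale

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(self.standardize(X))
        d2 = ((Z[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(-1)
        return np.exp(-self.gamma * d2) @ self.dual_coef + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        f = self.decision_function(X)
        return np.asarray(self.classes, dtype=object)[(f > 0).astype(int)]

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        d = {
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "gamma": self.gamma,
            "C": self.C,
            "classes": self.classes,
            "ar_order": self.ar_order,
            "training_accuracy": self.training_accuracy,
            "electrode_labels": self.electrode_labels,
            "frequency_map": None if self.frequency_map is None else {
                "frequencies": self.frequency_map.frequencies,
                "separations": self.frequency_map.separations,
            },
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        d = json.loads(text)
        fm = d.pop("frequency_map")
        return cls(
            feature_mean=np.array(d["feature_mean"]),
            feature_scale=np.array(d["feature_scale"]),
            support_vectors=np.array(d["support_vectors"]),
            dual_coef=np.array(d["dual_coef"]),
            intercept=float(d["intercept"]),
            gamma=float(d["gamma"]),
            C=float(d["C"]),
            classes=list(d["classes"]),
            frequency_map=None if fm is None else OptimalFrequencyMap(
                {k: int(v) for k, v in fm["frequencies"].items()},
                {k: float(v) for k, v in fm["separations"].items()}),
            electrode_labels=d["electrode_labels"],
            ar_order=int(d["ar_order"]),
            training_accuracy=d["training_accuracy"],
        )


def median_heuristic_gamma(Z: np.ndarray, max_points: int = 500) -> float:
    """RBF width from the median pairwise squared distance of (standardized)
    training features: gamma = 1 / median(|z_i - z_j|^2). Deterministic;
    subsamples evenly when the training set is large."""
    Z = np.asarray(Z)
    if len(Z) > max_points:
        Z = Z[np.linspace(0, len(Z) - 1, max_points).astype(int)]
    d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(-1)
    med = np.median(d2[np.triu_indices(len(Z), k=1)])
    return 1.0 / med if med > 0 else 1.0


def train_model(features: np.ndarray, labels: Sequence[str], C: float = 1.0,
                kernel_width: float | None = None) -> TrainedModel:
    """Fit the standardizer and binary RBF-SVM on training features.

    ``kernel_width`` is the RBF gamma; when omitted it is set by the median
    heuristic on the standardized features. Deterministic for fixed inputs.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if len(np.unique(y)) < 2:
        raise InsufficientClassesError("training needs both task labels")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale
    gamma = kernel_width if kernel_width is not None else median_heuristic_gamma(Z)
    svc = SVC(C=C, kernel="rbf", gamma=gamma)
    svc.fit(Z, y)
    model = TrainedModel(
        feature_mean=mean,
        feature_scale=scale,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        gamma=float(gamma),
        C=C,
        classes=[str(c) for c in svc.classes_],
    )
    model.training_accuracy = float(np.mean(model.predict(X) == y))
    return model


def epoch_features(epochs: EpochSet, fmap: OptimalFrequencyMap,
                   ar_order: int = DEFAULT_AR_ORDER) -> np.ndarray:
    """Per-epoch feature matrix: Burg -> normalize -> power at optimal freq."""
    table = normalize_powers(compute_power_table(epochs, ar_order))
    return extract_features(table, fmap)


def train_from_recording(
    rec: SessionRecording,
    spec: ProtocolSpec | None = None,
    cfg: FilterChainConfig | None = None,
    electrodes: Sequence[str] = MOTOR_9,
    ar_order: int = DEFAULT_AR_ORDER,
    C: float = 1.0,
    kernel_width: float | None = None,
) -> TrainedModel:
    """Full training pipeline on the first ``training_trials`` trials."""
    spec = spec or ProtocolSpec()
    es = preprocess(rec, spec, cfg, electrodes)
    train = es.subset(es.trials <= spec.training_trials)
    table = normalize_powers(compute_power_table(train, ar_order))
    fmap = select_optimal_frequencies(table)
    X = extract_features(table, fmap)
    model = train_model(X, train.labels, C=C, kernel_width=kernel_width)
    model.frequency_map = fmap
    model.electrode_labels = list(train.channel_labels)
    model.ar_order = ar_order
    return model


@dataclass
class PredictionStream:
    """Per-epoch online predictions plus feedback-bar accounting."""

    records: pd.DataFrame  # epoch_start_s, trial, task_index, true_label,
                           # predicted_label, correct
    feedback_bars: dict[int, int]  # task_index -> final bar size

    @property
    def n_predictions(self) -> int:
        return len(self.records)

    def to_tsv(self) -> str:
        cols = ["epoch_start_s", "trial", "task_index",
                "true_label", "predicted_label", "correct"]
        return self.records[cols].to_csv(sep="\t", index=False)


def run_online_session(
    rec: SessionRecording,
    model: TrainedModel,
    spec: ProtocolSpec | None = None,
    cfg: FilterChainConfig | None = None,
) -> PredictionStream:
    """Stream the evaluation trials through the trained model.

    Every epoch of trials ``training_trials+1 .. trials_per_session`` is
    filtered, Laplacian-referenced, reduced to the model's electrodes,
    converted to its nine features and classified; the feedback counter of
    a task occurrence grows by one per correct prediction inside it.
    """
    spec = spec or ProtocolSpec()
    if model.frequency_map is None or model.electrode_labels is None:
        raise ValueError("model lacks a frequency map / electrode list; "
                         "train it with train_from_recording")
    missing = set(model.electrode_labels) - {c.upper() for c in rec.channel_labels}
    if missing:
        raise ValueError(f"recording lacks model electrodes: {sorted(missing)}")

    es = preprocess(rec, spec, cfg, model.electrode_labels)
    ev = es.subset(es.trials > spec.training_trials)
    X = epoch_features(ev, model.frequency_map, model.ar_order)
    pred = model.predict(X)

    # task occurrence index: position of the enclosing task event
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


def realtime_accuracy(stream: PredictionStream | pd.DataFrame) -> float:
    """100 x correct / total over every prediction of the stream."""
    df = stream.records if isinstance(stream, PredictionStream) else stream
    if len(df) == 0:
        raise ValueError("empty prediction stream")
    return 100.0 * float(df["correct"].mean())
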