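"""ERD statistic, mu-band motor-cortex summary, histograms, accuracy tables.

Event-related desynchronization (ERD) at electrode E and frequency f is

    ERD_E(f) = 100 * (P(f) - R(f)) / R(f)

where P(f) is the mean power at f over all pedaling-imagery epochs and R(f)
over all relax epochs. Negative values mean suppression during imagery. The
mu-band motor-cortex summary averages ERD over f = 8..12 Hz and E = Cz, C1,
C2, C3, C4 (vertex electrodes over the leg area of M1).

ERD is computed from RAW (unnormalized) spectra: per-epoch normalization
removes exactly the overall power change ERD is meant to measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .spectral import InsufficientClassesError, OptimalFrequencyMap, PowerTable

MU_BAND_FREQS = (8, 9, 10, 11, 12)
MOTOR_CORTEX_5 = ("CZ", "C1", "C2", "C3", "C4")
DEFAULT_BANDS = ((6, 12), (13, 20), (21, 30))


def erd(P: float, R: float) -> float:
    """Percent power change of imagery (P) relative to relax (R)."""
    if R <= 0:
        raise ValueError("reference power R must be positive")
    return 100.0 * (P - R) / R


@dataclass
class ERDMatrix:
    """Per-electrode, per-frequency ERD percentages."""

    values: np.ndarray              # (n_electrodes, n_freqs), percent
    electrode_labels: list[str]
    frequencies_hz: np.ndarray

    def at(self, electrode: str, frequency_hz: float) -> float:
        labels = [l.upper() for l in self.electrode_labels]
        try:
            i = labels.index(electrode.upper())
        except ValueError:
            raise KeyError(f"electrode {electrode!r} not in matrix") from None
        j = np.flatnonzero(np.isclose(self.frequencies_hz, frequency_hz))
        if j.size == 0:
            raise KeyError(f"frequency {frequency_hz} Hz not in matrix")
        return float(self.values[i, j[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.electrode_labels,
                            columns=self.frequencies_hz)


def erd_matrix(powers: PowerTable, imagery_label: str = "IMAGINE",
               relax_label: str = "RELAX") -> ERDMatrix:
    """ERD of every (electrode, frequency) cell from a raw power table."""
    if powers.normalized:
        raise ValueError(
            "ERD requires raw powers; per-slice normalization removes the "
            "power change being measured")
    present = set(map(str, np.unique(powers.labels)))
    if not {imagery_label, relax_label} <= present:
        raise InsufficientClassesError(
            f"need both {imagery_label} and {relax_label}, got {sorted(present)}")
    P = powers.values[powers.labels == imagery_label].mean(axis=0)
    R = powers.values[powers.labels == relax_label].mean(axis=0)
    if np.any(R <= 0):
        raise ValueError("non-positive reference power encountered")
    return ERDMatrix(100.0 * (P - R) / R, list(powers.electrode_labels),
                     np.asarray(powers.frequencies_hz))


def mu_motor_erd(m: ERDMatrix,
                 electrodes: Sequence[str] = MOTOR_CORTEX_5,
                 frequencies_hz: Sequence[int] = MU_BAND_FREQS) -> float:
    """Unweighted mean ERD over the mu band at the five vertex electrodes."""
    vals = [m.at(e, f) for e in electrodes for f in frequencies_hz]
    return float(np.mean(vals))


def band_counts(maps: Iterable[OptimalFrequencyMap],
                bands: Sequence[tuple[int, int]] = DEFAULT_BANDS) -> tuple[int, ...]:
    """Count optimal frequencies per closed integer band across subjects."""
    counts = [0] * len(bands)
    for fmap in maps:
        for f in fmap.frequencies.values():
            lo_all, hi_all = bands[0][0], bands[-1][1]
            if not (lo_all <= f <= hi_all):
                raise ValueError(f"optimal frequency {f} Hz outside "
                                 f"{lo_all}-{hi_all} Hz")
            for i, (lo, hi) in enumerate(bands):
                if lo <= f <= hi:
                    counts[i] += 1
                    break
    return tuple(counts)


def optimal_frequency_histogram(
    maps_by_group_day: Mapping[tuple[str, int], Iterable[OptimalFrequencyMap]],
    bands: Sequence[tuple[int, int]] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Band histogram per (group, day): one row per group x band, day columns.

    With 7 subjects x 9 electrodes each cell column sums to 63 per group-day.
    """
    rows = {}
    days = sorted({d for _, d in maps_by_group_day})
    for (group, day), maps in sorted(maps_by_group_day.items()):
        counts = band_counts(maps, bands)
        for (lo, hi), c in zip(bands, counts):
            rows.setdefault((group, f"({lo}-{hi}) Hz"), {})[f"Day {day}"] = c
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"Day {d}" for d in days])
    df.index = pd.MultiIndex.from_tuples(df.index, names=["Group", "Band"])
    return df


@dataclass
class AccuracySummary:
    """Per-subject multi-day means and group mean +/- sd, per group."""

    per_session: pd.DataFrame    # group, subject, day, accuracy
    per_subject: pd.DataFrame    # group, subject, mean accuracy across days
    group_mean: dict[str, float]
    group_sd: dict[str, float | None]   # None when a group has one subject

    def table(self) -> pd.DataFrame:
        """Wide per-subject table, one column per group, plus the mean row."""
        wide = self.per_subject.pivot(index="subject", columns="group",
                                      values="accuracy")
        mean_row = {g: self.group_mean[g] for g in wide.columns}
        wide.loc["Mean"] = mean_row
        return wide


def accuracy_summary(per_session: pd.DataFrame) -> AccuracySummary:
    """Summarize per-session accuracies (columns: group, subject, day,
    accuracy in percent) into per-subject means and group mean +/- sd.

    Every subject must have every day of their group (no partial cohorts);
    the sd is the between-subject sd of the multi-day means (ddof=1),
    undefined (None) for single-subject groups.
    """
    req = {"group", "subject", "day", "accuracy"}
    if not req <= set(per_session.columns):
        raise ValueError(f"per_session must have columns {sorted(req)}")
    if ((per_session.accuracy < 0) | (per_session.accuracy > 100)).any():
        raise ValueError("accuracies must lie in [0, 100]")
    for g, sub in per_session.groupby("group"):
        days = set(sub.day.unique())
        counts = sub.groupby("subject").day.apply(set)
        bad = [s for s, d in counts.items() if d != days]
        if bad:
            raise ValueError(f"group {g}: subjects {bad} missing sessions")
    per_subject = (per_session.groupby(["group", "subject"], as_index=False)
                   .accuracy.mean())
    gm, gs = {}, {}
    for g, sub in per_subject.groupby("group"):
        gm[g] = float(sub.accuracy.mean())
        gs[g] = float(sub.accuracy.std(ddof=1)) if len(sub) > 1 else None
    return AccuracySummary(per_session.copy(), per_subject, gm, gs)
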