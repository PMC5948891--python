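"""Readers and writers: EDF+ input, the package's delimited session
container, epoch-set archives, and delimited power/map exports.

Sessions written by this package use a two-file container: a gzipped
tab-delimited signal matrix (``<prefix>.signals.tsv.gz``, one row per
sample, one column per channel, microvolts) and a JSON sidecar
(``<prefix>.meta.json``) holding the sampling rate, channel labels and cue
events. EDF+ files are read through MNE; their annotations become schedule
events.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import EpochSet
from .protocol import ProtocolSpec, ScheduleEvent
from .spectral import OptimalFrequencyMap, PowerTable
from .synthetic import SessionRecording

_FLOAT_FMT = "%.4f"  # 0.1 nV resolution, far below EEG noise floor


def save_session(rec: SessionRecording, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(rec.samples.T, columns=rec.channel_labels)
    df.to_csv(Path(str(prefix) + ".signals.tsv.gz"), sep="\t", index=False,
              float_format=_FLOAT_FMT)
    meta = {
        "sampling_rate_hz": rec.sampling_rate_hz,
        "channel_labels": rec.channel_labels,
        "events": [
            {"label": e.label, "onset_s": e.onset_s,
             "duration_s": e.duration_s, "trial": e.trial}
            for e in rec.events
        ],
    }
    Path(str(prefix) + ".meta.json").write_text(json.dumps(meta))


def load_session(prefix: str | Path) -> SessionRecording:
    prefix = Path(prefix)
    meta = json.loads(Path(str(prefix) + ".meta.json").read_text())
    df = pd.read_csv(Path(str(prefix) + ".signals.tsv.gz"), sep="\t")
    events = [ScheduleEvent(e["label"], e["onset_s"], e["duration_s"],
                            e.get("trial", 0)) for e in meta["events"]]
    return SessionRecording(df.to_numpy().T, meta["sampling_rate_hz"],
                            meta["channel_labels"], events)


def read_session_edf(path: str | Path,
                     spec: ProtocolSpec | None = None) -> SessionRecording:
    """Read an EDF+ recording; annotations become schedule events.

    Annotation descriptions must be the cue labels (RELAX / IMAGINE /
    CUE_CROSS, case-insensitive). When a protocol spec is given, trial
    indices are inferred from event onsets.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    events = []
    trial_dur = spec.trial_duration_s if spec is not None else None
    for onset, dur, desc in zip(raw.annotations.onset,
                                raw.annotations.duration,
                                raw.annotations.description):
        label = str(desc).strip().upper()
        trial = int(onset // trial_dur) + 1 if trial_dur else 0
        events.append(ScheduleEvent(label, float(onset), float(dur), trial))
    return SessionRecording(data, float(raw.info["sfreq"]),
                            [ch.upper() for ch in raw.ch_names], events)


def save_epochs(es: EpochSet, prefix: str | Path) -> None:
    """Array container (.npz) plus JSON sidecar for the labels/metadata."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(Path(str(prefix) + ".epochs.npz"), epochs=es.epochs)
    sidecar = {
        "labels": [str(l) for l in es.labels],
        "epoch_start_s": es.epoch_start_s.tolist(),
        "channel_labels": es.channel_labels,
        "sampling_rate_hz": es.sampling_rate_hz,
        "trials": es.trials.tolist(),
    }
    Path(str(prefix) + ".epochs.json").write_text(json.dumps(sidecar))


def load_epochs(prefix: str | Path) -> EpochSet:
    prefix = Path(prefix)
    arr = np.load(Path(str(prefix) + ".epochs.npz"))["epochs"]
    side = json.loads(Path(str(prefix) + ".epochs.json").read_text())
    return EpochSet(arr, np.array(side["labels"]),
                    np.array(side["epoch_start_s"]), side["channel_labels"],
                    side["sampling_rate_hz"], np.array(side["trials"]))


def power_table_to_frame(table: PowerTable) -> pd.DataFrame:
    """Long-form (epoch, electrode, frequency_hz, power[, task]) table."""
    e, c, f = table.values.shape
    idx = pd.MultiIndex.from_product(
        [range(e), table.electrode_labels, table.frequencies_hz],
        names=["epoch", "electrode", "frequency_hz"])
    df = pd.DataFrame({"power": table.values.reshape(-1)}, index=idx).reset_index()
    df["task"] = np.repeat(table.labels, c * f)
    return df


def frequency_map_to_json(fmap: OptimalFrequencyMap) -> str:
    return json.dumps({"frequencies": fmap.frequencies,
                       "separations": fmap.separations})


def frequency_map_from_json(text: str) -> OptimalFrequencyMap:
    d = json.loads(text)
    return OptimalFrequencyMap({k: int(v) for k, v in d["frequencies"].items()},
                               {k: float(v) for k, v in d["separations"].items()})
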