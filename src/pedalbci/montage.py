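"""Electrode montage: the 30-channel 10-10 subset and 2D scalp coordinates.

Coordinates come from the standard 10-05 idealized head shipped with MNE,
projected to the plane by the usual azimuthal-equidistant map (Cz at the
origin, radius = polar angle from the vertex). The 2D positions drive both
the distance-weighted Laplacian reference and the synthetic generator's
spatial projection of the sensorimotor rhythm.
"""

from __future__ import annotations

import functools

import numpy as np

#: The 30 recording channels, as labeled by the acquisition hardware.
CHANNELS_30 = (
    "P7", "P4", "CZ", "PZ", "P3", "P8", "O1", "O2", "C2", "C4",
    "F4", "FP2", "FZ", "C3", "F3", "FP1", "C1", "OZ", "PO4", "FC6",
    "FC2", "AF4", "CP6", "CP2", "CP1", "CP5", "FC1", "FC5", "AF3", "PO3",
)

#: The nine motor-area electrodes used for classification (over M1/S1/SMA/PM,
#: covering the foot/leg representation around the vertex).
MOTOR_9 = ("CZ", "CP1", "CP2", "C1", "C2", "C3", "C4", "FC1", "FC2")


def canonical(label: str) -> str:
    """Uppercase canonical form used throughout the package."""
    return label.strip().upper()


@functools.lru_cache(maxsize=1)
def _standard_positions_3d() -> dict[str, np.ndarray]:
    import mne

    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mont = mne.channels.make_standard_montage("standard_1005")
    return {canonical(k): np.asarray(v) for k, v in mont.get_positions()["ch_pos"].items()}


@functools.lru_cache(maxsize=1)
def positions_2d() -> dict[str, np.ndarray]:
    """Azimuthal-equidistant 2D scalp positions (unit: radians of arc).

    Computed once for the full 30-channel montage; the head is re-centered
    on the electrode cloud so the vertex (Cz) maps to the origin. Distances
    in this plane approximate along-scalp distances, which is what the 1/d
    Laplacian weighting wants.
    """
    labels = CHANNELS_30
    pos3 = _standard_positions_3d()
    all_xyz = np.array([pos3[canonical(l)] for l in labels])
    center = all_xyz.mean(axis=0)
    # crude sphere fit: center the cloud, use mean radius
    v = all_xyz - center
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    out: dict[str, np.ndarray] = {}
    for lab, u in zip(labels, v):
        polar = np.arccos(np.clip(u[2], -1.0, 1.0))
        azim = np.arctan2(u[1], u[0])
        out[canonical(lab)] = np.array([polar * np.cos(azim), polar * np.sin(azim)])
    # shift so CZ is exactly at the origin when present
    if "CZ" in out:
        cz = out["CZ"].copy()
        for lab in out:
            out[lab] = out[lab] - cz
    return out


def coordinate_array(labels: list[str] | tuple[str, ...]) -> np.ndarray:
    """(n_channels, 2) array of 2D positions in the order given.

    Labels must belong to the 30-channel montage.
    """
    pos = positions_2d()
    try:
        return np.array([pos[canonical(l)] for l in labels])
    except KeyError as e:  # pragma: no cover - defensive
        raise KeyError(f"unknown electrode label: {e.args[0]}") from None


def median_neighbor_spacing(labels=CHANNELS_30) -> float:
    """Median nearest-neighbor distance in the 2D plane (montage scale)."""
    xy = coordinate_array(list(labels))
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return float(np.median(d.min(axis=1)))
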