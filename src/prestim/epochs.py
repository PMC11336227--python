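"""Epoch-level EEG container, I/O, referencing, and trial curation.

The :class:`EpochSet` is the pipeline's in-memory unit: a trials x channels
x samples voltage array cut around face onset (0 ms), with per-trial valence
ratings.  Containers are stored as a ``.npz`` array file plus a ``.json``
sidecar carrying axes, labels and provenance, so the metadata stays
human-diffable.  Raw BrainVision / EDF recordings are imported through mne.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

RATINGS = ("negative", "positive", "neutral", "missed")
#: previous_rating value for the first trial of a run (no preceding rating)
NO_PREVIOUS = "none"

_SCHEMA_VERSION = 1

__all__ = [
    "EpochSet",
    "TrialSelection",
    "read_epochs",
    "write_epochs",
    "from_brainvision",
    "from_edf",
    "common_average_reference",
    "select_rated",
    "equalize_trials",
    "inclusion_check",
    "RATINGS",
    "NO_PREVIOUS",
]


@dataclass
class EpochSet:
    """Trials x channels x samples voltage array with per-trial metadata.

    ``times`` is in milliseconds relative to face onset (stimulus shown
    0-200 ms); the default epoch spans -2000..+2000 ms inclusive at 500 Hz
    (2001 samples).  ``metadata`` has one row per trial with at least a
    ``rating`` column in :data:`RATINGS`; ``previous_rating`` additionally
    admits :data:`NO_PREVIOUS`.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    channels: tuple
    metadata: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n_trials, n_channels, n_samples = self.data.shape
        if len(self.channels) != n_channels:
            raise ValueError("channel labels do not match data")
        if len(set(self.channels)) != n_channels:
            raise ValueError("channel labels must be unique")
        if self.times.shape != (n_samples,):
            raise ValueError("times axis does not match data")
        dt = 1000.0 / self.sfreq
        if n_samples > 1 and not np.allclose(np.diff(self.times), dt):
            raise ValueError("times must be evenly spaced at 1/sampling_rate")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if len(self.metadata) != n_trials:
            raise ValueError("metadata length must equal trial count")
        bad = set(self.metadata["rating"]) - set(RATINGS)
        if bad:
            raise ValueError(f"unknown rating labels: {sorted(bad)}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.times.copy(), self.sfreq,
                        tuple(self.channels), self.metadata.copy())

    def select(self, indices) -> "EpochSet":
        indices = np.asarray(indices, dtype=int)
        md = self.metadata.iloc[indices].reset_index(drop=True)
        return EpochSet(self.data[indices], self.times.copy(), self.sfreq,
                        tuple(self.channels), md)


@dataclass(frozen=True)
class TrialSelection:
    """A curated subset of trial indices with its provenance."""

    indices: np.ndarray
    note: str = ""
    seed: int | None = None

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("indices must be 1-D")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("indices must be unique")
        if np.any(np.diff(idx) < 0):
            idx = np.sort(idx)
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# container I/O


def write_epochs(epochs: EpochSet, path) -> None:
    """Write an EpochSet as ``<path>.npz`` + ``<path>.json`` (lossless)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), data=epochs.data, times=epochs.times)
    sidecar = {
        "schema_version": _SCHEMA_VERSION,
        "sfreq": epochs.sfreq,
        "channels": list(epochs.channels),
        "metadata": epochs.metadata.to_dict(orient="list"),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_epochs(path) -> EpochSet:
    """Read an EpochSet written by :func:`write_epochs`."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    version = sidecar.get("schema_version")
    if version != _SCHEMA_VERSION:
        raise ValueError(f"unsupported container schema version: {version!r}")
    with np.load(path.with_suffix(".npz")) as npz:
        data = npz["data"]
        times = npz["times"]
    metadata = pd.DataFrame(sidecar["metadata"])
    return EpochSet(data, times, float(sidecar["sfreq"]),
                    tuple(sidecar["channels"]), metadata)


def _epoch_raw(raw, events: pd.DataFrame, window=(-2000.0, 2000.0),
               channels=None) -> EpochSet:
    """Cut epochs out of an mne Raw object around event onset samples."""
    sfreq = raw.info["sfreq"]
    if channels is not None:
        raw = raw.copy().pick(list(channels))
    data = raw.get_data()  # channels x samples, volts for eeg
    n_samples_total = data.shape[1]
    lo = int(round(window[0] / 1000.0 * sfreq))
    hi = int(round(window[1] / 1000.0 * sfreq))
    times = np.arange(lo, hi + 1) / sfreq * 1000.0
    trials = []
    ratings = []
    for _, ev in events.iterrows():
        onset = int(ev["onset_sample"])
        start, stop = onset + lo, onset + hi + 1
        if start < 0 or stop > n_samples_total:
            raise ValueError(
                f"epoch for event at sample {onset} extends past the "
                f"recording edge (need samples {start}..{stop - 1} of "
                f"{n_samples_total})")
        trials.append(data[:, start:stop])
        ratings.append(str(ev["rating"]) if "rating" in ev else "missed")
    md = pd.DataFrame({"rating": ratings})
    md["previous_rating"] = [NO_PREVIOUS] + ratings[:-1]
    return EpochSet(np.array(trials) * 1e6, times, sfreq,
                    tuple(raw.ch_names), md)


def _read_event_table(events_path) -> pd.DataFrame:
    events = pd.read_csv(events_path, sep="\t")
    if "onset_sample" not in events.columns:
        raise ValueError("event table needs an 'onset_sample' column")
    return events


def from_brainvision(vhdr_path, events_path, window=(-2000.0, 2000.0),
                     channels=None) -> EpochSet:
    """Import a BrainVision recording plus a TSV event table as epochs.

    The event table needs columns ``onset_sample`` and (optionally)
    ``rating``; epochs are cut ``window`` ms around each onset.  Voltages
    are returned in microvolts.
    """
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    return _epoch_raw(raw, _read_event_table(events_path), window, channels)


def from_edf(edf_path, events_path, window=(-2000.0, 2000.0),
             channels=None) -> EpochSet:
    """Import an EDF/EDF+ recording plus a TSV event table as epochs."""
    import mne

    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    return _epoch_raw(raw, _read_event_table(events_path), window, channels)


# ---------------------------------------------------------------------------
# curation


def common_average_reference(epochs: EpochSet) -> EpochSet:
    """Re-reference to the common average: channel mean is 0 at every sample.

    Idempotent, and preserves all pairwise channel differences exactly.
    """
    if epochs.n_channels < 2:
        raise ValueError("common average reference needs at least 2 channels")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return replace(epochs.copy(), data=data)


def select_rated(epochs: EpochSet, keep) -> TrialSelection:
    """Indices of trials whose rating is in ``keep`` (e.g. negative/positive)."""
    keep = set(keep)
    unknown = keep - set(RATINGS)
    if unknown:
        raise ValueError(f"unknown rating labels: {sorted(unknown)}")
    mask = epochs.metadata["rating"].isin(keep).to_numpy()
    return TrialSelection(np.flatnonzero(mask), note=f"rating in {sorted(keep)}")


def equalize_trials(selections: dict, seed: int) -> dict:
    """Equalize two rating classes by subsampling the larger one.

    ``selections`` maps label -> TrialSelection (or index sequence).  The
    larger class is subsampled uniformly without replacement to the size of
    the smaller one; the smaller class is kept whole.  Deterministic under
    ``seed``.
    """
    if len(selections) != 2:
        raise ValueError("equalization is defined over exactly two classes")
    idx = {}
    for label, sel in selections.items():
        arr = sel.indices if isinstance(sel, TrialSelection) else np.asarray(sel, dtype=int)
        if len(arr) == 0:
            raise ValueError(f"class {label!r} has no trials")
        idx[label] = np.sort(arr)
    n_keep = min(len(a) for a in idx.values())
    rng = np.random.default_rng(seed)
    out = {}
    # iterate in sorted label order so the rng stream does not depend on
    # dict insertion order
    for label in sorted(idx):
        arr = idx[label]
        if len(arr) > n_keep:
            arr = np.sort(rng.choice(arr, size=n_keep, replace=False))
            note = f"subsampled to {n_keep}"
        else:
            note = "kept whole"
        out[label] = TrialSelection(arr, note=note, seed=seed)
    return out


def inclusion_check(counts: dict, minimum: int = 10) -> bool:
    """Participant inclusion rule: every class count >= ``minimum`` (10)."""
    return all(int(c) >= minimum for c in counts.values())
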