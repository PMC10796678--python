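"""On-disk containers: HDF5 epochs fixtures, ITPC maps, cohort metadata.

Epochs fixture layout (HDF5)::

    /data              float64, (trials, channels, samples), µV
    /channel_labels    variable-length UTF-8 strings
    attrs: sample_rate (float), t0_index (int), subject_id (str)

ITPC map layout::

    /values            float64, (channels, freqs, times)
    /valid             bool, same shape
    /freqs, /times     float64 axes
    /channel_labels    strings
    attrs: n_trials (int)
"""
from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .epochs import Epochs
from .exceptions import FixtureFormatError

__all__ = [
    "write_fixture", "read_fixture",
    "write_itpc_map", "read_itpc_map",
    "write_cohort_metadata", "read_cohort_metadata",
    "read_raw_edf",
]

_STR = h5py.string_dtype(encoding="utf-8")


def write_fixture(epochs: Epochs, path) -> None:
    """Write an epochs fixture; lossless round trip with :func:`read_fixture`."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("channel_labels",
                         data=np.array(epochs.channel_labels, dtype=object),
                         dtype=_STR)
        f.attrs["sample_rate"] = float(epochs.sample_rate)
        f.attrs["t0_index"] = int(epochs.t0_index)
        f.attrs["subject_id"] = epochs.subject_id


def read_fixture(path) -> Epochs:
    """Read an epochs fixture written by :func:`write_fixture`."""
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise FixtureFormatError(f"{path}: no 'data' dataset")
        for attr in ("sample_rate", "t0_index"):
            if attr not in f.attrs:
                raise FixtureFormatError(f"{path}: missing attribute {attr!r}")
        data = f["data"][()]
        if data.ndim != 3:
            raise FixtureFormatError(f"{path}: data must be 3-D, got {data.shape}")
        labels = [s.decode() if isinstance(s, bytes) else str(s)
                  for s in f["channel_labels"][()]] if "channel_labels" in f else []
        return Epochs(data=data,
                      sample_rate=float(f.attrs["sample_rate"]),
                      t0_index=int(f.attrs["t0_index"]),
                      channel_labels=labels,
                      subject_id=str(f.attrs.get("subject_id", "")))


def write_itpc_map(itpc_map, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=itpc_map.values)
        f.create_dataset("valid", data=itpc_map.valid)
        f.create_dataset("freqs", data=itpc_map.freqs)
        f.create_dataset("times", data=itpc_map.times)
        f.create_dataset("channel_labels",
                         data=np.array(itpc_map.channel_labels, dtype=object),
                         dtype=_STR)
        f.attrs["n_trials"] = int(itpc_map.n_trials)


def read_itpc_map(path):
    from .tfr import ITPCMap
    with h5py.File(path, "r") as f:
        for name in ("values", "valid", "freqs", "times"):
            if name not in f:
                raise FixtureFormatError(f"{path}: missing dataset {name!r}")
        labels = [s.decode() if isinstance(s, bytes) else str(s)
                  for s in f["channel_labels"][()]] if "channel_labels" in f else []
        return ITPCMap(values=f["values"][()], valid=f["valid"][()].astype(bool),
                       freqs=f["freqs"][()], times=f["times"][()],
                       n_trials=int(f.attrs["n_trials"]),
                       channel_labels=labels)


_META_COLUMNS = ["subject_id", "condition", "diag1", "diag2", "diag3", "diag4",
                 "diag5", "abris", "etiology"]


def write_cohort_metadata(subjects, condition: str, path) -> None:
    """Write the cohort metadata TSV (one row per subject)."""
    rows = []
    for s in subjects:
        diags = list(s.diagnoses[:5]) + [""] * (5 - len(s.diagnoses[:5]))
        rows.append([s.subject_id, condition, *diags, s.abris, s.etiology])
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cohort_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_META_COLUMNS) - set(df.columns)
    if missing:
        raise FixtureFormatError(f"{path}: metadata TSV missing columns {sorted(missing)}")
    return df


def read_raw_edf(path, events_csv=None):
    """Read continuous EDF/BDF data (requires the optional ``mne`` extra).

    Returns ``(data_uV (channels, samples), sample_rate, channel_labels,
    onsets)`` where ``onsets`` are the stimulus onset samples from the
    ``events_csv`` sidecar (columns: onset_sample, condition) or None.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF/BDF requires mne (pip install chirpefr[edf])") from exc
    path = Path(path)
    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> µV
    onsets = None
    if events_csv is not None:
        events = pd.read_csv(events_csv)
        onsets = events["onset_sample"].to_numpy(dtype=int)
    return data, float(raw.info["sfreq"]), list(raw.ch_names), onsets
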