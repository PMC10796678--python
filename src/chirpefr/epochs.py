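"""The epoched-EEG container shared by the whole pipeline.

An :class:`Epochs` holds a ``trials x channels x samples`` voltage array (µV)
with a time axis locked to stimulus onset: sample ``i`` occurs at
``(i - t0_index) / sample_rate`` seconds relative to onset.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigurationError

__all__ = ["Epochs"]


@dataclass
class Epochs:
    """Multi-trial, multi-channel epoched EEG.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Voltages in microvolts.
    sample_rate : float
        Sampling rate in Hz.
    t0_index : int
        Sample index of stimulus onset (time zero) within each epoch.
    channel_labels : list of str
        One label per channel, e.g. ``"FCz"``.
    subject_id : str
        Free-form identifier carried through to curves and reports.
    """

    data: np.ndarray
    sample_rate: float
    t0_index: int
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ConfigurationError(
                f"epochs data must be 3-D (trials, channels, samples), got {self.data.shape}"
            )
        if self.channel_labels and len(self.channel_labels) != self.data.shape[1]:
            raise ConfigurationError(
                f"{len(self.channel_labels)} labels for {self.data.shape[1]} channels"
            )
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[1])]
        if not 0 <= self.t0_index < self.data.shape[2]:
            raise ConfigurationError("t0_index outside the epoch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Per-sample times in seconds relative to stimulus onset."""
        return (np.arange(self.n_samples) - self.t0_index) / self.sample_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None

    def pick_channels(self, labels: list[str]) -> "Epochs":
        """Return a copy restricted to ``labels`` (in the given order)."""
        idx = [self.channel_index(lb) for lb in labels]
        return replace(self, data=self.data[:, idx, :], channel_labels=list(labels))

    def select_trials(self, index: np.ndarray) -> "Epochs":
        """Return a copy keeping the trials in ``index`` (original order of the index)."""
        return replace(self, data=self.data[np.asarray(index)], channel_labels=list(self.channel_labels))

    def copy(self) -> "Epochs":
        return replace(self, data=self.data.copy(), channel_labels=list(self.channel_labels))
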