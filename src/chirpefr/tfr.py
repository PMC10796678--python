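"""Short-time Fourier decomposition and intertrial phase clustering (ITPC).

The spectral estimator is a single Hanning taper sliding over each epoch:

    F_k(f, t) = sum_s x_k(s) h(s) exp(-i 2 pi f (s - center) / rate)

over a 500 ms window centered at output time ``t``.  At 512 Hz a 500 ms
window holds 256 samples, natively giving 2 Hz frequency spacing for the
2-120 Hz analysis grid, and the output time grid steps every 5 samples
(9.765625 ms).  Output times whose full window would leave the epoch are kept
on the grid but marked invalid.

Across trials the phase consistency is summarised by the intertrial phase
clustering coefficient

    ITPC(f, t) = | (1/n) sum_k F_k(f, t) / |F_k(f, t)| |,

the resultant length of the unit-normalised spectral estimates: 0 for random
phases (with a chance floor ~ sqrt(pi)/2/sqrt(n)), 1 for perfect phase
locking.  Cells where any trial has a zero coefficient are undefined and
tracked with an explicit validity mask rather than a sentinel value.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import fft as sfft
from scipy.signal import windows

from .epochs import Epochs
from .exceptions import ConfigurationError
from .stimuli import DEFAULT_FREQ_GRID

__all__ = ["SpectralEstimates", "ITPCMap", "stft", "itpc", "channel_average",
           "DEFAULT_TIME_STEP"]

#: Output temporal resolution in seconds (5 samples at 512 Hz).
DEFAULT_TIME_STEP = 0.009765625


@dataclass
class SpectralEstimates:
    """Per-trial complex STFT coefficients.

    ``values`` has shape (trials, channels, freqs, times) and is only
    populated at ``valid`` output times (full window inside the epoch);
    invalid time columns are zero and masked.
    """

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    valid: np.ndarray  # (times,) bool
    window_length: float
    channel_labels: list[str]


@dataclass
class ITPCMap:
    """Across-trial ITPC field, (channels, freqs, times), with validity mask."""

    values: np.ndarray
    valid: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    n_trials: int
    channel_labels: list[str]

    def time_index(self, t: float) -> int:
        """Index of the nearest time bin center."""
        return int(np.argmin(np.abs(self.times - t)))

    def freq_index(self, f: float) -> int:
        i = int(np.argmin(np.abs(self.freqs - f)))
        if abs(self.freqs[i] - f) > 1e-6:
            raise ConfigurationError(f"{f} Hz is not on the frequency grid")
        return i


def stft(epochs: Epochs, freqs=None, window_length: float = 0.5,
         time_step: float = DEFAULT_TIME_STEP) -> SpectralEstimates:
    """Hanning-tapered sliding-window Fourier decomposition of every trial.

    Parameters
    ----------
    epochs : Epochs
        Baseline-corrected epochs (any sampling rate; the defaults are tuned
        for 512 Hz).
    freqs : array-like, optional
        Analysis frequencies in Hz; defaults to 2-120 Hz in 2 Hz steps.
    window_length : float
        Taper length in seconds (default 0.5).
    time_step : float
        Output temporal resolution in seconds; must be a whole number of
        samples (default 9.765625 ms = 5 samples at 512 Hz).
    """
    freqs = DEFAULT_FREQ_GRID if freqs is None else np.asarray(freqs, dtype=float)
    sr = epochs.sample_rate
    step = time_step * sr
    step_n = int(round(step))
    if step_n < 1 or abs(step - step_n) > 1e-6:
        raise ConfigurationError(
            f"time step {time_step} s is not a whole number of samples at {sr} Hz"
        )
    wlen = int(round(window_length * sr))
    n = epochs.n_samples
    if wlen > n:
        raise ConfigurationError("window longer than the epoch")
    if np.any(freqs >= sr / 2):
        raise ConfigurationError("analysis frequency at or above Nyquist")

    # Output grid: anchored at stimulus onset so t = 0 is always a bin center.
    t0 = epochs.t0_index
    first = t0 % step_n
    centers = np.arange(first, n, step_n)
    half_pre = wlen // 2
    half_post = wlen - half_pre
    valid = (centers - half_pre >= 0) & (centers + half_post <= n)
    if not np.any(valid):
        raise ConfigurationError("no output time has a full window inside the epoch")
    times = (centers - t0) / sr

    taper = windows.hann(wlen, sym=True)
    n_trials, n_ch = epochs.n_trials, epochs.n_channels
    vidx = np.flatnonzero(valid)
    starts = centers[vidx] - half_pre
    # Gather all valid windows: (trials, channels, n_valid, wlen).  Single
    # precision throughout: only the coefficient phases matter downstream and
    # the across-trial ITPC average is accumulated in double precision.
    win_view = np.lib.stride_tricks.sliding_window_view(epochs.data, wlen, axis=-1)
    wins = win_view[:, :, starts, :].astype(np.float32) * taper.astype(np.float32)

    # The analysis frequencies usually sit exactly on the window's DFT bins
    # (e.g. 2-120 Hz in 2 Hz steps with a 256-sample window at 512 Hz), in
    # which case one FFT per window replaces the dense basis product; the
    # centered-window phase convention needs a per-bin rotation of
    # exp(+i 2 pi k half_pre / wlen).
    bins = freqs * wlen / sr
    kint = np.rint(bins).astype(int)
    if np.all(np.abs(bins - kint) < 1e-9) and np.all(kint <= wlen // 2):
        k_lo, k_hi = int(kint.min()), int(kint.max())
        spec_all = sfft.rfft(wins, axis=-1)[..., k_lo:k_hi + 1]
        coef = spec_all[..., kint - k_lo]
        rot = np.exp(2j * np.pi * kint * half_pre / wlen).astype(np.complex64)
        coef = coef * rot
    else:
        s_rel = np.arange(wlen) - half_pre
        omega = 2 * np.pi * freqs[:, None] * s_rel[None, :] / sr
        basis = (np.cos(omega) - 1j * np.sin(omega)).astype(np.complex64)
        coef = wins @ basis.T
    vals = np.zeros((n_trials, n_ch, len(freqs), len(centers)), dtype=np.complex64)
    vals[:, :, :, vidx] = np.moveaxis(coef, 2, 3)
    return SpectralEstimates(values=vals, freqs=freqs, times=times, valid=valid,
                             window_length=window_length,
                             channel_labels=list(epochs.channel_labels))


def itpc(spec: SpectralEstimates) -> ITPCMap:
    """ITPC per channel: unit-normalise each trial's coefficient, average
    across trials, take the modulus.

    Cells where any trial has a zero-magnitude coefficient are undefined and
    excluded via the validity mask (they never poison neighbouring cells).
    """
    n_trials = spec.values.shape[0]
    if n_trials < 2:
        raise ConfigurationError("ITPC needs at least 2 trials")
    values = spec.values
    mag = np.abs(values)
    zero = mag == 0
    safe = np.where(zero, mag.dtype.type(1.0), mag)
    unit = values / safe
    # unit vectors keep the input precision; the across-trial average is
    # accumulated in double precision regardless
    resultant = np.abs(unit.mean(axis=0, dtype=np.complex128))
    resultant = np.asarray(resultant, dtype=float)
    cell_valid = ~zero.any(axis=0)
    valid = cell_valid & spec.valid[None, None, :]
    values = np.where(valid, resultant, 0.0)
    return ITPCMap(values=values, valid=valid, freqs=spec.freqs,
                   times=spec.times, n_trials=n_trials,
                   channel_labels=list(spec.channel_labels))


def channel_average(itpc_map: ITPCMap, channels: list[str]) -> ITPCMap:
    """Average ITPC values (computed per channel first) across ``channels``.

    A cell of the averaged map is valid only where it is valid on every
    selected channel.
    """
    missing = [c for c in channels if c not in itpc_map.channel_labels]
    if missing:
        raise ConfigurationError(f"channels not in map: {missing}")
    idx = [itpc_map.channel_labels.index(c) for c in channels]
    values = itpc_map.values[idx].mean(axis=0, keepdims=True)
    valid = itpc_map.valid[idx].all(axis=0, keepdims=True)
    return replace(itpc_map, values=np.where(valid, values, 0.0), valid=valid,
                   channel_labels=["avg"])
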