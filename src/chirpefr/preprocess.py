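"""Deterministic preprocessing: filtering, re-referencing, decimation,
epoching, baseline correction, artifact rejection and epoch-count
equalization.

The chain mirrors a conventional evoked-response pipeline: zero-phase 8th
order Butterworth high-pass plus 50 Hz notch on the continuous data, common
average reference, 2:1 decimation to 512 Hz, segmentation into
onset-locked epochs, baseline correction over a pre-onset window, rule-based
artifact rejection on the analysis channels, and equalization of the epoch
count across subjects (subjects with fewer than 200 clean epochs are
excluded; more than 240 are randomly subsampled to exactly 240).

Ocular ICA and bad-channel interpolation are deliberately absent: those are
interactive steps, and this pipeline expects already-cleaned (or synthetic)
input.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .epochs import Epochs
from .exceptions import ConfigurationError

__all__ = [
    "PreprocConfig",
    "RejectionRecord",
    "EqualizeResult",
    "filter_continuous",
    "rereference_average",
    "downsample",
    "segment_and_baseline",
    "baseline_correct",
    "reject_artifacts",
    "equalize_epochs",
    "preprocess_epochs",
]

logger = logging.getLogger(__name__)

ANALYSIS_CHANNELS = ("FC1", "FC2", "C1", "C2", "Fz", "FCz", "Cz")


@dataclass(frozen=True)
class PreprocConfig:
    """Preprocessing parameters.

    Rejection rules (per analysis channel, any hit rejects the epoch):

    a. any sample outside ``±amp_limit`` µV;
    b. peak-to-peak range above ``max_diff`` µV within any sliding window of
       ``diff_interval`` seconds (1-sample step);
    c. a step between consecutive samples faster than ``max_step`` µV/ms.
    """

    highpass_cutoff: float = 0.5
    highpass_order: int = 8
    notch_freq: float = 50.0
    notch_bandwidth: float = 2.0
    target_rate: float = 512.0
    epoch_window: tuple[float, float] = (-0.7, 1.2)
    baseline_window: tuple[float, float] = (-0.699, -0.200)
    amp_limit: float = 200.0
    max_diff: float = 200.0
    diff_interval: float = 0.200
    max_step: float = 150.0
    min_epochs: int = 200
    cap_epochs: int = 240
    analysis_channels: tuple[str, ...] = ANALYSIS_CHANNELS
    seed: int = 0

    @classmethod
    def wideband(cls, **kwargs) -> "PreprocConfig":
        """Defaults for the wide-band condition (longer epochs)."""
        kwargs.setdefault("epoch_window", (-0.7, 1.7))
        return cls(**kwargs)


@dataclass(frozen=True)
class RejectionRecord:
    """Why one epoch was rejected: criterion letters and the worst channel."""

    trial: int
    reasons: tuple[str, ...]
    channels: tuple[str, ...]


@dataclass
class EqualizeResult:
    """Outcome of epoch-count equalization.

    ``status`` is ``"ok"`` (200-240 epochs kept unchanged), ``"subsampled"``
    (more than the cap; a seeded random subset of exactly ``cap_epochs`` in
    original order) or ``"excluded"`` (fewer than ``min_epochs``; ``epochs``
    is None and the subject leaves the analysis, which is a flag, not an
    error).
    """

    epochs: Epochs | None
    status: str
    selected: np.ndarray


# ---------------------------------------------------------------------------
# Continuous-data stages


def filter_continuous(data: np.ndarray, sample_rate: float,
                      config: PreprocConfig | None = None) -> np.ndarray:
    """Zero-phase high-pass + notch on continuous data (last axis = time).

    An 8th-order Butterworth high-pass applied forward-backward (so the net
    phase response is zero) followed by a zero-phase IIR notch at the line
    frequency; the mean (DC) is removed first.
    """
    config = config or PreprocConfig()
    nyq = sample_rate / 2.0
    if config.highpass_cutoff >= nyq:
        raise ConfigurationError("high-pass cutoff at or above Nyquist")
    if config.notch_freq >= nyq:
        raise ConfigurationError("notch frequency at or above Nyquist")
    data = np.asarray(data, dtype=float)
    out = data - data.mean(axis=-1, keepdims=True)
    sos = signal.butter(config.highpass_order, config.highpass_cutoff,
                        btype="highpass", fs=sample_rate, output="sos")
    out = signal.sosfiltfilt(sos, out, axis=-1)
    q = config.notch_freq / config.notch_bandwidth
    b, a = signal.iirnotch(config.notch_freq, q, fs=sample_rate)
    out = signal.filtfilt(b, a, out, axis=-1)
    return out


def rereference_average(epochs: Epochs) -> Epochs:
    """Common average reference: subtract the across-channel mean per sample."""
    if epochs.n_channels < 2:
        raise ConfigurationError("average reference needs at least 2 channels")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return replace(epochs, data=data)


def downsample(epochs: Epochs, target_rate: float) -> Epochs:
    """Anti-alias filtered decimation to ``target_rate``.

    The original rate must be an integer multiple of the target and the onset
    sample must sit on the decimated grid, so time zero is preserved exactly.
    """
    ratio = epochs.sample_rate / target_rate
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ConfigurationError(
            f"sample rate {epochs.sample_rate} is not an integer multiple of {target_rate}"
        )
    if q == 1:
        return epochs.copy()
    if epochs.t0_index % q != 0:
        raise ConfigurationError(
            f"t0_index {epochs.t0_index} not divisible by decimation factor {q}"
        )
    data = signal.resample_poly(epochs.data, up=1, down=q, axis=-1)
    return replace(epochs, data=data, sample_rate=target_rate,
                   t0_index=epochs.t0_index // q)


def segment_and_baseline(data: np.ndarray, sample_rate: float,
                         onsets: np.ndarray, config: PreprocConfig,
                         channel_labels: list[str] | None = None,
                         subject_id: str = "") -> Epochs:
    """Cut onset-locked epochs out of continuous data and baseline-correct.

    Onsets too close to a recording edge for the full window are dropped with
    a logged warning.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ConfigurationError("continuous data must be (channels, samples)")
    n_total = data.shape[1]
    n_pre = int(round(-config.epoch_window[0] * sample_rate))
    # length from the full window, so rounding never loses a sample
    n_len = int(round((config.epoch_window[1] - config.epoch_window[0]) * sample_rate))
    n_post = n_len - n_pre
    keep, dropped = [], []
    for on in np.asarray(onsets, dtype=int):
        if on - n_pre < 0 or on + n_post > n_total:
            dropped.append(int(on))
        else:
            keep.append(data[:, on - n_pre:on + n_post])
    if dropped:
        logger.warning("dropped %d onset(s) too close to the recording edge: %s",
                       len(dropped), dropped)
    if not keep:
        raise ConfigurationError("no onset leaves room for a full epoch")
    epochs = Epochs(data=np.stack(keep), sample_rate=sample_rate,
                    t0_index=n_pre, channel_labels=channel_labels or [],
                    subject_id=subject_id)
    return baseline_correct(epochs, config.baseline_window)


def baseline_correct(epochs: Epochs, window: tuple[float, float]) -> Epochs:
    """Subtract the per-epoch, per-channel mean over the baseline window."""
    times = epochs.times
    mask = (times >= window[0]) & (times <= window[1])
    if not np.any(mask):
        raise ConfigurationError("baseline window contains no samples")
    data = epochs.data - epochs.data[:, :, mask].mean(axis=-1, keepdims=True)
    return replace(epochs, data=data)


# ---------------------------------------------------------------------------
# Epoch-level stages


def _sliding_ptp(x: np.ndarray, width: int) -> np.ndarray:
    """Peak-to-peak over every full sliding window of ``width`` samples.

    Output length along the last axis is ``n - width + 1``; ``out[..., j]``
    covers ``x[..., j:j+width]``.  Uses C-fast 1-D rank filters; the default
    (centered) alignment is shifted back to left-aligned by slicing, which
    only touches interior values, so edge padding never leaks in.
    """
    from scipy.ndimage import maximum_filter1d, minimum_filter1d
    n = x.shape[-1]
    if width > n:
        raise ConfigurationError("sliding window longer than the epoch")
    mx = maximum_filter1d(x, size=width, axis=-1, mode="nearest")
    mn = minimum_filter1d(x, size=width, axis=-1, mode="nearest")
    ptp = mx - mn
    lo = width // 2
    return ptp[..., lo:lo + (n - width + 1)]


def reject_artifacts(epochs: Epochs, config: PreprocConfig | None = None
                     ) -> tuple[Epochs, list[RejectionRecord]]:
    """Apply the three rejection rules on the analysis channels.

    An epoch is rejected if **any** analysis channel (a) leaves the
    ``±amp_limit`` range, (b) spans more than ``max_diff`` µV within any
    ``diff_interval`` sliding window, or (c) jumps faster than ``max_step``
    µV/ms between consecutive samples.  Returns the retained epochs and a log
    of per-epoch reasons.
    """
    config = config or PreprocConfig()
    present = [c for c in config.analysis_channels if c in epochs.channel_labels]
    if not present:
        raise ConfigurationError("none of the analysis channels is present")
    idx = [epochs.channel_index(c) for c in present]
    x = epochs.data[:, idx, :]

    hit_a = np.abs(x) > config.amp_limit  # (trials, ch, samples)
    bad_a = hit_a.any(axis=-1)

    width = int(round(config.diff_interval * epochs.sample_rate))
    bad_b = (_sliding_ptp(x, width) > config.max_diff).any(axis=-1)

    dt_ms = 1000.0 / epochs.sample_rate
    bad_c = (np.abs(np.diff(x, axis=-1)) > config.max_step * dt_ms).any(axis=-1)

    log: list[RejectionRecord] = []
    bad_any = (bad_a | bad_b | bad_c).any(axis=1)
    for k in np.flatnonzero(bad_any):
        reasons, chans = [], set()
        for letter, bad in (("a", bad_a), ("b", bad_b), ("c", bad_c)):
            if bad[k].any():
                reasons.append(letter)
                chans.update(np.array(present)[bad[k]])
        log.append(RejectionRecord(trial=int(k), reasons=tuple(reasons),
                                   channels=tuple(sorted(chans))))
    kept = epochs.select_trials(np.flatnonzero(~bad_any))
    return kept, log


def equalize_epochs(epochs: Epochs, config: PreprocConfig | None = None
                    ) -> EqualizeResult:
    """Equalize the epoch count: <min excludes, >cap subsamples to the cap."""
    config = config or PreprocConfig()
    n = epochs.n_trials
    if n < config.min_epochs:
        return EqualizeResult(epochs=None, status="excluded",
                              selected=np.array([], dtype=int))
    if n <= config.cap_epochs:
        return EqualizeResult(epochs=epochs, status="ok",
                              selected=np.arange(n))
    rng = np.random.default_rng(config.seed)
    selected = np.sort(rng.choice(n, size=config.cap_epochs, replace=False))
    return EqualizeResult(epochs=epochs.select_trials(selected),
                          status="subsampled", selected=selected)


def preprocess_epochs(epochs: Epochs, config: PreprocConfig | None = None
                      ) -> tuple[EqualizeResult, list[RejectionRecord]]:
    """Epoched-input pipeline: decimate, baseline, reject, equalize.

    This is the path synthetic (or externally cleaned) epochs take; the
    continuous path adds :func:`filter_continuous`, :func:`rereference_average`
    and :func:`segment_and_baseline` in front.
    """
    config = config or PreprocConfig()
    out = epochs
    if out.sample_rate != config.target_rate:
        out = downsample(out, config.target_rate)
    out = baseline_correct(out, config.baseline_window)
    out, log = reject_artifacts(out, config)
    return equalize_epochs(out, config), log
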