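"""Chirp stimulus synthesis and instantaneous-frequency trajectories.

Two stimulus families are implemented:

* **narrowband** — a 1000 Hz carrier, 100 % amplitude modulated by a linear
  chirp whose modulation frequency falls from 55 to 25 Hz over 500 ms, with
  10 ms linear onset/offset ramps.  The modulation envelope is raised-cosine,
  so full modulation depth keeps the envelope in [0, 1].
* **wideband** — a train of 1 ms white-noise bursts ("clicks") whose rate
  falls logarithmically from 100 to 30 Hz over 1000 ms, one click per
  modulation cycle.

Both laws are analytic and are continued outside the stimulus interval, which
is what lets the envelope-following-response curve be sampled before onset and
after offset.  The instantaneous modulation frequency laws are

    narrowband (linear):      f(t) = f_start + (f_end - f_start) * t / D
    wideband  (logarithmic):  f(t) = f_start * (f_end / f_start)**(t / D)

with D the stimulus duration; the modulation phase in cycles is the running
integral ``phi(t) = int_0^t f(tau) dtau``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np

from .exceptions import AliasingError, ConfigurationError

__all__ = [
    "StimulusSpec",
    "ChirpTrajectory",
    "Waveform",
    "instantaneous_frequency",
    "narrowband_instfreq",
    "wideband_instfreq",
    "modulation_phase",
    "inverse_frequency",
    "synth_narrowband",
    "synth_wideband",
    "wideband_click_times",
    "trajectory",
    "default_span",
    "DEFAULT_FREQ_GRID",
]

#: The time-frequency analysis grid: 2-120 Hz in 2 Hz steps.
DEFAULT_FREQ_GRID = np.arange(2.0, 121.0, 2.0)

#: Curve spans (seconds) over which each trajectory is extrapolated.
_DEFAULT_SPANS = {"narrowband": (-0.400, 0.800), "wideband": (-0.160, 1.190)}


@dataclass(frozen=True)
class StimulusSpec:
    """Definition of a chirp-modulated stimulus.

    ``f_start`` and ``f_end`` are the modulation frequencies at stimulus onset
    and offset; the sweep is downward (``f_start > f_end``).
    """

    kind: Literal["narrowband", "wideband"]
    f_start: float
    f_end: float
    duration: float
    carrier_freq: float | None = None
    ramp: float | None = None
    click_width: float | None = None
    sample_rate: float = 48000.0

    def __post_init__(self) -> None:
        if self.kind not in ("narrowband", "wideband"):
            raise ConfigurationError(f"unknown stimulus kind {self.kind!r}")
        if not (self.f_start > self.f_end > 0):
            raise ConfigurationError("need f_start > f_end > 0 (downward sweep)")
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.kind == "narrowband" and self.carrier_freq is None:
            raise ConfigurationError("narrowband stimulus needs a carrier_freq")
        if self.kind == "wideband" and self.click_width is None:
            raise ConfigurationError("wideband stimulus needs a click_width")

    @classmethod
    def narrowband(cls, f_start: float = 55.0, f_end: float = 25.0,
                   duration: float = 0.5, carrier_freq: float = 1000.0,
                   ramp: float = 0.010, sample_rate: float = 48000.0) -> "StimulusSpec":
        """The amplitude-modulated narrow-band chirp (defaults: 55→25 Hz, 500 ms)."""
        return cls("narrowband", f_start, f_end, duration,
                   carrier_freq=carrier_freq, ramp=ramp, sample_rate=sample_rate)

    @classmethod
    def wideband(cls, f_start: float = 100.0, f_end: float = 30.0,
                 duration: float = 1.0, click_width: float = 0.001,
                 sample_rate: float = 48000.0) -> "StimulusSpec":
        """The click-train wide-band chirp (defaults: 100→30 Hz, 1000 ms)."""
        return cls("wideband", f_start, f_end, duration,
                   click_width=click_width, sample_rate=sample_rate)


@dataclass(frozen=True)
class Waveform:
    """A peak-normalised audio waveform (|samples| <= 1)."""

    samples: np.ndarray
    sample_rate: float

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate


@dataclass(frozen=True)
class ChirpTrajectory:
    """The stimulus's instantaneous-frequency path through the TF plane.

    ``times`` are strictly increasing and ``freqs`` strictly decreasing along
    the path; within [0, duration] the path equals the stimulus's modulation
    frequency and outside it the same analytic law continued.
    """

    times: np.ndarray
    freqs: np.ndarray
    span: tuple[float, float]
    law: Literal["linear", "logarithmic"]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.freqs):
            raise ConfigurationError("times and freqs length mismatch")
        if len(self.times) and (np.any(np.diff(self.times) <= 0)
                                or np.any(np.diff(self.freqs) >= 0)):
            raise ConfigurationError("trajectory must be monotone (t up, f down)")

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(zip(self.times, self.freqs))


# ---------------------------------------------------------------------------
# Frequency laws


def narrowband_instfreq(spec: StimulusSpec, t):
    """Linear law f(t) = f_start + (f_end - f_start) t / D, any t."""
    t = np.asarray(t, dtype=float)
    return spec.f_start + (spec.f_end - spec.f_start) * t / spec.duration


def wideband_instfreq(spec: StimulusSpec, t):
    """Logarithmic law f(t) = f_start (f_end/f_start)**(t/D), any t."""
    t = np.asarray(t, dtype=float)
    return spec.f_start * (spec.f_end / spec.f_start) ** (t / spec.duration)


def instantaneous_frequency(spec: StimulusSpec, t):
    """Instantaneous modulation frequency at time ``t`` (analytic continuation)."""
    if spec.kind == "narrowband":
        return narrowband_instfreq(spec, t)
    return wideband_instfreq(spec, t)


def modulation_phase(spec: StimulusSpec, t):
    """Modulation phase in cycles, ``phi(t) = int_0^t f(tau) d tau``.

    Closed forms: linear law ``f_start t + (f_end-f_start) t^2 / (2D)``;
    logarithmic law ``f_start D (r**(t/D) - 1) / ln r`` with r = f_end/f_start.
    """
    t = np.asarray(t, dtype=float)
    if spec.kind == "narrowband":
        return spec.f_start * t + (spec.f_end - spec.f_start) * t**2 / (2 * spec.duration)
    r = spec.f_end / spec.f_start
    return spec.f_start * spec.duration * (r ** (t / spec.duration) - 1.0) / np.log(r)


def inverse_frequency(spec: StimulusSpec, f):
    """Time at which the (extrapolated) law passes through frequency ``f``."""
    f = np.asarray(f, dtype=float)
    if spec.kind == "narrowband":
        return (f - spec.f_start) * spec.duration / (spec.f_end - spec.f_start)
    return spec.duration * np.log(f / spec.f_start) / np.log(spec.f_end / spec.f_start)


# ---------------------------------------------------------------------------
# Synthesis


def synth_narrowband(spec: StimulusSpec) -> Waveform:
    """Synthesise the amplitude-modulated narrow-band chirp.

    ``samples = ramp(t) * [0.5 - 0.5 cos(2 pi phi(t))] * sin(2 pi f_c t)``:
    a raised-cosine modulator at the chirp's phase (100 % depth, envelope
    touching zero at every modulation trough) on a sine carrier, with linear
    onset/offset ramps.
    """
    if spec.kind != "narrowband":
        raise ConfigurationError("synth_narrowband needs a narrowband spec")
    if spec.sample_rate < 2 * (spec.carrier_freq + spec.f_start):
        raise AliasingError(
            f"sample rate {spec.sample_rate} Hz cannot represent carrier "
            f"{spec.carrier_freq} Hz with {spec.f_start} Hz modulation"
        )
    n = int(round(spec.duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    modulator = 0.5 - 0.5 * np.cos(2 * np.pi * modulation_phase(spec, t))
    carrier = np.sin(2 * np.pi * spec.carrier_freq * t)
    samples = modulator * carrier
    if spec.ramp and spec.ramp > 0:
        n_ramp = int(round(spec.ramp * spec.sample_rate))
        ramp = np.ones(n)
        ramp[:n_ramp] = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
        ramp[n - n_ramp:] = np.linspace(1.0, 0.0, n_ramp)
        samples = samples * ramp
    peak = np.max(np.abs(samples))
    if peak > 0:
        samples = samples / peak
    return Waveform(samples=samples, sample_rate=spec.sample_rate)


def wideband_click_times(spec: StimulusSpec, include_onset_click: bool = True) -> np.ndarray:
    """Click times of the wide-band train: one click per modulation cycle.

    Click ``k`` sits where the modulation phase completes ``k`` cycles,
    ``phi(t_k) = k``; inverting the logarithmic phase gives

        t_k = D * ln(1 + k ln(r) / (f_start D)) / ln(r),   r = f_end/f_start.

    With the 100→30 Hz defaults ``phi(D) ≈ 58.14`` cycles, so k runs 0..58 and
    the train holds 59 clicks.  ``include_onset_click=False`` drops the k = 0
    click at t = 0 (58 clicks).  Inter-click intervals increase monotonically
    as the rate falls.
    """
    if spec.kind != "wideband":
        raise ConfigurationError("wideband_click_times needs a wideband spec")
    total_cycles = float(modulation_phase(spec, spec.duration))
    k0 = 0 if include_onset_click else 1
    k = np.arange(k0, int(np.floor(total_cycles)) + 1, dtype=float)
    r = spec.f_end / spec.f_start
    t_k = spec.duration * np.log1p(k * np.log(r) / (spec.f_start * spec.duration)) / np.log(r)
    return t_k


def synth_wideband(spec: StimulusSpec, seed: int) -> Waveform:
    """Synthesise the wide-band click train: 1 ms seeded white-noise bursts
    at each click time, silence elsewhere, peak-normalised."""
    if spec.kind != "wideband":
        raise ConfigurationError("synth_wideband needs a wideband spec")
    if spec.f_start > 1.0 / spec.click_width:
        raise ConfigurationError(
            "clicks would overlap: f_start exceeds 1/click_width"
        )
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration * spec.sample_rate))
    samples = np.zeros(n)
    width = max(1, int(round(spec.click_width * spec.sample_rate)))
    for t_k in wideband_click_times(spec):
        start = int(round(t_k * spec.sample_rate))
        stop = min(start + width, n)
        if start < n:
            samples[start:stop] = rng.uniform(-1.0, 1.0, stop - start)
    peak = np.max(np.abs(samples))
    if peak > 0:
        samples = samples / peak
    return Waveform(samples=samples, sample_rate=spec.sample_rate)


# ---------------------------------------------------------------------------
# Trajectory


def default_span(spec: StimulusSpec) -> tuple[float, float]:
    """The default extrapolated curve span for this stimulus kind."""
    return _DEFAULT_SPANS[spec.kind]


def trajectory(spec: StimulusSpec, freq_grid=None,
               span: tuple[float, float] | None = None) -> ChirpTrajectory:
    """Map TF-grid frequencies onto trajectory times via the inverse law.

    For every grid frequency reachable within ``span`` under the extrapolated
    law, emit the exact time ``t(f)``; unreachable grid frequencies are
    omitted.  Snapping of these exact times onto the discrete TF time axis is
    the curve extractor's job, not this function's.
    """
    freq_grid = DEFAULT_FREQ_GRID if freq_grid is None else np.asarray(freq_grid, dtype=float)
    if span is None:
        span = default_span(spec)
    t_min, t_max = span
    if t_min >= t_max:
        raise ConfigurationError("span must be an increasing (t_min, t_max) pair")
    f_hi = float(instantaneous_frequency(spec, t_min))  # downward sweep: max at t_min
    f_lo = float(instantaneous_frequency(spec, t_max))
    mask = (freq_grid >= f_lo) & (freq_grid <= f_hi)
    if not np.any(mask):
        raise ConfigurationError(
            f"no grid frequency falls in the law's range [{f_lo:.2f}, {f_hi:.2f}] Hz over the span"
        )
    freqs = freq_grid[mask]
    times = inverse_frequency(spec, freqs)
    order = np.argsort(times)
    law = "linear" if spec.kind == "narrowband" else "logarithmic"
    return ChirpTrajectory(times=times[order], freqs=freqs[order], span=span, law=law)
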