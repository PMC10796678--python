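"""Envelope-following-response curves: the ITPC map sampled along the chirp
trajectory.

For each trajectory point ``(t_f, f)`` the curve value is the mean ITPC over
a temporal window from 50 ms before to 100 ms after the trajectory time,
which absorbs the temporal smoothing of the 500 ms analysis window and the
sensory conduction delay.  The window is anchored at *each point's own*
trajectory time — anchoring it at stimulus onset would make the curve
independent of frequency.  ``t_f`` snaps to the nearest TF time-bin center
and a bin belongs to the window when its center lies in the closed interval
``[t_f - 0.05, t_f + 0.10]``.

Frequencies whose window touches any invalid map cell (or leaves the time
grid) are dropped from the subject's curve and logged — never silently
truncated.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError
from .stimuli import ChirpTrajectory
from .tfr import ITPCMap

__all__ = ["EFRCurve", "extract_efr", "grand_mean_curves", "DEFAULT_WINDOW"]

logger = logging.getLogger(__name__)

#: Sampling window around each trajectory time: (-50 ms, +100 ms).
DEFAULT_WINDOW = (-0.050, 0.100)


@dataclass
class EFRCurve:
    """ITPC along the (extrapolated) chirp trajectory, one value per bin.

    ``freqs`` are strictly increasing; ``times`` carries each frequency's
    trajectory time (after snapping to the TF grid).
    """

    freqs: np.ndarray
    values: np.ndarray
    times: np.ndarray
    condition: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if not (len(self.freqs) == len(self.values) == len(self.times)):
            raise ConfigurationError("freqs/values/times length mismatch")
        if len(self.freqs) > 1 and np.any(np.diff(self.freqs) <= 0):
            raise ConfigurationError("curve frequencies must strictly increase")

    def __len__(self) -> int:
        return len(self.freqs)

    def value_at(self, f: float) -> float:
        i = int(np.argmin(np.abs(self.freqs - f)))
        if abs(self.freqs[i] - f) > 1e-6:
            raise KeyError(f"{f} Hz not on this curve")
        return float(self.values[i])


def extract_efr(itpc_map: ITPCMap, traj: ChirpTrajectory,
                window: tuple[float, float] = DEFAULT_WINDOW,
                condition: str = "", subject_id: str = "") -> EFRCurve:
    """Sample a channel-averaged ITPC map along a chirp trajectory.

    The map must be single-channel (apply :func:`chirpefr.tfr.channel_average`
    first).  Returns a curve over the trajectory's grid frequencies, omitting
    (and logging) frequencies whose window is not fully supported.
    """
    if itpc_map.values.shape[0] != 1:
        raise ConfigurationError("extract_efr expects a single (channel-averaged) map")
    if window[0] >= window[1]:
        raise ConfigurationError("window must be an increasing pair")
    vals = itpc_map.values[0]
    valid = itpc_map.valid[0]
    times = itpc_map.times
    half_bin = 0.5 * float(np.median(np.diff(times)))

    freqs_out, values_out, times_out, dropped = [], [], [], []
    for t_f, f in zip(traj.times, traj.freqs):
        try:
            fi = itpc_map.freq_index(f)
        except ConfigurationError:
            dropped.append((f, "not on frequency grid"))
            continue
        ti = int(np.argmin(np.abs(times - t_f)))
        t_snap = times[ti]
        if abs(t_snap - t_f) > half_bin + 1e-9:
            dropped.append((f, "trajectory time outside the time grid"))
            continue
        in_win = (times >= t_snap + window[0] - 1e-12) & (times <= t_snap + window[1] + 1e-12)
        # the window must not extend beyond the grid edges
        if t_snap + window[0] < times[0] - half_bin or t_snap + window[1] > times[-1] + half_bin:
            dropped.append((f, "window leaves the time grid"))
            continue
        if not np.all(valid[fi, in_win]):
            dropped.append((f, "window touches invalid cells"))
            continue
        freqs_out.append(f)
        values_out.append(float(vals[fi, in_win].mean()))
        times_out.append(float(t_snap))
    if dropped:
        logger.info("extract_efr dropped %d frequencies: %s", len(dropped), dropped)
    order = np.argsort(freqs_out)
    return EFRCurve(freqs=np.asarray(freqs_out)[order],
                    values=np.asarray(values_out)[order],
                    times=np.asarray(times_out)[order],
                    condition=condition, subject_id=subject_id)


def grand_mean_curves(curves: list[EFRCurve]) -> tuple[EFRCurve, np.ndarray]:
    """Pointwise mean curve and per-frequency SEM (sd/sqrt(N), ddof=1).

    All curves must share the same frequency grid.
    """
    if not curves:
        raise ConfigurationError("no curves to average")
    ref = curves[0].freqs
    for c in curves[1:]:
        if len(c.freqs) != len(ref) or np.any(np.abs(c.freqs - ref) > 1e-9):
            raise ConfigurationError("curves do not share a frequency grid")
    stack = np.vstack([c.values for c in curves])
    mean = stack.mean(axis=0)
    if len(curves) > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(len(curves))
    else:
        sem = np.zeros_like(mean)
    mean_curve = EFRCurve(freqs=ref.copy(), values=mean,
                          times=curves[0].times.copy(),
                          condition=curves[0].condition, subject_id="grand_mean")
    return mean_curve, sem
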