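"""Synthetic epoched EEG with a ground-truth envelope-following response.

The generator emulates the statistical structure of frontocentral EEG under
chirp stimulation: per-channel 1/f background noise (optionally plus 50 Hz
line interference), and on the seven analysis channels a response that tracks
the stimulus's modulation envelope with trial-to-trial phase jitter.

Phase jitter is implemented as a trial-wise *time* shift

    delta_k = theta_k / (2 pi f_ref),   theta_k ~ vonMises(0, kappa),

with the reference frequency f_ref = 40 Hz.  At 40 Hz along the trajectory
the spectral phase of the response is therefore exactly von Mises distributed
and the population ITPC equals the mean resultant length I1(kappa)/I0(kappa);
at another trajectory frequency f the phase jitter scales by f/40, so the
effective concentration differs (documented, which is why recovery tests
reference 40 Hz).  kappa = 0 gives uniform phases (no envelope following
beyond the chance floor ~ sqrt(pi)/2 / sqrt(n)); kappa -> inf gives perfectly
repeated trials.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import special

from .epochs import Epochs
from .exceptions import ConfigurationError
from .stimuli import StimulusSpec, modulation_phase, wideband_click_times

__all__ = [
    "ANALYSIS_CHANNELS",
    "DEFAULT_CHANNELS",
    "SimParams",
    "GroundTruth",
    "CohortGroup",
    "CohortSubject",
    "expected_itpc",
    "modulation_response",
    "one_over_f_noise",
    "resonance_gain",
    "simulate_trials",
    "simulate_cohort",
    "contrast_design",
]

#: The seven frontocentral channels entering the analysis.
ANALYSIS_CHANNELS = ("FC1", "FC2", "C1", "C2", "Fz", "FCz", "Cz")

#: Default simulated montage: the analysis channels plus three unused ones,
#: so channel selection is actually exercised.
DEFAULT_CHANNELS = ANALYSIS_CHANNELS + ("Pz", "Oz", "T7")

#: Reference frequency (Hz) at which the von Mises phase jitter is exact.
F_REF = 40.0


def expected_itpc(kappa: float) -> float:
    """Population ITPC of a von Mises phase sample: I1(kappa)/I0(kappa).

    Uses exponentially scaled Bessel functions so arbitrarily large kappa is
    safe; kappa = 0 gives 0.
    """
    if kappa < 0:
        raise ConfigurationError("kappa must be >= 0")
    return float(special.i1e(kappa) / special.i0e(kappa))


@dataclass(frozen=True)
class SimParams:
    """Parameters of a single simulated subject/recording.

    Amplitudes are in µV.  ``noise_amplitude`` is the per-channel RMS of the
    1/f background; ``response_amplitude`` is the peak of the envelope-locked
    response added on ``response_channels``.  ``latency`` models the sensory
    conduction delay.  ``t0_align`` keeps the onset sample on-grid under 2:1
    decimation.
    """

    n_trials: int = 200
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    sample_rate: float = 1024.0
    epoch_window: tuple[float, float] = (-0.7, 1.2)
    response_channels: tuple[str, ...] = ANALYSIS_CHANNELS
    response_amplitude: float = 1.0
    kappa: float = 1.0
    latency: float = 0.050
    noise_exponent: float = 1.0
    noise_amplitude: float = 10.0
    line_noise_amplitude: float = 0.0
    resonance_center: float = 40.0
    resonance_sigma: float = 0.30
    resonance_floor: float = 0.2
    seed: int = 0
    t0_align: int = 2

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if self.kappa < 0:
            raise ConfigurationError("kappa must be >= 0")
        if self.epoch_window[0] >= self.epoch_window[1]:
            raise ConfigurationError("epoch_window must increase")
        missing = set(self.response_channels) - set(self.channels)
        if missing:
            raise ConfigurationError(f"response channels {missing} not in montage")


@dataclass(frozen=True)
class GroundTruth:
    """What the simulator actually injected, for parameter-recovery tests."""

    kappa: float
    expected_itpc: float
    jitters: np.ndarray  # per-trial time shifts, seconds


def modulation_response(stim: StimulusSpec, t: np.ndarray) -> np.ndarray:
    """Zero-mean envelope-following waveform evaluated at times ``t`` (s).

    Narrowband: the zero-mean part of the raised-cosine modulator,
    ``-0.5 cos(2 pi phi(t))`` inside [0, D], zero outside; peak-normalised.
    Wideband: the click train convolved with a 10 ms exponentially decaying
    kernel (a transient response much shorter than one modulation period),
    demeaned over the stimulation interval and peak-normalised.
    """
    t = np.asarray(t, dtype=float)
    if stim.kind == "narrowband":
        inside = (t >= 0) & (t <= stim.duration)
        out = np.where(inside, -0.5 * np.cos(2 * np.pi * modulation_phase(stim, t)), 0.0)
        return out / 0.5
    tau = 0.010  # kernel time constant, s
    support = 5 * tau
    out = np.zeros_like(t)
    for t_k in wideband_click_times(stim):
        dt = t - t_k
        m = (dt >= 0) & (dt < support)
        out[m] += np.exp(-dt[m] / tau)
    inside = (t >= 0) & (t <= stim.duration + support)
    if np.any(inside):
        out[inside] -= out[inside].mean()
    peak = np.max(np.abs(out)) if out.size else 0.0
    return out / peak if peak > 0 else out


def resonance_gain(f, center: float = 40.0, sigma: float = 0.30,
                   floor: float = 0.2) -> np.ndarray:
    """Low-gamma resonance profile of the evoked response.

    Steady-state auditory responses are strongest near 40 Hz (the classic
    ASSR resonance, usually attributed to superposition of middle-latency
    components); the gain is a log-Gaussian bump of width ``sigma`` (natural
    log units) over a ``floor`` baseline, normalised to 1 at the center.
    ``sigma = inf`` or ``floor = 1`` recovers a frequency-flat response.
    """
    f = np.asarray(f, dtype=float)
    with np.errstate(divide="ignore"):
        z = np.where(f > 0, np.log(np.maximum(f, 1e-12) / center) / sigma, np.inf)
    return floor + (1.0 - floor) * np.exp(-0.5 * z * z)


def one_over_f_noise(rng: np.random.Generator, shape: tuple[int, ...],
                     sample_rate: float, exponent: float = 1.0,
                     rms: float = 1.0) -> np.ndarray:
    """Gaussian noise with power spectral density ~ 1/f**exponent.

    Synthesised in the frequency domain (complex Gaussian coefficients scaled
    by f**(-exponent/2), zero DC) and normalised to the requested RMS per
    trace along the last axis.
    """
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    spec_shape = shape[:-1] + (len(freqs),)
    coeffs = (rng.standard_normal(spec_shape) + 1j * rng.standard_normal(spec_shape)) * scale
    x = np.fft.irfft(coeffs, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * rms


def _epoch_geometry(params: SimParams) -> tuple[int, int]:
    """(n_samples, t0_index) for the configured epoch window, onset aligned."""
    sr = params.sample_rate
    a = max(1, int(params.t0_align))
    n_pre = int(round(-params.epoch_window[0] * sr / a)) * a
    n_post = int(round(params.epoch_window[1] * sr))
    if n_pre < 0:
        raise ConfigurationError("epoch must start before stimulus onset")
    return n_pre + n_post, n_pre


def simulate_trials(stim: StimulusSpec, params: SimParams,
                    subject_id: str = "sim") -> tuple[Epochs, GroundTruth]:
    """Simulate one subject's epoched recording.

    Each trial is ``background + response``: seeded 1/f noise on every
    channel (plus optional 50 Hz line interference with a random phase per
    trial), and on the response channels
    ``response_amplitude * m(t - latency - delta_k)`` with ``m`` the zero-mean
    modulation waveform and ``delta_k`` the von Mises time jitter.
    """
    if params.epoch_window[1] < params.latency + stim.duration:
        raise ConfigurationError(
            "epoch_window too short to contain the delayed response"
        )
    rng = np.random.default_rng(params.seed)
    n_samples, t0_index = _epoch_geometry(params)
    times = (np.arange(n_samples) - t0_index) / params.sample_rate

    kappa = params.kappa
    if kappa == 0:
        theta = rng.uniform(-np.pi, np.pi, params.n_trials)
    else:
        theta = rng.vonmises(0.0, kappa, params.n_trials)
    jitters = theta / (2 * np.pi * F_REF)

    n_ch = len(params.channels)
    data = np.zeros((params.n_trials, n_ch, n_samples))
    if params.noise_amplitude > 0:
        data += one_over_f_noise(rng, (params.n_trials, n_ch, n_samples),
                                 params.sample_rate, params.noise_exponent,
                                 params.noise_amplitude)
    if params.line_noise_amplitude > 0:
        phases = rng.uniform(0, 2 * np.pi, params.n_trials)
        line = params.line_noise_amplitude * np.sin(
            2 * np.pi * 50.0 * times[None, :] + phases[:, None])
        data += line[:, None, :]

    if params.response_amplitude != 0 and params.response_channels:
        resp_idx = [params.channels.index(c) for c in params.response_channels]
        from .stimuli import instantaneous_frequency
        for k in range(params.n_trials):
            t_shift = times - params.latency - jitters[k]
            gain = resonance_gain(instantaneous_frequency(stim, t_shift),
                                  params.resonance_center,
                                  params.resonance_sigma,
                                  params.resonance_floor)
            wave = params.response_amplitude * gain * modulation_response(stim, t_shift)
            data[k, resp_idx, :] += wave[None, :]

    epochs = Epochs(data=data, sample_rate=params.sample_rate,
                    t0_index=t0_index, channel_labels=list(params.channels),
                    subject_id=subject_id)
    truth = GroundTruth(kappa=kappa, expected_itpc=expected_itpc(kappa),
                        jitters=jitters)
    return epochs, truth


def simulate_itpc_curves(n_subjects: int, n_bins: int, n_trials: int = 200,
                         kappa: float = 0.0, seed: int = 0) -> np.ndarray:
    """Curve-level cohort generator for statistical calibration.

    Skips the waveform level entirely: per subject and frequency bin it draws
    ``n_trials`` spectral phases (von Mises with the given concentration,
    uniform when kappa = 0, independent across bins) and runs them through the
    package's own ITPC estimator.  Returns an (n_subjects, n_bins) matrix of
    ITPC values — the exact sampling distribution the EEG-level pipeline
    produces in the noiseless limit, at a tiny fraction of the cost, which is
    what makes e.g. 200-replicate type-I calibrations of the cluster test
    affordable.
    """
    from .tfr import SpectralEstimates, itpc as _itpc
    rng = np.random.default_rng(seed)
    out = np.empty((n_subjects, n_bins))
    freqs = np.arange(n_bins, dtype=float)
    times = np.zeros(1)
    valid = np.ones(1, dtype=bool)
    for s in range(n_subjects):
        if kappa == 0:
            theta = rng.uniform(-np.pi, np.pi, (n_trials, 1, n_bins, 1))
        else:
            theta = rng.vonmises(0.0, kappa, (n_trials, 1, n_bins, 1))
        est = SpectralEstimates(values=np.exp(1j * theta), freqs=freqs,
                                times=times, valid=valid, window_length=0.5,
                                channel_labels=["avg"])
        out[s] = _itpc(est).values[0, :, 0]
    return out


# ---------------------------------------------------------------------------
# Cohorts

_GROUP_DIAGNOSES = {"UWS": "UWS", "MCS-": "MCS-", "MCS+": "MCS+", "EMCS": "EMCS", "HC": "HC"}
_DIAG_ORDER = ("UWS", "MCS-", "MCS+", "EMCS")


@dataclass(frozen=True)
class CohortGroup:
    """One simulated diagnostic group.

    ``kappa_between_sd`` is the SD of a lognormal multiplier applied to the
    group kappa per subject (between-subject heterogeneity);
    ``diagnosis_disagreement`` is the probability that any single behavioural
    assessment slips to an adjacent diagnosis.
    """

    label: str
    n_subjects: int
    params: SimParams
    kappa_between_sd: float = 0.25
    diagnosis_disagreement: float = 0.0
    abris_refer_rate: float = 0.0
    etiologies: tuple[str, ...] = ("other",)

    def __post_init__(self) -> None:
        if self.label not in _GROUP_DIAGNOSES:
            raise ConfigurationError(f"unknown group label {self.label!r}")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")


@dataclass
class CohortSubject:
    """One simulated subject: metadata, its epochs, and the injected truth."""

    subject_id: str
    group_label: str
    diagnoses: tuple[str, ...]
    abris: str
    etiology: str
    epochs: Epochs
    truth: GroundTruth


def contrast_design(n_uws: int = 27, n_mcse: int = 27,
                    kappa_uws: float = 0.2, kappa_mcse: float = 1.5,
                    n_trials: int = 200,
                    params: SimParams | None = None) -> list[CohortGroup]:
    """The benchmark two-group design: a UWS-like cohort with weak phase
    locking versus an aware-like (MCS-) cohort with strong locking, otherwise
    default recording conditions."""
    base = params or SimParams(n_trials=n_trials)
    return [
        CohortGroup("UWS", n_uws, replace(base, kappa=kappa_uws)),
        CohortGroup("MCS-", n_mcse, replace(base, kappa=kappa_mcse)),
    ]


def _jitter_diagnosis(base: str, rng: np.random.Generator, p: float) -> str:
    if base == "HC" or p <= 0 or rng.uniform() >= p:
        return base
    i = _DIAG_ORDER.index(base)
    step = -1 if (i == len(_DIAG_ORDER) - 1 or (i > 0 and rng.uniform() < 0.5)) else 1
    return _DIAG_ORDER[i + step]


def simulate_cohort(design: Sequence[CohortGroup], stim: StimulusSpec,
                    seed: int = 0, n_assessments: int = 5) -> list[CohortSubject]:
    """Simulate a whole cohort, one epoched recording per subject.

    Subject-level kappa is drawn around the group kappa; each subject gets
    ``n_assessments`` behavioural diagnoses (identical by default).  Fully
    deterministic for a given seed.
    """
    if not design:
        raise ConfigurationError("empty cohort design")
    master = np.random.SeedSequence(seed)
    subjects: list[CohortSubject] = []
    for group, group_seed in zip(design, master.spawn(len(design))):
        rng = np.random.default_rng(group_seed)
        child_seeds = group_seed.spawn(group.n_subjects)
        for i in range(group.n_subjects):
            mult = float(np.exp(rng.normal(0.0, group.kappa_between_sd))) \
                if group.kappa_between_sd > 0 else 1.0
            kappa_i = group.params.kappa * mult
            subj_seed = int(child_seeds[i].generate_state(1, dtype=np.uint32)[0] % (2**31))
            params_i = replace(group.params, kappa=kappa_i, seed=subj_seed)
            sid = f"{group.label}-{i:02d}"
            epochs, truth = simulate_trials(stim, params_i, subject_id=sid)
            base = _GROUP_DIAGNOSES[group.label]
            diags = tuple(_jitter_diagnosis(base, rng, group.diagnosis_disagreement)
                          for _ in range(n_assessments))
            abris = "refer" if rng.uniform() < group.abris_refer_rate else "pass"
            etiology = group.etiologies[int(rng.integers(len(group.etiologies)))]
            subjects.append(CohortSubject(subject_id=sid, group_label=group.label,
                                          diagnoses=diags, abris=abris,
                                          etiology=etiology, epochs=epochs,
                                          truth=truth))
    return subjects
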