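# Methods

`chirpefr` analyses EEG responses to chirp-modulated auditory stimulation.
This note describes the models and procedures the package implements, the
choices made where several reasonable options existed, and what the synthetic
data generator does and does not emulate.

## Stimuli and trajectories

Two stimulus families are synthesised:

* **Narrow-band chirp (NBC)** — a 1000 Hz carrier, 100 % amplitude-modulated
  by a linear downward chirp, 55 → 25 Hz over 500 ms, with 10 ms linear
  onset/offset ramps. The modulator is raised-cosine,
  `0.5 − 0.5 cos(2π Φ(t))`, with `Φ(t) = ∫₀ᵗ f(τ) dτ` the modulation phase in
  cycles; full depth then keeps the envelope in [0, 1] and it touches zero at
  every trough. The linear law integrates to
  `Φ(D) = D · (f_start + f_end)/2 = 20` cycles.
* **Wide-band chirp (WBC)** — a train of 1 ms white-noise bursts whose rate
  falls logarithmically, 100 → 30 Hz over 1000 ms. One click is placed per
  modulation cycle, at each time where `Φ(t)` crosses an integer (a sinusoidal
  cycle has two zero crossings; the one-click-per-cycle convention is the one
  that makes the train's instantaneous rate equal `f(t)`). The logarithmic
  law gives `Φ(1 s) = (f_start − f_end)/ln(f_start/f_end) ≈ 58.14` cycles, so
  the default train has 59 clicks including the one at `t = 0`; whether the
  onset click is counted is configurable.

The **chirp trajectory** maps analysis frequencies to the time at which the
(extrapolated) frequency law passes through them; it is computed by the exact
inverse of the analytic law and only snapped to the discrete time–frequency
grid at curve-extraction time. Extrapolation simply continues the same law
outside `[0, D]`. Default spans are (−0.4, 0.8) s for NBC — covering 7–79 Hz,
hence grid bins 8–78 Hz — and (−0.16, 1.19) s for WBC (grid bins 24–120 Hz;
the span's early edge reaches ≈121 Hz, just above the grid top).

## Synthetic EEG

`simulate_trials` produces epoched multi-channel data (default 1024 Hz,
epochs −0.699…1.2 s around onset, the onset sample aligned so 2:1 decimation
keeps it on-grid) as `background + response`:

* **Background**: per-channel Gaussian noise with a `1/f^α` power spectrum
  (default α = 1, RMS 10 µV — ordinary resting EEG scale), synthesised in the
  frequency domain; optionally a 50 Hz line component with a random phase per
  trial. Channels are independent by default; the analysis averages ITPC,
  not voltage, across channels, so spatial correlation of the noise is not
  load-bearing.
* **Response**: on the seven frontocentral analysis channels only,
  `A · G(f(t′)) · m(t′)` with `t′ = t − latency − δ_k`, where `m` is the
  zero-mean modulation waveform of the stimulus (NBC: the demeaned
  raised-cosine modulator; WBC: the click train convolved with a 10 ms
  exponentially decaying kernel — any transient much shorter than one
  modulation period preserves envelope following), `A` the response amplitude
  (default 1 µV, a typical steady-state response magnitude), and `latency`
  50 ms of sensory conduction delay.

Trial-to-trial **phase jitter** is a time shift `δ_k = θ_k / (2π·40 Hz)` with
`θ_k ~ vonMises(0, κ)`. At 40 Hz on the trajectory the spectral phases are
then exactly von Mises and the population ITPC equals the mean resultant
length `I₁(κ)/I₀(κ)`; at other frequencies the phase jitter scales by `f/40`,
so parameter-recovery statements are made at 40 Hz. `κ = 0` yields uniform
phases and only the Rayleigh chance floor `≈ √π/2·n^(−1/2)` survives.

`G(f)` is a **low-gamma resonance gain**: a log-Gaussian bump centred at
40 Hz (σ = 0.30 log-units) over a 0.2 floor. Auditory steady-state responses
are well known to be strongest near 40 Hz, and the patient and control data
this generator emulates peak at 40–50 Hz; without the resonance the emergent
curve peak sits near 32 Hz (the product of jitter scaling and 1/f noise),
which is not what chirp EFR recordings look like. The profile was fixed once
so the strong-locking grand curve peaks in the observed 40–50 Hz region;
`floor = 1` recovers a frequency-flat response.

Cohorts draw subject-level κ from a lognormal jitter around the group κ
(default SD 0.25 log-units), give each subject five behavioural diagnoses
(identical by default, with a configurable disagreement rate that slips
single assessments to adjacent categories), and a pass/refer brainstem
screening label.

What the generator does **not** emulate: real artifact morphology (blinks,
EMG) beyond what the rejection rules need, volume conduction and channel
covariance, between-channel response latency differences, and any dependence
of response amplitude on etiology. Passing tests therefore demonstrate the
correctness and calibration of the *analysis*, not clinical performance on
real recordings.

### Curve-level null generator

For statistical calibration that needs hundreds of replicate cohorts,
`simulate_itpc_curves` skips the waveform level: it draws the trial spectral
phases per frequency bin directly (von Mises, uniform at κ = 0) and runs them
through the same ITPC estimator. In the noiseless limit this is exactly the
sampling distribution the EEG-level pipeline produces, at a tiny fraction of
the cost; it is used for the type-I-error calibration of the cluster test.

## Preprocessing

Deterministic chain, epoched path: decimate to 512 Hz (polyphase FIR,
onset-preserving), baseline-correct over (−0.699, −0.200) s, reject, equalize.
The continuous path adds, in front: DC removal, zero-phase 8th-order
Butterworth high-pass (default cutoff 0.5 Hz — the filter's cutoff is not
dictated by the acquisition convention; 0.5 Hz is standard evoked-response
practice and leaves the lowest 2 Hz analysis bin untouched), a zero-phase
50 Hz IIR notch (2 Hz bandwidth), common average reference, and onset-locked
segmentation (NBC −0.7…1.2 s, WBC −0.7…1.7 s).

An epoch is rejected when **any** analysis channel (FC1, FC2, C1, C2, Fz,
FCz, Cz) (a) leaves ±200 µV, (b) spans more than 200 µV peak-to-peak within
any 200 ms window sliding one sample at a time (the maximally strict
convention), or (c) steps faster than 150 µV/ms between consecutive samples.
Epoch counts are then equalized: fewer than 200 clean epochs excludes the
subject (a flag, not an error); more than 240 are reduced to exactly 240 by a
seeded uniform draw without replacement, original order preserved.

Interactive steps — ocular ICA and bad-channel interpolation — are
deliberately not implemented; the pipeline expects cleaned (or synthetic)
input.

## Time–frequency decomposition and ITPC

A single Hanning taper slides over each epoch:
`F_k(f,t) = Σ_s x_k(s) h(s) e^(−i2πf(s−center)/rate)` over a 500 ms window
*centred* at the output time `t` (the convention of the common EEG toolboxes;
valid output times therefore end 250 ms short of each epoch edge, which is
exactly compatible with the default epoch and curve spans). The output grid
steps 9.765625 ms (5 samples at 512 Hz) and is anchored so `t = 0` is always
a bin centre; frequencies run 2–120 Hz in 2 Hz steps, which a 256-sample
window resolves natively without zero padding. When the requested
frequencies sit exactly on the window's DFT bins the transform runs as one
FFT per window with a phase rotation for the centred convention (bit-equal to
the direct form, which remains as the general path). Coefficients are kept
in single precision — only their phases matter downstream — and the
across-trial average is accumulated in double precision.

The intertrial phase clustering coefficient is
`ITPC(f,t) = |1/n Σ_k F_k(f,t)/|F_k(f,t)||`, per channel; cells where any
trial has a zero coefficient are undefined and tracked with an explicit
validity mask (no sentinel values, no NaN contagion). ITPC is invariant to
per-trial amplitude scaling and bounded in [0, 1]. Channel averaging takes
the arithmetic mean of per-channel ITPC over the seven analysis channels —
ITPC first, averaging second.

## The EFR curve

For each trajectory point `(t_f, f)` the curve value is the mean ITPC over
the window `[t_f − 50 ms, t_f + 100 ms]`, which absorbs the temporal
smoothing of the 500 ms analysis window and the conduction delay. The window
is anchored at each point's own trajectory time; anchored at stimulus onset
it would make the curve independent of frequency, which contradicts the
curves this analysis is meant to produce. `t_f` snaps to the nearest time-bin
centre and bin membership is by centre in the closed interval (16 bins at the
default resolution). Frequencies whose window touches any invalid cell are
dropped from that subject's curve and logged; group statistics then handle
them complete-case per bin.

## Group comparison

Five behavioural assessments collapse to the modal diagnosis; ties break
toward the *less* favourable category on UWS < MCS− < MCS+ < EMCS (a tie
never upgrades the patient — the conservative choice, since repeated
assessment exists to avoid amplifying single diagnostic errors). UWS stays
one group; MCS−, MCS+ and EMCS pool into "MCSe".

Subjects whose whole-curve mean ITPC exceeds `Q3 + 1.5·IQR` of the pooled
cohort (linearly interpolated quartiles; controls included in the pool when
present) are removed before testing. Only high outliers are removable by
default: an excessively strong response is the artifactual kind, while a
floor-level response is a finding.

The two groups are compared with a one-sided cluster-based permutation test
(alternative: MCSe > UWS). Per bin, a pooled-variance two-sample t (Welch
optional); bins with one-sided uncorrected p < 0.005 form clusters by
adjacency along the curve (after extraction each bin maps to one trajectory
time, so curve adjacency is simultaneous frequency and time adjacency);
clusters score by summed t; the max cluster score per relabelling builds the
null (30,000 seeded Monte-Carlo shuffles with fixed group sizes, or exact
enumeration whenever `C(n, n_A) ≤ 10⁵`, which also sets the attainable
p floor). Monte-Carlo p-values use `(1 + exceedances)/(1 + n_perm)`, never
zero; exact p-values are exceedance fractions over all assignments. A
cluster is significant at p < 0.001 (0.005 as a relaxed reporting level).
Bins with zero pooled variance are excluded from cluster forming and logged.
Missing bins are handled complete-case per bin: the permutation statistics
carry per-bin group counts, so a subject missing one frequency still
contributes everywhere else.

Degenerate and edge cases: groups smaller than 2 are refused; identical
groups yield no suprathreshold cluster; fixed seeds make every result —
including the full study report — bit-identical across runs.

The factorial screening-by-diagnosis question (pass/refer × UWS/MCSe over
cluster-mean ITPC) is out of scope as a test; the study report emits the 2×2
cell counts and means so any external ANOVA tool can consume them.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run: the ITPC floor at n = 100
phases × 1000 replicates; noiseless recovery at 240 trials (20 replicates per
κ in the suite, 5 in the script); permutation validity with exact
enumeration at 4+4 and 200 curve-level null cohorts of 10+10 at 1000
permutations; and the benchmark cohort of 27 + 27 subjects × 200 trials with
30,000 permutations. These sizes make the full pipeline demonstrably correct
while keeping a complete run in the minutes range on one core.

## Known limitations

* The phase-jitter model ties concentration to 40 Hz; recovery statements at
  other frequencies need the `f/40` scaling applied.
* EDF/BDF input is a thin optional path (via `mne`) without a bundled
  round-trip test, since no writer for those formats ships with the package's
  dependencies; the HDF5 fixture is the canonical container.
* The IQR outlier screen uses the whole-curve mean; a subject inflated in a
  narrow band only may escape it, as it would in the original procedure.
* Welch permutation thresholds vary per relabelling with missing data; the
  pooled statistic (the default, and the convention of the field's toolboxes)
  has a fixed per-bin df under relabelling and is the tested path.
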