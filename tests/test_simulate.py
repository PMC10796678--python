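"""Synthetic EEG generator: ground truth, noise statistics, cohorts, fixtures."""
import dataclasses

import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats as sstats

from chirpefr import (ANALYSIS_CHANNELS, CohortGroup, ConfigurationError,
                      FixtureFormatError, SimParams, channel_average,
                      expected_itpc, extract_efr, itpc, one_over_f_noise,
                      read_fixture, simulate_cohort, simulate_itpc_curves,
                      simulate_trials, stft, trajectory, write_fixture)


def on_trajectory_itpc(stim, params, freq=40.0):
    """Pipeline shortcut: ITPC at one trajectory frequency (512 Hz path)."""
    from chirpefr.preprocess import PreprocConfig, preprocess_epochs
    epochs, truth = simulate_trials(stim, params)
    eq, _ = preprocess_epochs(epochs, PreprocConfig(min_epochs=2))
    sel = eq.epochs.pick_channels(list(ANALYSIS_CHANNELS))
    est = stft(sel)
    avg = channel_average(itpc(est), sel.channel_labels)
    curve = extract_efr(avg, trajectory(stim, freq_grid=est.freqs))
    return curve.value_at(freq), truth


class TestExpectedITPC:
    def test_bessel_ratio_reference_values(self):
        assert expected_itpc(0.0) == 0.0
        assert expected_itpc(2.0) == pytest.approx(0.6978, abs=1e-4)
        assert expected_itpc(1e6) == pytest.approx(1.0, abs=1e-5)
        with pytest.raises(ConfigurationError):
            expected_itpc(-1.0)


class TestSimulateTrials:
    def test_perfect_locking_gives_unit_itpc(self, narrowband):
        params = SimParams(n_trials=20, kappa=1e6, noise_amplitude=0.0, seed=0)
        value, _ = on_trajectory_itpc(narrowband, params)
        assert value == pytest.approx(1.0, abs=1e-3)

    def test_kappa2_recovery_at_reference_frequency(self, narrowband):
        params = SimParams(n_trials=240, kappa=2.0, noise_amplitude=0.0, seed=3)
        value, truth = on_trajectory_itpc(narrowband, params)
        assert value == pytest.approx(truth.expected_itpc, abs=0.05)

    def test_noise_only_sits_at_rayleigh_floor(self, narrowband):
        # uniform-phase floor E[ITPC] = sqrt(pi)/2/sqrt(n); with n = 200 that
        # is 0.0627.  Averaging the whole off-response map beats the
        # single-cell Monte-Carlo error.
        params = SimParams(n_trials=200, kappa=0.0, response_amplitude=0.0,
                           seed=4)
        epochs, _ = simulate_trials(narrowband, params)
        from chirpefr.preprocess import PreprocConfig, preprocess_epochs
        eq, _ = preprocess_epochs(epochs, PreprocConfig(min_epochs=2))
        est = stft(eq.epochs.pick_channels(list(ANALYSIS_CHANNELS)))
        m = itpc(est)
        floor = np.sqrt(np.pi) / 2 / np.sqrt(200)
        assert m.values[m.valid].mean() == pytest.approx(floor, rel=0.05)

    def test_itpc_monotone_in_kappa(self, narrowband):
        values = []
        for kappa in (0.0, 0.5, 1.0, 2.0, 5.0):
            params = SimParams(n_trials=200, kappa=kappa, noise_amplitude=0.0,
                               seed=8)
            v, _ = on_trajectory_itpc(narrowband, params)
            values.append(v)
        assert all(b > a - 0.02 for a, b in zip(values, values[1:]))
        assert values[-1] > values[0] + 0.5

    def test_response_confined_to_response_channels(self, narrowband):
        params = SimParams(n_trials=30, kappa=5.0, noise_amplitude=0.0, seed=5)
        epochs, _ = simulate_trials(narrowband, params)
        silent = epochs.pick_channels(["Pz", "Oz", "T7"])
        assert np.all(silent.data == 0.0)
        driven = epochs.pick_channels(["FCz"])
        assert np.max(np.abs(driven.data)) > 0.5

    def test_wideband_response_follows_click_rate(self, wideband):
        params = SimParams(n_trials=2, kappa=1e6, noise_amplitude=0.0,
                           epoch_window=(-0.7, 1.7), seed=6)
        epochs, _ = simulate_trials(wideband, params)
        x = epochs.data[0, epochs.channel_index("FCz")]
        # transient energy present (attenuated by the resonance gain away
        # from 40 Hz), nothing before the delayed train starts
        assert 0.2 < np.max(np.abs(x)) <= 1.0
        times = epochs.times
        assert np.all(x[times < params.latency - 0.01] == 0)
        # strongest response where the click rate crosses the 40 Hz resonance
        t40 = float(np.log(40.0 / 100.0) / np.log(30.0 / 100.0))  # inverse law
        near = (times > t40 - 0.1) & (times < t40 + 0.1)
        far = (times > 0.0) & (times < 0.15)
        assert np.max(np.abs(x[near])) > np.max(np.abs(x[far]))

    def test_deterministic_given_seed(self, narrowband):
        params = SimParams(n_trials=5, seed=42)
        a, _ = simulate_trials(narrowband, params)
        b, _ = simulate_trials(narrowband, params)
        assert np.array_equal(a.data, b.data)

    def test_epoch_too_short_rejected(self, narrowband):
        with pytest.raises(ConfigurationError):
            simulate_trials(narrowband, SimParams(epoch_window=(-0.2, 0.4)))


class TestNoiseSpectrum:
    @pytest.mark.parametrize("exponent", [0.5, 1.0, 1.5])
    def test_slope_recovered_by_periodogram_regression(self, rng, exponent):
        x = one_over_f_noise(rng, (8, 16384), 512.0, exponent=exponent, rms=10.0)
        f, pxx = sps.welch(x, fs=512.0, nperseg=2048, axis=-1)
        band = (f >= 2.0) & (f <= 100.0)
        slope = np.polyfit(np.log(f[band]), np.log(pxx[:, band].mean(axis=0)), 1)[0]
        assert -slope == pytest.approx(exponent, abs=0.2)

    def test_rms_normalisation(self, rng):
        x = one_over_f_noise(rng, (4, 3, 4096), 1024.0, rms=10.0)
        assert np.allclose(x.std(axis=-1), 10.0, rtol=1e-9)


class TestOffResponseFloor:
    def test_off_channel_itpc_indistinguishable_from_null(self, narrowband):
        # ITPC on a non-response channel (noise only) should match the
        # kappa = 0 sampling distribution: KS test at alpha = 0.01 against
        # replicates drawn from the uniform-phase null.  Overlapping STFT
        # windows correlate neighbouring time bins, so the comparison uses
        # cells spaced a full window apart (and well-separated frequencies).
        params = SimParams(n_trials=60, kappa=3.0, seed=13)
        epochs, _ = simulate_trials(narrowband, params)
        from chirpefr.preprocess import PreprocConfig, preprocess_epochs
        eq, _ = preprocess_epochs(epochs, PreprocConfig(min_epochs=2))
        est = stft(eq.epochs.pick_channels(["Pz"]),
                   freqs=[10.0, 30.0, 50.0, 70.0, 90.0, 110.0])
        m = itpc(est)
        cols = np.flatnonzero(m.valid[0, 0])[::52]  # >= 0.5 s apart
        observed = m.values[0][:, cols].ravel()
        null = simulate_itpc_curves(1, len(observed), n_trials=60, kappa=0.0,
                                    seed=14)[0]
        assert sstats.ks_2samp(observed, null).pvalue > 0.01


class TestCohort:
    def _design(self, n_trials=4):
        base = SimParams(n_trials=n_trials, noise_amplitude=5.0)
        return [
            CohortGroup("UWS", 3, dataclasses.replace(base, kappa=0.2)),
            CohortGroup("MCS-", 2, dataclasses.replace(base, kappa=1.2)),
            CohortGroup("MCS+", 2, dataclasses.replace(base, kappa=1.5)),
            CohortGroup("EMCS", 1, dataclasses.replace(base, kappa=2.0)),
        ]

    def test_sizes_and_metadata(self, narrowband):
        cohort = simulate_cohort(self._design(), narrowband, seed=1)
        assert len(cohort) == 8
        assert sum(1 for s in cohort if s.group_label == "UWS") == 3
        for s in cohort:
            assert len(s.diagnoses) == 5
            assert set(s.diagnoses) == {_GROUP_BASE[s.group_label]}
            assert s.abris == "pass"

    def test_reproducible_for_a_seed(self, narrowband):
        a = simulate_cohort(self._design(), narrowband, seed=2)
        b = simulate_cohort(self._design(), narrowband, seed=2)
        assert all(np.array_equal(x.epochs.data, y.epochs.data)
                   for x, y in zip(a, b))
        assert [x.truth.kappa for x in a] == [y.truth.kappa for y in b]

    def test_group_kappa_ordering_propagates_to_itpc(self, narrowband):
        # stronger concentration in the aware-like group must show up as a
        # larger mean resultant length at the ground-truth level
        cohort = simulate_cohort(self._design(), narrowband, seed=3)
        uws = [expected_itpc(s.truth.kappa) for s in cohort if s.group_label == "UWS"]
        aware = [expected_itpc(s.truth.kappa) for s in cohort
                 if s.group_label in ("MCS-", "MCS+", "EMCS")]
        assert np.mean(aware) > np.mean(uws)

    def test_empty_design_rejected(self, narrowband):
        with pytest.raises(ConfigurationError):
            simulate_cohort([], narrowband)


_GROUP_BASE = {"UWS": "UWS", "MCS-": "MCS-", "MCS+": "MCS+", "EMCS": "EMCS"}


class TestFixtureRoundTrip:
    def test_lossless(self, tmp_path, rng):
        from chirpefr import Epochs
        ep = Epochs(data=rng.standard_normal((240, 7, 973)), sample_rate=512.0,
                    t0_index=358, channel_labels=list(ANALYSIS_CHANNELS),
                    subject_id="s1")
        path = tmp_path / "ep.h5"
        write_fixture(ep, path)
        back = read_fixture(path)
        assert np.array_equal(back.data, ep.data)
        assert back.sample_rate == 512.0
        assert back.t0_index == 358
        assert back.channel_labels == list(ANALYSIS_CHANNELS)
        assert back.subject_id == "s1"

    def test_missing_onset_attribute_is_a_format_error(self, tmp_path, rng):
        import h5py
        path = tmp_path / "bad.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=rng.standard_normal((2, 2, 10)))
            f.attrs["sample_rate"] = 512.0
        with pytest.raises(FixtureFormatError):
            read_fixture(path)
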