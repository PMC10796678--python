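"""Diagnosis aggregation, outlier screening and the cluster permutation test."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from chirpefr import (ConfigurationError, EFRCurve, PermutationConfig,
                      SubjectRecord, assign_group, cluster_mean_itpc,
                      cluster_permutation, freq_diag, iqr_outliers,
                      simulate_itpc_curves)


class TestFreqDiag:
    @pytest.mark.parametrize("diags, expected", [
        (["UWS", "UWS", "MCS-", "UWS", "MCS-"], "UWS"),
        (["MCS-", "MCS-", "MCS+", "MCS+", "EMCS"], "MCS-"),  # 2-2 tie, less favorable
        (["EMCS"] * 5, "EMCS"),
        (["MCS+", "EMCS", "EMCS", "MCS+", "MCS+"], "MCS+"),
    ])
    def test_mode_with_conservative_tie_break(self, diags, expected):
        assert freq_diag(diags) == expected

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.sampled_from(["UWS", "MCS-", "MCS+", "EMCS"]),
                    min_size=5, max_size=5),
           st.randoms(use_true_random=False))
    def test_permutation_invariant(self, diags, rnd):
        shuffled = list(diags)
        rnd.shuffle(shuffled)
        assert freq_diag(diags) == freq_diag(shuffled)

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            freq_diag([])


class TestAssignGroup:
    @pytest.mark.parametrize("diag, group", [
        ("UWS", "UWS"), ("MCS-", "MCSe"), ("MCS+", "MCSe"), ("EMCS", "MCSe"),
    ])
    def test_mapping(self, diag, group):
        assert assign_group(diag) == group

    def test_cohort_table_sizes(self):
        # 28 UWS + (15 MCS- + 6 MCS+ + 5 EMCS) -> 28 vs 26
        records = (
            [SubjectRecord(f"u{i}", ("UWS",) * 5) for i in range(28)]
            + [SubjectRecord(f"m{i}", ("MCS-",) * 5) for i in range(15)]
            + [SubjectRecord(f"p{i}", ("MCS+",) * 5) for i in range(6)]
            + [SubjectRecord(f"e{i}", ("EMCS",) * 5) for i in range(5)]
        )
        groups = [r.group for r in records]
        assert groups.count("UWS") == 28
        assert groups.count("MCSe") == 26


def curve(values, sid):
    values = np.asarray(values, float)
    return EFRCurve(freqs=np.arange(10.0, 10.0 + 2 * len(values), 2.0),
                    values=values, times=np.zeros(len(values)), subject_id=sid)


class TestIQROutliers:
    def test_gross_high_outlier_flagged(self):
        curves = [curve([0.05, 0.05], f"s{i}") for i in range(20)]
        curves.append(curve([0.9, 0.9], "hot"))
        assert iqr_outliers(curves) == ["hot"]

    def test_all_equal_nothing_flagged(self):
        curves = [curve([0.2, 0.2], f"s{i}") for i in range(8)]
        assert iqr_outliers(curves) == []

    def test_low_outliers_kept_by_default(self, rng):
        curves = [curve(rng.uniform(0.4, 0.6, 3), f"s{i}") for i in range(12)]
        curves.append(curve([0.0, 0.0, 0.0], "flat"))
        assert "flat" not in iqr_outliers(curves)
        assert "flat" in iqr_outliers(curves, high_only=False)

    def test_matches_quantile_oracle_on_random_cohorts(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 30))
            scalars = rng.uniform(0, 1, n)
            curves = [curve([s], f"s{i}") for i, s in enumerate(scalars)]
            got = set(iqr_outliers(curves))
            q1, q3 = np.quantile(scalars, [0.25, 0.75])  # linear interpolation
            hi = q3 + 1.5 * (q3 - q1)
            expected = {f"s{i}" for i in range(n) if scalars[i] > hi}
            assert got == expected

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            iqr_outliers([curve([0.1], "a"), curve([0.2], "b")])


class TestClusterPermutation:
    def test_identical_groups_produce_no_cluster(self, rng):
        X = rng.uniform(0, 1, (6, 10))
        res = cluster_permutation(X, X.copy(), freqs=np.arange(10.0),
                                  config=PermutationConfig(n_permutations=200, seed=0))
        assert res.clusters == []

    def test_localised_contrast_recovers_injected_bins(self, rng):
        # effect confined to bins 36-50 Hz of a 2 Hz grid
        freqs = np.arange(20.0, 61.0, 2.0)
        idx = (freqs >= 36) & (freqs <= 50)
        A = rng.normal(0.08, 0.01, (14, len(freqs)))
        B = rng.normal(0.08, 0.01, (14, len(freqs)))
        B[:, idx] += 0.08
        res = cluster_permutation(A, B, freqs=freqs,
                                  config=PermutationConfig(n_permutations=2000, seed=1))
        sig = [c for c in res.clusters if c.p_value < 0.001]
        assert len(sig) == 1
        assert abs(sig[0].freq_lo - 36.0) <= 2.0
        assert abs(sig[0].freq_hi - 50.0) <= 2.0
        # location oracle: per-bin t-tests agree with the cluster's extent
        t, _ = sps.ttest_ind(B, A, axis=0)
        assert np.argmax(t) == np.argmax(res.observed_t)

    def test_monte_carlo_p_matches_exact_enumeration(self, rng):
        # n = 4 + 4: all C(8,4) = 70 label assignments are enumerable
        A = rng.normal(0.0, 1.0, (4, 5))
        B = rng.normal(1.6, 1.0, (4, 5))
        exact = cluster_permutation(
            A, B, freqs=np.arange(5.0),
            config=PermutationConfig(forming_p=0.05, exact_threshold=100))
        assert exact.method == "exact"
        assert exact.n_permutations == math.comb(8, 4)
        mc = cluster_permutation(
            A, B, freqs=np.arange(5.0),
            config=PermutationConfig(forming_p=0.05, n_permutations=20000,
                                     seed=3, exact_threshold=1))
        assert mc.method == "monte_carlo"
        for ce, cm in zip(exact.clusters, mc.clusters):
            p = ce.p_value
            tol = 2 * np.sqrt(p * (1 - p) / 20000) + 1 / 20000
            assert abs(cm.p_value - p) <= tol + 1e-9

    def test_exact_enumeration_matches_brute_force_oracle(self, rng):
        # independent oracle: re-enumerate assignments with scipy t-tests
        A = rng.normal(0.0, 1.0, (4, 3))
        B = rng.normal(1.2, 1.0, (4, 3))
        config = PermutationConfig(forming_p=0.05, exact_threshold=100)
        res = cluster_permutation(A, B, freqs=np.arange(3.0), config=config)
        X = np.vstack([A, B])
        crit = sps.t.isf(0.05, 6)

        def max_clusterstat(labels):
            a, b = X[~labels], X[labels]
            t, _ = sps.ttest_ind(b, a, axis=0)
            best, run = 0.0, 0.0
            for v in t:
                run = run + v if v > crit else 0.0
                best = max(best, run)
            return best

        null = []
        for combo in itertools.combinations(range(8), 4):
            labels = np.zeros(8, dtype=bool)
            labels[list(combo)] = True
            null.append(max_clusterstat(labels))
        null = np.array(null)
        for c in res.clusters:
            expected = np.count_nonzero(null >= c.clusterstat - 1e-9) / len(null)
            assert c.p_value == pytest.approx(expected, abs=1e-12)

    def test_pvalues_never_zero_and_reproducible(self, rng):
        A = rng.normal(0, 0.01, (10, 8))
        B = A + 0.5
        cfg = PermutationConfig(n_permutations=500, seed=7, exact_threshold=1)
        r1 = cluster_permutation(A, B, freqs=np.arange(8.0), config=cfg)
        r2 = cluster_permutation(A, B, freqs=np.arange(8.0), config=cfg)
        assert r1.clusters[0].p_value >= 1 / 501
        assert r1.clusters[0].p_value == r2.clusters[0].p_value
        assert np.array_equal(r1.null_max_stats, r2.null_max_stats)

    def test_degenerate_bins_excluded_not_poisoning(self, rng):
        A = rng.normal(0, 1, (5, 4))
        B = rng.normal(0, 1, (5, 4))
        A[:, 2] = 0.5
        B[:, 2] = 0.5  # identical within both groups -> t undefined
        res = cluster_permutation(A, B, freqs=np.arange(4.0),
                                  config=PermutationConfig(n_permutations=100, seed=0,
                                                           exact_threshold=1))
        assert 2 in res.excluded_bins
        assert np.isfinite(res.observed_t[[0, 1, 3]]).all()

    def test_effect_monotone_in_contrast(self):
        # larger kappa contrast must not shrink the observed clusterstat
        base = simulate_itpc_curves(10, 12, n_trials=150, kappa=0.3, seed=21)
        stats = []
        for i, kappa_b in enumerate((0.5, 1.0, 2.0)):
            other = simulate_itpc_curves(10, 12, n_trials=150, kappa=kappa_b,
                                         seed=22 + i)
            res = cluster_permutation(base, other, freqs=np.arange(12.0),
                                      config=PermutationConfig(n_permutations=300,
                                                               seed=5,
                                                               exact_threshold=1))
            stats.append(max((c.clusterstat for c in res.clusters), default=0.0))
        assert stats[0] <= stats[1] + 1e-9 <= stats[2] + 2e-9

    def test_type_one_error_controlled_under_null(self):
        # both groups identical kappa; nominal alpha 0.05 on the max-cluster p
        n_sims, alpha = 60, 0.05
        hits = 0
        for i in range(n_sims):
            X = simulate_itpc_curves(16, 20, n_trials=100, kappa=0.5,
                                     seed=1000 + i)
            res = cluster_permutation(X[:8], X[8:], freqs=np.arange(20.0),
                                      config=PermutationConfig(n_permutations=500,
                                                               forming_p=0.05,
                                                               seed=i,
                                                               exact_threshold=1))
            p_min = min((c.p_value for c in res.clusters), default=1.0)
            hits += p_min < alpha
        bound = alpha + 2 * np.sqrt(alpha * (1 - alpha) / n_sims)
        assert hits / n_sims <= bound


class TestClusterMean:
    def test_single_bin_cluster(self):
        curves = [curve([0.1], "a"), curve([0.2], "b")]
        mean, sd = cluster_mean_itpc(curves, (10.0, 10.0))
        assert mean == pytest.approx(0.15)
        assert sd == pytest.approx(np.std([0.1, 0.2], ddof=1))

    def test_constant_cohort(self):
        curves = [curve([0.3, 0.3, 0.3], f"s{i}") for i in range(6)]
        mean, sd = cluster_mean_itpc(curves, (10.0, 14.0))
        assert mean == pytest.approx(0.3)
        assert sd == 0.0

    def test_matches_double_loop_oracle(self, rng):
        X = rng.uniform(0, 1, (9, 6))
        freqs = np.arange(10.0, 22.0, 2.0)
        mean, sd = cluster_mean_itpc(X, (12.0, 18.0), freqs)
        per_subject = [np.mean([X[i, j] for j in range(6)
                                if 12.0 <= freqs[j] <= 18.0]) for i in range(9)]
        assert mean == pytest.approx(np.mean(per_subject), abs=1e-12)
        assert sd == pytest.approx(np.std(per_subject, ddof=1), abs=1e-12)

    def test_empty_range_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            cluster_mean_itpc(rng.uniform(0, 1, (4, 3)), (11.0, 11.5),
                              np.array([10.0, 12.0, 14.0]))
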