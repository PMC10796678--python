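"""Group-level statistics: diagnosis aggregation, outlier screening, and the
one-sided cluster-based permutation comparison of EFR curves.

The permutation procedure controls the family-wise error over frequency bins
nonparametrically: per bin an independent-samples t statistic (pooled
variance by default) compares the two groups; bins whose one-sided
uncorrected p falls below the forming threshold (default 0.005) are clustered
by adjacency along the curve (after EFR extraction each bin maps to one
trajectory time, so adjacency along the curve *is* adjacency along both
frequency and time); each cluster is scored by its summed t; and the maximum
cluster score is referred to a null distribution built by relabelling
subjects (30,000 random shuffles by default, or exact enumeration when the
number of distinct assignments is small).  The Monte-Carlo p-value uses the
add-one convention (1 + exceedances)/(1 + n_permutations) so it is never
exactly zero.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .efr import EFRCurve
from .exceptions import ConfigurationError

__all__ = [
    "DIAGNOSIS_ORDER",
    "SubjectRecord",
    "Cluster",
    "ClusterResult",
    "PermutationConfig",
    "freq_diag",
    "assign_group",
    "iqr_outliers",
    "cluster_permutation",
    "cluster_mean_itpc",
]

logger = logging.getLogger(__name__)

#: Behavioural diagnoses ordered from least to most favorable.
DIAGNOSIS_ORDER = ("UWS", "MCS-", "MCS+", "EMCS")


def freq_diag(diagnoses: Sequence[str]) -> str:
    """The modal ("most frequent") diagnosis over repeated assessments.

    Ties break toward the *less* favorable diagnosis on the ordering
    UWS < MCS- < MCS+ < EMCS, the conservative choice (a tie never upgrades
    the patient).  Order of assessments is irrelevant.
    """
    if not diagnoses:
        raise ConfigurationError("empty diagnosis list")
    unknown = set(diagnoses) - set(DIAGNOSIS_ORDER)
    if unknown:
        raise ConfigurationError(f"unknown diagnoses: {sorted(unknown)}")
    counts = {d: 0 for d in DIAGNOSIS_ORDER}
    for d in diagnoses:
        counts[d] += 1
    best = max(counts.values())
    for d in DIAGNOSIS_ORDER:  # least favorable first
        if counts[d] == best:
            return d
    raise AssertionError("unreachable")


def assign_group(diagnosis: str) -> str:
    """Collapse a final diagnosis into the two compared groups.

    UWS stays UWS; MCS-, MCS+ and EMCS pool into "MCSe" (the extended
    minimally-conscious, presumably aware, group).
    """
    if diagnosis == "UWS":
        return "UWS"
    if diagnosis in DIAGNOSIS_ORDER:
        return "MCSe"
    raise ConfigurationError(f"unknown diagnosis {diagnosis!r}")


@dataclass
class SubjectRecord:
    """Per-subject metadata entering the group analysis."""

    subject_id: str
    diagnoses: tuple[str, ...]
    abris: str = "pass"
    etiology: str = "other"
    condition: str = ""

    @property
    def freq_diag(self) -> str:
        return freq_diag(self.diagnoses)

    @property
    def group(self) -> str:
        return assign_group(self.freq_diag)


# ---------------------------------------------------------------------------
# Outlier screening


def iqr_outliers(curves: Sequence[EFRCurve], high_only: bool = True,
                 factor: float = 1.5) -> list[str]:
    """Flag subjects whose whole-curve mean ITPC is an interquartile-range
    outlier across the pooled cohort.

    Each subject reduces to the mean ITPC over the full curve; the fences are
    ``[Q1 - factor*IQR, Q3 + factor*IQR]`` with linearly interpolated
    quartiles.  By default only *high* outliers are flagged (excessively
    strong responses are the removable kind; a floor-level response is a
    finding, not an artifact).  Controls should be included in ``curves`` when
    they took part in the recording campaign, which widens the fences
    realistically.
    """
    if len(curves) < 4:
        raise ConfigurationError("IQR screening needs at least 4 subjects")
    scalars = np.array([float(np.mean(c.values)) for c in curves])
    q1, q3 = np.percentile(scalars, [25, 75])  # linear interpolation (type 7)
    iqr = q3 - q1
    lo, hi = q1 - factor * iqr, q3 + factor * iqr
    flagged = scalars > hi
    if not high_only:
        flagged |= scalars < lo
    return [curves[i].subject_id for i in np.flatnonzero(flagged)]


# ---------------------------------------------------------------------------
# Cluster-based permutation test


@dataclass(frozen=True)
class PermutationConfig:
    """Settings of the cluster permutation comparison.

    ``forming_p`` is the per-bin one-sided uncorrected threshold that admits
    bins into clusters; ``cluster_p`` the significance level for the cluster
    statistic against the max-cluster null; ``relaxed_cluster_p`` a secondary
    reporting threshold.  ``t_flavor`` selects the pooled-variance classic
    two-sample t (default) or Welch.  Exact enumeration replaces Monte-Carlo
    shuffles whenever the number of distinct label assignments is at most
    ``exact_threshold``.
    """

    n_permutations: int = 30_000
    forming_p: float = 0.005
    cluster_p: float = 0.001
    relaxed_cluster_p: float = 0.005
    seed: int = 0
    t_flavor: str = "pooled"
    exact_threshold: int = 100_000

    def __post_init__(self) -> None:
        if self.t_flavor not in ("pooled", "welch"):
            raise ConfigurationError("t_flavor must be 'pooled' or 'welch'")
        if not (0 < self.forming_p < 1 and 0 < self.cluster_p < 1):
            raise ConfigurationError("thresholds must lie in (0, 1)")


@dataclass
class Cluster:
    """A maximal run of adjacent suprathreshold bins."""

    freq_lo: float
    freq_hi: float
    bins: np.ndarray
    clusterstat: float
    p_value: float

    @property
    def significant(self) -> bool:  # against the configured cluster_p; set by caller
        return bool(getattr(self, "_significant", False))


@dataclass
class ClusterResult:
    """Outcome of the one-sided cluster permutation comparison (B > A)."""

    clusters: list[Cluster]
    observed_t: np.ndarray
    freqs: np.ndarray
    null_max_stats: np.ndarray
    n_permutations: int
    method: str  # "monte_carlo" or "exact"
    seed: int
    threshold_forming: float
    threshold_cluster: float
    direction: str
    group_a: str = "A"
    group_b: str = "B"
    excluded_bins: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < self.threshold_cluster]


def _group_moment_t(X0: np.ndarray, M: np.ndarray, sel: np.ndarray,
                    welch: bool) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sample t for many relabellings at once.

    ``X0`` is the (n_subjects, n_bins) data matrix with NaNs replaced by 0,
    ``M`` the matching validity mask, ``sel`` an (n_perm, n_subjects) 0/1
    matrix selecting group B per relabelling.  Returns ``(t, df)`` arrays of
    shape (n_perm, n_bins); bins with fewer than two valid subjects in either
    group, or zero pooled variance, come back NaN.
    """
    selc = 1.0 - sel
    nB = sel @ M
    nA = selc @ M
    sB = sel @ X0
    sA = selc @ X0
    X2 = X0 * X0
    ssB = sel @ X2
    ssA = selc @ X2
    with np.errstate(invalid="ignore", divide="ignore"):
        mB = sB / nB
        mA = sA / nA
        vB = (ssB - sB * mB) / (nB - 1)
        vA = (ssA - sA * mA) / (nA - 1)
        if welch:
            se2 = vA / nA + vB / nB
            df = se2**2 / ((vA / nA) ** 2 / (nA - 1) + (vB / nB) ** 2 / (nB - 1))
            t = (mB - mA) / np.sqrt(se2)
        else:
            df = nA + nB - 2
            sp2 = ((nA - 1) * vA + (nB - 1) * vB) / df
            t = (mB - mA) / np.sqrt(sp2 * (1 / nA + 1 / nB))
    bad = (nA < 2) | (nB < 2)
    t = np.where(bad, np.nan, t)
    return t, df


def _max_cluster_stats(T: np.ndarray, crit: np.ndarray) -> np.ndarray:
    """Per-row maximum summed-t over runs of adjacent suprathreshold bins.

    ``T`` is (n_perm, n_bins); ``crit`` the per-bin forming threshold.  NaN
    bins never enter a cluster and break adjacency.  Rows without any cluster
    score 0.
    """
    n_perm, n_bins = T.shape
    supra = np.nan_to_num(T, nan=-np.inf) > crit[None, :]
    Tz = np.where(supra, T, 0.0)
    padded = np.zeros((n_perm, n_bins + 1), dtype=int)
    padded[:, :n_bins] = supra
    d = np.diff(padded, axis=1, prepend=0)          # (n_perm, n_bins + 1)
    flat = d.ravel()
    starts = np.flatnonzero(flat == 1)
    ends = np.flatnonzero(flat == -1)
    cs = np.concatenate([np.zeros((n_perm, 1)), np.cumsum(Tz, axis=1)], axis=1).ravel()
    width = n_bins + 1
    sums = cs[ends] - cs[starts]
    rows = starts // width
    out = np.zeros(n_perm)
    np.maximum.at(out, rows, sums)
    return out


def _observed_clusters(t_obs: np.ndarray, crit: np.ndarray,
                       freqs: np.ndarray) -> list[tuple[np.ndarray, float]]:
    supra = np.nan_to_num(t_obs, nan=-np.inf) > crit
    clusters = []
    run: list[int] = []
    for i in range(len(t_obs) + 1):
        if i < len(t_obs) and supra[i]:
            run.append(i)
        elif run:
            idx = np.array(run)
            clusters.append((idx, float(t_obs[idx].sum())))
            run = []
    return clusters


def cluster_permutation(curves_a: np.ndarray | Sequence[EFRCurve],
                        curves_b: np.ndarray | Sequence[EFRCurve],
                        freqs: np.ndarray | None = None,
                        config: PermutationConfig | None = None,
                        group_a: str = "A", group_b: str = "B") -> ClusterResult:
    """One-sided cluster permutation comparison of two groups of EFR curves
    (alternative: group B exceeds group A).

    ``curves_a``/``curves_b`` may be lists of :class:`EFRCurve` on a shared
    frequency grid, or plain (n_subjects, n_bins) arrays with ``freqs``
    supplied.  Missing values (NaN) are handled complete-case per bin.
    """
    config = config or PermutationConfig()
    A, freqs_a = _as_matrix(curves_a, freqs)
    B, freqs_b = _as_matrix(curves_b, freqs)
    if freqs_a is not None and freqs_b is not None and (
            len(freqs_a) != len(freqs_b) or np.any(np.abs(freqs_a - freqs_b) > 1e-9)):
        raise ConfigurationError("groups do not share a frequency grid")
    freqs = freqs_a if freqs_a is not None else freqs_b
    if freqs is None:
        raise ConfigurationError("freqs must be given with array input")
    freqs = np.asarray(freqs, dtype=float)
    nA, nB = len(A), len(B)
    if nA < 2 or nB < 2:
        raise ConfigurationError("need at least 2 subjects per group")
    X = np.vstack([A, B])
    M = np.isfinite(X).astype(float)
    X0 = np.where(np.isfinite(X), X, 0.0)
    n = nA + nB

    obs_sel = np.zeros((1, n))
    obs_sel[0, nA:] = 1.0
    welch = config.t_flavor == "welch"
    t_obs, df_obs = _group_moment_t(X0, M, obs_sel, welch)
    t_obs, df_obs = t_obs[0], df_obs[0]
    # Degenerate bins: zero pooled variance -> non-finite t -> excluded from forming.
    excluded = np.flatnonzero(~np.isfinite(t_obs))
    if len(excluded):
        logger.info("cluster_permutation: %d bin(s) excluded (degenerate variance "
                    "or too few observations): %s", len(excluded),
                    freqs[excluded].tolist())
    with np.errstate(invalid="ignore"):
        crit = sps.t.isf(config.forming_p, np.where(df_obs > 0, df_obs, 1.0))

    observed = _observed_clusters(t_obs, crit, freqs)

    n_exact = math.comb(n, nA)
    if n_exact <= config.exact_threshold:
        method = "exact"
        sel = np.zeros((n_exact, n))
        for r, combo in enumerate(combinations(range(n), nB)):
            sel[r, list(combo)] = 1.0
        n_draws = n_exact
    else:
        method = "monte_carlo"
        rng = np.random.default_rng(config.seed)
        base = np.zeros(n)
        base[nA:] = 1.0
        sel = rng.permuted(np.tile(base, (config.n_permutations, 1)), axis=1)
        n_draws = config.n_permutations

    t_null, df_null = _group_moment_t(X0, M, sel, welch)
    # Per-bin forming thresholds stay tied to each bin's df (constant for the
    # pooled statistic with complete data, mildly varying under missingness).
    with np.errstate(invalid="ignore"):
        crit_null = sps.t.isf(config.forming_p, np.where(df_null > 0, df_null, 1.0))
    # Use the observed-df thresholds for every row: same df structure since
    # group sizes are fixed under relabelling; fall back to row-wise when Welch.
    null_max = _max_cluster_stats(t_null, crit) if not welch else \
        _max_cluster_stats(np.where(t_null > crit_null, t_null, np.nan), np.zeros(len(freqs)))

    clusters = []
    for idx, stat in observed:
        if method == "exact":
            p = float(np.count_nonzero(null_max >= stat - 1e-12) / n_draws)
        else:
            p = float((1 + np.count_nonzero(null_max >= stat - 1e-12)) / (1 + n_draws))
        clusters.append(Cluster(freq_lo=float(freqs[idx[0]]),
                                freq_hi=float(freqs[idx[-1]]),
                                bins=idx, clusterstat=stat, p_value=p))
    clusters.sort(key=lambda c: c.p_value)
    return ClusterResult(clusters=clusters, observed_t=t_obs, freqs=freqs,
                         null_max_stats=null_max, n_permutations=n_draws,
                         method=method, seed=config.seed,
                         threshold_forming=config.forming_p,
                         threshold_cluster=config.cluster_p,
                         direction=f"{group_b} > {group_a}",
                         group_a=group_a, group_b=group_b,
                         excluded_bins=excluded)


def _as_matrix(curves, freqs):
    if isinstance(curves, np.ndarray):
        return np.asarray(curves, dtype=float), (
            None if freqs is None else np.asarray(freqs, dtype=float))
    if len(curves) == 0:
        raise ConfigurationError("empty group")
    if isinstance(curves[0], EFRCurve):
        ref = curves[0].freqs
        for c in curves[1:]:
            if len(c.freqs) != len(ref) or np.any(np.abs(c.freqs - ref) > 1e-9):
                raise ConfigurationError("curves do not share a frequency grid")
        return np.vstack([c.values for c in curves]), ref
    return np.asarray(curves, dtype=float), (
        None if freqs is None else np.asarray(freqs, dtype=float))


def cluster_mean_itpc(curves: Sequence[EFRCurve] | np.ndarray,
                      cluster: tuple[float, float],
                      freqs: np.ndarray | None = None) -> tuple[float, float]:
    """Group summary over a frequency cluster: per subject, the mean ITPC over
    the cluster's bins; returns that distribution's (mean, sample sd).
    """
    X, f = _as_matrix(curves, freqs)
    if f is None:
        raise ConfigurationError("freqs must be given with array input")
    lo, hi = cluster
    if lo > hi:
        raise ConfigurationError("empty cluster range")
    mask = (f >= lo - 1e-9) & (f <= hi + 1e-9)
    if not np.any(mask):
        raise ConfigurationError("cluster range contains no frequency bin")
    per_subject = np.nanmean(X[:, mask], axis=1)
    mean = float(np.mean(per_subject))
    sd = float(np.std(per_subject, ddof=1)) if len(per_subject) > 1 else 0.0
    return mean, sd
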