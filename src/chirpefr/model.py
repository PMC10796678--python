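"""Model/Results interface to the group comparison.

:class:`EFRGroupModel` is built from per-subject EFR curves plus group labels
and behaves like a statsmodels model: ``fit()`` runs the one-sided
cluster-based permutation comparison and returns an
:class:`EFRGroupResults` carrying the observed t curve, the clusters with
their permutation p-values, per-group cluster summaries, and a ``summary()``
table; plotting hangs off the results object.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .efr import EFRCurve
from .exceptions import ConfigurationError
from .stats import (Cluster, ClusterResult, PermutationConfig,
                    cluster_mean_itpc, cluster_permutation, iqr_outliers)

__all__ = ["EFRGroupModel", "EFRGroupResults"]


class EFRGroupModel:
    """Two-group comparison of envelope-following-response curves.

    Parameters
    ----------
    values : ndarray, shape (n_subjects, n_bins)
        Per-subject EFR curves (ITPC per frequency bin); NaN marks a missing
        bin and is handled complete-case per bin.
    freqs : ndarray
        Shared frequency grid in Hz, strictly increasing.
    groups : sequence of str
        Group label per subject; exactly the two labels in ``group_order``
        may appear.
    group_order : (str, str)
        ``(group_a, group_b)``; the test is one-sided for B > A.  Default
        ("UWS", "MCSe"): the aware group is expected to respond more.
    """

    def __init__(self, values, freqs, groups, subject_ids=None,
                 group_order: tuple[str, str] = ("UWS", "MCSe")):
        self.values = np.asarray(values, dtype=float)
        self.freqs = np.asarray(freqs, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.freqs):
            raise ConfigurationError("values must be (n_subjects, n_bins)")
        self.groups = np.asarray(list(groups))
        if len(self.groups) != len(self.values):
            raise ConfigurationError("one group label per subject required")
        extra = set(self.groups) - set(group_order)
        if extra:
            raise ConfigurationError(f"unexpected group labels: {sorted(extra)}")
        self.group_order = group_order
        self.subject_ids = (list(subject_ids) if subject_ids is not None
                            else [f"s{i:03d}" for i in range(len(self.values))])

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_curves(cls, curves: list[EFRCurve], groups,
                    group_order=("UWS", "MCSe")) -> "EFRGroupModel":
        """Build from :class:`EFRCurve` objects sharing a frequency grid."""
        if not curves:
            raise ConfigurationError("no curves")
        ref = curves[0].freqs
        for c in curves[1:]:
            if len(c.freqs) != len(ref) or np.any(np.abs(c.freqs - ref) > 1e-9):
                raise ConfigurationError("curves do not share a frequency grid")
        values = np.vstack([c.values for c in curves])
        return cls(values, ref, groups,
                   subject_ids=[c.subject_id for c in curves],
                   group_order=group_order)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, value_col: str = "itpc",
                       freq_col: str = "freq_hz", group_col: str = "group",
                       subject_col: str = "subject_id",
                       group_order=("UWS", "MCSe")) -> "EFRGroupModel":
        """Build from a long-format table (subject, group, freq, value)."""
        wide = df.pivot_table(index=subject_col, columns=freq_col,
                              values=value_col)
        groups = df.drop_duplicates(subject_col).set_index(subject_col)[group_col]
        groups = groups.loc[wide.index]
        return cls(wide.to_numpy(), wide.columns.to_numpy(dtype=float),
                   groups.to_numpy(), subject_ids=list(wide.index),
                   group_order=group_order)

    # -- fitting ------------------------------------------------------------

    def fit(self, n_permutations: int = 30_000, forming_p: float = 0.005,
            cluster_p: float = 0.001, seed: int = 0,
            t_flavor: str = "pooled", remove_outliers: bool = False
            ) -> "EFRGroupResults":
        """Run the one-sided cluster permutation comparison.

        ``remove_outliers`` applies the pooled IQR screen (high outliers
        only) before testing; usually outlier removal has already happened at
        the study level with controls included, so it defaults off here.
        """
        values, groups, ids = self.values, self.groups, list(self.subject_ids)
        removed: list[str] = []
        if remove_outliers:
            curves = [EFRCurve(self.freqs, v, np.zeros_like(self.freqs),
                               subject_id=i) for v, i in zip(values, ids)]
            removed = iqr_outliers(curves)
            keep = [i for i, sid in enumerate(ids) if sid not in removed]
            values, groups = values[keep], groups[keep]
            ids = [ids[i] for i in keep]
        ga, gb = self.group_order
        A = values[groups == ga]
        B = values[groups == gb]
        config = PermutationConfig(n_permutations=n_permutations,
                                   forming_p=forming_p, cluster_p=cluster_p,
                                   seed=seed, t_flavor=t_flavor)
        result = cluster_permutation(A, B, freqs=self.freqs, config=config,
                                     group_a=ga, group_b=gb)
        return EFRGroupResults(model=self, cluster_result=result,
                               values_a=A, values_b=B,
                               outliers_removed=removed)


@dataclass
class EFRGroupResults:
    """Fitted group comparison: clusters, per-bin t curve, group summaries."""

    model: EFRGroupModel
    cluster_result: ClusterResult
    values_a: np.ndarray
    values_b: np.ndarray
    outliers_removed: list[str] = field(default_factory=list)

    # -- accessors ----------------------------------------------------------

    @property
    def freqs(self) -> np.ndarray:
        return self.cluster_result.freqs

    @property
    def clusters(self) -> list[Cluster]:
        return self.cluster_result.clusters

    @property
    def significant_clusters(self) -> list[Cluster]:
        return self.cluster_result.significant_clusters

    @property
    def observed_t(self) -> np.ndarray:
        return self.cluster_result.observed_t

    def group_mean_curves(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-group (mean, SEM) curves over frequency."""
        out = {}
        for label, X in ((self.cluster_result.group_a, self.values_a),
                         (self.cluster_result.group_b, self.values_b)):
            mean = np.nanmean(X, axis=0)
            n = np.sum(np.isfinite(X), axis=0)
            sd = np.nanstd(X, axis=0, ddof=1)
            out[label] = (mean, np.where(n > 1, sd / np.sqrt(n), 0.0))
        return out

    def cluster_group_means(self, cluster: Cluster) -> dict[str, tuple[float, float]]:
        """Per-group (mean, sd) of subject-mean ITPC over a cluster's bins."""
        span = (cluster.freq_lo, cluster.freq_hi)
        return {
            self.cluster_result.group_a:
                cluster_mean_itpc(self.values_a, span, self.freqs),
            self.cluster_result.group_b:
                cluster_mean_itpc(self.values_b, span, self.freqs),
        }

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table of the fitted comparison."""
        from statsmodels.iolib.table import SimpleTable
        cr = self.cluster_result
        ga, gb = cr.group_a, cr.group_b
        head = [
            ("Comparison", f"{gb} > {ga} (one-sided)"),
            ("N subjects", f"{ga}: {len(self.values_a)}   {gb}: {len(self.values_b)}"),
            ("Frequency bins", f"{len(cr.freqs)} ({cr.freqs[0]:g}-{cr.freqs[-1]:g} Hz)"),
            ("Permutations", f"{cr.n_permutations} ({cr.method})"),
            ("Forming p / cluster p", f"{cr.threshold_forming:g} / {cr.threshold_cluster:g}"),
            ("Outliers removed", ", ".join(self.outliers_removed) or "none"),
        ]
        lines = [str(SimpleTable([[v] for _, v in head],
                                 stubs=[k for k, _ in head],
                                 title="EFR group comparison"))]
        if cr.clusters:
            rows = []
            for c in cr.clusters:
                means = self.cluster_group_means(c)
                rows.append([
                    f"{c.freq_lo:g}-{c.freq_hi:g}",
                    f"{c.clusterstat:.2f}",
                    f"{c.p_value:.5f}",
                    "yes" if c.p_value < cr.threshold_cluster else "no",
                    f"{means[ga][0]:.4f} ({means[ga][1]:.4f})",
                    f"{means[gb][0]:.4f} ({means[gb][1]:.4f})",
                ])
            lines.append(str(SimpleTable(
                rows,
                headers=["cluster (Hz)", "clusterstat", "p", "significant",
                         f"{ga} mean (sd)", f"{gb} mean (sd)"],
                title="Suprathreshold clusters")))
        else:
            lines.append("No suprathreshold cluster.")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Group mean curves ± SEM with significant clusters shaded."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        for label, (mean, sem) in self.group_mean_curves().items():
            ax.plot(self.freqs, mean, label=label)
            ax.fill_between(self.freqs, mean - sem, mean + sem, alpha=0.25)
        for c in self.significant_clusters:
            ax.axvspan(c.freq_lo, c.freq_hi, color="pink", alpha=0.4)
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("ITPC")
        ax.legend()
        return ax
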