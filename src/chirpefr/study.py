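"""End-to-end study driver: epochs in, cluster report out.

``run_study`` chains the whole analysis for a cohort of subjects:
preprocessing (decimation, baseline, artifact rejection, epoch-count
equalization), time-frequency decomposition and ITPC, channel averaging over
the seven frontocentral channels, EFR-curve extraction along the stimulus
trajectory, diagnosis aggregation into the UWS / MCSe groups, pooled IQR
outlier screening, the one-sided cluster permutation comparison, and cluster
summaries.  The report is a plain JSON-serialisable dictionary (schema
version ``1``) so external tools can consume it directly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .efr import DEFAULT_WINDOW, EFRCurve, extract_efr
from .epochs import Epochs
from .exceptions import ConfigurationError
from .model import EFRGroupModel, EFRGroupResults
from .preprocess import PreprocConfig, preprocess_epochs
from .simulate import ANALYSIS_CHANNELS, CohortSubject
from .stats import PermutationConfig, SubjectRecord, iqr_outliers
from .stimuli import StimulusSpec, default_span, trajectory
from .tfr import channel_average, itpc, stft

__all__ = ["StudySubject", "StudyReport", "run_study", "subject_curve",
           "curves_to_frame"]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class StudySubject:
    """Input bundle for one subject: metadata plus epoched EEG."""

    record: SubjectRecord
    epochs: Epochs

    @classmethod
    def from_cohort_subject(cls, s: CohortSubject) -> "StudySubject":
        rec = SubjectRecord(subject_id=s.subject_id, diagnoses=s.diagnoses,
                            abris=s.abris, etiology=s.etiology)
        return cls(record=rec, epochs=s.epochs)


@dataclass
class StudyReport:
    """Everything the study computed, JSON-serialisable via :meth:`to_dict`."""

    condition: str
    results: EFRGroupResults | None
    curves: list[EFRCurve]
    records: list[SubjectRecord]
    excluded: dict[str, str]
    outliers_removed: list[str]
    seed: int
    abris_subset: "StudyReport | None" = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        cr = self.results.cluster_result if self.results else None
        d = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "condition": self.condition,
            "seed": self.seed,
            "n_subjects": {
                g: int(sum(1 for r in self.records if r.group == g))
                for g in ("UWS", "MCSe")
            },
            "excluded_subjects": dict(self.excluded),
            "outliers_removed": list(self.outliers_removed),
            "clusters": [],
            "abris_by_group": self.extras.get("abris_by_group", {}),
        }
        if cr is not None:
            d["n_permutations"] = int(cr.n_permutations)
            d["permutation_method"] = cr.method
            d["threshold_forming"] = cr.threshold_forming
            d["threshold_cluster"] = cr.threshold_cluster
            d["direction"] = cr.direction
            for c in cr.clusters:
                means = self.results.cluster_group_means(c)
                d["clusters"].append({
                    "freq_lo_hz": c.freq_lo,
                    "freq_hi_hz": c.freq_hi,
                    "clusterstat": c.clusterstat,
                    "p_value": c.p_value,
                    "significant": bool(c.p_value < cr.threshold_cluster),
                    "group_means": {g: {"mean": m, "sd": s}
                                    for g, (m, s) in means.items()},
                })
        if self.abris_subset is not None:
            d["abris_pass_only"] = self.abris_subset.to_dict()
        return d


def subject_curve(epochs: Epochs, stim: StimulusSpec,
                  preproc: PreprocConfig | None = None,
                  channels: Sequence[str] = ANALYSIS_CHANNELS,
                  window: tuple[float, float] = DEFAULT_WINDOW,
                  condition: str = "") -> tuple[EFRCurve | None, str]:
    """Preprocess one subject's epochs and extract its EFR curve.

    Returns ``(curve, status)``; curve is None when equalization excluded the
    subject (too few clean epochs).
    """
    preproc = preproc or PreprocConfig()
    eq, _log = preprocess_epochs(epochs, preproc)
    if eq.epochs is None:
        return None, "excluded: fewer than minimum clean epochs"
    clean = eq.epochs.pick_channels([c for c in channels
                                     if c in eq.epochs.channel_labels])
    est = stft(clean)
    avg = channel_average(itpc(est), clean.channel_labels)
    traj = trajectory(stim, freq_grid=est.freqs, span=default_span(stim))
    curve = extract_efr(avg, traj, window=window, condition=condition,
                        subject_id=epochs.subject_id)
    return curve, "ok"


def curves_to_frame(curves: Sequence[EFRCurve],
                    records: Sequence[SubjectRecord] | None = None) -> pd.DataFrame:
    """Long-format table of curves (one row per subject x frequency bin)."""
    groups = {r.subject_id: r.group for r in records} if records else {}
    rows = []
    for c in curves:
        for f, v, t in zip(c.freqs, c.values, c.times):
            rows.append({"subject_id": c.subject_id, "condition": c.condition,
                         "group": groups.get(c.subject_id, ""),
                         "freq_hz": f, "itpc": v, "traj_time_s": t})
    return pd.DataFrame(rows)


def run_study(subjects: Sequence[StudySubject], stim: StimulusSpec,
              condition: str = "NBC",
              preproc: PreprocConfig | None = None,
              perm: PermutationConfig | None = None,
              remove_outliers: bool = True,
              abris_pass_only: bool = False,
              seed: int = 0) -> StudyReport:
    """Run the full group analysis on a cohort.

    ``subjects`` may include healthy controls ("HC" via non-patient records is
    not modelled here; every record must map to UWS or MCSe — controls enter
    only through the outlier pool when their curves are passed separately).
    With ``abris_pass_only`` the comparison is additionally rerun on the
    subset of subjects with a "pass" brainstem screening result.
    """
    if not subjects:
        raise ConfigurationError("empty cohort")
    preproc = preproc or PreprocConfig()
    perm = perm or PermutationConfig(seed=seed)

    curves: list[EFRCurve] = []
    records: list[SubjectRecord] = []
    excluded: dict[str, str] = {}
    for s in subjects:
        curve, status = subject_curve(s.epochs, stim, preproc=preproc,
                                      condition=condition)
        if curve is None:
            excluded[s.record.subject_id] = status
            continue
        curves.append(curve)
        records.append(s.record)

    outliers = iqr_outliers(curves) if (remove_outliers and len(curves) >= 4) else []
    if outliers:
        logger.info("IQR screening removed: %s", outliers)
        keep = [i for i, c in enumerate(curves) if c.subject_id not in outliers]
        curves = [curves[i] for i in keep]
        records = [records[i] for i in keep]

    report = _fit_report(curves, records, condition, perm, outliers,
                         excluded, seed)
    if abris_pass_only:
        keep = [i for i, r in enumerate(records) if r.abris == "pass"]
        report.abris_subset = _fit_report(
            [curves[i] for i in keep], [records[i] for i in keep],
            condition + "/abris-pass", perm, [], {}, seed)
    return report


def _fit_report(curves, records, condition, perm, outliers, excluded,
                seed) -> StudyReport:
    groups = [r.group for r in records]
    n_uws = groups.count("UWS")
    n_mcse = groups.count("MCSe")
    if n_uws < 2 or n_mcse < 2:
        raise ConfigurationError(
            f"need >= 2 subjects per group after exclusions (UWS={n_uws}, MCSe={n_mcse})"
        )
    model = EFRGroupModel.from_curves(curves, groups)
    results = model.fit(n_permutations=perm.n_permutations,
                        forming_p=perm.forming_p, cluster_p=perm.cluster_p,
                        seed=perm.seed, t_flavor=perm.t_flavor)
    # 2x2 ABRIS x group cell means over each significant cluster, for any
    # external factorial analysis.
    abris_cells: dict[str, dict] = {}
    for c in results.significant_clusters:
        key = f"{c.freq_lo:g}-{c.freq_hi:g}Hz"
        cells = {}
        X = model.values
        mask = (model.freqs >= c.freq_lo - 1e-9) & (model.freqs <= c.freq_hi + 1e-9)
        per_subj = np.nanmean(X[:, mask], axis=1)
        for g in ("UWS", "MCSe"):
            for a in ("pass", "refer"):
                sel = [i for i, r in enumerate(records)
                       if r.group == g and r.abris == a]
                cells[f"{g}/{a}"] = {
                    "n": len(sel),
                    "mean": float(np.mean(per_subj[sel])) if sel else None,
                }
        abris_cells[key] = cells
    return StudyReport(condition=condition, results=results, curves=curves,
                       records=records, excluded=excluded,
                       outliers_removed=outliers, seed=seed,
                       extras={"abris_by_group": abris_cells})
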