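"""Cluster labeling by majority FDT status, confusion summaries, and the
age-ablation experiment.

A cluster is labeled "normal" when strictly more than half of its argmax-
assigned members are FDT-normal; empty clusters and exact ties are labeled
"glaucoma" (the conservative choice for a screening statistic).
Specificity = fraction of FDT-normal fields falling in normal-labeled
clusters; sensitivity = fraction of FDT-abnormal fields in glaucoma-labeled
clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

NORMAL, GLAUCOMA = "normal", "glaucoma"


def _counts(assignments: np.ndarray, labels: np.ndarray, K: int
            ) -> tuple[np.ndarray, np.ndarray]:
    assignments = np.asarray(assignments)
    labels = np.asarray(labels)
    if assignments.shape != labels.shape:
        raise ValueError("assignments and labels must align")
    normal = np.array([np.sum((assignments == k) & (labels == "normal")) for k in range(K)])
    abnormal = np.array([np.sum((assignments == k) & (labels == "abnormal")) for k in range(K)])
    return normal, abnormal


def label_clusters(assignments: np.ndarray, labels: np.ndarray, K: int) -> list[str]:
    """Majority labeling: normal iff >50% of members are FDT-normal."""
    normal, abnormal = _counts(assignments, labels, K)
    out = []
    for k in range(K):
        total = normal[k] + abnormal[k]
        if total == 0:
            log.warning("cluster %d is empty; labeled glaucoma", k)
            out.append(GLAUCOMA)
        elif normal[k] > total / 2:
            out.append(NORMAL)
        else:
            out.append(GLAUCOMA)  # ties conservative
    return out


@dataclass
class ConfusionSummary:
    """Cluster-by-label counts with majority labeling and the derived
    specificity / sensitivity of the induced normal-vs-glaucoma rule."""

    normal_counts: np.ndarray
    abnormal_counts: np.ndarray
    cluster_labels: list[str]
    specificity: Optional[float]
    sensitivity: Optional[float]

    @classmethod
    def from_counts(cls, normal_counts: Sequence[int],
                    abnormal_counts: Sequence[int]) -> "ConfusionSummary":
        """Build from a printed cluster-composition table (counts per cluster)."""
        normal = np.asarray(normal_counts, dtype=int)
        abnormal = np.asarray(abnormal_counts, dtype=int)
        if normal.shape != abnormal.shape:
            raise ValueError("count vectors must align")
        K = normal.size
        labels = []
        for k in range(K):
            total = normal[k] + abnormal[k]
            labels.append(NORMAL if total > 0 and normal[k] > total / 2 else GLAUCOMA)
        is_norm = np.array([lab == NORMAL for lab in labels])
        n_normal, n_abnormal = normal.sum(), abnormal.sum()
        specificity = float(normal[is_norm].sum() / n_normal) if n_normal else None
        sensitivity = float(abnormal[~is_norm].sum() / n_abnormal) if n_abnormal else None
        if n_abnormal == 0:
            log.warning("no abnormal fields; sensitivity undefined")
        return cls(normal, abnormal, labels, specificity, sensitivity)

    @property
    def K(self) -> int:
        return self.normal_counts.size

    def cluster_sizes(self) -> np.ndarray:
        return self.normal_counts + self.abnormal_counts

    def abnormal_fraction(self, k: int) -> float:
        return float(self.abnormal_counts[k] / max(self.cluster_sizes()[k], 1))

    def normal_cluster_index(self) -> Optional[int]:
        """The normal-labeled cluster holding the most normal fields."""
        idx = [k for k, lab in enumerate(self.cluster_labels) if lab == NORMAL]
        if not idx:
            return None
        return int(max(idx, key=lambda k: self.normal_counts[k]))

    def to_frame(self) -> pd.DataFrame:
        """Cluster-composition table (rows normal/abnormal/total x clusters)."""
        cols = [f"cluster_{k}" for k in range(self.K)]
        df = pd.DataFrame(
            [self.normal_counts, self.abnormal_counts, self.cluster_sizes()],
            index=["normal", "abnormal", "total"], columns=cols,
        )
        df.loc["majority_label"] = self.cluster_labels
        return df

    def display(self) -> str:
        spec = "n/a" if self.specificity is None else f"{100 * self.specificity:.1f}%"
        sens = "n/a" if self.sensitivity is None else f"{100 * self.sensitivity:.1f}%"
        return f"specificity {spec}, sensitivity {sens}"


def confusion(assignments: np.ndarray, labels: np.ndarray, K: int) -> ConfusionSummary:
    """Confusion summary from hard cluster assignments and FDT labels."""
    normal, abnormal = _counts(assignments, labels, K)
    return ConfusionSummary.from_counts(normal, abnormal)


@dataclass
class AgeAblationReport:
    """Paired pipeline outcomes with and without the age input."""

    baseline: ConfusionSummary
    ablated: ConfusionSummary
    pattern_differences: pd.DataFrame  # per matched axis: max |deviation diff|

    @property
    def delta_specificity(self) -> Optional[float]:
        if self.baseline.specificity is None or self.ablated.specificity is None:
            return None
        return self.ablated.specificity - self.baseline.specificity

    @property
    def delta_sensitivity(self) -> Optional[float]:
        if self.baseline.sensitivity is None or self.ablated.sensitivity is None:
            return None
        return self.ablated.sensitivity - self.baseline.sensitivity


def age_ablation(cohort, grid, knee_override=None, k_sd: float = 2.0) -> AgeAblationReport:
    """Re-run the selected pipeline with the age input held constant.

    The constant age column is dropped before standardization (a zero-variance
    input cannot be z-scored), matching the intent of removing age's
    influence.  Seeds are shared between the two runs, so any output
    difference is attributable to the age dimension alone.
    """
    import copy
    from dataclasses import replace as dc_replace

    from .pipeline import run_pipeline

    base = run_pipeline(cohort, grid, knee_override=knee_override, k_sd=k_sd)

    ablated_records = [copy.copy(r) for r in cohort.records]
    for r in ablated_records:
        r.age = 0.0
    ablated_cohort = dc_replace(cohort, records=ablated_records)
    abl = run_pipeline(ablated_cohort, grid, knee_override=knee_override, k_sd=k_sd)

    rows = []
    base_pat = {(p.cluster_rank, p.axis_rank): p for p in base.patterns if p.k > 0}
    abl_pat = {(p.cluster_rank, p.axis_rank): p for p in abl.patterns if p.k > 0}
    for key in sorted(set(base_pat) & set(abl_pat)):
        d = np.max(np.abs(base_pat[key].deviations - abl_pat[key].deviations))
        rows.append({"cluster_rank": key[0], "axis_rank": key[1],
                     "max_abs_deviation_diff_db": float(d)})
    diff = pd.DataFrame(rows, columns=["cluster_rank", "axis_rank",
                                       "max_abs_deviation_diff_db"])
    return AgeAblationReport(baseline=base.confusion, ablated=abl.confusion,
                             pattern_differences=diff)
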