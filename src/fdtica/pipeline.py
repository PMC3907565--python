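"""End-to-end orchestration: search -> select -> knee pruning -> retraining ->
orientation -> confusion -> pattern generation.

This is glue over the analysis modules; each stage remains individually
usable (and individually tested)."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import axis_model, evaluation, model_search, patterns
from .axis_model import AxisSpec
from .evaluation import ConfusionSummary
from .fields_io import Cohort, feature_matrix
from .model_search import CandidateFit, SearchGrid
from .patterns import PatternGrid
from .vbica import VimModel, axis_magnitudes, standardize

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    search: list[CandidateFit]
    selected: CandidateFit
    model: VimModel                  # pruned + retrained
    retained: list[int]
    normal_cluster_index: int
    axes: list[AxisSpec]
    confusion: ConfusionSummary
    patterns: list[PatternGrid]
    Z: np.ndarray

    def search_table(self) -> pd.DataFrame:
        return model_search.search_table(self.search)


def _rank_patterns(pats: list[PatternGrid], confusion: ConfusionSummary,
                   axes: list[AxisSpec]) -> None:
    """Attach presentation ranks: clusters ordered by decreasing normal
    fraction, axes within a cluster by decreasing magnitude (robust pairing
    key across reruns with permuted cluster indices)."""
    order = np.argsort(-np.array([
        confusion.normal_counts[k] / max(confusion.cluster_sizes()[k], 1)
        for k in range(confusion.K)
    ]), kind="stable")
    crank = {int(k): i for i, k in enumerate(order)}
    for k in range(confusion.K):
        cluster_axes = sorted((a for a in axes if a.cluster_index == k),
                              key=lambda a: -a.magnitude)
        arank = {a.axis_index: i for i, a in enumerate(cluster_axes)}
        for p in pats:
            if p.cluster_index == k:
                p.cluster_rank = crank[k]
                p.axis_rank = arank[p.axis_index]


def run_pipeline(cohort: Cohort, grid: SearchGrid, spec_goal: float = 0.90,
                 knee_override: Optional[Sequence[int]] = None, k_sd: float = 2.0,
                 retrain_iterations: Optional[int] = None) -> PipelineResult:
    """Run the full analysis on a labeled cohort.

    knee_override: per-cluster retained axis counts (bypasses knee detection,
    in cluster-index order of the selected model).  k_sd: pattern offsets
    are generated at +/- k_sd axis SDs from the normal centroid.
    """
    labels = cohort.labels()
    X, _ = feature_matrix(cohort)
    Z, _ = standardize(X)

    candidates = model_search.run_search(cohort, grid)
    selected = model_search.select_best(candidates, spec_goal=spec_goal)
    model = selected.fit.model
    K = model.K

    retained = []
    for k in range(K):
        mags = np.sort(axis_magnitudes(model, k))[::-1]
        override_k = None if knee_override is None else knee_override[k]
        retained.append(axis_model.knee_point(mags, override=override_k))
    n_iter = grid.n_iterations if retrain_iterations is None else retrain_iterations
    pruned = axis_model.prune_and_retrain(model, retained, Z, n_iterations=n_iter,
                                          convergence_tol=grid.convergence_tol)

    assignments = pruned.hard_assignments()
    conf = evaluation.confusion(assignments, labels, K)
    normal_idx = conf.normal_cluster_index()
    if normal_idx is None:
        log.warning("no majority-normal cluster; anchoring at the most-normal cluster")
        normal_idx = int(np.argmax(conf.normal_counts / np.maximum(conf.cluster_sizes(), 1)))

    axes = axis_model.orient_axes(pruned, normal_idx, Z, labels)
    pats = []
    for axis in axes:
        for k_val in (-k_sd, k_sd):
            pats.append(patterns.generate_axis_pattern(pruned, axis, k_val))
    _rank_patterns(pats, conf, axes)

    return PipelineResult(search=candidates, selected=selected, model=pruned,
                          retained=retained, normal_cluster_index=normal_idx,
                          axes=axes, confusion=conf, patterns=pats, Z=Z)
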