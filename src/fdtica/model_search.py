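"""Candidate-model grid: enumeration, fitting with restarts, and selection
by the specificity/sensitivity trade-off.

FDT labels are used only here, post hoc, to score and select already-fitted
unsupervised models; they never enter vbica fitting (which receives only the
standardized data matrix).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import evaluation
from .fields_io import Cohort, feature_matrix
from .vbica import FitResult, VimConfig, VimModel, fit_vbica_mm, standardize

log = logging.getLogger(__name__)


@dataclass
class SearchGrid:
    """The candidate-model grid: K x L_max x m x restarts."""

    cluster_counts: tuple[int, ...] = (2, 3, 4, 5)
    axis_maxima: tuple[int, ...] = (10, 20)
    mixture_components: tuple[int, ...] = (3, 6, 8)
    n_restarts: int = 30
    n_iterations: int = 500
    convergence_tol: float = 1e-8
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cluster_counts", "axis_maxima", "mixture_components"):
            vals = tuple(sorted(set(getattr(self, name))))
            if not vals:
                raise ValueError(f"{name} must be non-empty")
            setattr(self, name, vals)
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")

    @property
    def n_candidates(self) -> int:
        return (len(self.cluster_counts) * len(self.axis_maxima)
                * len(self.mixture_components) * self.n_restarts)


def _candidate_seed(master_seed: int, K: int, L: int, m: int, restart: int) -> int:
    key = f"{master_seed}|{K}|{L}|{m}|{restart}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") & 0x7FFFFFFF


def enumerate_grid(grid: SearchGrid) -> list[tuple[VimConfig, int]]:
    """Deterministic Cartesian product (K, then L_max, then m, then restart);
    each candidate's seed is a stable hash of (master seed, config, restart)."""
    out = []
    for K in grid.cluster_counts:
        for L in grid.axis_maxima:
            for m in grid.mixture_components:
                for r in range(grid.n_restarts):
                    seed = _candidate_seed(grid.master_seed, K, L, m, r)
                    out.append((
                        VimConfig(K=K, L_max=L, m=m, n_iterations=grid.n_iterations,
                                  convergence_tol=grid.convergence_tol, seed=seed),
                        seed,
                    ))
    return out


@dataclass
class CandidateFit:
    config: VimConfig
    restart_index: int
    seed: int
    fit: Optional[FitResult] = None
    confusion: Optional["evaluation.ConfusionSummary"] = None
    error: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.error is None


def fit_cohort(cohort: Cohort, config: VimConfig) -> FitResult:
    """Standardize the cohort's 52+age feature matrix and fit one model."""
    X, _ = feature_matrix(cohort)
    Z, std = standardize(X)
    result = fit_vbica_mm(Z, config)
    result.model.standardization = std
    return result


def run_search(cohort: Cohort, grid: SearchGrid, parallelism: int = 1
               ) -> list[CandidateFit]:
    """Fit every grid candidate and score it against the FDT labels.

    Each candidate's seed is fixed by enumerate_grid, so results are
    independent of execution order; individual failures are recorded, not
    fatal.  The parallelism hint is accepted for API stability but fits run
    sequentially (they are memory-bound at cohort scale).
    """
    if parallelism != 1:
        log.info("parallelism hint %d noted; running sequentially", parallelism)
    labels = cohort.labels()
    X, _ = feature_matrix(cohort)
    Z, std = standardize(X)
    candidates = []
    n_rest = grid.n_restarts
    for i, (config, seed) in enumerate(enumerate_grid(grid)):
        cand = CandidateFit(config=config, restart_index=i % n_rest, seed=seed)
        try:
            fit = fit_vbica_mm(Z, config)
            fit.model.standardization = std
            assign = fit.model.hard_assignments()
            cand.fit = fit
            cand.confusion = evaluation.confusion(assign, labels, config.K)
        except Exception as exc:  # noqa: BLE001 - candidate failures are data
            log.warning("candidate %d (K=%d L=%d m=%d seed=%d) failed: %s",
                        i, config.K, config.L_max, config.m, seed, exc)
            cand.error = str(exc)
        candidates.append(cand)
    return candidates


def search_table(candidates: Sequence[CandidateFit]) -> pd.DataFrame:
    """One row per candidate: config, seed, elbo, specificity, sensitivity."""
    rows = []
    for i, c in enumerate(candidates):
        rows.append({
            "index": i, "K": c.config.K, "L_max": c.config.L_max, "m": c.config.m,
            "restart": c.restart_index, "seed": c.seed,
            "elbo": c.fit.final_elbo if c.ok else np.nan,
            "converged": c.fit.converged if c.ok else False,
            "specificity": c.confusion.specificity if c.ok else np.nan,
            "sensitivity": c.confusion.sensitivity if c.ok else np.nan,
            "error": c.error or "",
        })
    return pd.DataFrame(rows)


def select_best(candidates: Sequence[CandidateFit],
                spec_goal: float = 0.90) -> CandidateFit:
    """Lexicographic trade-off: among candidates meeting the specificity
    goal, maximal sensitivity; if none qualifies, maximal specificity.
    Ties broken by higher ELBO, then lower K, then lower candidate index."""
    ok = [(i, c) for i, c in enumerate(candidates) if c.ok]
    if not ok:
        raise ValueError("no successful candidates to select from")

    def sens(c):
        return -1.0 if c.confusion.sensitivity is None else c.confusion.sensitivity

    feasible = [(i, c) for i, c in ok if c.confusion.specificity >= spec_goal]
    pool, primary = (feasible, sens) if feasible else (ok, lambda c: c.confusion.specificity)
    return max(pool, key=lambda ic: (primary(ic[1]), ic[1].fit.final_elbo,
                                     -ic[1].config.K, -ic[0]))[1]
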