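"""Knee-point axis selection, pruning with constrained retraining, and axis
orientation / member assignment.

ARD already shrinks irrelevant mixing-matrix columns during fitting; this
module turns the soft shrinkage into a hard per-cluster axis count by finding
the knee of the sorted magnitude curve (largest discrete curvature), dropping
the remaining columns, and retraining the reduced model from the pruned
posterior.  Axes are then given a severity orientation: the positive
direction points toward greater abnormality.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .vbica import VimModel, _train, axis_magnitudes

log = logging.getLogger(__name__)


def knee_point(magnitudes: Sequence[float], override: Optional[int] = None) -> int:
    """Number of axes to retain from a sorted-descending magnitude curve.

    The knee is the interior position with the largest discrete second
    difference (maximum curvature of the scree curve); axes strictly before
    it are retained.  `override` bypasses detection (axis counts were chosen
    manually in the clinical analyses this mirrors, so the override is
    first-class).  An all-equal curve has no knee: the full length is
    returned with a warning.
    """
    mags = np.asarray(magnitudes, dtype=float)
    if mags.size == 0:
        raise ValueError("magnitudes must be non-empty")
    if np.any(mags < 0):
        raise ValueError("magnitudes must be non-negative")
    if np.any(np.diff(mags) > 1e-12):
        raise ValueError("magnitudes must be sorted in descending order")
    if override is not None:
        if not (1 <= override <= mags.size):
            raise ValueError(f"override {override} outside [1, {mags.size}]")
        return int(override)
    if mags.size == 1:
        return 1
    if np.allclose(mags, mags[0]):
        log.warning("magnitude curve is flat; no knee, retaining all axes")
        return int(mags.size)
    if mags.size == 2:
        log.warning("two-point magnitude curve has no interior knee; retaining both")
        return 2
    d2 = mags[:-2] - 2.0 * mags[1:-1] + mags[2:]
    knee = int(np.argmax(d2)) + 1  # interior index of the knee point
    return knee


def prune_and_retrain(model: VimModel, retained: Sequence[int], Z: np.ndarray,
                      n_iterations: int = 500,
                      convergence_tol: Optional[float] = None) -> VimModel:
    """Drop each cluster's lowest-magnitude axes and retrain with L fixed.

    Retraining warm-starts from the pruned posterior (the selected basin is
    preserved rather than refit from scratch) and runs up to n_iterations
    coordinate-ascent sweeps; the new ELBO trace is monotone.  The result has
    exactly the requested axis counts.
    """
    retained = list(retained)
    if len(retained) != model.K:
        raise ValueError("one retained count per cluster required")
    out = copy.deepcopy(model)
    for k, keep in enumerate(retained):
        c = out.clusters[k]
        if not (1 <= keep <= c.L):
            raise ValueError(f"retained count {keep} invalid for cluster {k} (L={c.L})")
        mags = axis_magnitudes(out, k)
        idx = np.sort(np.argsort(-mags)[:keep])  # keep original axis order
        c.mA = c.mA[:, idx]
        c.SA = c.SA[:, idx][:, :, idx]
        c.alpha_a = c.alpha_a[idx]
        c.alpha_b = c.alpha_b[idx]
        c.w = c.w[idx]
        c.eta_m = c.eta_m[idx]
        c.eta_v = c.eta_v[idx]
        c.beta_e = c.beta_e[idx]
        c.beta_f = c.beta_f[idx]
        if c.rho is not None:
            c.rho = c.rho[:, idx]
            c.ms = c.ms[:, idx]
            c.Ss = c.Ss[:, idx][:, :, idx]
    out.elbo_trace = []
    tol = model.config.convergence_tol if convergence_tol is None else convergence_tol
    _train(out, np.asarray(Z, float), n_iterations, tol)
    return out


@dataclass
class AxisSpec:
    """One oriented, unit-norm axis of one cluster (standardized space).

    The positive direction points toward greater abnormality; projection_sd
    is the SD of the cluster members' projections onto the direction, and is
    the unit in which pattern severity is expressed.
    """

    cluster_index: int
    axis_index: int
    direction: np.ndarray
    magnitude: float
    projection_sd: float
    orientation_sign: int
    anchor_cluster_index: int
    oriented: bool = True


def _field_space_change(model: VimModel, direction: np.ndarray) -> np.ndarray:
    """dB change of the 52 field dimensions per unit move along `direction`."""
    if model.standardization is None:
        return direction[:52]
    scale = np.asarray(model.standardization["scale"])
    return direction[:52] * scale[:52]


def orient_axes(model: VimModel, normal_cluster_index: int, Z: np.ndarray,
                labels: np.ndarray) -> list[AxisSpec]:
    """Unit-normalize and orient every retained axis of every cluster.

    Sign convention: the mean projection of the cluster's abnormal-labeled
    members exceeds that of its normal-labeled members along +direction.
    When a cluster holds a single label class, the fallback is geometric:
    +direction must decrease mean simulated field sensitivity.
    """
    Z = np.asarray(Z, float)
    labels = np.asarray(labels)
    assignments = model.hard_assignments()
    axes: list[AxisSpec] = []
    for k, c in enumerate(model.clusters):
        members = np.flatnonzero(assignments == k)
        mags = axis_magnitudes(model, k)
        for l in range(c.L):
            col = c.mA[:, l]
            norm = np.linalg.norm(col)
            if norm == 0:
                log.warning("cluster %d axis %d has zero direction", k, l)
                direction = np.zeros_like(col)
                direction[0] = 1.0
            else:
                direction = col / norm
            proj = (Z[members] - c.m_mu) @ direction if members.size else np.zeros(0)
            mem_labels = labels[members]
            sign = 1
            has_both = (mem_labels == "normal").any() and (mem_labels == "abnormal").any()
            if has_both:
                if proj[mem_labels == "abnormal"].mean() < proj[mem_labels == "normal"].mean():
                    sign = -1
            else:
                if _field_space_change(model, direction).mean() > 0:
                    sign = -1
            direction = sign * direction
            proj = sign * proj
            proj_sd = float(np.std(proj)) if proj.size >= 2 else 0.0
            if proj_sd <= 0:
                log.warning("cluster %d axis %d has degenerate projection SD; using 1",
                            k, l)
                proj_sd = 1.0
            axes.append(AxisSpec(
                cluster_index=k, axis_index=l, direction=direction,
                magnitude=float(mags[l]), projection_sd=proj_sd,
                orientation_sign=sign, anchor_cluster_index=normal_cluster_index,
            ))
    return axes


def assign_to_nearest_axis(model: VimModel, Z: np.ndarray, cluster_index: int,
                           axes: Optional[Sequence[AxisSpec]] = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Partition a cluster's member fields by largest |cosine| to an axis.

    Returns (member row indices, per-member axis position).  The axis set
    defaults to the cluster's mixing-matrix columns; pass oriented AxisSpecs
    to use pruned/oriented directions.  A zero-norm centered field is
    assigned to the first axis with a warning.
    """
    Z = np.asarray(Z, float)
    c = model.clusters[cluster_index]
    members = np.flatnonzero(model.hard_assignments() == cluster_index)
    if axes is None:
        dirs = c.mA / np.maximum(np.linalg.norm(c.mA, axis=0, keepdims=True), 1e-300)
    else:
        cluster_axes = [a for a in axes if a.cluster_index == cluster_index]
        if not cluster_axes:
            raise ValueError(f"no axes supplied for cluster {cluster_index}")
        dirs = np.column_stack([a.direction for a in cluster_axes])
    centered = Z[members] - c.m_mu
    norms = np.linalg.norm(centered, axis=1)
    cos = np.abs(centered @ dirs) / np.maximum(norms, 1e-300)[:, None]
    choice = np.argmax(cos, axis=1)
    zero = norms == 0
    if zero.any():
        log.warning("%d zero-norm centered field(s) assigned to axis 1", zero.sum())
        choice[zero] = 0
    return members, choice


def axis_report(axes: Sequence[AxisSpec], member_counts: Optional[dict] = None
                ) -> pd.DataFrame:
    rows = []
    for a in axes:
        rows.append({
            "cluster": a.cluster_index, "axis": a.axis_index,
            "magnitude": a.magnitude, "projection_sd": a.projection_sd,
            "orientation_sign": a.orientation_sign,
            "members": (member_counts or {}).get((a.cluster_index, a.axis_index), np.nan),
        })
    return pd.DataFrame(rows)
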