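"""Defect-pattern generation along axes and severity scoring by projection.

A pattern at k SD along an axis is the field obtained by moving k x
projection_sd from the normal-cluster centroid along the axis direction in
standardized space, mapped back to dB and expressed as pointwise deviations
from the (de-standardized) normal-cluster mean -- a simulated total-deviation
plot.  Patterns are anchored at the NORMAL cluster centroid for every
cluster's axes (an own-centroid flag exists for exploration).  Deviations are
not clipped at 0 dB: they simulate deviations, not raw thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .axis_model import AxisSpec
from .fields_io import FieldRecord, Grid242Layout, N_POINTS, layout_242
from .vbica import VimModel, destandardize

log = logging.getLogger(__name__)


@dataclass
class PatternGrid:
    """A generated field at k SD along one axis, as deviations on the 24-2 grid."""

    layout: Grid242Layout
    deviations: np.ndarray          # (52,) dB, negative = loss
    age: Optional[float]            # generated age (None if the model is age-free)
    cluster_index: int
    axis_index: int
    k: float
    cluster_rank: Optional[int] = None  # presentation ranks set by the pipeline
    axis_rank: Optional[int] = None

    def superior_mean(self) -> float:
        return float(self.deviations[self.layout.superior_mask].mean())

    def inferior_mean(self) -> float:
        return float(self.deviations[self.layout.inferior_mask].mean())


def generate_axis_pattern(model: VimModel, axis: AxisSpec, k: float,
                          normal_cluster_index: Optional[int] = None,
                          anchor: str = "normal") -> PatternGrid:
    """Pattern at k SD along an oriented axis, relative to the normal centroid.

    With anchor="own" the axis's own cluster mean is used instead (for
    exploration); the default follows the convention that every pattern is a
    deviation from the normal cluster mean.
    """
    if not axis.oriented:
        raise ValueError("axis must be oriented (see axis_model.orient_axes)")
    if normal_cluster_index is None:
        normal_cluster_index = axis.anchor_cluster_index
    anchor_idx = axis.cluster_index if anchor == "own" else normal_cluster_index
    mu_n = model.clusters[anchor_idx].m_mu
    x_std = mu_n + k * axis.projection_sd * axis.direction
    if model.standardization is not None:
        x = destandardize(x_std, model.standardization)
        ref = destandardize(mu_n, model.standardization)
    else:
        x, ref = x_std, mu_n
    deviations = x[:N_POINTS] - ref[:N_POINTS]
    age = float(x[N_POINTS]) if model.D > N_POINTS else None
    return PatternGrid(layout=layout_242(), deviations=deviations, age=age,
                       cluster_index=axis.cluster_index, axis_index=axis.axis_index,
                       k=float(k))


def severity(field: Union[FieldRecord, np.ndarray], axis: AxisSpec,
             model: VimModel) -> float:
    """Signed distance, in axis SD units, of a field from the normal centroid.

    severity = ((z - mu_N) . direction) / projection_sd with z the
    standardized field vector; positive = more severe, by the orientation
    convention.  Accepts a FieldRecord (standardized with the model's stored
    parameters) or an already-standardized D-vector.
    """
    if isinstance(field, FieldRecord):
        x = np.concatenate([field.thresholds, [field.age]])[:model.D]
        if model.standardization is None:
            raise ValueError("model has no standardization parameters")
        z = (x - np.asarray(model.standardization["center"])) \
            / np.asarray(model.standardization["scale"])
    else:
        z = np.asarray(field, dtype=float)
    if z.shape != (model.D,):
        raise ValueError(f"field dimension {z.shape} does not match model D={model.D}")
    mu_n = model.clusters[axis.anchor_cluster_index].m_mu
    return float((z - mu_n) @ axis.direction / axis.projection_sd)


def render_pattern(grid: PatternGrid, output_path: str | Path) -> Path:
    """Write a total-deviation-style heatmap: red = loss, green = gain,
    numeric deviation printed at each of the 52 points, age annotated.
    Purely presentational; nothing reads images back."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = grid.layout.coordinates()
    lim = float(np.max(np.abs(grid.deviations))) or 1.0
    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    sc = ax.scatter(coords[:, 0], coords[:, 1], c=grid.deviations,
                    cmap="RdYlGn", vmin=-lim, vmax=lim, s=600, edgecolors="k")
    for (x, y), v in zip(coords, grid.deviations):
        ax.annotate(f"{v:.1f}", (x, y), ha="center", va="center", fontsize=6)
    age_txt = "" if grid.age is None else f", age {grid.age:.1f} y"
    ax.set_title(f"cluster {grid.cluster_index} axis {grid.axis_index} "
                 f"at {grid.k:+.1f} SD{age_txt}")
    ax.set_xlabel("x (deg)")
    ax.set_ylabel("y (deg)")
    ax.set_aspect("equal")
    fig.colorbar(sc, ax=ax, label="deviation (dB)")
    output_path = Path(output_path)
    output_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(output_path, dpi=120)
    plt.close(fig)
    return output_path
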