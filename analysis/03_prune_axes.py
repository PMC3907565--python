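#!/usr/bin/env python
"""Knee-point axis selection and constrained retraining of the selected model.

Ranks each cluster's axes by magnitude, cuts at the knee of the scree curve
(maximum discrete curvature), retrains with the reduced axis counts, and
writes the axis report (magnitude, projection SD, orientation, nearest-axis
member counts) plus the magnitude-vs-rank plot.
"""

from pathlib import Path

import numpy as np

from fdtica import VimModel, feature_matrix, knee_point, load_cohort, orient_axes, prune_and_retrain
from fdtica.axis_model import assign_to_nearest_axis, axis_report
from fdtica.evaluation import confusion
from fdtica.vbica import axis_magnitudes, refresh_local_posteriors

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = load_cohort(OUT / "cohort.csv")
    model = VimModel.load(OUT / "best_model.json")
    X, _ = feature_matrix(cohort)
    Z = (X - np.asarray(model.standardization["center"])) \
        / np.asarray(model.standardization["scale"])
    refresh_local_posteriors(model, Z)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    retained = []
    for k in range(model.K):
        mags = np.sort(axis_magnitudes(model, k))[::-1]
        keep = knee_point(mags)
        retained.append(keep)
        ax.plot(np.arange(1, mags.size + 1), mags, marker="o",
                label=f"cluster {k} (keep {keep})")
    ax.set_xlabel("axis rank")
    ax.set_ylabel("axis magnitude")
    ax.legend()
    fig.savefig(OUT / "axis_magnitudes.png", dpi=120)

    pruned = prune_and_retrain(model, retained, Z, n_iterations=150)
    labels = cohort.labels()
    conf = confusion(pruned.hard_assignments(), labels, pruned.K)
    normal_idx = conf.normal_cluster_index()
    axes = orient_axes(pruned, normal_idx, Z, labels)
    counts = {}
    for k in range(pruned.K):
        _, choice = assign_to_nearest_axis(pruned, Z, k, axes)
        local = [a.axis_index for a in axes if a.cluster_index == k]
        for pos, ax_idx in enumerate(local):
            counts[(k, ax_idx)] = int(np.sum(choice == pos))
    axis_report(axes, counts).to_csv(OUT / "axis_report.csv", index=False)
    pruned.save(OUT / "pruned_model.json")

    print(f"retained axes per cluster: {retained}")
    print(f"post-retraining: {conf.display()}; normal cluster = {normal_idx}")
    print(conf.to_frame().to_string())


if __name__ == "__main__":
    main()
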