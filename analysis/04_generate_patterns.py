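#!/usr/bin/env python
"""Generate defect patterns at +/-2 SD along every retained axis.

Each pattern is the field obtained by moving 2 projection-SDs from the
normal-cluster centroid along an oriented axis, expressed as simulated
total-deviation values (dB) on the 24-2 grid; rendered with red = loss,
green = gain, and the generated age annotated.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fdtica import VimModel, feature_matrix, generate_axis_pattern, load_cohort, orient_axes, render_pattern
from fdtica.evaluation import confusion
from fdtica.vbica import refresh_local_posteriors

OUT = Path(__file__).resolve().parents[1] / "results"
K_SD = 2.0


def main() -> None:
    cohort = load_cohort(OUT / "cohort.csv")
    model = VimModel.load(OUT / "pruned_model.json")
    X, _ = feature_matrix(cohort)
    Z = (X - np.asarray(model.standardization["center"])) \
        / np.asarray(model.standardization["scale"])
    refresh_local_posteriors(model, Z)
    labels = cohort.labels()
    conf = confusion(model.hard_assignments(), labels, model.K)
    axes = orient_axes(model, conf.normal_cluster_index(), Z, labels)

    rows = []
    for a in axes:
        for k in (-K_SD, K_SD):
            grid = generate_axis_pattern(model, a, k)
            rows.append({
                "cluster": a.cluster_index, "axis": a.axis_index, "k": k,
                "age": grid.age,
                "superior_mean_db": grid.superior_mean(),
                "inferior_mean_db": grid.inferior_mean(),
                **{f"p{i+1:02d}": d for i, d in enumerate(grid.deviations)},
            })
            render_pattern(grid, OUT / "figures" /
                           f"pattern_c{a.cluster_index}_a{a.axis_index}_k{k:+.0f}.png")
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "patterns.csv", index=False)
    print(f"wrote {len(rows)} patterns; +2 SD hemifield means (dB):")
    plus = df[df["k"] > 0]
    print(plus[["cluster", "axis", "superior_mean_db", "inferior_mean_db", "age"]]
          .round(2).to_string(index=False))


if __name__ == "__main__":
    main()
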