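#!/usr/bin/env python
"""Fit the candidate-model grid and select the best model.

The demo grid is a reduced version of the full protocol (which enumerates
K in 2-5, L_max in {10, 20}, m in {3, 6, 8} with 30 restarts = 720 models):
here K in {2, 3, 4}, L_max 10, m = 3, 5 restarts, 150 training sweeps per
fit, which keeps the search under a few minutes on one CPU while preserving
the selection logic.  Writes the search table (one row per candidate), the
specificity/sensitivity scatter, and the selected model.
"""

from pathlib import Path

from fdtica import SearchGrid, load_cohort, run_search, select_best
from fdtica.model_search import search_table

MASTER_SEED = 20140
OUT = Path(__file__).resolve().parents[1] / "results"

GRID = SearchGrid(cluster_counts=(2, 3, 4), axis_maxima=(10,),
                  mixture_components=(3,), n_restarts=5,
                  n_iterations=150, master_seed=MASTER_SEED)


def main() -> None:
    cohort = load_cohort(OUT / "cohort.csv")
    candidates = run_search(cohort, GRID)
    table = search_table(candidates)
    table.to_csv(OUT / "search_table.csv", index=False)

    best = select_best(candidates, spec_goal=0.90)
    best.fit.model.save(OUT / "best_model.json")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.scatter(table["specificity"], table["sensitivity"], s=16, alpha=0.7)
    sel = best.confusion
    ax.scatter([sel.specificity], [sel.sensitivity], marker="x", color="red",
               label="selected")
    ax.set_xlabel("specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    fig.savefig(OUT / "search_scatter.png", dpi=120)

    print(f"{len(candidates)} candidate models fitted")
    print(f"selected: K={best.config.K}, L_max={best.config.L_max}, "
          f"m={best.config.m}, seed={best.seed}")
    print(f"selected-model training scores: {best.confusion.display()}")


if __name__ == "__main__":
    main()
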