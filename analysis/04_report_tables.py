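#!/usr/bin/env python
"""Stage 4 — summary tables.

Reads the study reports and prints/writes the derived summaries: the
year-by-month AUC grid with row averages, counts of monthly AUCs above
0.7 per engine, overall averages, and the projection-year table.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import pandas as pd
from common import load_config

from fjordsdm import evaluation


def main() -> None:
    cfg = load_config()
    study = cfg["paths"]["study"]
    grid_frame = pd.read_csv(study / "auc_grid.csv", index_col=[0, 1])
    grid = evaluation.ResultsGrid(grid_frame)
    summary = evaluation.summarize_grid(grid, threshold=0.7)

    print("Monthly mean CV AUC grid:")
    print(grid_frame.round(3).to_string())
    print("\nRow (year x engine) averages:")
    print(summary.row_averages.to_string())
    print("\nCells above AUC 0.7:")
    for kind in sorted(summary.counts_above):
        print(f"  {kind}: {summary.counts_above[kind]}/{summary.total_cells[kind]} "
              f"({summary.percent_above[kind]}%), overall average "
              f"{summary.overall_averages[kind]:.3f}")

    proj = pd.read_csv(study / "projections.csv")
    print("\nProjection year:")
    print(proj.to_string(index=False))
    for kind, grp in proj.groupby("model_kind"):
        print(f"  {kind} projection average AUC: {evaluation.round3(grp['auc'].mean()):.3f}")

    out = study / "summary.csv"
    summary.row_averages.rename("mean_auc").to_csv(out)
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
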