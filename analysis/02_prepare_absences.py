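#!/usr/bin/env python
"""Stage 2 — effort-based pseudo-absences.

For each study month: count the pseudo-absences from the effort formula
(hours x 4 + days x 5), build the trackline kernel-density surface, and
sample that many background points.  Writes results/data/absences.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import pandas as pd
from common import build_world, load_config

from fjordsdm import projection, pseudo_absence


def main() -> None:
    cfg = load_config()
    out = cfg["paths"]["data"]
    out.mkdir(parents=True, exist_ok=True)
    world = build_world(cfg)

    frames = []
    for m in sorted(world):
        d = world[m]
        seed = projection.derive_seed(cfg["seed"], "table", m)
        absences = pseudo_absence.absences_for_month(
            d.effort, d.tracklines, projection.water_grid(d.stack), seed
        )
        frames.append(absences.to_frame())
        print(f"{m}: {d.effort.effort_hours:.0f} h, {d.effort.search_days} d "
              f"-> {pseudo_absence.n_pseudo_absences(d.effort)} pseudo-absences")
    pd.concat(frames, ignore_index=True).to_csv(out / "absences.csv", index=False)
    print(f"wrote absences.csv to {out}")


if __name__ == "__main__":
    main()
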