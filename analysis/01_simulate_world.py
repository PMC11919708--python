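#!/usr/bin/env python
"""Stage 1 — simulate the synthetic study system.

Builds the multi-month synthetic bay (covariate stacks, true suitability,
boat tours, sightings) and writes the observation-level inputs — sightings,
effort and tracklines — under results/data/.  Rasters stay in memory for
the later stages, which rebuild the world deterministically from the seed.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import build_world, load_config

from fjordsdm import io_adapters


def main() -> None:
    cfg = load_config()
    out = cfg["paths"]["data"]
    out.mkdir(parents=True, exist_ok=True)
    world = build_world(cfg)

    frames = [world[m].sightings.to_frame() for m in sorted(world)]
    import pandas as pd

    pd.concat(frames, ignore_index=True).to_csv(out / "sightings.csv", index=False)
    io_adapters.write_effort([world[m].effort for m in sorted(world)], out / "effort.csv")
    tracklines = [tl for m in sorted(world) for tl in world[m].tracklines]
    io_adapters.write_tracklines(tracklines, out / "tracklines.geojson")

    for m in sorted(world):
        d = world[m]
        print(f"{m}: {len(d.sightings)} sightings, "
              f"{d.effort.effort_hours:.0f} h effort over {d.effort.search_days} days, "
              f"{len(d.tracklines)} tours")
    print(f"wrote sightings.csv, effort.csv, tracklines.geojson to {out}")


if __name__ == "__main__":
    main()
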