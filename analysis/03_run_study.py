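#!/usr/bin/env python
"""Stage 3 — the monthly model comparison and the projection year.

Runs the full study: per training month, fits MaxEnt from scratch and
warm-start-updates the network lineage, scores both with stratified
10-fold cross-validation and held-out permutation importance; then runs
both projection protocols for the held-back year.  Writes the CSV
reports, the final network, and a checksummed run manifest under
results/study/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import build_world, load_config, study_config

from fjordsdm import io_adapters, neural, projection


def main() -> None:
    cfg = load_config()
    out = cfg["paths"]["study"]
    out.mkdir(parents=True, exist_ok=True)
    world = build_world(cfg)
    study_cfg = study_config(cfg, out_dir=out)

    result = projection.run_study(study_cfg, world)

    neural.save_mlp(result.final_mlp, out / "final_network.json")
    manifest = io_adapters.RunManifest(
        config={k: v for k, v in cfg.items() if k != "paths"},
        seeds={"master": cfg["seed"]},
        counts={
            "training_months": len(cfg["months"]["training"]),
            "projection_months": len(cfg["months"]["projection"]),
            "eval_reports": len(result.eval_reports),
            "projections": len(result.projections),
        },
    )
    for name in ("monthly_eval.csv", "auc_grid.csv", "projections.csv", "final_network.json"):
        manifest.add_output(out / name)
    manifest.write(out / "manifest.json")

    for rep in result.eval_reports:
        print(f"{rep.month_id} {rep.model_kind:>6}: mean CV AUC {rep.mean_auc:.3f} ({rep.band})")
    for p in result.projections:
        flag = "  [low support]" if p.low_support_flag else ""
        print(f"projection {p.month_id} {p.model_kind:>6}: AUC {p.auc_vs_actual:.3f} "
              f"on {p.n_test_sightings} test sightings{flag}")
    print(f"wrote reports and manifest to {out}")


if __name__ == "__main__":
    main()
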