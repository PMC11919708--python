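"""Shared plumbing for the numbered analysis drivers."""

from __future__ import annotations

from pathlib import Path

import yaml

from fjordsdm import neural, projection

ROOT = Path(__file__).resolve().parent.parent
CONFIG_PATH = Path(__file__).resolve().parent / "config.yaml"


def load_config() -> dict:
    with open(CONFIG_PATH) as fh:
        cfg = yaml.safe_load(fh)
    cfg["paths"] = {k: ROOT / v for k, v in cfg["paths"].items()}
    return cfg


def all_months(cfg: dict) -> list[str]:
    return list(cfg["months"]["training"]) + list(cfg["months"]["projection"])


def build_world(cfg: dict) -> dict:
    w = cfg["world"]
    return projection.build_synthetic_world(
        all_months(cfg),
        shape=tuple(w["shape"]),
        cell_size=float(w["cell_size"]),
        seed=int(cfg["seed"]),
        n_sightings=int(w["n_sightings"]),
        tours_range=tuple(w["tours_range"]),
    )


def study_config(cfg: dict, out_dir=None) -> projection.StudyConfig:
    me = cfg["engines"]["maxent"]
    net = cfg["engines"]["network"]
    ev = cfg["evaluation"]
    return projection.StudyConfig(
        training_months=list(cfg["months"]["training"]),
        projection_months=list(cfg["months"]["projection"]),
        maxent_beta=float(me["beta"]),
        maxent_knots=int(me["knots_per_covariate"]),
        maxent_max_iterations=int(me["max_iterations"]),
        mlp_config=neural.TrainConfig(
            l1_strength=float(net["l1_strength"]),
            learning_rate=float(net["learning_rate"]),
            max_iterations=int(net["max_iterations"]),
            patience=int(net["patience"]),
        ),
        cv_folds=int(ev["cv_folds"]),
        importance_repeats=int(ev["importance_repeats"]),
        min_support=int(ev["min_support"]),
        seed=int(cfg["seed"]),
        out_dir=out_dir,
    )
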