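# fjordsdm

Comparing a from-scratch maximum-entropy model (MaxEnt) with a small
feedforward neural network as presence-only species distribution models
(SDMs), on a fully synthetic fjord survey system with effort-based
pseudo-absences.

## The scientific problem

Whale survey programmes produce *presence-only* data: sightings logged by
whale-watching boats, with no systematic record of where whales were
absent. Fitting an SDM to such data requires synthetic absences — and if
those are placed uniformly at random, the model partly learns where boats
go rather than where whales are. This package implements the
effort-correction approach of a monthly fjord survey study: the number of
pseudo-absences per month follows the effort formula

```
count = effort_hours × 4 + search_days × 5
```

and the points are placed proportionally to the kernel-smoothed density
of the month's boat tracklines, so the absence sample mirrors the
observation process that produced the presences.

On top of that observation model, two engines are compared month by
month:

- **MaxEnt** — hinge-feature maximum entropy with L1-penalized gain
  maximization, retrained from zero weights each month;
- **a 6-16-32-64-1 network** — ReLU hidden layers, sigmoid output,
  full-batch gradient descent on cross-entropy + L1, *continuously
  updated*: each month warm-starts from the previous month's weights.

Both are scored by stratified 10-fold cross-validated AUC with held-out
permutation importance, then projected onto a held-back year — MaxEnt by
refitting on pooled same-calendar-month history over year-averaged
covariates, the network by projecting its final lineage model without
retraining.

Everything runs on a synthetic study system with a *known* true
suitability surface (see `docs/methods.md`), so model recovery is
testable end to end without any downloads.

## Worked example

The numbered drivers under `analysis/` run the full study configured by
`analysis/config.yaml` (two training years of the May–August season, one
projection year, 64×64 grid, master seed 7):

```
python analysis/01_simulate_world.py    # synthetic world + survey logs
python analysis/02_prepare_absences.py  # effort-based pseudo-absences
python analysis/03_run_study.py         # both engines, all months (~45 s)
python analysis/04_report_tables.py     # summary tables
```

Stage 2 prints the effort formula at work:

```
2018-05: 153 h, 28 d -> 752 pseudo-absences
2018-06: 102 h, 24 d -> 528 pseudo-absences
2018-07: 117 h, 28 d -> 608 pseudo-absences
...
```

Stage 3 fits and scores both engines per month and projects the
held-back year:

```
2018-05 maxent: mean CV AUC 0.809 (good)
2018-05     dl: mean CV AUC 0.800 (satisfactory)
2018-06 maxent: mean CV AUC 0.768 (satisfactory)
2018-06     dl: mean CV AUC 0.777 (satisfactory)
...
projection 2020-05 maxent: AUC 0.769 on 150 test sightings
projection 2020-05     dl: AUC 0.750 on 150 test sightings
projection 2020-06 maxent: AUC 0.820 on 150 test sightings
projection 2020-06     dl: AUC 0.837 on 150 test sightings
```

Stage 4 assembles the results grid and derived summaries:

```
Monthly mean CV AUC grid:
                   May   June   July  August
year model_kind
2018 dl          0.800  0.777  0.781   0.823
     maxent      0.809  0.768  0.772   0.818
2019 dl          0.763  0.687  0.743   0.741
     maxent      0.756  0.694  0.738   0.730

Cells above AUC 0.7:
  dl: 7/8 (88%), overall average 0.764
  maxent: 7/8 (88%), overall average 0.761

  dl projection average AUC: 0.780
  maxent projection average AUC: 0.777
```

Reports land under `results/study/` (`monthly_eval.csv`, `auc_grid.csv`,
`projections.csv`, the serialized final network, and a checksummed run
manifest). Reruns with the same config and seed are byte-identical.

## Library layout

| Module | Role |
| --- | --- |
| `fjordsdm.grids` | planar raster grid with nodata mask, point↔cell mapping |
| `fjordsdm.synthetic` | synthetic bathymetry, monthly covariate fields, true suitability, boat tours, sightings |
| `fjordsdm.covariates` | the six-covariate stack, resampling, point extraction, collinearity screening |
| `fjordsdm.pseudo_absence` | effort formula, trackline kernel density, absence sampling |
| `fjordsdm.maxent` | hinge basis, gain, proximal-gradient fit, cloglog prediction |
| `fjordsdm.neural` | 6-16-32-64-1 MLP, backprop training, warm-started monthly updates, serialization |
| `fjordsdm.evaluation` | rank AUC, stratified k-fold CV, permutation importance, results-grid arithmetic |
| `fjordsdm.projection` | projection protocols, the `run_study` driver, synthetic world builder |
| `fjordsdm.io_adapters` | ESRI ASCII rasters, CSV points/effort, GeoJSON tracklines, run manifests |

## Reproduction

- Full test suite (unit, property and acceptance tests):

  ```
  python -m pytest -q tests/
  ```

  The acceptance tests in `tests/test_acceptance.py` check, among other
  things, that both engines recover a known synthetic suitability with
  mean 10-fold CV AUC ≥ 0.75 on an 8-month study and that identical
  seeds yield byte-identical reports.

- Headline acceptance targets (the five effort-formula counts):

  ```
  python scripts/acceptance.py --seed 1 --out results/acceptance.json
  ```

  prints

  ```
  t1: 618
  t2: 825
  t3: 785
  t4: 341
  t5: 523
  ```

- The analysis drivers above regenerate every file under `results/`
  deterministically from `analysis/config.yaml`.

Methodological details — model assumptions, parameter choices, numerical
decisions, and the generator's known limitations — are documented in
`docs/methods.md`.
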