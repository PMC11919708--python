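"""Model scoring: AUC, 10-fold cross-validation, quality bands,
permutation importance, and the monthly results grid arithmetic.

AUC uses the Mann–Whitney rank construction (probability that a random
presence outscores a random pseudo-absence, ties counting one half), so
it is invariant to any strictly increasing transform of the scores —
which is what makes MaxEnt's and the network's differently-scaled outputs
comparable.

Quality bands follow the conventional thresholds: < 0.6 bad, 0.6–0.7
poor, 0.7–0.8 satisfactory, 0.8–0.9 good, > 0.9 excellent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .covariates import COVARIATES
from .maxent import TrainingTable


def auc(scores_presence, scores_absence) -> float:
    """Rank-based AUC; ties count one half (Mann–Whitney U / (m n))."""
    sp = np.asarray(scores_presence, dtype=float)
    sa = np.asarray(scores_absence, dtype=float)
    if sp.size == 0 or sa.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([sp, sa]))
    u = ranks[: sp.size].sum() - sp.size * (sp.size + 1) / 2
    return float(u / (sp.size * sa.size))


def quality_band(mean_auc: float) -> str:
    if mean_auc < 0.6:
        return "bad"
    if mean_auc < 0.7:
        return "poor"
    if mean_auc <= 0.8:
        return "satisfactory"
    if mean_auc <= 0.9:
        return "good"
    return "excellent"


@dataclass
class EvalReport:
    month_id: str
    model_kind: str  # "maxent" | "dl"
    fold_aucs: list[float]
    mean_auc: float
    band: str = ""
    permutation_importance: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.band:
            self.band = quality_band(self.mean_auc)


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold index per row; presence/absence proportions preserved.

    Within each label class, rows are shuffled and dealt round-robin, so
    class counts per fold differ by at most one.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    fold = np.empty(len(labels), dtype=int)
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        if len(idx) < k:
            raise ValueError(f"label {lab} has fewer rows ({len(idx)}) than folds ({k})")
        idx = rng.permutation(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold


def crossval_auc(
    fit_and_score,
    table: TrainingTable,
    k: int = 10,
    seed: int = 0,
    month_id: str = "",
    model_kind: str = "",
) -> EvalReport:
    """k-fold cross-validated AUC.

    ``fit_and_score(train_table, test_X) -> scores`` trains on the fold
    complement and scores the held-out raw covariate rows.
    """
    y = table.y
    folds = stratified_folds(y, k, seed)
    fold_aucs = []
    for f in range(k):
        test = folds == f
        train_tab = TrainingTable(table.frame.loc[~test].reset_index(drop=True))
        test_X = table.X[test]
        scores = np.asarray(fit_and_score(train_tab, test_X), dtype=float)
        y_test = y[test]
        fold_aucs.append(auc(scores[y_test == 1], scores[y_test == 0]))
    mean_auc = float(np.mean(fold_aucs))
    return EvalReport(month_id, model_kind, fold_aucs, mean_auc, seed=seed)


def permutation_importance(
    predict, test_table: TrainingTable, seed: int = 0, n_repeats: int = 10
) -> dict[str, float]:
    """Per-covariate AUC-drop importance, as percentages summing to 100.

    Each covariate column is shuffled ``n_repeats`` times; the mean drop
    in AUC (floored at 0) is normalised across covariates.  If no
    covariate produces a drop the importances are uniform, with a warning.
    """
    X = test_table.X
    y = test_table.y
    if len(X) < 2:
        raise ValueError("need at least two test rows")
    rng = np.random.default_rng(seed)
    base_scores = np.asarray(predict(X), dtype=float)
    base_auc = auc(base_scores[y == 1], base_scores[y == 0])
    drops = np.zeros(len(COVARIATES))
    for j in range(len(COVARIATES)):
        acc = 0.0
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            s = np.asarray(predict(Xp), dtype=float)
            acc += base_auc - auc(s[y == 1], s[y == 0])
        drops[j] = max(0.0, acc / n_repeats)
    total = drops.sum()
    if total == 0:
        warnings.warn("no covariate permutation reduced the AUC; importances set uniform")
        pct = np.full(len(COVARIATES), 100.0 / len(COVARIATES))
    else:
        pct = 100.0 * drops / total
    return dict(zip(COVARIATES, pct.tolist()))


# -- results grid ------------------------------------------------------------

MONTH_COLUMNS = ("March", "April", "May", "June", "July", "August", "September", "October")


@dataclass
class ResultsGrid:
    """(year, model_kind) rows x month columns of mean AUCs."""

    table: pd.DataFrame  # MultiIndex (year, model_kind), columns = month names

    def yearly_averages(self) -> pd.Series:
        return self.table.mean(axis=1, skipna=True).round(3)


def round3(x: float) -> float:
    """Report rounding: 3 decimals, round-half-even."""
    return float(np.round(x, 3))


@dataclass
class GridSummary:
    row_averages: pd.Series
    counts_above: dict[str, int]
    percent_above: dict[str, int]
    overall_averages: dict[str, float]
    threshold: float
    total_cells: dict[str, int] = field(default_factory=dict)


def summarize_grid(grid: ResultsGrid, threshold: float = 0.7) -> GridSummary:
    """Row averages (3 decimals), strict-> counts above the threshold per
    model, rounded percentages, and per-model overall averages."""
    tab = grid.table
    if tab.size == 0:
        raise ValueError("empty results grid")
    row_avg = tab.mean(axis=1, skipna=True).round(3)
    counts, pcts, overall, totals = {}, {}, {}, {}
    for kind in tab.index.get_level_values("model_kind").unique():
        sub = tab.xs(kind, level="model_kind")
        cells = sub.to_numpy().ravel()
        cells = cells[~np.isnan(cells)]
        counts[kind] = int((cells > threshold).sum())
        totals[kind] = int(cells.size)
        pcts[kind] = int(np.round(100.0 * counts[kind] / cells.size))
        overall[kind] = round3(float(cells.mean()))
    return GridSummary(row_avg, counts, pcts, overall, threshold, totals)


def grid_from_records(records: list[tuple[int, str, str, float]]) -> ResultsGrid:
    """Build a ResultsGrid from (year, model_kind, month_name, mean_auc)."""
    frame = pd.DataFrame(records, columns=["year", "model_kind", "month", "auc"])
    tab = frame.pivot_table(
        index=["year", "model_kind"], columns="month", values="auc", aggfunc="first"
    )
    present = [m for m in MONTH_COLUMNS if m in tab.columns]
    return ResultsGrid(tab[present])
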