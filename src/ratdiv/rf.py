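"""Random-forest regression of Ho on the five predictors.

The forest size is chosen by a gridded search over candidate tree counts
(10 to 10,000 by default), keeping the fit with the smallest out-of-bag
(OOB) root mean square error.  Validation is a jackknife (leave-one-out,
without replacement): with fewer than a hundred localities per species, each
record is predicted by a forest trained on all the others.  Predictor
importance is the impurity (variance-reduction, "Gini") importance summed
over the forest, reported raw and max-normalized so the top predictor scores
exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.ensemble._forest import (  # bootstrap bookkeeping for OOB error
    _generate_unsampled_indices,
    _get_n_samples_bootstrap,
)

from .grid import PREDICTORS, AnalysisTable

DEFAULT_TREE_GRID = (10, 25, 50, 100, 250, 500, 1000, 2500, 5000, 10000)


@dataclass(frozen=True)
class RFConfig:
    """Forest hyperparameters; only the tree count is searched."""

    tree_grid: tuple[int, ...] = DEFAULT_TREE_GRID
    variables_per_split: int = 2   # floor(sqrt(5)), the regression default
    min_node_size: int = 5
    seed: int = 0

    def __post_init__(self):
        grid = tuple(self.tree_grid)
        if not grid:
            raise ValueError("tree_grid must be non-empty")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("tree_grid must be strictly increasing")
        if grid[0] < 10 or grid[-1] > 10000:
            raise ValueError("tree_grid must lie within [10, 10000]")
        object.__setattr__(self, "tree_grid", grid)


@dataclass
class RFFit:
    """A fitted forest plus the quantities reported about it."""

    n_trees: int
    oob_rmse: float
    importance_raw: dict[str, float]
    importance_norm: Optional[dict[str, float]]
    seed: int
    model: RandomForestRegressor
    ho_range: tuple[float, float]
    oob_coverage: float                      # fraction of records with OOB preds
    oob_rmse_grid: dict[int, float] = field(default_factory=dict)
    jackknife_pred: Optional[np.ndarray] = None
    jackknife_rmse: Optional[float] = None
    obs_pred_r2: Optional[float] = None
    obs_pred_p: Optional[float] = None


def _oob_predictions(model: RandomForestRegressor, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-record OOB predictions and a coverage mask.

    Averages each tree's prediction over the records left out of its
    bootstrap draw.  Records sampled by every tree (possible for very small
    forests) are flagged uncovered rather than filled with a default.
    """
    n = X.shape[0]
    total = np.zeros(n)
    count = np.zeros(n, dtype=int)
    n_boot = _get_n_samples_bootstrap(n, model.max_samples, None)
    for tree in model.estimators_:
        idx = _generate_unsampled_indices(tree.random_state, n, n_boot, None)
        if idx.size:
            total[idx] += tree.predict(X[idx])
            count[idx] += 1
    covered = count > 0
    pred = np.full(n, np.nan)
    pred[covered] = total[covered] / count[covered]
    return pred, covered


def fit_forest(table: AnalysisTable, n_trees: int, config: RFConfig) -> RFFit:
    """Fit one bootstrap regression forest and evaluate it out-of-bag.

    Raises ValueError("insufficient records") below 10 records.  With a
    constant response every tree is a single leaf: OOB RMSE is 0 and all raw
    importances are 0.
    """
    if table.n < 10:
        raise ValueError("insufficient records")
    X = table.predictors.to_numpy(dtype=float)
    y = table.ho
    model = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=config.variables_per_split,
        min_samples_leaf=config.min_node_size,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    pred, covered = _oob_predictions(model, X)
    if covered.any():
        oob_rmse = float(np.sqrt(np.mean((pred[covered] - y[covered]) ** 2)))
    else:
        oob_rmse = float("nan")
    raw = dict(zip(PREDICTORS, model.feature_importances_.astype(float)))
    norm = None
    if max(raw.values()) > 0:
        norm = normalize_importance(raw)
    return RFFit(
        n_trees=n_trees,
        oob_rmse=oob_rmse,
        importance_raw=raw,
        importance_norm=norm,
        seed=config.seed,
        model=model,
        ho_range=(float(y.min()), float(y.max())),
        oob_coverage=float(covered.mean()),
    )


def normalize_importance(importance_raw: dict[str, float]) -> dict[str, float]:
    """Scale raw impurity importances so the largest equals exactly 1."""
    top = max(importance_raw.values())
    if top <= 0:
        raise ValueError("degenerate importance vector (all zero)")
    return {k: v / top for k, v in importance_raw.items()}


def grid_search_trees(table: AnalysisTable, config: RFConfig) -> RFFit:
    """Fit one forest per candidate size; keep the minimal-OOB-RMSE fit.

    All candidates share the config seed.  Ties resolve to the smallest
    forest (candidates are visited in increasing order with a strict
    comparison).  The per-candidate OOB RMSEs are recorded on the winner.
    """
    best: Optional[RFFit] = None
    grid_rmse: dict[int, float] = {}
    for n_trees in config.tree_grid:
        fit = fit_forest(table, n_trees, config)
        grid_rmse[n_trees] = fit.oob_rmse
        if best is None or fit.oob_rmse < best.oob_rmse:
            best = fit
    best.oob_rmse_grid = grid_rmse
    return best


def _canonical_order(table: AnalysisTable) -> np.ndarray:
    """A record ordering independent of input row order (for seed stability)."""
    meta = table.meta
    keys = np.lexsort(
        (table.ho, meta["site"].to_numpy(), meta["study_id"].to_numpy(),
         meta["lat"].to_numpy(), meta["lon"].to_numpy())
    )
    return keys


def jackknife_validate(
    table: AnalysisTable, config: RFConfig, n_trees: int
) -> tuple[np.ndarray, float, float, float]:
    """Leave-one-out validation: each record predicted by a forest on the rest.

    Records are processed in a canonical order (sorted by coordinates, study,
    site, Ho) with per-record seed ``config.seed + canonical position``, so
    the held-out predictions do not depend on input row order.  Returns
    (predictions aligned to the input rows, RMSE, R^2 and p-value of the
    least-squares regression of observed on predicted Ho).
    """
    n = table.n
    if n < 3:
        raise ValueError("need at least 3 records for jackknife validation")
    X = table.predictors.to_numpy(dtype=float)
    y = table.ho
    order = _canonical_order(table)
    Xs, ys = X[order], y[order]
    pred = np.full(n, np.nan)
    for pos, i in enumerate(order):
        keep = np.ones(n, dtype=bool)
        keep[pos] = False
        model = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=config.variables_per_split,
            min_samples_leaf=config.min_node_size,
            bootstrap=True,
            random_state=config.seed + pos,
            n_jobs=1,
        )
        model.fit(Xs[keep], ys[keep])
        pred[i] = model.predict(X[i:i + 1])[0]
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    if np.ptp(pred) == 0 or np.ptp(y) == 0:
        r2, p = float("nan"), float("nan")
    else:
        fitline = stats.linregress(pred, y)
        r2, p = float(fitline.rvalue**2), float(fitline.pvalue)
    return pred, rmse, r2, p
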