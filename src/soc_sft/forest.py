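"""Weighted random forest ("meta-forest") over effect sizes.

A random forest regression of back-transformed effect sizes (percentage SOC
change) on environmental moderators, with the meta-analytic case weights
w_i = 1/(v_i + tau^2) propagated into both stages of the ensemble: each
tree's bootstrap sample is drawn with probability proportional to w_i, and
the drawn multiplicities additionally weight the split-improvement criterion
inside the tree.  With uniform weights this reduces to ordinary bagged
regression trees.

Variable importance follows the split-improvement convention: for every
split, the weighted decrease in squared error it achieves is credited to the
splitting variable; credits are summed per tree, averaged over the ensemble
and normalized to sum to one.  Importances of the one-hot columns of a
categorical predictor are summed back into the parent variable.

Prediction uncertainty is the across-tree standard deviation of the per-tree
predictions, as used for per-pixel uncertainty in gridded mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

__all__ = ["ForestModel", "fit_metaforest", "variable_importance",
           "predict_with_uncertainty", "aggregate_absolute_loss",
           "save_model", "load_model", "DEFAULT_PREDICTORS"]

FORMAT_VERSION = 1

#: environmental predictor set: baseline soil carbon, soil, climate,
#: topography and vegetation descriptors of each paired comparison
DEFAULT_PREDICTORS = (
    "baseline_soc", "soil_order", "layer", "mat", "map", "aridity_index",
    "pci", "summer_frac", "delta_t", "delta_map", "elevation", "landform",
    "npp", "biome",
)

DEFAULT_GRID = {
    "n_trees": (250, 500),
    "max_features": ("third", "sqrt"),
    "min_samples_leaf": (3, 5),
}


@dataclass
class ForestModel:
    trees: list = field(default_factory=list)
    feature_names: list = field(default_factory=list)
    predictors: list = field(default_factory=list)
    categories: dict = field(default_factory=dict)  # categorical col -> levels
    params: dict = field(default_factory=dict)
    cv_metrics: dict = field(default_factory=dict)  # {"rmse": ..., "r2": ...}
    weights: np.ndarray | None = None
    format_version: int = FORMAT_VERSION

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def _encode(table: pd.DataFrame, predictors, categories=None):
    """One-hot encode declared categorical predictors; returns (X, names,
    categories, flagged) where ``flagged`` marks rows with unseen levels."""
    table = table[list(predictors)]
    cat_cols = [c for c in predictors if table[c].dtype == object
                or isinstance(table[c].dtype, pd.CategoricalDtype)]
    if categories is None:
        categories = {c: sorted(table[c].astype(str).unique()) for c in cat_cols}
    flagged = np.zeros(len(table), dtype=bool)
    parts, names = [], []
    for col in predictors:
        if col in categories:
            vals = table[col].astype(str)
            flagged |= ~vals.isin(categories[col]).to_numpy()
            for level in categories[col]:
                parts.append((vals == level).to_numpy(dtype=float))
                names.append(f"{col}={level}")
        else:
            parts.append(table[col].to_numpy(dtype=float))
            names.append(col)
    return np.column_stack(parts), names, categories, flagged


def _max_features(spec, p):
    if spec == "third":
        return max(1, int(np.ceil(p / 3)))
    if spec == "sqrt":
        return max(1, int(np.ceil(np.sqrt(p))))
    return int(spec)


def _fit_ensemble(X, y, w, n_trees, max_features, min_samples_leaf, rng):
    """Weighted-bootstrap bagging: sampling probability and split loss ~ w."""
    n = len(y)
    prob = w / w.sum()
    trees = []
    for _ in range(n_trees):
        idx = rng.choice(n, size=n, replace=True, p=prob)
        counts = np.bincount(idx, minlength=n).astype(float)
        tree = DecisionTreeRegressor(
            max_features=_max_features(max_features, X.shape[1]),
            min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(2 ** 31 - 1)),
        )
        tree.fit(X, y, sample_weight=counts * w)
        trees.append(tree)
    return trees


def _ensemble_predict(trees, X):
    return np.mean([t.predict(X) for t in trees], axis=0)


def fit_metaforest(table: pd.DataFrame, outcome: str = "percent_change",
                   weight_column: str = "weight",
                   predictors=DEFAULT_PREDICTORS, n_trees: int | None = None,
                   cv_folds: int = 5, seed: int = 0,
                   grid: dict = DEFAULT_GRID, min_effects: int = 30) -> ForestModel:
    """Fit the weighted forest with a small hyperparameter search.

    ``table`` holds one row per effect size with the outcome, the
    meta-analytic weight and all predictor columns.  Candidate
    hyperparameters (``grid``) are scored by k-fold cross-validated weighted
    RMSE; the best combination is refit on all rows and its CV RMSE/R2 are
    stored on the model.  Passing ``n_trees`` pins the ensemble size instead
    of searching over it.  Deterministic given ``seed``.
    """
    missing = [c for c in (*predictors, outcome) if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks columns {missing}")
    if len(table) < min_effects:
        raise ValueError(f"need >= {min_effects} effects, have {len(table)}")
    y = table[outcome].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant; nothing to fit")
    w = (table[weight_column].to_numpy(dtype=float) if weight_column in table.columns
         else np.ones(len(table)))
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    X, names, categories, flagged = _encode(table, predictors)
    if np.any(np.isnan(X)):
        raise ValueError("predictors contain missing values")

    combos = [{"n_trees": nt, "max_features": mf, "min_samples_leaf": ml}
              for nt in ((n_trees,) if n_trees else grid["n_trees"])
              for mf in grid["max_features"]
              for ml in grid["min_samples_leaf"]]

    def cv_score(params, seed_offset=0):
        rng = np.random.default_rng(seed + seed_offset)
        preds = np.empty_like(y)
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        for train, test in kf.split(X):
            trees = _fit_ensemble(X[train], y[train], w[train], rng=rng, **params)
            preds[test] = _ensemble_predict(trees, X[test])
        rmse = float(np.sqrt(np.average((preds - y) ** 2, weights=w)))
        r2 = float(r2_score(y, preds, sample_weight=w))
        return rmse, r2

    scores = [cv_score(p, i) for i, p in enumerate(combos)]
    best = int(np.argmin([s[0] for s in scores]))
    params = combos[best]
    rng = np.random.default_rng(seed)
    trees = _fit_ensemble(X, y, w, rng=rng, **params)
    return ForestModel(
        trees=trees, feature_names=names, predictors=list(predictors),
        categories=categories, params=params,
        cv_metrics={"rmse": scores[best][0], "r2": scores[best][1],
                    "folds": cv_folds},
        weights=w,
    )


def variable_importance(model: ForestModel) -> pd.Series:
    """Split-improvement importances per predictor, normalized to sum to 1."""
    if not model.trees:
        raise ValueError("model has no trees")
    raw = np.mean([t.tree_.compute_feature_importances(normalize=False)
                   for t in model.trees], axis=0)
    per_feature = pd.Series(raw, index=model.feature_names)
    agg = {}
    for pred in model.predictors:
        if pred in model.categories:
            cols = [f"{pred}={lvl}" for lvl in model.categories[pred]]
            agg[pred] = per_feature[cols].sum()
        else:
            agg[pred] = per_feature[pred]
    out = pd.Series(agg)
    total = out.sum()
    return (out / total if total > 0 else out).sort_values(ascending=False)


def predict_with_uncertainty(model: ForestModel, table: pd.DataFrame) -> pd.DataFrame:
    """Per-row ensemble mean and across-tree SD; unseen categorical levels
    are flagged (column ``flagged``) rather than silently coerced."""
    X, _, _, flagged = _encode(table, model.predictors, model.categories)
    per_tree = np.array([t.predict(X) for t in model.trees])
    return pd.DataFrame({
        "mean": per_tree.mean(axis=0),
        "sd": per_tree.std(axis=0, ddof=0) if len(model.trees) > 1 else 0.0,
        "flagged": flagged,
    }, index=table.index)


def aggregate_absolute_loss(stocks, percent_change) -> float:
    """Total absolute SOC change, sum(stock_i * percent_i / 100), over grid cells."""
    stocks = np.asarray(stocks, dtype=float)
    pct = np.asarray(percent_change, dtype=float)
    return float(np.sum(stocks * pct / 100.0))


def save_model(model: ForestModel, path) -> None:
    joblib.dump(model, path)


def load_model(path) -> ForestModel:
    model = joblib.load(path)
    if getattr(model, "format_version", None) != FORMAT_VERSION:
        raise ValueError("incompatible model archive version")
    return model
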