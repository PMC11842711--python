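"""Random-forest models of log median nutrient concentration.

Per analyte, ln(site median concentration) is modelled as a function of
the human-effect composite, latitude, biome, and biophysical covariates,
with each site's observation count as its sample weight.  Hyperparameters
are tuned by weighted 10-fold cross-validated mean absolute error (MAE);
predictors are then pruned by backward elimination on impurity importance
(latitude, human effect, and biome are never dropped, because the
reference-condition counterfactual must be expressible through them), and
the final model is chosen on held-out test MAE with a fewest-terms tie
rule.  Per-catchment prediction uncertainty comes from bootstrap
resampling of sites with replacement.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, train_test_split

FIXED_PREDICTORS = ("latitude", "human_effect", "biome")
MAX_TREES = 900

RESPONSE_COL = "ln_median"
WEIGHT_COL = "n_obs"


class UnknownBiomeError(KeyError):
    """A biome level absent from training appeared at prediction time."""


@dataclass(frozen=True)
class TuningGrid:
    """Candidate hyperparameter values for forest tuning.

    ``max_features`` entries may be ints or the tokens ``"sqrt"``
    (⌊√P⌋ features per split), ``"third"`` (⌊P/3⌋), and ``"all"``.
    The default grid includes deep trees (leaf size 1) and full-feature
    splits because the reference-condition counterfactual evaluates the
    forest at the extreme low end of the human-effect range, where shallow
    or heavily feature-subsampled trees attenuate the predicted response.
    """

    n_estimators: Sequence[int] = (300, 600, 900)
    max_features: Sequence[int | str] = ("sqrt", "all")
    min_samples_leaf: Sequence[int] = (1, 5)
    cv_folds: int = 10

    def __post_init__(self):
        if not self.n_estimators or not self.max_features or not self.min_samples_leaf:
            raise ValueError("tuning grid must be non-empty in every dimension")
        if any(t > MAX_TREES or t < 1 for t in self.n_estimators):
            raise ValueError(f"tree counts must be in [1, {MAX_TREES}]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def cells(self):
        return itertools.product(
            self.n_estimators, self.max_features, self.min_samples_leaf
        )


def _resolve_max_features(token: int | str, n_features: int) -> int:
    if isinstance(token, str):
        if token == "sqrt":
            return max(1, int(math.isqrt(n_features)))
        if token == "third":
            return max(1, n_features // 3)
        if token == "all":
            return n_features
        raise ValueError(f"unknown max_features token {token!r}")
    return max(1, min(int(token), n_features))


def encode_features(
    df: pd.DataFrame,
    predictors: Sequence[str],
    biome_levels: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str], tuple[str, ...]]:
    """Build the numeric design matrix; ``biome`` expands to one-hot columns."""
    cols, names = [], []
    levels: tuple[str, ...] = tuple(biome_levels) if biome_levels else ()
    for p in predictors:
        if p == "biome":
            if not levels:
                levels = tuple(sorted(df["biome"].unique()))
            unseen = set(df["biome"].unique()) - set(levels)
            if unseen:
                raise UnknownBiomeError(
                    f"biome level(s) {sorted(unseen)} absent from training data"
                )
            for lvl in levels:
                cols.append((df["biome"] == lvl).to_numpy(dtype=float))
                names.append(f"biome={lvl}")
        else:
            cols.append(df[p].to_numpy(dtype=float))
            names.append(p)
    return np.column_stack(cols), names, levels


def split_train_test(
    table: pd.DataFrame,
    frac: float = 0.75,
    seed: int = 0,
    response: str = RESPONSE_COL,
    stratify_bins: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split sites 75/25, stratified on response quantile bins.

    Stratification keeps the concentration distribution similar between
    the training and testing sets.
    """
    n = len(table)
    if n < 8:
        raise ValueError(f"need at least 8 sites to split, got {n}")
    bins = pd.qcut(table[response], q=min(stratify_bins, n // 4), duplicates="drop")
    strat = bins if bins.nunique() > 1 else None
    train, test = train_test_split(
        table, train_size=frac, random_state=seed, stratify=strat
    )
    return train, test


def _fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray | None,
    n_estimators: int,
    max_features: int | str,
    min_samples_leaf: int,
    seed: int,
) -> RandomForestRegressor:
    model = RandomForestRegressor(
        n_estimators=n_estimators,
        max_features=_resolve_max_features(max_features, X.shape[1]),
        min_samples_leaf=min_samples_leaf,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X, y, sample_weight=w)
    return model


def tune_forest(
    train: pd.DataFrame,
    grid: TuningGrid,
    predictors: Sequence[str],
    seed: int = 0,
    response: str = RESPONSE_COL,
    weight_col: str = WEIGHT_COL,
    biome_levels: Sequence[str] | None = None,
) -> tuple[dict, float]:
    """Grid search by weighted k-fold cross-validated MAE.

    Returns the argmin grid cell (as a hyperparameter dict) and its CV MAE.
    Ties break toward the earlier grid cell, so the result is deterministic.
    """
    missing = set(predictors) - set(train.columns)
    if missing:
        raise ValueError(f"predictors not in table: {sorted(missing)}")
    X, _, levels = encode_features(train, predictors, biome_levels)
    y = train[response].to_numpy(dtype=float)
    w = train[weight_col].to_numpy(dtype=float) if weight_col in train else None

    n_splits = min(grid.cv_folds, len(train))
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(kf.split(X))

    best_params, best_mae = None, np.inf
    for trees, mf, leaf in grid.cells():
        abs_err_sum = 0.0
        weight_sum = 0.0
        for tr_idx, va_idx in folds:
            model = _fit_forest(
                X[tr_idx], y[tr_idx],
                w[tr_idx] if w is not None else None,
                trees, mf, leaf, seed,
            )
            pred = model.predict(X[va_idx])
            wv = w[va_idx] if w is not None else np.ones(len(va_idx))
            abs_err_sum += float(np.sum(wv * np.abs(y[va_idx] - pred)))
            weight_sum += float(np.sum(wv))
        mae = abs_err_sum / weight_sum
        if mae < best_mae:
            best_mae = mae
            best_params = {
                "n_estimators": trees,
                "max_features": mf,
                "min_samples_leaf": leaf,
            }
    return best_params, best_mae


@dataclass
class CandidateModel:
    predictors: tuple[str, ...]
    hyperparams: dict
    cv_mae: float
    model: RandomForestRegressor
    biome_levels: tuple[str, ...]
    feature_names: list[str] = field(default_factory=list)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        X, _, _ = encode_features(data, self.predictors, self.biome_levels)
        return self.model.predict(X)


@dataclass
class FittedModelBundle:
    """The selected forest with its predictor set, tuning, and metrics."""

    analyte: str
    predictors: tuple[str, ...]
    hyperparams: dict
    model: RandomForestRegressor
    biome_levels: tuple[str, ...]
    train_metrics: dict
    test_metrics: dict
    cv_mae: float
    seed: int

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        X, _, _ = encode_features(data, self.predictors, self.biome_levels)
        return self.model.predict(X)

    def summary(self) -> dict:
        return {
            "analyte": self.analyte,
            "predictors": list(self.predictors),
            "hyperparams": dict(self.hyperparams),
            "train_metrics": dict(self.train_metrics),
            "test_metrics": dict(self.test_metrics),
            "cv_mae": self.cv_mae,
            "seed": self.seed,
        }


def _grouped_importances(
    model: RandomForestRegressor, feature_names: Sequence[str]
) -> dict[str, float]:
    # sum one-hot biome columns back into a single 'biome' importance
    imp: dict[str, float] = {}
    for name, value in zip(feature_names, model.feature_importances_):
        key = "biome" if name.startswith("biome=") else name
        imp[key] = imp.get(key, 0.0) + float(value)
    return imp


def backward_eliminate(
    train: pd.DataFrame,
    predictors: Sequence[str],
    grid: TuningGrid,
    fixed: Sequence[str] = FIXED_PREDICTORS,
    seed: int = 0,
    response: str = RESPONSE_COL,
    weight_col: str = WEIGHT_COL,
    biome_levels: Sequence[str] | None = None,
) -> list[CandidateModel]:
    """Tune, fit, and prune: one candidate per predictor-set size.

    Starting from the full predictor list, each iteration tunes and fits a
    forest, then drops the lowest-importance predictor outside *fixed*;
    iteration stops when only the fixed predictors remain.  With P
    predictors and F fixed this yields P − F + 1 candidates.
    """
    predictors = list(dict.fromkeys(predictors))
    fixed = tuple(fixed)
    if not set(fixed) <= set(predictors):
        raise ValueError(
            f"fixed predictors {sorted(set(fixed) - set(predictors))} "
            "missing from predictor list"
        )
    y = train[response].to_numpy(dtype=float)
    w = train[weight_col].to_numpy(dtype=float) if weight_col in train else None

    current = list(predictors)
    candidates: list[CandidateModel] = []
    while True:
        params, cv_mae = tune_forest(
            train, grid, current, seed=seed, response=response,
            weight_col=weight_col, biome_levels=biome_levels,
        )
        X, names, levels = encode_features(train, current, biome_levels)
        model = _fit_forest(X, y, w, seed=seed, **params)
        candidates.append(
            CandidateModel(
                predictors=tuple(current),
                hyperparams=params,
                cv_mae=cv_mae,
                model=model,
                biome_levels=levels,
                feature_names=names,
            )
        )
        droppable = [p for p in current if p not in fixed]
        if not droppable:
            break
        imp = _grouped_importances(model, names)
        weakest = min(droppable, key=lambda p: (imp[p], p))
        current.remove(weakest)
    return candidates


def evaluate(
    observed: np.ndarray | pd.Series,
    predicted: np.ndarray | pd.Series,
    weights: np.ndarray | pd.Series | None = None,
) -> dict[str, float]:
    """MAE, RMSE (weighted when weights given), and regression R².

    R² is the squared correlation from a regression of observations on
    predictions; constant predictions score 0 by convention.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least 2 points to evaluate")
    w = np.ones_like(obs) if weights is None else np.asarray(weights, dtype=float)
    err = obs - pred
    mae = float(np.average(np.abs(err), weights=w))
    rmse = float(np.sqrt(np.average(err**2, weights=w)))
    if np.ptp(pred) == 0:
        r2 = 0.0
    else:
        r2 = float(stats.linregress(pred, obs).rvalue ** 2)
    return {"mae": mae, "rmse": rmse, "r2": r2}


def select_model(
    candidates: Sequence[CandidateModel],
    test: pd.DataFrame,
    rel_tol: float = 0.01,
    analyte: str = "",
    seed: int = 0,
    response: str = RESPONSE_COL,
    weight_col: str = WEIGHT_COL,
    train: pd.DataFrame | None = None,
) -> FittedModelBundle:
    """Pick the candidate with smallest test MAE; near-ties (within
    *rel_tol* relative) go to the fewest predictors, then to the earlier
    candidate."""
    if not candidates:
        raise ValueError("no candidate models")
    wts = test[weight_col] if weight_col in test else None
    maes = []
    for cand in candidates:
        m = evaluate(test[response], cand.predict(test), wts)
        maes.append(m["mae"])
    best_mae = min(maes)
    cutoff = best_mae * (1.0 + rel_tol)
    eligible = [i for i, m in enumerate(maes) if m <= cutoff]
    chosen = min(eligible, key=lambda i: (len(candidates[i].predictors), i))
    cand = candidates[chosen]

    test_metrics = evaluate(test[response], cand.predict(test), wts)
    if train is not None:
        train_metrics = evaluate(
            train[response], cand.predict(train),
            train[weight_col] if weight_col in train else None,
        )
    else:
        train_metrics = {}
    return FittedModelBundle(
        analyte=analyte,
        predictors=cand.predictors,
        hyperparams=cand.hyperparams,
        model=cand.model,
        biome_levels=cand.biome_levels,
        train_metrics=train_metrics,
        test_metrics=test_metrics,
        cv_mae=cand.cv_mae,
        seed=seed,
    )


def bootstrap_predictions(
    bundle: FittedModelBundle,
    train: pd.DataFrame,
    frames: Sequence[pd.DataFrame],
    reps: int = 1000,
    seed: int = 0,
    response: str = RESPONSE_COL,
    weight_col: str = WEIGHT_COL,
) -> list[np.ndarray]:
    """Refit the selected forest on site-bootstrapped training data.

    Returns, for each frame in *frames*, a (reps × n_rows) array of
    predictions — one row per refit — so that intervals for several
    prediction targets (e.g. current and reference inputs) come from the
    same resamples.
    """
    if reps < 2:
        raise ValueError(f"reps must be >= 2, got {reps}")
    rng = np.random.default_rng(seed)
    n = len(train)
    y = train[response].to_numpy(dtype=float)
    w = train[weight_col].to_numpy(dtype=float) if weight_col in train else None
    X_train, _, _ = encode_features(train, bundle.predictors, bundle.biome_levels)
    X_frames = [
        encode_features(f, bundle.predictors, bundle.biome_levels)[0] for f in frames
    ]
    outs = [np.empty((reps, Xf.shape[0])) for Xf in X_frames]
    for r in range(reps):
        idx = rng.integers(0, n, size=n)
        model = _fit_forest(
            X_train[idx], y[idx],
            w[idx] if w is not None else None,
            seed=int(rng.integers(0, 2**31 - 1)),
            **bundle.hyperparams,
        )
        for i, Xf in enumerate(X_frames):
            outs[i][r] = model.predict(Xf)
    return outs


def bootstrap_ci(
    bundle: FittedModelBundle,
    train: pd.DataFrame,
    data: pd.DataFrame,
    reps: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    response: str = RESPONSE_COL,
    weight_col: str = WEIGHT_COL,
) -> pd.DataFrame:
    """Percentile prediction intervals for *data*, with the point estimate.

    The interval is widened, when necessary, to contain the full-data
    point prediction.
    """
    draws = bootstrap_predictions(
        bundle, train, [data], reps=reps, seed=seed,
        response=response, weight_col=weight_col,
    )[0]
    point = bundle.predict(data)
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(draws, alpha, axis=0)
    upper = np.quantile(draws, 1.0 - alpha, axis=0)
    return pd.DataFrame(
        {
            "lower": np.minimum(lower, point),
            "point": point,
            "upper": np.maximum(upper, point),
        },
        index=data.index,
    )
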