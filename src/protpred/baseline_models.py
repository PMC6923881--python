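"""Random-forest and LASSO baselines with the study's tuning grids.

Both models see all transcripts (no top-k filter): they are the
"computationally efficient" model class. The random forest mean-imputes
missing transcript values from training means; LASSO instead restricts its
feature pool to transcripts that are complete and non-constant in the
training split, and records a failed prediction when that pool is empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import lars_path

from .data_io import ValidationError, substream
from .preprocess import make_folds


@dataclass(frozen=True)
class RFParams:
    n_trees: int = 100
    mtry: int | None = None                 # None -> tune over the grid
    mtry_grid: tuple[int, ...] = (5, 10, 25)
    inner_folds: int = 3

    def __post_init__(self) -> None:
        if self.n_trees < 1 or not self.mtry_grid:
            raise ValidationError("need n_trees >= 1 and a non-empty mtry grid")
        if self.mtry is not None and self.mtry < 1:
            raise ValidationError("mtry must be >= 1")


@dataclass(frozen=True)
class LassoParams:
    fraction_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    inner_folds: int = 5

    def __post_init__(self) -> None:
        if not self.fraction_grid or not all(0 < f < 1 for f in self.fraction_grid):
            raise ValidationError("penalty fractions must lie in (0, 1)")


@dataclass
class ModelOutput:
    test_pred: np.ndarray
    train_pred: np.ndarray
    status: str            # ok | degenerate | failed
    info: dict = field(default_factory=dict)


def _impute_train_means(X_train: pd.DataFrame, X_test: pd.DataFrame):
    means = X_train.mean(axis=0)
    means = means.fillna(0.0)  # feature fully missing in training
    return X_train.fillna(means), X_test.fillna(means)


def rf_train_predict(
    X_train: pd.DataFrame,
    y_train: pd.Series,
    X_test: pd.DataFrame,
    params: RFParams,
    seed: int,
) -> ModelOutput:
    """Bagged CART regression; mtry features per split; OOB training preds.

    When ``params.mtry`` is None the grid is tuned by inner cross-validation
    on the training split (per-protein mode); the benchmark pipeline instead
    tunes once globally via :func:`tune_rf_mtry`. Deterministic given seed.
    """
    y = y_train.to_numpy(dtype=float)
    obs = y[~np.isnan(y)]
    Xtr, Xte = _impute_train_means(X_train, X_test)
    keep = ~np.isnan(y)
    Xtr, y = Xtr.loc[keep], y[keep]
    if len(y) < 10:
        return ModelOutput(np.full(len(X_test), np.nan),
                           np.full(len(X_train), np.nan), "failed")
    if np.all(y == y[0]):
        c = float(y[0])
        return ModelOutput(np.full(len(X_test), c), np.full(len(X_train), c),
                           "degenerate", {"mtry": None})
    mtry = params.mtry
    if mtry is None:
        mtry = _tune_mtry_one(Xtr, y, params, seed)
    mtry = min(int(mtry), Xtr.shape[1])
    rng = substream(seed, "rf")
    forest = RandomForestRegressor(
        n_estimators=params.n_trees, max_features=mtry, oob_score=True,
        bootstrap=True, random_state=int(rng.integers(2**31)), n_jobs=1,
    )
    forest.fit(Xtr.to_numpy(), y)
    test_pred = forest.predict(Xte.to_numpy())
    oob = np.full(len(X_train), np.nan)
    oob[np.flatnonzero(keep)] = forest.oob_prediction_
    return ModelOutput(test_pred, oob, "ok", {"mtry": mtry})


def _tune_mtry_one(Xtr: pd.DataFrame, y: np.ndarray, params: RFParams,
                   seed: int) -> int:
    from .benchmark import pearson

    folds = make_folds(Xtr.index, min(params.inner_folds, len(Xtr) // 4 or 2),
                       seed=int(substream(seed, "rf_tune").integers(2**31)))
    best, best_score = params.mtry_grid[0], -np.inf
    for mtry in params.mtry_grid:
        scores = []
        for fold in range(folds.n_folds):
            tr, te = folds.train_samples(fold), folds.test_samples(fold)
            f = RandomForestRegressor(
                n_estimators=params.n_trees,
                max_features=min(int(mtry), Xtr.shape[1]),
                random_state=int(substream(seed, "rf_tune", mtry, fold).integers(2**31)),
                n_jobs=1)
            ytr = y[Xtr.index.get_indexer(tr)]
            f.fit(Xtr.loc[tr].to_numpy(), ytr)
            r = pearson(y[Xtr.index.get_indexer(te)], f.predict(Xtr.loc[te].to_numpy()))
            if not np.isnan(r):
                scores.append(r)
        score = float(np.mean(scores)) if scores else -np.inf
        if score > best_score:
            best, best_score = mtry, score
    return int(best)


def tune_rf_mtry(
    X_train: pd.DataFrame,
    Y_train: pd.DataFrame,
    params: RFParams,
    seed: int,
    max_proteins: int = 12,
) -> int:
    """Global mtry choice: inner-CV mean correlation pooled over a fixed
    subset of proteins (the study tunes one mtry for the whole dataset).

    Returns the winning mtry and a one-row-per-mtry trace table.
    """
    from .benchmark import pearson

    pids = sorted(Y_train.columns)[:max_proteins]
    inner = min(params.inner_folds, max(2, len(X_train) // 10))
    folds = make_folds(X_train.index, inner,
                       seed=int(substream(seed, "rf_global_tune").integers(2**31)))
    rows = []
    best, best_score = params.mtry_grid[0], -np.inf
    for mtry in params.mtry_grid:
        scores = []
        for fold in range(folds.n_folds):
            tr, te = folds.train_samples(fold), folds.test_samples(fold)
            Xtr, Xte = _impute_train_means(X_train.loc[tr], X_train.loc[te])
            for pid in pids:
                y = Y_train.loc[tr, pid].to_numpy(dtype=float)
                keep = ~np.isnan(y)
                if keep.sum() < 10 or np.nanstd(y) == 0:
                    continue
                f = RandomForestRegressor(
                    n_estimators=params.n_trees,
                    max_features=min(int(mtry), Xtr.shape[1]),
                    random_state=int(substream(seed, "rf_global", mtry, fold,
                                               pid).integers(2**31)),
                    n_jobs=1)
                f.fit(Xtr.to_numpy()[keep], y[keep])
                r = pearson(Y_train.loc[te, pid].to_numpy(),
                            f.predict(Xte.to_numpy()))
                if not np.isnan(r):
                    scores.append(r)
        score = float(np.mean(scores)) if scores else -np.inf
        rows.append({"mtry": int(mtry),
                     "mean_corr": score if np.isfinite(score) else np.nan})
        if score > best_score:
            best, best_score = mtry, score
    return int(best), pd.DataFrame(rows, columns=["mtry", "mean_corr"])


# ---------------------------------------------------------------------------
# LASSO


def lasso_admissible_features(X_train: pd.DataFrame) -> list[str]:
    """Transcripts with no missing training values and nonzero variance."""
    complete = X_train.notna().all(axis=0)
    var = X_train.var(axis=0, ddof=1)
    ok = complete & (var > 0)
    return list(X_train.columns[ok])


def _coef_at_fraction(coefs: np.ndarray, fraction: float) -> np.ndarray:
    """Interpolate LARS-lasso path coefficients at an L1-norm fraction.

    ``coefs`` is (n_features, n_knots). The fraction coordinate is the L1
    norm at each knot relative to the final (least-penalized) knot, made
    non-decreasing; coefficients are piecewise linear between knots.
    """
    l1 = np.abs(coefs).sum(axis=0)
    if l1[-1] == 0:
        return np.zeros(coefs.shape[0])
    frac = np.maximum.accumulate(l1 / l1[-1])
    idx = np.searchsorted(frac, fraction, side="left")
    if idx == 0:
        lo_f, hi_f, lo_c, hi_c = 0.0, frac[0], np.zeros(coefs.shape[0]), coefs[:, 0]
    else:
        idx = min(idx, len(frac) - 1)
        lo_f, hi_f = frac[idx - 1], frac[idx]
        lo_c, hi_c = coefs[:, idx - 1], coefs[:, idx]
    if hi_f == lo_f:
        return hi_c
    w = (fraction - lo_f) / (hi_f - lo_f)
    return lo_c + np.clip(w, 0.0, 1.0) * (hi_c - lo_c)


def _lasso_fit(X: np.ndarray, y: np.ndarray, fraction: float):
    """Standardized LARS-lasso fit at one penalty fraction.

    Returns (coefficients on the original scale, intercept).
    """
    x_mean, y_mean = X.mean(axis=0), y.mean()
    x_sd = X.std(axis=0, ddof=0)
    x_sd[x_sd == 0] = 1.0
    Xs = (X - x_mean) / x_sd
    _, _, coefs = lars_path(Xs, y - y_mean, method="lasso")
    beta_std = _coef_at_fraction(coefs, fraction)
    beta = beta_std / x_sd
    intercept = y_mean - float(x_mean @ beta)
    return beta, intercept


def lasso_train_predict(
    X_train: pd.DataFrame,
    y_train: pd.Series,
    X_test: pd.DataFrame,
    params: LassoParams,
    seed: int,
) -> ModelOutput:
    """L1-penalized linear regression with the penalty fraction chosen from
    the grid by inner cross-validation (mean Pearson; RMSE as tie-breaker
    when correlation is undefined everywhere).

    Fails — NaN predictions, status "failed" — when no transcript passes the
    completeness/variance filter.
    """
    from .benchmark import pearson

    features = lasso_admissible_features(X_train)
    nan_te = np.full(len(X_test), np.nan)
    nan_tr = np.full(len(X_train), np.nan)
    if not features:
        return ModelOutput(nan_te, nan_tr, "failed", {"n_features": 0})
    y = y_train.to_numpy(dtype=float)
    keep = ~np.isnan(y)
    if keep.sum() < 3:
        return ModelOutput(nan_te, nan_tr, "failed", {"n_features": len(features)})
    Xtr = X_train.loc[keep, features].to_numpy(dtype=float)
    ytr = y[keep]
    train_means = X_train[features].mean(axis=0)
    Xte = X_test[features].fillna(train_means).to_numpy(dtype=float)
    Xtr_full = X_train[features].fillna(train_means).to_numpy(dtype=float)
    if np.all(ytr == ytr[0]):
        c = float(ytr[0])
        return ModelOutput(np.full(len(X_test), c), np.full(len(X_train), c),
                           "degenerate", {"fraction": None,
                                          "n_features": len(features)})
    n_inner = min(params.inner_folds, max(2, len(ytr) // 3))
    folds = make_folds([str(i) for i in range(len(ytr))], n_inner,
                       seed=int(substream(seed, "lasso_tune").integers(2**31)))
    corr_scores = {f: [] for f in params.fraction_grid}
    rmse_scores = {f: [] for f in params.fraction_grid}
    for fold in range(n_inner):
        tr = [int(s) for s in folds.train_samples(fold)]
        te = [int(s) for s in folds.test_samples(fold)]
        Xa, ya, Xb, yb = Xtr[tr], ytr[tr], Xtr[te], ytr[te]
        if np.all(ya == ya[0]):
            continue
        x_mean, y_mean = Xa.mean(axis=0), ya.mean()
        x_sd = Xa.std(axis=0, ddof=0)
        x_sd[x_sd == 0] = 1.0
        _, _, coefs = lars_path((Xa - x_mean) / x_sd, ya - y_mean, method="lasso")
        for f in params.fraction_grid:
            beta = _coef_at_fraction(coefs, f) / x_sd
            pred = Xb @ beta + (y_mean - x_mean @ beta)
            r = pearson(yb, pred)
            if not np.isnan(r):
                corr_scores[f].append(r)
            rmse_scores[f].append(float(np.sqrt(np.mean((yb - pred) ** 2))))
    def _score(f):
        if corr_scores[f]:
            return float(np.mean(corr_scores[f]))
        return -float(np.mean(rmse_scores[f])) if rmse_scores[f] else -np.inf
    best = max(params.fraction_grid, key=lambda f: (_score(f), -f))
    beta, intercept = _lasso_fit(Xtr, ytr, best)
    test_pred = Xte @ beta + intercept
    train_pred = Xtr_full @ beta + intercept
    coef = pd.Series(beta, index=features)
    return ModelOutput(test_pred, train_pred, "ok",
                       {"fraction": best, "n_features": len(features),
                        "coef": coef})
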