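"""Fuzzy-logic regression of protein abundance on selected transcripts.

For each selected transcript, the training samples whose transcript value
lies within tau transcript-SDs of the query sample form a local window; the
protein values in that window give a kernel-density estimate — a fuzzy set
of candidate protein abundances whose membership function is the density.
Densities are evaluated on a fixed grid of 0.1 protein-SD intervals spanning
the protein's training range. Each transcript's support is the hull of grid
points with density above alpha; the prediction range is the intersection of
these hulls, the combined membership is the pointwise minimum of densities
(fuzzy intersection), and the prediction is the grid midpoint maximizing
that minimum — the abundance most agreed upon by all transcripts.

Windows holding fewer than ``min_window_samples`` training samples are
discarded; if every transcript is discarded, or the support hulls share no
grid point, the predictor falls back to the training mean and flags it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, ValidationError, substream
from .preprocess import TranscriptSelection, make_folds

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class FuzzyParams:
    """Tuning parameters: window half-width tau (in transcript SDs), density
    cutoff alpha, grid step (protein SDs) and the minimum window occupancy."""

    tau: float = 1.0
    alpha: float = 0.1
    grid_step_sd: float = 0.1
    min_window_samples: int = 10

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.alpha <= 0 or self.grid_step_sd <= 0:
            raise ValidationError("tau, alpha, grid_step_sd must be > 0")


@dataclass
class DensityGrid:
    """One transcript's local density of the protein, on the shared grid."""

    transcript_id: str
    grid: np.ndarray
    density: np.ndarray
    n_window: int

    def __post_init__(self) -> None:
        steps = np.diff(self.grid)
        if len(steps) and (steps.min() <= 0 or
                           not np.allclose(steps, steps[0], rtol=1e-8)):
            raise ValidationError("grid must be strictly increasing and uniform")
        if (self.density < 0).any():
            raise ValidationError("densities must be non-negative")


@dataclass(frozen=True)
class FuzzyPrediction:
    value: float
    status: str  # ok | fallback_mean | failed
    n_retained: int


def _quantile_sorted(xs: np.ndarray, q: float) -> float:
    """Linear-interpolation quantile of pre-sorted data (numpy's default)."""
    pos = q * (len(xs) - 1)
    i = int(pos)
    frac = pos - i
    if frac == 0.0:
        return float(xs[i])
    return float(xs[i] * (1.0 - frac) + xs[i + 1] * frac)


def nrd0_bandwidth(x: np.ndarray) -> float:
    """Silverman rule-of-thumb bandwidth (R's ``bw.nrd0``)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = x.std(ddof=1) if n > 1 else 0.0
    xs = np.sort(x)
    iqr = _quantile_sorted(xs, 0.75) - _quantile_sorted(xs, 0.25)
    lo = min(sd, iqr / 1.34) if min(sd, iqr / 1.34) > 0 else (sd or abs(x[0]) or 1.0)
    return 0.9 * lo * n ** (-0.2)


def gaussian_kde_on_grid(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Gaussian-kernel density of ``values`` evaluated at ``grid`` points."""
    h = nrd0_bandwidth(values)
    z = (grid[:, None] - values[None, :]) / h
    return np.exp(-0.5 * z * z).sum(axis=1) / (len(values) * h * _SQRT_2PI)


def protein_grid(protein_train: np.ndarray, grid_step_sd: float = 0.1) -> np.ndarray:
    """Evaluation grid: interval midpoints at 0.1 protein-SD steps, anchored
    at the training minimum and spanning the training range."""
    y = np.asarray(protein_train, dtype=float)
    y = y[~np.isnan(y)]
    if len(y) == 0:
        raise ValidationError("no observed protein training values")
    sd = y.std(ddof=1) if len(y) > 1 else 0.0
    if sd == 0.0:
        return np.array([float(y[0])])
    step = grid_step_sd * sd
    n_cells = max(1, math.ceil((y.max() - y.min()) / step - 1e-12))
    return y.min() + step * (np.arange(n_cells) + 0.5)


def local_density(
    protein_train: np.ndarray,
    transcript_train: np.ndarray,
    query_value: float,
    params: FuzzyParams,
    grid: np.ndarray | None = None,
    transcript_id: str = "",
) -> DensityGrid | None:
    """Local density of the protein near one query transcript value.

    Training pairs are pairwise-complete. The window holds pairs with
    ``|x - query| <= tau * sd(x)``; returns None (discarded) when the window
    holds fewer than ``min_window_samples`` pairs or the transcript is
    degenerate. A window of identical protein values is legal and yields a
    narrow peak (the bandwidth rule falls back rather than dividing by zero).
    """
    y = np.asarray(protein_train, dtype=float)
    x = np.asarray(transcript_train, dtype=float)
    if np.isnan(query_value):
        return None
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y_pairs = x[ok], y[ok]
    if len(x) < 2:
        return None
    sigma_x = x.std(ddof=1)
    if not (sigma_x > 0):
        return None
    in_window = np.abs(x - query_value) <= params.tau * sigma_x
    n_window = int(in_window.sum())
    if n_window < params.min_window_samples:
        return None
    if grid is None:
        grid = protein_grid(protein_train, params.grid_step_sd)
    density = gaussian_kde_on_grid(y_pairs[in_window], np.asarray(grid))
    return DensityGrid(transcript_id=transcript_id, grid=np.asarray(grid),
                       density=density, n_window=n_window)


def _fallback(protein_train: np.ndarray, n_retained: int) -> FuzzyPrediction:
    y = np.asarray(protein_train, dtype=float)
    y = y[~np.isnan(y)]
    if len(y) == 0:
        return FuzzyPrediction(np.nan, "failed", n_retained)
    return FuzzyPrediction(float(y.mean()), "fallback_mean", n_retained)


def _intersect_arrays(
    densities: list[np.ndarray], grid: np.ndarray, alpha: float
) -> float | None:
    lo, hi = 0, len(grid) - 1
    for d in densities:
        above = np.nonzero(d > alpha)[0]
        if len(above) == 0:
            return None
        lo = max(lo, int(above[0]))
        hi = min(hi, int(above[-1]))
    if lo > hi:
        return None
    m = np.min([d[lo : hi + 1] for d in densities], axis=0)
    best = lo + int(np.argmax(m))  # argmax takes the first (lowest) maximizer
    return float(grid[best])


def intersect_densities(
    grids: list[DensityGrid], alpha: float
) -> tuple[float, int] | None:
    """Fuzzy intersection: alpha-support hulls intersected, then argmax of
    the pointwise-minimum density over the shared range.

    Returns (predicted value, retained count) or None when the shared range
    is empty. Ties in the argmax break toward the smallest grid value.
    """
    if not grids:
        return None
    value = _intersect_arrays([dg.density for dg in grids], grids[0].grid,
                              alpha)
    if value is None:
        return None
    return value, len(grids)


def fuzzy_predict_one(
    selection: TranscriptSelection,
    transcripts_train: pd.DataFrame | ExpressionMatrix,
    protein_train: np.ndarray,
    test_values: pd.Series | dict,
    params: FuzzyParams,
) -> FuzzyPrediction:
    """Predict one test sample's protein level from its transcript values."""
    if not selection.transcript_ids:
        raise ValidationError("selection is empty")
    X = (transcripts_train.to_frame()
         if isinstance(transcripts_train, ExpressionMatrix) else transcripts_train)
    grid = protein_grid(protein_train, params.grid_step_sd)
    retained: list[DensityGrid] = []
    for tid in selection.transcript_ids:
        q = float(test_values[tid]) if tid in test_values else np.nan
        dg = local_density(protein_train, X[tid].to_numpy(), q, params,
                           grid=grid, transcript_id=tid)
        if dg is not None:
            retained.append(dg)
    if not retained:
        return _fallback(protein_train, 0)
    hit = intersect_densities(retained, params.alpha)
    if hit is None:
        return _fallback(protein_train, len(retained))
    value, n_ret = hit
    return FuzzyPrediction(value, "ok", n_ret)


class FuzzyModel:
    """Fitted fuzzy predictor for one protein: precomputes per-transcript
    paired training vectors so batch prediction avoids re-slicing."""

    def __init__(self, selection: TranscriptSelection,
                 transcripts_train: pd.DataFrame,
                 protein_train: np.ndarray, params: FuzzyParams):
        self.selection = selection
        self.params = params
        y = np.asarray(protein_train, dtype=float)
        self.grid = protein_grid(y, params.grid_step_sd)
        obs = y[~np.isnan(y)]
        self.train_mean = float(obs.mean()) if len(obs) else np.nan
        self._pairs: list[tuple[str, np.ndarray, np.ndarray, float]] = []
        for tid in selection.transcript_ids:
            x = transcripts_train[tid].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            xs, ys = x[ok], y[ok]
            if len(xs) < 2:
                continue
            sd = xs.std(ddof=1)
            if sd > 0:
                self._pairs.append((tid, xs, ys, sd))

    def _predict_values(self, qvals: np.ndarray) -> FuzzyPrediction:
        """Predict from transcript values aligned with ``self._pairs``."""
        p = self.params
        densities: list[np.ndarray] = []
        for k, (tid, xs, ys, sd) in enumerate(self._pairs):
            q = qvals[k]
            if np.isnan(q):
                continue
            win = np.abs(xs - q) <= p.tau * sd
            if int(win.sum()) < p.min_window_samples:
                continue
            densities.append(gaussian_kde_on_grid(ys[win], self.grid))
        if not densities:
            return FuzzyPrediction(self.train_mean, "fallback_mean", 0) \
                if not np.isnan(self.train_mean) else FuzzyPrediction(np.nan, "failed", 0)
        value = _intersect_arrays(densities, self.grid, p.alpha)
        if value is None:
            return FuzzyPrediction(self.train_mean, "fallback_mean",
                                   len(densities))
        return FuzzyPrediction(value, "ok", len(densities))

    def predict_one(self, test_values: pd.Series | dict) -> FuzzyPrediction:
        qvals = np.array([
            float(test_values[tid]) if tid in test_values else np.nan
            for tid, *_ in self._pairs])
        return self._predict_values(qvals)

    def predict(self, X_test: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        cols = [t for t, *_ in self._pairs]
        arr = (X_test[cols].to_numpy(dtype=float)
               if cols else np.empty((len(X_test), 0)))
        values = np.empty(len(X_test))
        statuses = []
        for i in range(len(X_test)):
            pred = self._predict_values(arr[i])
            values[i] = pred.value
            statuses.append(pred.status)
        return values, statuses


def tune_fuzzy(
    transcripts_train: pd.DataFrame | ExpressionMatrix,
    proteins_train: pd.DataFrame | ExpressionMatrix,
    selections: dict[str, TranscriptSelection],
    tau_grid: tuple[float, ...],
    alpha_grid: tuple[float, ...],
    seed: int,
    inner_folds: int = 3,
    grid_step_sd: float = 0.1,
    min_window_samples: int = 10,
) -> tuple[FuzzyParams, pd.DataFrame]:
    """Pick (tau, alpha) by inner cross-validation on the training split.

    Every grid combination is scored by the median Pearson correlation of
    inner-held-out predictions pooled over proteins and inner folds (NRMSE is
    traced alongside). Ties, and the all-undefined case, fall back to
    tau=1, alpha=0.1. Returns the winning params and the full trace table.
    """
    from .benchmark import nrmse, pearson  # late import avoids a cycle

    X = (transcripts_train.to_frame()
         if isinstance(transcripts_train, ExpressionMatrix) else transcripts_train)
    Y = (proteins_train.to_frame()
         if isinstance(proteins_train, ExpressionMatrix) else proteins_train)
    folds = make_folds(X.index, inner_folds, seed=seed)
    rows = []
    best: tuple[float, FuzzyParams] | None = None
    for tau in tau_grid:
        for alpha in alpha_grid:
            params = FuzzyParams(tau=tau, alpha=alpha, grid_step_sd=grid_step_sd,
                                 min_window_samples=min_window_samples)
            corrs, errs = [], []
            for fold in range(inner_folds):
                tr = folds.train_samples(fold)
                te = folds.test_samples(fold)
                for pid, sel in selections.items():
                    model = FuzzyModel(sel, X.loc[tr], Y.loc[tr, pid].to_numpy(),
                                       params)
                    pred, _ = model.predict(X.loc[te])
                    truth = Y.loc[te, pid].to_numpy()
                    r = pearson(truth, pred)
                    e = nrmse(truth, pred)
                    if not np.isnan(r):
                        corrs.append(r)
                    if not np.isnan(e):
                        errs.append(e)
            med_corr = float(np.median(corrs)) if corrs else np.nan
            med_err = float(np.median(errs)) if errs else np.nan
            rows.append({"tau": tau, "alpha": alpha,
                         "median_corr": med_corr, "median_nrmse": med_err})
            if not np.isnan(med_corr) and (best is None or med_corr > best[0]):
                best = (med_corr, params)
    trace = pd.DataFrame(rows, columns=["tau", "alpha", "median_corr",
                                        "median_nrmse"])
    if best is None:
        chosen = FuzzyParams(tau=1.0, alpha=0.1, grid_step_sd=grid_step_sd,
                             min_window_samples=min_window_samples)
    else:
        chosen = best[1]
    return chosen, trace
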