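"""Cross-validated evaluation harness and metrics.

Per (protein, fold, method) the harness records predictions with a status
flag, then scores Pearson correlation and NRMSE (RMSE over the test
ground-truth range), pools all defined per-protein per-fold values into
per-method medians, and counts how often each protein reaches the top-k
correlations across folds (the cross-fold consistency table).

Methods only ever see training rows; feature selection, tuning, fitting and
ensemble weighting all happen inside the fold's training split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ensemble as ens
from .baseline_models import (LassoParams, RFParams, lasso_train_predict,
                              rf_train_predict, tune_rf_mtry)
from .bayes_net import bn_train_predict
from .data_io import (BenchmarkReport, ExpressionMatrix, RunConfig,
                      ValidationError, align_layers, substream)
from .fuzzy_predictor import FuzzyModel, FuzzyParams, tune_fuzzy
from .preprocess import (FoldSplit, TranscriptSelection, make_folds,
                         select_top_transcripts, zscore_features)

logger = logging.getLogger(__name__)

PREDICTION_COLUMNS = ["protein", "fold", "sample", "method", "prediction", "status"]
METRIC_COLUMNS = ["protein", "fold", "method", "pearson", "nrmse", "n_test", "status"]


# ---------------------------------------------------------------------------
# metrics


def pearson(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Sample Pearson correlation; NaN (undefined) when fewer than 3 complete
    pairs or either vector is constant."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValidationError("vector length mismatch")
    ok = ~(np.isnan(y_true) | np.isnan(y_pred))
    if ok.sum() < 3:
        return np.nan
    a, b = y_true[ok], y_pred[ok]
    # exact range check: std() of identical floats can be ~1e-17, not 0
    if a.max() == a.min() or b.max() == b.min():
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def nrmse(y_true: np.ndarray, y_pred: np.ndarray, norm: str = "range") -> float:
    """RMSE normalized by the ground-truth range (or SD); NaN when the truth
    is constant or there are no complete pairs."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValidationError("vector length mismatch")
    ok = ~(np.isnan(y_true) | np.isnan(y_pred))
    if ok.sum() == 0:
        return np.nan
    a, b = y_true[ok], y_pred[ok]
    if norm == "range":
        denom = float(a.max() - a.min())
    elif norm == "sd":
        denom = float(a.std(ddof=1)) if len(a) > 1 else 0.0
    else:
        raise ValidationError("norm must be 'range' or 'sd'")
    if denom == 0:
        return np.nan
    return float(np.sqrt(np.mean((a - b) ** 2)) / denom)


# ---------------------------------------------------------------------------
# method wrappers (uniform fit/predict surface over the four models)


class Method:
    """One registered predictor. ``fit_predict`` receives training rows only
    plus the test feature rows; it must return test predictions, training
    predictions (for ensemble weighting), a fold-level status, and optional
    per-sample statuses."""

    name: str = ""
    needs_selection: bool = False

    def fit_predict(self, X_train, y_train, X_test, selection, config, seed):
        raise NotImplementedError


class FuzzyMethod(Method):
    name = "fuzzy"
    needs_selection = True

    def __init__(self, params: FuzzyParams):
        self.params = params

    def fit_predict(self, X_train, y_train, X_test, selection, config, seed):
        model = FuzzyModel(selection, X_train, y_train.to_numpy(dtype=float),
                           self.params)
        test_pred, test_status = model.predict(X_test)
        train_pred, _ = model.predict(X_train)
        if all(s == "failed" for s in test_status):
            return test_pred, train_pred, "failed", test_status
        return test_pred, train_pred, "ok", test_status


class BNMethod(Method):
    name = "bn"
    needs_selection = True

    def __init__(self, p_filter: float = 0.05):
        self.p_filter = p_filter

    def fit_predict(self, X_train, y_train, X_test, selection, config, seed):
        test_pred, train_pred, status, _ = bn_train_predict(
            X_train, y_train, X_test, selection, p_filter=self.p_filter)
        return test_pred, train_pred, status, None


class RFMethod(Method):
    name = "rf"

    def __init__(self, mtry: int | None = None):
        self.mtry = mtry

    def fit_predict(self, X_train, y_train, X_test, selection, config, seed):
        params = RFParams(n_trees=config.rf_n_trees, mtry=self.mtry,
                          mtry_grid=config.rf_mtry_grid,
                          inner_folds=config.inner_folds)
        out = rf_train_predict(X_train, y_train, X_test, params, seed)
        self.last_info = {"mtry": out.info.get("mtry")}
        return out.test_pred, out.train_pred, out.status, None


class LassoMethod(Method):
    name = "lasso"

    def fit_predict(self, X_train, y_train, X_test, selection, config, seed):
        params = LassoParams(fraction_grid=config.lasso_fraction_grid,
                             inner_folds=config.lasso_inner_folds)
        out = lasso_train_predict(X_train, y_train, X_test, params, seed)
        self.last_info = {"fraction": out.info.get("fraction"),
                          "n_features": out.info.get("n_features")}
        return out.test_pred, out.train_pred, out.status, None


class OracleMethod(Method):
    """Returns the ground truth; harness sanity check only."""

    name = "oracle"

    def __init__(self, truth: ExpressionMatrix):
        self.truth = truth.to_frame()

    def fit_predict(self, X_train, y_train, X_test, selection, config, seed):
        pid = str(y_train.name)
        test = self.truth.loc[X_test.index, pid].to_numpy(dtype=float)
        return test, y_train.to_numpy(dtype=float), "ok", None


class MeanMethod(Method):
    """Predicts the training mean everywhere; harness baseline."""

    name = "mean"

    def fit_predict(self, X_train, y_train, X_test, selection, config, seed):
        m = float(np.nanmean(y_train.to_numpy(dtype=float)))
        return (np.full(len(X_test), m), np.full(len(X_train), m), "ok", None)


# ---------------------------------------------------------------------------
# harness


@dataclass
class CVResult:
    method: str
    predictions: pd.DataFrame
    # (protein, fold) -> (test_pred, fold status); and training correlations
    per_fold: dict = field(default_factory=dict)
    train_corr: dict = field(default_factory=dict)
    fit_info: pd.DataFrame | None = None  # chosen hyperparameters audit

    def train_corr_frame(self) -> pd.DataFrame:
        rows = [{"protein": pid, "fold": fold, "method": self.method,
                 "train_corr": r}
                for (pid, fold), r in sorted(self.train_corr.items())]
        return pd.DataFrame(rows, columns=["protein", "fold", "method",
                                           "train_corr"])


def precompute_selections(
    transcripts: ExpressionMatrix,
    proteins: ExpressionMatrix,
    folds: FoldSplit,
    k: int,
) -> dict[int, dict[str, TranscriptSelection]]:
    """Top-k transcript selection on every fold's training split."""
    X = transcripts.to_frame()
    Y = proteins.to_frame()
    out: dict[int, dict[str, TranscriptSelection]] = {}
    for fold in range(folds.n_folds):
        tr = folds.train_samples(fold)
        Xtr = ExpressionMatrix.from_frame(X.loc[tr])
        sel = {}
        for pid in Y.columns:
            try:
                sel[pid] = select_top_transcripts(
                    Xtr, Y.loc[tr, pid].to_numpy(), k, protein_id=pid)
            except ValidationError:
                logger.warning("no selectable transcripts for %s fold %d",
                               pid, fold)
        out[fold] = sel
    return out


def run_cv(
    transcripts: ExpressionMatrix,
    proteins: ExpressionMatrix,
    method: Method,
    folds: FoldSplit,
    config: RunConfig,
    selections: dict[int, dict[str, TranscriptSelection]] | None = None,
) -> CVResult:
    """Cross-validate one method over every protein and fold.

    Produces exactly n_proteins x n_folds records; failures surface as
    status "failed" with NaN predictions, never as missing rows.
    """
    X = transcripts.to_frame()
    Y = proteins.to_frame()
    if selections is None and method.needs_selection:
        selections = precompute_selections(transcripts, proteins, folds,
                                           config.top_k_transcripts)
    rows = []
    info_rows = []
    per_fold, train_corr = {}, {}
    for fold in range(folds.n_folds):
        tr = folds.train_samples(fold)
        te = folds.test_samples(fold)
        if set(tr) & set(te):
            raise AssertionError("train/test overlap: harness bug")
        X_tr, X_te = X.loc[tr], X.loc[te]
        for pid in Y.columns:
            y_tr = Y.loc[tr, pid]
            sel = (selections or {}).get(fold, {}).get(pid) \
                if method.needs_selection else None
            if method.needs_selection and sel is None:
                test_pred = np.full(len(te), np.nan)
                train_pred = np.full(len(tr), np.nan)
                status, sample_status = "failed", None
            else:
                seed = int(substream(config.seed, "method", method.name,
                                     pid, fold).integers(2**31))
                method.last_info = None
                test_pred, train_pred, status, sample_status = \
                    method.fit_predict(X_tr, y_tr, X_te, sel, config, seed)
                if getattr(method, "last_info", None):
                    info_rows.append({"protein": pid, "fold": fold,
                                      "method": method.name,
                                      **method.last_info})
            per_fold[(pid, fold)] = (np.asarray(test_pred, dtype=float), status)
            train_corr[(pid, fold)] = pearson(y_tr.to_numpy(), train_pred) \
                if train_pred is not None else np.nan
            for i, sample in enumerate(te):
                rows.append({
                    "protein": pid, "fold": fold, "sample": sample,
                    "method": method.name, "prediction": float(test_pred[i]),
                    "status": (sample_status[i] if sample_status is not None
                               else status),
                })
    predictions = pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
    fit_info = pd.DataFrame(info_rows) if info_rows else None
    return CVResult(method=method.name, predictions=predictions,
                    per_fold=per_fold, train_corr=train_corr,
                    fit_info=fit_info)


def _fold_status(statuses: pd.Series) -> str:
    if (statuses == "failed").all():
        return "failed"
    if (statuses == "degenerate").all():
        return "degenerate"
    return "ok"


def score_predictions(
    predictions: pd.DataFrame,
    proteins: ExpressionMatrix,
    norm: str = "range",
) -> pd.DataFrame:
    """Per (protein, fold, method) Pearson and NRMSE against ground truth."""
    truth = proteins.to_frame()
    rows = []
    grouped = predictions.groupby(["method", "protein", "fold"], sort=True)
    for (method, pid, fold), grp in grouped:
        status = _fold_status(grp["status"])
        y_true = truth.loc[grp["sample"], pid].to_numpy(dtype=float)
        y_pred = grp["prediction"].to_numpy(dtype=float)
        n_test = int((~np.isnan(y_true)).sum())
        if status == "failed":
            r, e = np.nan, np.nan
        else:
            r = pearson(y_true, y_pred)
            e = nrmse(y_true, y_pred, norm=norm)
        rows.append({"protein": pid, "fold": int(fold), "method": method,
                     "pearson": r, "nrmse": e, "n_test": n_test,
                     "status": status})
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def summarize(metrics: pd.DataFrame) -> dict:
    """Per-method medians over all defined per-protein per-fold values, plus
    failure accounting. Folds are pooled, not averaged per protein first."""
    out = {}
    for method, grp in metrics.groupby("method"):
        corr = grp["pearson"].dropna()
        err = grp["nrmse"].dropna()
        if corr.empty:
            logger.warning("method %s: no defined correlations", method)
        out[str(method)] = {
            "median_correlation": float(corr.median()) if not corr.empty else None,
            "median_nrmse": float(err.median()) if not err.empty else None,
            "n_records": int(len(grp)),
            "n_ok": int((grp["status"] == "ok").sum()),
            "n_failed": int((grp["status"] == "failed").sum()),
            "n_degenerate": int((grp["status"] == "degenerate").sum()),
        }
    return out


def topk_consistency(
    metrics: pd.DataFrame, k: int, n_folds: int
) -> pd.DataFrame:
    """Count, per protein, the folds in which it ranked in the top k by
    correlation. Undefined correlations rank last; ties break by protein ID."""
    rows = []
    for method, grp in metrics.groupby("method"):
        n_proteins = grp["protein"].nunique()
        k_eff = k
        if k > n_proteins:
            logger.warning("k=%d clamped to %d proteins", k, n_proteins)
            k_eff = n_proteins
        counts: dict[str, int] = {}
        for fold, fgrp in grp.groupby("fold"):
            ranked = fgrp.sort_values(
                ["pearson", "protein"], ascending=[False, True],
                na_position="last")
            for pid in ranked["protein"].head(k_eff):
                counts[pid] = counts.get(pid, 0) + 1
        for pid, count in counts.items():
            if count > n_folds:
                raise AssertionError("consistency count exceeds fold count")
            rows.append({"method": method, "protein": pid, "count": count})
    frame = pd.DataFrame(rows, columns=["method", "protein", "count"])
    return frame.sort_values(["method", "count", "protein"],
                             ascending=[True, False, True]).reset_index(drop=True)


def report_histograms(
    metrics: pd.DataFrame, bins: int = 20
) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]:
    """Binned correlation and NRMSE distributions per method.

    Returns {(method, metric): (bin_edges, counts)}; counts sum to the number
    of defined records for that method/metric.
    """
    out = {}
    for method, grp in metrics.groupby("method"):
        for metric in ("pearson", "nrmse"):
            vals = grp[metric].dropna().to_numpy()
            if len(vals) == 0:
                out[(str(method), metric)] = (np.array([]), np.array([]))
                continue
            counts, edges = np.histogram(vals, bins=bins)
            out[(str(method), metric)] = (edges, counts)
    return out


def save_histograms(metrics: pd.DataFrame, outdir: str | Path,
                    bins: int = 20) -> None:
    """Write histogram TSVs and rendered PNG panels per method."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hists = report_histograms(metrics, bins=bins)
    for (method, metric), (edges, counts) in hists.items():
        frame = pd.DataFrame({
            "bin_left": edges[:-1] if len(edges) else [],
            "bin_right": edges[1:] if len(edges) else [],
            "count": counts,
        })
        frame.to_csv(outdir / f"hist_{method}_{metric}.tsv", sep="\t",
                     index=False)
    methods = sorted({m for m, _ in hists})
    if methods:
        fig, axes = plt.subplots(len(methods), 2,
                                 figsize=(8, 2.4 * len(methods)),
                                 squeeze=False)
        for i, method in enumerate(methods):
            for j, metric in enumerate(("pearson", "nrmse")):
                edges, counts = hists[(method, metric)]
                ax = axes[i][j]
                if len(edges):
                    ax.bar(edges[:-1], counts, width=np.diff(edges),
                           align="edge")
                ax.set_title(f"{method}: {metric}", fontsize=9)
        fig.tight_layout()
        fig.savefig(outdir / "histograms.png", dpi=100)
        plt.close(fig)


# ---------------------------------------------------------------------------
# full benchmark


def _ensemble_rows(results: dict[str, CVResult], folds: FoldSplit,
                   protein_ids) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combine component predictions per (protein, fold) into ensemble rows
    and the weight audit table."""
    pred_rows, weight_rows = [], []
    method_names = sorted(results)
    for fold in range(folds.n_folds):
        te = folds.test_samples(fold)
        for pid in protein_ids:
            preds, corrs, failed = {}, {}, set()
            for m in method_names:
                vec, status = results[m].per_fold[(pid, fold)]
                corrs[m] = results[m].train_corr[(pid, fold)]
                if status == "failed" or np.isnan(vec).any():
                    failed.add(m)
                preds[m] = vec
            try:
                weights = ens.ensemble_weights(corrs, failed=failed)
                combined = ens.ensemble_predict(preds, weights)
                status = "ok"
            except ens.EnsembleFailure:
                weights = None
                combined = np.full(len(te), np.nan)
                status = "failed"
            for m in method_names:
                weight_rows.append({
                    "protein": pid, "fold": fold, "method": m,
                    "weight": weights.weights[m] if weights else np.nan,
                    "train_corr": corrs[m],
                })
            for i, sample in enumerate(te):
                pred_rows.append({
                    "protein": pid, "fold": fold, "sample": sample,
                    "method": "ensemble", "prediction": float(combined[i]),
                    "status": status,
                })
    return (pd.DataFrame(pred_rows, columns=PREDICTION_COLUMNS),
            pd.DataFrame(weight_rows, columns=["protein", "fold", "method",
                                               "weight", "train_corr"]))


def run_benchmark(
    transcripts: ExpressionMatrix,
    proteins: ExpressionMatrix,
    config: RunConfig,
    methods: tuple[str, ...] = ("fuzzy", "bn", "rf", "lasso"),
    tune_max_proteins: int = 20,
) -> BenchmarkReport:
    """Preprocess, tune, cross-validate every method, ensemble, and score.

    Fuzzy (tau, alpha) and RF mtry are tuned once per run by inner CV on the
    first fold's training split, mirroring one global optimum per dataset.
    """
    transcripts, proteins = align_layers(transcripts.sorted(), proteins.sorted())
    transcripts = zscore_features(transcripts)
    proteins = zscore_features(proteins)
    folds = make_folds(proteins.sample_ids, config.n_folds, seed=config.seed)
    X, Y = transcripts.to_frame(), proteins.to_frame()

    need_sel = {"fuzzy", "bn"} & set(methods)
    selections = (precompute_selections(transcripts, proteins, folds,
                                        config.top_k_transcripts)
                  if need_sel else {})
    tuning: dict = {}
    registry: dict[str, Method] = {}
    tr0 = folds.train_samples(0)
    if "fuzzy" in methods:
        sub = {pid: selections[0][pid]
               for pid in sorted(selections[0])[:tune_max_proteins]}
        fuzzy_params, trace = tune_fuzzy(
            X.loc[tr0], Y.loc[tr0], sub,
            config.fuzzy_tau_grid, config.fuzzy_alpha_grid,
            seed=int(substream(config.seed, "fuzzy_tune").integers(2**31)),
            inner_folds=config.inner_folds,
            grid_step_sd=config.fuzzy_grid_step_sd,
            min_window_samples=config.min_window_samples)
        tuning["fuzzy_trace"] = trace
        tuning["fuzzy_tau"] = fuzzy_params.tau
        tuning["fuzzy_alpha"] = fuzzy_params.alpha
        registry["fuzzy"] = FuzzyMethod(fuzzy_params)
    if "bn" in methods:
        registry["bn"] = BNMethod()
    if "rf" in methods:
        rf_params = RFParams(n_trees=config.rf_n_trees,
                             mtry_grid=config.rf_mtry_grid,
                             inner_folds=config.inner_folds)
        mtry, rf_trace = tune_rf_mtry(X.loc[tr0], Y.loc[tr0], rf_params,
                                      seed=config.seed)
        tuning["rf_mtry"] = mtry
        tuning["rf_trace"] = rf_trace
        registry["rf"] = RFMethod(mtry=mtry)
    if "lasso" in methods:
        registry["lasso"] = LassoMethod()
    for name in methods:
        if name not in registry:
            raise ValidationError(f"unknown method {name!r}")

    results = {name: run_cv(transcripts, proteins, registry[name], folds,
                            config, selections=selections or None)
               for name in methods}
    info_frames = [r.fit_info for r in results.values() if r.fit_info is not None]
    if info_frames:
        tuning["hyperparameters"] = pd.concat(info_frames, ignore_index=True)
    all_preds = [results[name].predictions for name in sorted(results)]
    weights = pd.DataFrame(columns=["protein", "fold", "method", "weight",
                                    "train_corr"])
    if len(results) > 1:
        ens_preds, weights = _ensemble_rows(results, folds, proteins.feature_ids)
        all_preds.append(ens_preds)
    predictions = pd.concat(all_preds, ignore_index=True)
    metrics = score_predictions(predictions, proteins, norm=config.nrmse_norm)
    summary = summarize(metrics)
    consistency = topk_consistency(metrics, k=config.top_k_report,
                                   n_folds=config.n_folds)
    return BenchmarkReport(config=config, predictions=predictions,
                           metrics=metrics, summary=summary,
                           consistency=consistency, weights=weights,
                           tuning=tuning)
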