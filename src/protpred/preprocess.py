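"""Normalization, institute merging, CV folds, and top-k transcript selection."""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionMatrix, ValidationError, substream

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldSplit:
    """A balanced random partition of samples into test folds."""

    n_folds: int
    sample_ids: tuple[str, ...]
    assignment: np.ndarray  # per-sample fold index

    def __post_init__(self) -> None:
        counts = np.bincount(self.assignment, minlength=self.n_folds)
        if counts.max() - counts.min() > 1:
            raise ValidationError("fold sizes differ by more than 1")
        if len(self.assignment) != len(self.sample_ids):
            raise ValidationError("assignment length mismatch")

    def test_samples(self, fold: int) -> list[str]:
        return [s for s, f in zip(self.sample_ids, self.assignment) if f == fold]

    def train_samples(self, fold: int) -> list[str]:
        return [s for s, f in zip(self.sample_ids, self.assignment) if f != fold]


@dataclass(frozen=True)
class TranscriptSelection:
    """The transcripts most (anti-)correlated with one protein, ranked by |rho|."""

    protein_id: str
    transcript_ids: tuple[str, ...]
    rhos: tuple[float, ...]

    def __post_init__(self) -> None:
        absr = [abs(r) for r in self.rhos]
        if any(a < b - 1e-12 for a, b in zip(absr, absr[1:])):
            raise ValidationError("selection must be sorted by |rho| descending")


def zscore_features(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each feature over its observed values (mean 0, sample SD 1).

    This is R's ``scale`` applied column-wise with NA handling: the mask is
    untouched, and features that are constant or have fewer than 2 observed
    values cannot be standardized — they are dropped from the output (and
    logged), so downstream feature pools never see them.
    """
    frame = matrix.to_frame()
    n_obs = frame.notna().sum(axis=0)
    sd = frame.std(axis=0, ddof=1)
    bad = (n_obs < 2) | (sd == 0.0) | sd.isna()
    if bad.any():
        logger.warning(
            "excluding %d constant/underobserved features: %s",
            int(bad.sum()), list(frame.columns[bad])[:10],
        )
        frame = frame.loc[:, ~bad]
        sd = sd[~bad]
    out = (frame - frame.mean(axis=0)) / sd
    return ExpressionMatrix.from_frame(
        out, cohort=matrix.cohort, layer=matrix.layer, institute=matrix.institute
    )


def merge_institutes(
    a: ExpressionMatrix, b: ExpressionMatrix, keep: str = "first"
) -> ExpressionMatrix:
    """Merge two institute versions of one protein layer.

    Only proteins measured by both institutes are retained; values (and the
    sample set) come from matrix ``a``. Averaging across institutes is
    deliberately not offered — reconciling two iTRAQ ratio scales is not a
    well-posed elementwise operation.
    """
    if keep != "first":
        raise ValidationError("only keep='first' is supported")
    shared = sorted(set(a.feature_ids) & set(b.feature_ids))
    if not shared:
        raise ValidationError("institutes share no proteins")
    return a.subset(features=shared)


def make_folds(sample_ids, n_folds: int, seed: int) -> FoldSplit:
    """Random balanced partition into ``n_folds`` test folds.

    Deterministic given the seed, and invariant to the input ordering of
    ``sample_ids`` (they are sorted before shuffling).
    """
    ids = sorted(map(str, sample_ids))
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample IDs")
    if len(ids) < n_folds:
        raise ValidationError(f"{len(ids)} samples cannot fill {n_folds} folds")
    rng = substream(seed, "folds")
    perm = rng.permutation(len(ids))
    assignment = np.empty(len(ids), dtype=int)
    # deal samples round-robin in shuffled order -> sizes differ by <= 1
    assignment[perm] = np.arange(len(ids)) % n_folds
    return FoldSplit(n_folds=n_folds, sample_ids=tuple(ids), assignment=assignment)


def _spearman_one(x: np.ndarray, y: np.ndarray, min_pairs: int = 3) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < min_pairs:
        return np.nan
    rx = stats.rankdata(x[ok])
    ry = stats.rankdata(y[ok])
    rx -= rx.mean()
    ry -= ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return np.nan
    return float(rx @ ry) / denom


def spearman_vector(
    transcripts: ExpressionMatrix, protein: np.ndarray, min_pairs: int = 3
) -> pd.Series:
    """Pairwise-complete Spearman rho of each transcript against one protein."""
    protein = np.asarray(protein, dtype=float)
    if len(protein) != len(transcripts.sample_ids):
        raise ValidationError("protein vector length mismatch")
    X = transcripts.values
    out = {}
    x_ok = ~np.isnan(X)
    y_ok = ~np.isnan(protein)
    if x_ok.all() and y_ok.all():
        # fast path: rank once, Pearson on ranks (identical to per-pair
        # Spearman when there is no missingness)
        rx = stats.rankdata(X, axis=0)
        ry = stats.rankdata(protein)
        rx = rx - rx.mean(axis=0)
        ry = ry - ry.mean()
        denom = np.sqrt((rx**2).sum(axis=0) * (ry**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (rx.T @ ry) / denom
        for j, tid in enumerate(transcripts.feature_ids):
            out[tid] = float(r[j]) if np.isfinite(r[j]) else np.nan
    else:
        for j, tid in enumerate(transcripts.feature_ids):
            out[tid] = _spearman_one(X[:, j], protein, min_pairs)
    return pd.Series(out)


def select_top_transcripts(
    transcripts_train: ExpressionMatrix,
    protein_train: np.ndarray,
    k: int,
    protein_id: str = "",
    min_pairs: int = 3,
) -> TranscriptSelection:
    """Pick the k transcripts with the largest |Spearman rho| to the protein.

    Anti-correlated transcripts count as much as correlated ones. Ties in
    |rho| break lexicographically on transcript ID; transcripts with fewer
    than ``min_pairs`` complete observation pairs are ineligible.
    """
    rhos = spearman_vector(transcripts_train, protein_train, min_pairs)
    rhos = rhos.dropna()
    if rhos.empty:
        raise ValidationError(
            f"no transcript has >= {min_pairs} complete pairs with protein "
            f"{protein_id or '<unnamed>'}"
        )
    order = sorted(rhos.index, key=lambda t: (-abs(rhos[t]), t))
    chosen = order[: int(k)]
    return TranscriptSelection(
        protein_id=protein_id,
        transcript_ids=tuple(chosen),
        rhos=tuple(float(rhos[t]) for t in chosen),
    )


def selections_to_frame(selections: dict[str, TranscriptSelection]) -> pd.DataFrame:
    """Audit table: one row per (protein, rank, transcript, rho)."""
    rows = []
    for pid in sorted(selections):
        sel = selections[pid]
        for rank, (tid, rho) in enumerate(zip(sel.transcript_ids, sel.rhos), 1):
            rows.append({"protein": pid, "rank": rank, "transcript": tid,
                         "rho": rho})
    return pd.DataFrame(rows, columns=["protein", "rank", "transcript", "rho"])


def matched_correlations(
    layer_a: ExpressionMatrix, layer_b: ExpressionMatrix, min_pairs: int = 3
) -> pd.DataFrame:
    """Per-feature Pearson correlation and covariance between two data layers.

    For every feature present in both layers, correlates the two layers'
    vectors over their shared samples (pairwise-complete). Features with
    fewer than ``min_pairs`` shared observations are skipped with a warning.
    Output is histogram-ready: columns feature, correlation, covariance, n.
    """
    shared_features = sorted(set(layer_a.feature_ids) & set(layer_b.feature_ids))
    shared_samples = sorted(set(layer_a.sample_ids) & set(layer_b.sample_ids))
    if not shared_features or not shared_samples:
        raise ValidationError("layers share no features or no samples")
    a = layer_a.subset(samples=shared_samples, features=shared_features)
    b = layer_b.subset(samples=shared_samples, features=shared_features)
    rows = []
    for j, fid in enumerate(shared_features):
        x, y = a.values[:, j], b.values[:, j]
        ok = ~(np.isnan(x) | np.isnan(y))
        n = int(ok.sum())
        if n < min_pairs:
            logger.warning("feature %s skipped: only %d shared observations", fid, n)
            continue
        xs, ys = x[ok], y[ok]
        cov = float(np.cov(xs, ys, ddof=1)[0, 1])
        sx, sy = xs.std(ddof=1), ys.std(ddof=1)
        corr = float(cov / (sx * sy)) if sx > 0 and sy > 0 else np.nan
        rows.append({"feature": fid, "correlation": corr, "covariance": cov, "n": n})
    return pd.DataFrame(rows, columns=["feature", "correlation", "covariance", "n"])
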