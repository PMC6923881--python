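"""Expression-matrix containers, file I/O, run configuration, pipeline and CLI.

The canonical in-memory orientation is samples x features. Expression files
on disk conventionally keep genes in rows, so the reader transposes by
default. Missing
values are "NA" (or empty) on disk and NaN in memory; the boolean mask
derived from NaN positions is the authoritative missingness record.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
import click


class ValidationError(ValueError):
    """Raised when inputs violate a structural contract (duplicates, shapes)."""


class ParseError(ValueError):
    """Raised when a file cell cannot be parsed; names the offending row/column."""


MISSING_TOKENS = ("", "NA", "NaN", "nan")


def substream(seed: int, *keys) -> np.random.Generator:
    """Derive an independent RNG substream from a master seed and stage keys.

    Every source of randomness in the pipeline draws from one of these, so
    adding or reordering one stage never perturbs another stage's draws.
    """
    ints = [zlib.crc32(str(k).encode("utf8")) for k in keys]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *ints]))


@dataclass
class ExpressionMatrix:
    """A samples x features real-valued expression table.

    Parameters
    ----------
    sample_ids, feature_ids:
        Unique identifiers for rows and columns respectively.
    values:
        Float array of shape ``(len(sample_ids), len(feature_ids))``;
        NaN marks missing entries.
    cohort, layer, institute:
        Optional axis metadata; ``layer`` is one of ``transcript``,
        ``protein`` or ``cnv``.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    cohort: str | None = None
    layer: str | None = None
    institute: str | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample IDs")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("duplicate feature IDs")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.sample_ids)}, {len(self.feature_ids)})"
            )

    # -- missingness ------------------------------------------------------
    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the entry is missing."""
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    # -- conversion -------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        cohort: str | None = None,
        layer: str | None = None,
        institute: str | None = None,
    ) -> "ExpressionMatrix":
        return cls(
            sample_ids=list(map(str, frame.index)),
            feature_ids=list(map(str, frame.columns)),
            values=frame.to_numpy(dtype=float),
            cohort=cohort,
            layer=layer,
            institute=institute,
        )

    # -- subsetting -------------------------------------------------------
    def subset(
        self,
        samples: Sequence[str] | None = None,
        features: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        frame = self.to_frame()
        if samples is not None:
            frame = frame.loc[list(samples)]
        if features is not None:
            frame = frame[list(features)]
        return ExpressionMatrix.from_frame(
            frame, cohort=self.cohort, layer=self.layer, institute=self.institute
        )

    def sorted(self) -> "ExpressionMatrix":
        """Canonical form: samples and features in lexicographic order."""
        return self.subset(sorted(self.sample_ids), sorted(self.feature_ids))

    def column(self, feature_id: str) -> np.ndarray:
        j = self.feature_ids.index(feature_id)
        return self.values[:, j]


def read_expression_tsv(
    path: str | Path,
    orientation: str = "features_in_rows",
    cohort: str | None = None,
    layer: str | None = None,
    institute: str | None = None,
) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    ``orientation="features_in_rows"`` (the common convention: one gene per
    row, first column gene identifier) transposes on load so the result is
    samples x features. Missing cells may be empty or "NA".
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate row identifiers in {path}: {dups}")
    if raw.columns.has_duplicates:
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate column identifiers in {path}: {dups}")
    cleaned = raw.apply(lambda col: col.str.strip())
    is_missing = cleaned.isin(MISSING_TOKENS)
    numeric = cleaned.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~is_missing
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"malformed numeric cell at row {raw.index[i]!r}, "
            f"column {raw.columns[j]!r} in {path}: {raw.iat[i, j]!r}"
        )
    frame = numeric.astype(float)
    if orientation == "features_in_rows":
        frame = frame.T
    return ExpressionMatrix.from_frame(
        frame, cohort=cohort, layer=layer, institute=institute
    )


def write_expression_tsv(
    matrix: ExpressionMatrix,
    path: str | Path,
    orientation: str = "features_in_rows",
) -> None:
    """Write a matrix as TSV with the "NA" missing token (round-trip safe)."""
    frame = matrix.to_frame()
    if orientation == "features_in_rows":
        frame = frame.T
        frame.index.name = "gene"
    else:
        frame.index.name = "sample"
    frame.to_csv(path, sep="\t", na_rep="NA")


def align_layers(
    transcripts: ExpressionMatrix, proteins: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both layers to their shared samples, in identical sorted order.

    Only measurements taken from the same samples are comparable across
    layers; samples present in just one layer are dropped.
    """
    shared = sorted(set(transcripts.sample_ids) & set(proteins.sample_ids))
    if not shared:
        raise ValidationError("transcript and protein matrices share no samples")
    return transcripts.subset(samples=shared), proteins.subset(samples=shared)


@dataclass
class RunConfig:
    """All tunable knobs of a benchmark run.

    Defaults reproduce the study conditions: 10-fold CV, top-8 Spearman
    transcript filter for the fuzzy and network models, fuzzy grids
    tau in {0.5, 1, 2} (transcript-SD window half-widths) x alpha in
    {0.1, 0.3} (density cutoffs), 100-tree random forests with
    mtry in {5, 10, 25}, LASSO penalty fractions 0.1..0.9, top-100
    consistency reporting, and a 10-sample minimum fuzzy window.
    """

    n_folds: int = 10
    top_k_transcripts: int = 8
    top_k_report: int = 100
    fuzzy_tau_grid: tuple[float, ...] = (0.5, 1.0, 2.0)
    fuzzy_alpha_grid: tuple[float, ...] = (0.1, 0.3)
    fuzzy_grid_step_sd: float = 0.1
    rf_n_trees: int = 100
    rf_mtry_grid: tuple[int, ...] = (5, 10, 25)
    lasso_fraction_grid: tuple[float, ...] = (
        0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9,
    )
    min_window_samples: int = 10
    inner_folds: int = 3
    lasso_inner_folds: int = 5
    nrmse_norm: str = "range"  # or "sd"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if self.top_k_transcripts < 1:
            raise ValidationError("top_k_transcripts must be >= 1")
        for name in ("fuzzy_tau_grid", "fuzzy_alpha_grid", "rf_mtry_grid",
                     "lasso_fraction_grid"):
            if not len(getattr(self, name)):
                raise ValidationError(f"{name} must be non-empty")
        if self.nrmse_norm not in ("range", "sd"):
            raise ValidationError("nrmse_norm must be 'range' or 'sd'")

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        for key, val in payload.items():
            if isinstance(val, tuple):
                payload[key] = list(val)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        fields = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, val in payload.items():
            if key not in fields:
                raise ValidationError(f"unknown config key {key!r}")
            if isinstance(val, list):
                val = tuple(val)
            kwargs[key] = val
        return cls(**kwargs)


@dataclass
class BenchmarkReport:
    """Everything a benchmark run produces, ready to serialize."""

    config: RunConfig
    predictions: pd.DataFrame  # protein, fold, sample, method, prediction, status
    metrics: pd.DataFrame      # protein, fold, method, pearson, nrmse, n_test, status
    summary: dict              # per-method medians and failure accounting
    consistency: pd.DataFrame  # method, protein, count
    weights: pd.DataFrame      # protein, fold, method, weight
    tuning: dict               # fuzzy trace table, chosen fuzzy params, mtry

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.predictions.to_csv(outdir / "predictions.tsv", sep="\t", index=False)
        self.metrics.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
        self.consistency.to_csv(outdir / "consistency.tsv", sep="\t", index=False)
        self.weights.to_csv(outdir / "weights.tsv", sep="\t", index=False)
        (outdir / "summary.json").write_text(json.dumps(self.summary, indent=2, sort_keys=True))
        self.config.to_yaml(outdir / "config.yaml")
        for key, fname in (("fuzzy_trace", "fuzzy_tuning.tsv"),
                           ("rf_trace", "rf_tuning.tsv"),
                           ("hyperparameters", "hyperparameters.tsv")):
            frame = self.tuning.get(key)
            if frame is not None:
                frame.to_csv(outdir / fname, sep="\t", index=False)
        chosen = {k: v for k, v in self.tuning.items()
                  if not isinstance(v, pd.DataFrame)}
        (outdir / "tuning.json").write_text(json.dumps(chosen, indent=2, sort_keys=True))


def run_pipeline(
    config: RunConfig,
    transcripts: ExpressionMatrix | None = None,
    proteins: ExpressionMatrix | None = None,
    cohort_spec=None,
    outdir: str | Path | None = None,
    methods: Sequence[str] = ("fuzzy", "bn", "rf", "lasso"),
) -> BenchmarkReport:
    """Run the full benchmark: preprocess, per-protein per-fold model fits,
    ensemble, and metric summaries.

    Either ``transcripts`` + ``proteins`` or a synthetic ``cohort_spec`` must
    be given. Deterministic for a fixed config seed; invariant to the row and
    column ordering of the inputs (matrices are canonicalized on entry).
    """
    from . import benchmark as bm  # local import: benchmark depends on our types

    config.validate()
    if cohort_spec is not None:
        from .synthetic_data import generate_cohort

        transcripts, proteins, _ = generate_cohort(cohort_spec)
    if transcripts is None or proteins is None:
        raise ValidationError("provide transcripts+proteins or a cohort_spec")
    report = bm.run_benchmark(transcripts, proteins, config, methods=methods)
    if outdir is not None:
        report.write(outdir)
    return report


# ---------------------------------------------------------------------------
# CLI


@click.group()
def cli() -> None:
    """protpred: benchmark transcript-to-protein abundance predictors."""


@cli.command()
@click.option("--out", "outdir", type=click.Path(), required=True)
@click.option("--seed", type=int, required=True)
@click.option("--n-samples", type=int, default=120, show_default=True)
@click.option("--n-transcripts", type=int, default=200, show_default=True)
@click.option("--n-proteins", type=int, default=60, show_default=True)
@click.option("--missing-rate", type=float, default=0.05, show_default=True)
@click.option("--cohort", type=str, default="BRCA", show_default=True)
@click.option("--institute-pair/--no-institute-pair", default=False,
              help="Also write a second, noisier institute version of the proteins.")
def simulate(outdir, seed, n_samples, n_transcripts, n_proteins, missing_rate,
             cohort, institute_pair):
    """Generate a synthetic cohort and write TSV matrices plus the manifest."""
    from .synthetic_data import CohortSpec, generate_cohort, generate_institute_pair

    spec = CohortSpec(
        n_samples=n_samples,
        n_transcripts=n_transcripts,
        n_proteins=n_proteins,
        missing_rate=missing_rate,
        cohort=cohort,
        seed=seed,
    )
    transcripts, proteins, manifest = generate_cohort(spec)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_tsv(transcripts, out / "transcripts.tsv")
    write_expression_tsv(proteins, out / "proteins.tsv")
    if institute_pair:
        a, b = generate_institute_pair(
            proteins, spec.institute_noise_sd, spec.institute_overlap,
            seed=spec.seed + 1,
        )
        write_expression_tsv(a, out / "proteins_institute_a.tsv")
        write_expression_tsv(b, out / "proteins_institute_b.tsv")
    (out / "manifest.json").write_text(manifest.to_json())
    click.echo(f"wrote cohort ({n_samples} samples, {n_transcripts} transcripts, "
               f"{n_proteins} proteins) to {out}")


def _config_options(func):
    opts = [
        click.option("--n-folds", type=int, default=10, show_default=True),
        click.option("--top-k-transcripts", type=int, default=8, show_default=True),
        click.option("--top-k-report", type=int, default=100, show_default=True),
        click.option("--rf-n-trees", type=int, default=100, show_default=True),
        click.option("--seed", type=int, default=0, show_default=True),
        click.option("--config", "config_path", type=click.Path(exists=True),
                     default=None, help="YAML config; flags override it."),
    ]
    for opt in reversed(opts):
        func = opt(func)
    return func


@cli.command()
@click.option("--transcripts", "transcripts_path", type=click.Path(exists=True),
              required=True)
@click.option("--proteins", "proteins_path", type=click.Path(exists=True),
              required=True)
@click.option("--out", "outdir", type=click.Path(), required=True)
@_config_options
def run(transcripts_path, proteins_path, outdir, n_folds, top_k_transcripts,
        top_k_report, rf_n_trees, seed, config_path):
    """Run the benchmark on TSV expression matrices and write result tables."""
    if config_path:
        config = RunConfig.from_yaml(config_path)
        config = dataclasses.replace(
            config, n_folds=n_folds, top_k_transcripts=top_k_transcripts,
            top_k_report=top_k_report, rf_n_trees=rf_n_trees, seed=seed,
        )
    else:
        config = RunConfig(
            n_folds=n_folds, top_k_transcripts=top_k_transcripts,
            top_k_report=top_k_report, rf_n_trees=rf_n_trees, seed=seed,
        )
    transcripts = read_expression_tsv(transcripts_path, layer="transcript")
    proteins = read_expression_tsv(proteins_path, layer="protein")
    report = run_pipeline(config, transcripts, proteins, outdir=outdir)
    click.echo(json.dumps(report.summary, indent=2, sort_keys=True))


@cli.command()
@click.option("--predictions", "predictions_path", type=click.Path(exists=True),
              required=True, help="predictions.tsv from a previous run")
@click.option("--proteins", "proteins_path", type=click.Path(exists=True),
              required=True, help="ground-truth protein TSV")
@click.option("--out", "outdir", type=click.Path(), required=True)
@click.option("--top-k", type=int, default=100, show_default=True)
@click.option("--bins", type=int, default=20, show_default=True)
def report(predictions_path, proteins_path, outdir, top_k, bins):
    """Recompute metrics, consistency tables and histograms from stored predictions."""
    from . import benchmark as bm

    predictions = pd.read_csv(predictions_path, sep="\t")
    proteins = read_expression_tsv(proteins_path, layer="protein")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    metrics = bm.score_predictions(predictions, proteins)
    metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)
    summary = bm.summarize(metrics)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    n_folds = int(predictions["fold"].max()) + 1
    consistency = bm.topk_consistency(metrics, k=top_k, n_folds=n_folds)
    consistency.to_csv(out / "consistency.tsv", sep="\t", index=False)
    bm.save_histograms(metrics, out, bins=bins)
    click.echo(json.dumps(summary, indent=2, sort_keys=True))


if __name__ == "__main__":
    cli()
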