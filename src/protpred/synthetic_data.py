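"""Synthetic proteogenomic cohorts with known transcript-protein structure.

Emulates the statistical shape of matched tumor RNA-seq / iTRAQ proteomics
cohorts: z-scored transcript values with correlated blocks, protein values
generated from a mixture of relationship archetypes, two correlated-but-not-
identical "institute" versions of the protein layer, and missing entries.
Each protein's generating archetype is recorded in a ground-truth manifest
so recovery tests can check what a method should (and should not) find.

Archetypes
----------
linear_sparse   y = sum_j beta_j x_j + eps          (sparse linear signal)
chain           x2 = rho x1 + e,  y = rho x2 + e'   (Markov chain; the
                x1-y association is entirely indirect, which is what a
                data-processing-inequality pruner must detect)
additive_and    y = (x_a + x_b)/2 + eps             (both transcripts needed)
threshold_and   y = +1 if x_a>0 and x_b>0 else -1, plus eps  (logical AND,
                strongly non-linear)
null            y = eps                              (no signal at all)

Default noise levels put the strongest per-transcript protein correlation
near 0.5 for signal archetypes, matching the ~0.4-0.5 transcript-protein
correlations reported for matched tumor cohorts.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionMatrix, ValidationError, substream

ARCHETYPE_KINDS = ("linear_sparse", "chain", "additive_and", "threshold_and", "null")

# support sizes per archetype
_SUPPORT_SIZE = {
    "linear_sparse": 3,
    "chain": 2,
    "additive_and": 2,
    "threshold_and": 2,
    "null": 0,
}

# defaults chosen so max_j corr(y, x_j) ~ 0.5 for signal archetypes
DEFAULT_LINEAR_BETAS = (1.0, 0.7, 0.5)
DEFAULT_LINEAR_NOISE_SD = 1.503   # beta1/sqrt(sum beta^2 + sd^2) = 0.5
DEFAULT_ADDITIVE_NOISE_SD = 0.707  # 0.5/sqrt(0.5 + sd^2) = 0.5
DEFAULT_THRESHOLD_NOISE_SD = 0.5
DEFAULT_NULL_NOISE_SD = 1.0
DEFAULT_CHAIN_RHO = 0.9


@dataclass(frozen=True)
class ArchetypeSpec:
    """Ground truth for one protein: its generating model class."""

    kind: str
    support: tuple[int, ...]
    coefficients: tuple[float, ...]
    noise_sd: float

    def __post_init__(self) -> None:
        if self.kind not in ARCHETYPE_KINDS:
            raise ValidationError(f"unknown archetype kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.kind == "null":
            if self.support:
                raise ValidationError("null archetype must have empty support")
        elif not self.support:
            raise ValidationError(f"{self.kind} archetype needs non-empty support")
        if self.kind in ("chain", "additive_and", "threshold_and") and len(self.support) != 2:
            raise ValidationError(f"{self.kind} archetype needs exactly 2 support transcripts")


@dataclass(frozen=True)
class CohortSpec:
    """Shape and noise parameters of one synthetic cohort."""

    n_samples: int = 120
    n_transcripts: int = 200
    n_proteins: int = 60
    proportions: tuple[tuple[str, float], ...] = (
        ("linear_sparse", 0.30),
        ("chain", 0.15),
        ("additive_and", 0.20),
        ("threshold_and", 0.15),
        ("null", 0.20),
    )
    block_size: int = 10
    block_rho: float = 0.5
    chain_rho: float = DEFAULT_CHAIN_RHO
    linear_betas: tuple[float, ...] = DEFAULT_LINEAR_BETAS
    linear_noise_sd: float = DEFAULT_LINEAR_NOISE_SD
    additive_noise_sd: float = DEFAULT_ADDITIVE_NOISE_SD
    threshold_noise_sd: float = DEFAULT_THRESHOLD_NOISE_SD
    null_noise_sd: float = DEFAULT_NULL_NOISE_SD
    missing_rate: float = 0.05            # protein layer
    transcript_missing_rate: float = 0.01  # transcript layer (RNA-seq is near-complete)
    institute_noise_sd: float = 1.0
    institute_overlap: float = 0.9
    cohort: str = "BRCA"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 20:
            raise ValidationError("n_samples must be >= 20")
        total = sum(p for _, p in self.proportions)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"archetype proportions sum to {total}, not 1")
        for kind, _ in self.proportions:
            if kind not in ARCHETYPE_KINDS:
                raise ValidationError(f"unknown archetype kind {kind!r}")
        if not (0.0 <= self.missing_rate < 1.0 and 0.0 <= self.transcript_missing_rate < 1.0):
            raise ValidationError("missing rates must be in [0, 1)")
        if not (0.0 < self.institute_overlap <= 1.0):
            raise ValidationError("institute_overlap must be in (0, 1]")


@dataclass
class GroundTruthManifest:
    """Per-protein archetypes plus the spec; fully determines regeneration."""

    archetypes: dict[str, ArchetypeSpec]
    spec: CohortSpec

    def to_json(self) -> str:
        payload = {
            "spec": dataclasses.asdict(self.spec),
            "archetypes": {
                pid: dataclasses.asdict(a) for pid, a in self.archetypes.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        payload = json.loads(text)
        spec_kwargs = dict(payload["spec"])
        spec_kwargs["proportions"] = tuple(
            (k, p) for k, p in spec_kwargs["proportions"]
        )
        spec_kwargs["linear_betas"] = tuple(spec_kwargs["linear_betas"])
        spec = CohortSpec(**spec_kwargs)
        archetypes = {
            pid: ArchetypeSpec(
                kind=a["kind"],
                support=tuple(a["support"]),
                coefficients=tuple(a["coefficients"]),
                noise_sd=a["noise_sd"],
            )
            for pid, a in payload["archetypes"].items()
        }
        return cls(archetypes=archetypes, spec=spec)


def archetype_counts(spec: CohortSpec) -> dict[str, int]:
    """Largest-remainder apportionment of proteins to archetypes."""
    raw = {kind: prop * spec.n_proteins for kind, prop in spec.proportions}
    counts = {kind: math.floor(v) for kind, v in raw.items()}
    short = spec.n_proteins - sum(counts.values())
    by_frac = sorted(raw, key=lambda k: (-(raw[k] - counts[k]), k))
    for kind in by_frac[:short]:
        counts[kind] += 1
    return counts


def _blocked_transcripts(rng: np.random.Generator, n: int, p: int,
                         block_size: int, rho: float) -> np.ndarray:
    """Standard-normal transcripts with AR(1) correlation inside each block."""
    z = rng.standard_normal((n, p))
    if block_size <= 1 or rho == 0.0:
        return z
    x = z.copy()
    scale = math.sqrt(1.0 - rho * rho)
    for j in range(1, p):
        if j % block_size != 0:  # block boundary restarts the chain
            x[:, j] = rho * x[:, j - 1] + scale * z[:, j]
    return x


def _assign_archetypes(spec: CohortSpec) -> list[ArchetypeSpec]:
    counts = archetype_counts(spec)
    cursor = 0
    out: list[ArchetypeSpec] = []
    order = [kind for kind, _ in spec.proportions]
    for kind in order:
        size = _SUPPORT_SIZE[kind]
        for _ in range(counts[kind]):
            support = tuple(range(cursor, cursor + size))
            if support and support[-1] >= spec.n_transcripts:
                raise ValidationError(
                    f"support index {support[-1]} >= n_transcripts "
                    f"{spec.n_transcripts}; cohort spec is infeasible"
                )
            cursor += size
            if kind == "linear_sparse":
                out.append(ArchetypeSpec(kind, support, tuple(spec.linear_betas),
                                         spec.linear_noise_sd))
            elif kind == "chain":
                out.append(ArchetypeSpec(kind, support, (spec.chain_rho,),
                                         math.sqrt(1.0 - spec.chain_rho**2)))
            elif kind == "additive_and":
                out.append(ArchetypeSpec(kind, support, (0.5, 0.5),
                                         spec.additive_noise_sd))
            elif kind == "threshold_and":
                out.append(ArchetypeSpec(kind, support, (),
                                         spec.threshold_noise_sd))
            else:
                out.append(ArchetypeSpec(kind, (), (), spec.null_noise_sd))
    return out


def _realize_protein(arch: ArchetypeSpec, X: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw one protein column; may rewrite a transcript column for chains."""
    n = X.shape[0]
    eps = arch.noise_sd * rng.standard_normal(n)
    if arch.kind == "null":
        return eps
    if arch.kind == "linear_sparse":
        betas = np.asarray(arch.coefficients[: len(arch.support)])
        return X[:, list(arch.support)] @ betas + eps
    if arch.kind == "chain":
        i, j = arch.support
        rho = arch.coefficients[0]
        scale = math.sqrt(1.0 - rho * rho)
        X[:, j] = rho * X[:, i] + scale * rng.standard_normal(n)
        return rho * X[:, j] + eps  # noise_sd is already sqrt(1-rho^2)
    if arch.kind == "additive_and":
        a, b = arch.support
        return 0.5 * (X[:, a] + X[:, b]) + eps
    if arch.kind == "threshold_and":
        a, b = arch.support
        return np.where((X[:, a] > 0) & (X[:, b] > 0), 1.0, -1.0) + eps
    raise AssertionError(arch.kind)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruthManifest]:
    """Generate one cohort: transcripts, proteins and the truth manifest.

    Deterministic given ``spec.seed``: regenerating from the manifest's spec
    reproduces both matrices bit-for-bit. Support indices are disjoint across
    proteins, so every protein's archetype can be identified unambiguously.
    """
    rng_x = substream(spec.seed, "transcripts", spec.cohort)
    rng_y = substream(spec.seed, "proteins", spec.cohort)
    X = _blocked_transcripts(rng_x, spec.n_samples, spec.n_transcripts,
                             spec.block_size, spec.block_rho)
    archetypes = _assign_archetypes(spec)
    width = len(str(spec.n_proteins))
    protein_ids = [f"P{i+1:0{width}d}" for i in range(spec.n_proteins)]
    twidth = len(str(spec.n_transcripts))
    transcript_ids = [f"T{j+1:0{twidth}d}" for j in range(spec.n_transcripts)]
    Y = np.empty((spec.n_samples, spec.n_proteins))
    for i, arch in enumerate(archetypes):
        Y[:, i] = _realize_protein(arch, X, rng_y)
    sample_ids = [f"{spec.cohort}_S{i+1:03d}" for i in range(spec.n_samples)]
    transcripts = ExpressionMatrix(sample_ids, transcript_ids, X,
                                   cohort=spec.cohort, layer="transcript")
    proteins = ExpressionMatrix(sample_ids, protein_ids, Y,
                                cohort=spec.cohort, layer="protein")
    if spec.transcript_missing_rate > 0:
        transcripts = inject_missing(
            transcripts, spec.transcript_missing_rate,
            seed=spec.seed, _stream=("missing", "transcript", spec.cohort))
    if spec.missing_rate > 0:
        proteins = inject_missing(
            proteins, spec.missing_rate,
            seed=spec.seed, _stream=("missing", "protein", spec.cohort))
    manifest = GroundTruthManifest(
        archetypes=dict(zip(protein_ids, archetypes)), spec=spec)
    return transcripts, proteins, manifest


def generate_institute_pair(
    proteins: ExpressionMatrix,
    noise_sd: float,
    overlap: float,
    seed: int,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Two "institute" quantifications of one protein layer.

    Institute A is the input unchanged; institute B adds independent Gaussian
    noise and is restricted to a random fraction ``overlap`` of the proteins,
    mimicking two mass-spec sites measuring overlapping but not identical
    protein panels with imperfect agreement.
    """
    if not (0.0 < overlap <= 1.0):
        raise ValidationError("overlap must be in (0, 1]")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = substream(seed, "institute_pair")
    n_keep = max(1, int(round(overlap * len(proteins.feature_ids))))
    keep_idx = np.sort(rng.choice(len(proteins.feature_ids), size=n_keep,
                                  replace=False))
    keep = [proteins.feature_ids[j] for j in keep_idx]
    a = dataclasses.replace(proteins, institute="A")
    b_values = proteins.values[:, keep_idx] + noise_sd * rng.standard_normal(
        (len(proteins.sample_ids), n_keep))
    b = ExpressionMatrix(list(proteins.sample_ids), keep, b_values,
                         cohort=proteins.cohort, layer=proteins.layer,
                         institute="B")
    return a, b


def inject_missing(
    matrix: ExpressionMatrix,
    rate: float,
    seed: int,
    _stream: tuple = ("missing",),
) -> ExpressionMatrix:
    """Mask each entry independently with probability ``rate``."""
    if not (0.0 <= rate < 1.0):
        raise ValidationError("missing rate must be in [0, 1)")
    if rate == 0.0:
        return dataclasses.replace(matrix, values=matrix.values.copy())
    rng = substream(seed, *_stream)
    drop = rng.random(matrix.values.shape) < rate
    values = matrix.values.copy()
    values[drop] = np.nan
    return dataclasses.replace(matrix, values=values)
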