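"""Bulk-expression signature scoring.

Counts are library-size normalized to counts-per-million and log2
transformed, z-scored per gene across samples, and summed over signature
genes (up minus down).  The custom 5-gene score is the fixed signature
up = {TP63, KRT5, KRT6A}, down = {GATA6, HNF4A}.  A transform-state flag
on the matrix enforces the order of operations.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FieldRangeError, MissingGeneError, SchemaError, TransformStateError


class TransformState(str, enum.Enum):
    COUNTS = "counts"
    LOG_CPM = "log_cpm"
    ZSCORE = "zscore"


CUSTOM5_UP = ("TP63", "KRT5", "KRT6A")
CUSTOM5_DOWN = ("GATA6", "HNF4A")

#: Known alternate casings/synonyms, applied after uppercasing.
GENE_ALIASES = {"HNF4ALPHA": "HNF4A", "P63": "TP63"}


def _canon(symbol: str) -> str:
    s = symbol.strip().upper()
    return GENE_ALIASES.get(s, s)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples values with a tracked transform state."""

    values: pd.DataFrame
    state: TransformState = TransformState.COUNTS

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise SchemaError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise SchemaError("duplicate sample ids")
        if self.state is TransformState.COUNTS and (self.values.values < 0).any():
            raise FieldRangeError("negative counts")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def find_gene(self, symbol: str) -> str | None:
        """Case-insensitive, alias-aware lookup of a gene row id."""
        target = _canon(symbol)
        for g in self.values.index:
            if _canon(str(g)) == target:
                return g
        return None


@dataclass(frozen=True)
class GeneSignature:
    name: str
    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        up = {_canon(g) for g in self.up_genes}
        down = {_canon(g) for g in self.down_genes}
        if up & down:
            raise SchemaError(f"signature {self.name}: up and down overlap")
        if not (up | down):
            raise SchemaError(f"signature {self.name}: empty gene sets")


CUSTOM5 = GeneSignature("custom5", up_genes=CUSTOM5_UP, down_genes=CUSTOM5_DOWN)


@dataclass(frozen=True)
class ScoreVector:
    signature: str
    samples: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (len(self.samples),):
            raise SchemaError("one score per sample required")
        if not np.isfinite(scores).all():
            raise FieldRangeError("non-finite signature score")
        object.__setattr__(self, "scores", scores)


def _require_state(matrix: ExpressionMatrix, state: TransformState, op: str) -> None:
    if matrix.state is not state:
        raise TransformStateError(
            f"{op} requires a matrix in state {state.value!r}, "
            f"got {matrix.state.value!r}"
        )


def cpm_log2(counts: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """value -> log2(1e6 * value / column_sum + pseudocount)."""
    _require_state(counts, TransformState.COUNTS, "cpm_log2")
    libsize = counts.values.sum(axis=0)
    if (libsize <= 0).any():
        bad = list(libsize.index[libsize <= 0])
        raise FieldRangeError(f"zero library size for samples {bad}")
    cpm = counts.values * (1e6 / libsize)
    return ExpressionMatrix(values=np.log2(cpm + pseudocount),
                            state=TransformState.LOG_CPM)


def zscore_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each gene row to unit sample sd (n-1 denominator)
    across samples; zero-variance rows map to zeros."""
    _require_state(matrix, TransformState.LOG_CPM, "zscore_genes")
    if matrix.values.shape[1] < 2:
        raise FieldRangeError("z-scoring requires at least 2 samples")
    x = matrix.values
    centered = x.sub(x.mean(axis=1), axis=0)
    sd = x.std(axis=1, ddof=1)
    z = centered.div(sd.where(sd > 0, np.inf), axis=0)
    return ExpressionMatrix(values=z, state=TransformState.ZSCORE)


def signature_score(matrix: ExpressionMatrix, signature: GeneSignature) -> ScoreVector:
    """Per sample: sum of z over up genes minus sum of z over down genes.

    Signature genes absent from the matrix are skipped with a warning;
    if none are present, that is an error.
    """
    _require_state(matrix, TransformState.ZSCORE, "signature_score")
    up_rows, down_rows, missing = [], [], []
    for g in signature.up_genes:
        row = matrix.find_gene(g)
        (up_rows.append(row) if row is not None else missing.append(g))
    for g in signature.down_genes:
        row = matrix.find_gene(g)
        (down_rows.append(row) if row is not None else missing.append(g))
    if not up_rows and not down_rows:
        raise MissingGeneError(
            f"signature {signature.name}: no signature gene present"
        )
    if missing:
        warnings.warn(
            f"signature {signature.name}: skipping absent genes {missing}",
            stacklevel=2,
        )
    scores = np.zeros(matrix.values.shape[1])
    if up_rows:
        scores = scores + matrix.values.loc[up_rows].sum(axis=0).to_numpy()
    if down_rows:
        scores = scores - matrix.values.loc[down_rows].sum(axis=0).to_numpy()
    return ScoreVector(signature=signature.name,
                       samples=tuple(matrix.samples), scores=scores)


def custom5_score(matrix: ExpressionMatrix) -> ScoreVector:
    """[z(TP63) + z(KRT5) + z(KRT6A)] - [z(GATA6) + z(HNF4A)] per sample.

    All five genes must be present (case-insensitive symbol match).
    """
    _require_state(matrix, TransformState.ZSCORE, "custom5_score")
    absent = [g for g in (*CUSTOM5_UP, *CUSTOM5_DOWN)
              if matrix.find_gene(g) is None]
    if absent:
        raise MissingGeneError(f"5-gene score needs {absent} in the matrix")
    return ScoreVector(
        signature=CUSTOM5.name,
        samples=tuple(matrix.samples),
        scores=signature_score(matrix, CUSTOM5).scores,
    )


def dichotomize_scores(scores: ScoreVector, rule: str = "median") -> dict[str, str]:
    """Scores strictly above the median -> HIGH, at or below -> LOW.

    Identical scores everywhere is degenerate: everything is LOW and a
    warning is issued.
    """
    if rule != "median":
        raise FieldRangeError(f"unknown dichotomization rule {rule!r}")
    if len(scores.samples) < 2:
        raise FieldRangeError("dichotomization needs at least 2 samples")
    if np.ptp(scores.scores) == 0:
        warnings.warn("all signature scores identical; every sample is LOW",
                      stacklevel=2)
        return {s: "LOW" for s in scores.samples}
    med = float(np.median(scores.scores))
    return {
        s: ("HIGH" if v > med else "LOW")
        for s, v in zip(scores.samples, scores.scores)
    }


def rank_log2fc(matrix: ExpressionMatrix, groups: dict[str, str]) -> pd.DataFrame:
    """Per-gene mean(high) - mean(low) on the log2 scale, sorted
    descending.  Expects a LOG_CPM matrix and HIGH/LOW labels."""
    _require_state(matrix, TransformState.LOG_CPM, "rank_log2fc")
    high = [s for s in matrix.samples if groups.get(s) == "HIGH"]
    low = [s for s in matrix.samples if groups.get(s) == "LOW"]
    if not high or not low:
        raise FieldRangeError("both HIGH and LOW groups must be non-empty")
    lfc = (matrix.values[high].mean(axis=1)
           - matrix.values[low].mean(axis=1))
    out = pd.DataFrame({"gene": matrix.genes, "log2fc": lfc.to_numpy()})
    return out.sort_values("log2fc", ascending=False, kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, *,
                    state: TransformState = TransformState.COUNTS) -> ExpressionMatrix:
    """Read a delimited genes x samples matrix (first column: gene id).

    Tab- and comma-separated files are both accepted.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return ExpressionMatrix(values=df, state=state)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    """Read a two-column gene/direction TSV (direction: up|down)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "direction"} <= set(df.columns):
        raise SchemaError("signature file needs 'gene' and 'direction' columns")
    up = tuple(df.loc[df["direction"].str.lower() == "up", "gene"])
    down = tuple(df.loc[df["direction"].str.lower() == "down", "gene"])
    return GeneSignature(name or Path(path).stem, up_genes=up, down_genes=down)
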