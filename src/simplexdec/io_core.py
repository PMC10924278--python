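"""Expression-matrix I/O, validation, and scatter-simplex projection.

The deconvolution model is linear on the measurement scale:
``X[g, n] = sum_k S[g, k] * A[n, k]`` with a genes x samples observed
matrix ``X``, a non-negative cell-type expression matrix ``S`` and a
row-stochastic sample x cell-type proportion matrix ``A``.  Every gene
row of ``X``, divided by its own sum, is then a convex combination of
the (column-normalized) columns of ``A`` — the "scatter simplex" whose
vertices this package hunts for.  This module owns the container for
``X``, the readers/writers for the on-disk formats, and the
perspective projection onto that simplex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger("simplexdec")

__all__ = [
    "ExpressionMatrix",
    "NormalizedScatter",
    "ScaleReport",
    "ValidationError",
    "load_expression",
    "save_expression",
    "detect_scale",
    "filter_genes",
    "normalize_gene_vectors",
]

#: max-entry threshold below which input is flagged as probably log-scale
LOG_SCALE_MAX = 50.0


class ValidationError(ValueError):
    """Raised when an input matrix violates the model's preconditions."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Non-negative genes x samples expression matrix on the linear scale.

    Parameters
    ----------
    values
        Dense float array, shape ``(n_genes, n_samples)``, all entries
        finite and ``>= 0``.
    gene_ids
        Unique row identifiers, one per gene.
    sample_ids
        Unique column identifiers, one per sample.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", [str(g) for g in self.gene_ids])
        object.__setattr__(self, "sample_ids", [str(s) for s in self.sample_ids])
        if values.ndim != 2:
            raise ValidationError(f"expected a 2-d matrix, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            g, n = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite entry at gene row {g} ({self.gene_ids[g]}), "
                f"sample column {n}"
            )
        if np.any(values < 0):
            g, n = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative entry {values[g, n]!r} at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[n]!r}; expression must be non-negative "
                "linear-scale intensities"
            )
        if len(self.gene_ids) != values.shape[0]:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {values.shape[0]} rows"
            )
        if len(self.sample_ids) != values.shape[1]:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {values.shape[1]} columns"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
                raise ValidationError(f"duplicate {name} id {dup!r}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.sample_ids)
        df.insert(0, "gene_id", self.gene_ids)
        return df


@dataclass(frozen=True)
class NormalizedScatter:
    """Row-sum-normalized gene vectors: the scatter simplex point cloud.

    ``points[i]`` sums to 1 and corresponds to original gene row
    ``retained_gene_index[i]``.  Genes whose row summed to zero cannot
    be projected and are listed in ``dropped_genes`` as
    ``(original_row, reason)`` pairs.
    """

    points: np.ndarray
    retained_gene_index: np.ndarray
    dropped_genes: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        object.__setattr__(
            self, "retained_gene_index", np.asarray(self.retained_gene_index, dtype=int)
        )
        if pts.shape[0] != self.retained_gene_index.shape[0]:
            raise ValidationError("retained_gene_index length must match point count")
        if pts.size and np.max(np.abs(pts.sum(axis=1) - 1.0)) > 1e-9:
            raise ValidationError("scatter rows must sum to 1 within 1e-9")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_samples(self) -> int:
        return self.points.shape[1]


@dataclass(frozen=True)
class ScaleReport:
    suspected_log: bool
    max_value: float


def _numeric_frame(df: pd.DataFrame, path: str) -> np.ndarray:
    """Coerce a parsed table to floats, reporting the first bad cell."""
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric cell {df.iat[r, c]!r} at gene row "
            f"{df.index[r]!r}, sample column {df.columns[c]!r}"
        )
    if coerced.isna().to_numpy().any():
        r, c = np.argwhere(coerced.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: missing value at gene row {df.index[r]!r}, "
            f"sample column {df.columns[c]!r}"
        )
    # exact strtod parse so that full-precision writes round-trip bit-identically
    return df.to_numpy(dtype=str).astype(np.float64)


def load_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Load an expression matrix from TSV, CSV, or MatrixMarket.

    TSV/CSV files carry sample ids in the header row and gene ids in the
    first column.  The MTX variant expects one-id-per-line sidecar files
    ``genes.txt`` and ``samples.txt`` next to the ``.mtx`` file.  Row and
    column ordering is preserved exactly as on disk.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "tsv"
        )
    if format == "mtx":
        genes_file = path.parent / "genes.txt"
        samples_file = path.parent / "samples.txt"
        for sidecar in (genes_file, samples_file):
            if not sidecar.exists():
                raise FileNotFoundError(
                    f"MTX input requires sidecar id file {sidecar}"
                )
        mat = mmread(path)
        values = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
        gene_ids = genes_file.read_text().split()
        sample_ids = samples_file.read_text().split()
        return ExpressionMatrix(values, gene_ids, sample_ids)
    if format not in ("tsv", "csv"):
        raise ValueError(f"unknown format {format!r}")
    sep = "\t" if format == "tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    values = _numeric_frame(df, str(path))
    return ExpressionMatrix(values, list(df.index), list(df.columns))


def save_expression(X: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a matrix as TSV/CSV with full-precision (``repr``) floats.

    Full precision makes save -> load an exact bit-level round trip for
    float64 data.
    """
    sep = "\t" if format == "tsv" else ","
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id" + sep + sep.join(X.sample_ids) + "\n")
        for gid, row in zip(X.gene_ids, X.values):
            fh.write(gid + sep + sep.join(repr(float(v)) for v in row) + "\n")


def detect_scale(X: ExpressionMatrix) -> ScaleReport:
    """Heuristically flag data that looks log-transformed.

    Linear mixing is additive; log-scale input silently breaks the model,
    so a matrix whose maximum entry is below ``LOG_SCALE_MAX`` is flagged.
    Report only — the data is never transformed.
    """
    max_value = float(X.values.max()) if X.values.size else 0.0
    return ScaleReport(suspected_log=max_value < LOG_SCALE_MAX, max_value=max_value)


def filter_genes(X: ExpressionMatrix, min_peak: float = 0.0) -> ExpressionMatrix:
    """Keep genes whose peak expression reaches ``min_peak`` and whose
    row sum is positive; row order is preserved."""
    if min_peak < 0:
        raise ValueError("min_peak must be >= 0")
    peaks = X.values.max(axis=1) if X.values.size else np.zeros(X.n_genes)
    sums = X.values.sum(axis=1)
    keep = (peaks >= min_peak) & (sums > 0)
    if not keep.any():
        raise ValidationError("no genes survive filtering")
    kept = np.flatnonzero(keep)
    if kept.size < X.n_genes:
        logger.info(
            "filter_genes: kept %d/%d genes (min_peak=%g)",
            kept.size, X.n_genes, min_peak,
        )
    return ExpressionMatrix(
        X.values[kept], [X.gene_ids[i] for i in kept], X.sample_ids
    )


def normalize_gene_vectors(X: ExpressionMatrix) -> NormalizedScatter:
    """Perspective-project gene rows onto the standard simplex (L1).

    Each retained row is divided by its own sum so the point cloud lives
    on the standard simplex where convex-combination geometry holds
    exactly; all-zero rows cannot be projected and are dropped with
    reason ``"all-zero"``.
    """
    sums = X.values.sum(axis=1)
    keep = sums > 0
    dropped = [(int(i), "all-zero") for i in np.flatnonzero(~keep)]
    if dropped:
        logger.info("normalize_gene_vectors: dropped %d all-zero genes", len(dropped))
    kept = np.flatnonzero(keep)
    points = X.values[kept] / sums[kept, None]
    return NormalizedScatter(points=points, retained_gene_index=kept, dropped_genes=dropped)
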