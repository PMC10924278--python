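"""Turn the selected simplex into proportions A, signatures S, and markers.

The K selected vertex directions equal the (column-normalized) columns
of the proportion matrix A up to a positive per-column scale; the scales
are recovered from the row-stochasticity of A, and the cell-type
expression matrix S then follows by per-gene non-negative least squares
against A.  ``run_pipeline`` chains the full workflow:

    filter -> normalize -> radius-fixed clustering -> (optional merge)
    -> LP vertex candidates -> floating search + MDL -> A, S, markers
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io_core import ExpressionMatrix, filter_genes, normalize_gene_vectors
from .model_select import ModelSelectionTrace, SimplexModel, merge_adjacent_clusters, select_model
from .rfc import RFCResult, _angles_to, cluster_center_matrix, radius_fixed_cluster
from .rfc import DEFAULT_MIN_MEMBERS, DEFAULT_RADIUS
from .simplex_lp import DEFAULT_LP_TOLERANCE, detect_vertex_candidates

logger = logging.getLogger("simplexdec")

__all__ = [
    "DeconvolutionConfig",
    "DeconvolutionResult",
    "PipelineError",
    "estimate_A",
    "estimate_S",
    "assign_markers",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is attached to the message."""


@dataclass(frozen=True)
class DeconvolutionConfig:
    """Tunable knobs of the deconvolution pipeline.

    ``radius``/``min_members`` control marker-cluster tightness and
    density, ``lp_tolerance`` the margin above which a cluster counts as
    a simplex vertex, and ``K_min``/``K_max`` the surveyed model orders.
    """

    min_peak: float = 0.0
    radius: float = DEFAULT_RADIUS
    min_members: int = DEFAULT_MIN_MEMBERS
    merge_enabled: bool = False
    merge_angle: float | None = None  # defaults to radius / 2
    lp_tolerance: float = DEFAULT_LP_TOLERANCE
    K_min: int = 2
    K_max: int = 8

    def validate(self) -> None:
        if self.min_peak < 0:
            raise ValueError("min_peak must be >= 0")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.min_members < 1:
            raise ValueError("min_members must be >= 1")
        if not 0 < self.lp_tolerance < 0.5:
            raise ValueError("lp_tolerance must lie in (0, 0.5)")
        if not 2 <= self.K_min <= self.K_max:
            raise ValueError("need 2 <= K_min <= K_max")
        if self.merge_angle is not None and self.merge_angle < 0:
            raise ValueError("merge_angle must be >= 0")

    @property
    def effective_merge_angle(self) -> float:
        return self.radius / 2 if self.merge_angle is None else self.merge_angle


@dataclass(frozen=True)
class DeconvolutionResult:
    A: np.ndarray                 # samples x K, rows sum to 1
    S: np.ndarray                 # genes x K (all input genes)
    markers: pd.DataFrame         # gene_id, cell_type_index, angle_to_vertex
    trace: ModelSelectionTrace
    config_echo: dict
    sample_ids: list[str]
    gene_ids: list[str]
    rfc: RFCResult | None = None

    @property
    def K(self) -> int:
        return self.A.shape[1]

    def A_frame(self) -> pd.DataFrame:
        cols = [f"celltype_{k}" for k in range(1, self.K + 1)]
        df = pd.DataFrame(self.A, columns=cols)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def S_frame(self) -> pd.DataFrame:
        cols = [f"celltype_{k}" for k in range(1, self.K + 1)]
        df = pd.DataFrame(self.S, columns=cols)
        df.insert(0, "gene_id", self.gene_ids)
        return df


def estimate_A(model: SimplexModel) -> np.ndarray:
    """Recover the row-stochastic proportion matrix from the vertices.

    Each normalized vertex row equals a column of A divided by its sum,
    so A is fixed up to one positive scale per column.  The scales are
    the least-squares solution of "rows of V^T · diag(c) sum to 1";
    negative ripples are clipped at zero and rows renormalized.
    """
    V = model.vertex_matrix  # K x samples, rows sum to 1
    K, N = V.shape
    if K < 2:
        raise ValueError("need at least 2 vertices")
    if np.linalg.matrix_rank(V) < K:
        raise ValueError("collinear vertices: vertex matrix rank < K")
    c, *_ = np.linalg.lstsq(V.T, np.ones(N), rcond=None)
    c = np.clip(c, 0.0, None)
    A = V.T * c[None, :]
    A = np.clip(A, 0.0, None)
    row_sums = A.sum(axis=1, keepdims=True)
    if np.any(row_sums == 0):
        raise ValueError("a sample received zero total proportion")
    return A / row_sums


def estimate_S(X: ExpressionMatrix, A: np.ndarray) -> np.ndarray:
    """Per-gene NNLS signature estimate: S[g] = argmin_{s>=0} |x_g − A s|."""
    A = np.asarray(A, dtype=float)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("rank-deficient proportion matrix")
    S = np.empty((X.n_genes, A.shape[1]))
    for g in range(X.n_genes):
        S[g], _ = nnls(A, X.values[g])
    return S


def assign_markers(
    clusters: RFCResult,
    model: SimplexModel,
    scatter,
    gene_ids: list[str],
) -> pd.DataFrame:
    """Emit every member of a vertex cluster as a marker of that cell type.

    Cell-type indices (1-based) follow the vertex order of the model,
    which is the RFC extraction order restricted to the selected
    clusters.  Genes in non-vertex clusters and outliers are not markers.
    """
    rows = []
    for k, ci in enumerate(model.vertex_cluster_indices, start=1):
        cl = clusters.clusters[ci]
        angles = _angles_to(scatter.points[cl.member_rows], cl.center)
        for r, a in zip(cl.member_rows, angles):
            rows.append((gene_ids[scatter.retained_gene_index[r]], k, float(a)))
    return pd.DataFrame(rows, columns=["gene_id", "cell_type_index", "angle_to_vertex"])


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r}: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(X: ExpressionMatrix, config: DeconvolutionConfig | None = None) -> DeconvolutionResult:
    """Full unsupervised deconvolution of a bulk expression matrix.

    Deterministic given the input and config: there is no randomness in
    any stage.  Stage failures are re-raised as ``PipelineError`` with
    the stage name attached.
    """
    config = config or DeconvolutionConfig()
    config.validate()

    Xf = _stage("filter")(filter_genes)(X, config.min_peak)
    scatter = _stage("normalize")(normalize_gene_vectors)(Xf)
    logger.info("scatter: %d genes x %d samples", scatter.n_points, scatter.n_samples)

    rfc_result = _stage("rfc")(radius_fixed_cluster)(
        scatter, radius=config.radius, min_members=config.min_members
    )
    merge_log: list[tuple[int, int]] = []
    if config.merge_enabled:
        rfc_result, merge_log = _stage("merge")(merge_adjacent_clusters)(
            rfc_result, config.effective_merge_angle, scatter
        )
    if rfc_result.n_clusters < 2:
        raise PipelineError(
            f"stage 'rfc': only {rfc_result.n_clusters} cluster(s) found; "
            "lower min_members or enlarge radius"
        )

    centers = _stage("lp")(cluster_center_matrix)(rfc_result)
    candidates = _stage("lp")(detect_vertex_candidates)(centers, config.lp_tolerance)

    n_cand = candidates.n_candidates
    K_max = min(config.K_max, n_cand)
    if K_max < config.K_max:
        logger.info("K_max clamped from %d to %d (only %d vertex candidates)",
                    config.K_max, K_max, n_cand)
    if config.K_min > K_max:
        raise PipelineError(
            f"stage 'model_select': K_min={config.K_min} exceeds the "
            f"{n_cand} available vertex candidates"
        )
    weights = np.array([c.size for c in rfc_result.clusters], dtype=float)
    trace = _stage("model_select")(select_model)(
        scatter, candidates, centers, weights, config.K_min, K_max, merge_log
    )
    model = trace.selected

    A = _stage("estimate_A")(estimate_A)(model)
    S = _stage("estimate_S")(estimate_S)(X, A)  # all input genes, incl. filtered
    markers = _stage("markers")(assign_markers)(rfc_result, model, scatter, Xf.gene_ids)

    echo = asdict(config)
    echo.update(selected_K=trace.selected_K, n_clusters=rfc_result.n_clusters,
                n_candidates=n_cand, n_genes=X.n_genes, n_samples=X.n_samples)
    return DeconvolutionResult(A=A, S=S, markers=markers, trace=trace,
                               config_echo=echo, sample_ids=X.sample_ids,
                               gene_ids=X.gene_ids, rfc=rfc_result)
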