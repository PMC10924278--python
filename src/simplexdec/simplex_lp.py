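"""Linear-programming detection of scatter-simplex vertex clusters.

A cluster center is a vertex of the convex hull of all centers iff it
cannot be written as a convex combination of the centers with (near)
zero weight on itself.  For center ``x_j`` the LP

    minimize s_j  subject to  sum_i s_i x_i = x_j,  sum_i s_i = 1,  s >= 0

is always feasible (take ``s_j = 1``); its optimum — the *vertex
margin* — is 0 for interior/face points and strictly positive for
vertices.  One small LP per cluster replaces an exact convex-hull
computation, which scales poorly with sample dimension; the exact hull
(Quickhull via scipy) is kept only as a small-instance test oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial import ConvexHull

logger = logging.getLogger("simplexdec")

__all__ = [
    "VertexCandidateSet",
    "DegenerateSimplexError",
    "vertex_margin",
    "detect_vertex_candidates",
    "brute_force_vertices",
]

DEFAULT_LP_TOLERANCE = 1e-2  # margin above which a cluster is called a vertex


class DegenerateSimplexError(RuntimeError):
    """Fewer than two vertex candidates survive: no simplex exists."""


@dataclass(frozen=True)
class VertexCandidateSet:
    """Per-cluster vertex margins thresholded at ``tolerance``."""

    candidate_indices: np.ndarray
    margins: np.ndarray
    tolerance: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "candidate_indices",
                           np.asarray(self.candidate_indices, dtype=int))
        object.__setattr__(self, "margins", np.asarray(self.margins, dtype=float))

    @property
    def n_candidates(self) -> int:
        return self.candidate_indices.size

    def to_table(self) -> pd.DataFrame:
        is_cand = np.zeros(self.margins.size, dtype=bool)
        is_cand[self.candidate_indices] = True
        return pd.DataFrame({
            "cluster_id": np.arange(1, self.margins.size + 1),
            "margin": self.margins,
            "is_candidate": is_cand,
        })


def vertex_margin(j: int, centers: np.ndarray) -> float:
    """Minimal self-weight of center ``j`` in any convex combination of
    all centers reproducing it; > 0 iff ``j`` is a hull vertex."""
    centers = np.asarray(centers, dtype=float)
    N, d = centers.shape
    if N < 2:
        raise ValueError("need at least 2 centers")
    if not 0 <= j < N:
        raise IndexError(f"center index {j} out of range for {N} centers")
    c = np.zeros(N)
    c[j] = 1.0
    A_eq = np.vstack([centers.T, np.ones((1, N))])
    b_eq = np.concatenate([centers[j], [1.0]])
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"LP solver failed for center {j}: {res.message}")
    return float(np.clip(res.fun, 0.0, 1.0))


def detect_vertex_candidates(
    centers: np.ndarray, tolerance: float = DEFAULT_LP_TOLERANCE
) -> VertexCandidateSet:
    """Run the margin LP for every cluster center and threshold.

    The per-center problems are independent; they are solved in a fixed
    order so the result never depends on scheduling.
    """
    if not 0 < tolerance < 0.5:
        raise ValueError("tolerance must lie in (0, 0.5)")
    centers = np.asarray(centers, dtype=float)
    margins = np.array([vertex_margin(j, centers) for j in range(centers.shape[0])])
    candidates = np.flatnonzero(margins > tolerance)
    if candidates.size < 2:
        raise DegenerateSimplexError(
            f"only {candidates.size} vertex candidate(s) at tolerance {tolerance}; "
            "degenerate simplex"
        )
    logger.info("LP vertex detection: %d/%d candidates (tolerance=%g)",
                candidates.size, centers.shape[0], tolerance)
    return VertexCandidateSet(candidate_indices=candidates, margins=margins,
                              tolerance=tolerance)


def brute_force_vertices(centers: np.ndarray) -> np.ndarray:
    """Exact convex-hull vertex indices — small-instance test oracle only.

    Centers live on the affine hyperplane of row-sum-1 vectors, so the
    cloud is first reduced to its intrinsic dimension by SVD, then passed
    to Quickhull.  Degenerate intrinsic dimensions (0 and 1) are handled
    directly.
    """
    centers = np.asarray(centers, dtype=float)
    N, d = centers.shape
    if N > 200:
        raise ValueError("brute_force_vertices is capped at 200 points; use the LP path")
    if N <= 2:
        return np.arange(N)
    mean = centers.mean(axis=0)
    Y = centers - mean
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    rank = int(np.sum(s > 1e-10 * max(s[0], 1.0)))
    if rank > 8:
        raise ValueError("intrinsic dimension > 8; use the LP path")
    if rank == 0:
        return np.array([0])  # all points coincide
    Z = Y @ Vt[:rank].T
    if rank == 1:
        return np.unique([int(np.argmin(Z[:, 0])), int(np.argmax(Z[:, 0]))])
    hull = ConvexHull(Z)
    return np.sort(hull.vertices)
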