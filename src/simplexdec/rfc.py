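"""Radius-fixed clustering (RFC) of scatter-simplex gene vectors.

Marker genes of a cell type collapse onto (near) a single direction in
sample space, so tight angular clusters on the scatter simplex are
marker-cluster candidates.  Unlike k-means, RFC is fully deterministic:
every gene seeds a fixed-radius angular ball, the densest ball wins,
its members are removed, and the loop repeats until no ball reaches the
minimum membership.  The number of clusters is an output, not an input,
and genes belonging to no qualifying ball are reported as outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import NormalizedScatter

logger = logging.getLogger("simplexdec")

__all__ = [
    "GeneCluster",
    "RFCResult",
    "cosine_score",
    "radius_fixed_cluster",
    "cluster_center_matrix",
]

DEFAULT_RADIUS = 0.06  # radians; max angular distance member -> center
DEFAULT_MIN_MEMBERS = 25


def cosine_score(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two non-negative vectors, in [0, 1].

    Equals 1 iff the vectors are positive scalar multiples of each other
    (same direction), 0 iff they are orthogonal.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have the same length")
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("cosine_score is defined for non-negative vectors")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine_score undefined for a zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), 0.0, 1.0))


@dataclass(frozen=True)
class GeneCluster:
    """One angular ball of scatter rows.

    ``center`` is the row-sum-normalized mean of the member points (after
    the single recentering pass), ``mean_angle`` the average angular
    distance (radians) of members to that center.
    """

    member_rows: np.ndarray
    center: np.ndarray
    size: int
    mean_angle: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_rows", np.asarray(self.member_rows, dtype=int))
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))


@dataclass(frozen=True)
class RFCResult:
    clusters: list[GeneCluster]
    outlier_rows: np.ndarray
    radius: float
    min_members: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "outlier_rows", np.asarray(self.outlier_rows, dtype=int))

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def to_table(self, scatter: NormalizedScatter, gene_ids: list[str]) -> pd.DataFrame:
        """Marker-cluster table: cluster_id, gene_id, angle_to_center."""
        rows = []
        for cid, cl in enumerate(self.clusters, start=1):
            angles = _angles_to(scatter.points[cl.member_rows], cl.center)
            for r, a in zip(cl.member_rows, angles):
                rows.append((cid, gene_ids[scatter.retained_gene_index[r]], float(a)))
        return pd.DataFrame(rows, columns=["cluster_id", "gene_id", "angle_to_center"])


def _unit_rows(P: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(P, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("scatter contains a zero row")
    return P / norms


def _angles_to(P: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Angular distances (radians) from each row of P to center."""
    c = center / np.linalg.norm(center)
    cosines = _unit_rows(P) @ c
    return np.arccos(np.clip(cosines, -1.0, 1.0))


def _l1_normalize(v: np.ndarray) -> np.ndarray:
    return v / v.sum()


def radius_fixed_cluster(
    scatter: NormalizedScatter,
    radius: float = DEFAULT_RADIUS,
    min_members: int = DEFAULT_MIN_MEMBERS,
) -> RFCResult:
    """Greedy deterministic extraction of fixed-radius angular clusters.

    Every remaining row seeds a candidate ball of rows within ``radius``
    (angular distance, i.e. ``arccos`` of the cosine score).  The largest
    ball is extracted — ties broken by smaller mean member angle, then by
    lowest seed-row index — its center recomputed once as the normalized
    member mean with members re-collected around it, and its rows removed.
    The loop stops when no candidate ball reaches ``min_members``;
    whatever remains is reported as outliers.

    The pairwise angle matrix is O(G^2) memory/time; exact, and adequate
    for the few-thousand-gene scale this package targets.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if min_members < 1:
        raise ValueError("min_members must be >= 1")
    P = scatter.points
    G = P.shape[0]
    if G == 0:
        raise ValueError("empty scatter")

    U = _unit_rows(P)
    ang = np.arccos(np.clip(U @ U.T, -1.0, 1.0))
    np.fill_diagonal(ang, 0.0)

    remaining = np.ones(G, dtype=bool)
    clusters: list[GeneCluster] = []
    while True:
        idx = np.flatnonzero(remaining)
        if idx.size == 0:
            break
        sub = ang[np.ix_(idx, idx)]
        within = sub <= radius
        sizes = within.sum(axis=1)
        best_size = int(sizes.max())
        if best_size < min_members:
            break
        tied = np.flatnonzero(sizes == best_size)
        if tied.size > 1:
            mean_angles = np.array([sub[t, within[t]].mean() for t in tied])
            tied = tied[mean_angles == mean_angles.min()]
        seed_local = int(tied[0])  # lowest seed-row index last
        ball = idx[within[seed_local]]

        # single recentering pass: normalized member mean, re-collect once
        center = _l1_normalize(P[ball].mean(axis=0))
        recollect = idx[_angles_to(P[idx], center) <= radius]
        if recollect.size >= min_members:
            members = recollect
        else:
            # recentering emptied the ball (pathological); keep the seed ball
            members = ball
            center = _l1_normalize(P[idx[seed_local]].copy())
        mean_angle = float(_angles_to(P[members], center).mean())
        clusters.append(
            GeneCluster(member_rows=np.sort(members), center=center,
                        size=int(members.size), mean_angle=mean_angle)
        )
        remaining[members] = False

    clusters.sort(key=lambda c: (-c.size, c.mean_angle, int(c.member_rows[0])))
    outliers = np.flatnonzero(remaining)
    logger.info(
        "RFC: %d clusters, %d outliers of %d points (radius=%g, min_members=%d)",
        len(clusters), outliers.size, G, radius, min_members,
    )
    return RFCResult(clusters=clusters, outlier_rows=outliers,
                     radius=radius, min_members=min_members)


def cluster_center_matrix(result: RFCResult) -> np.ndarray:
    """Stack cluster centers into a clusters x samples row-stochastic matrix."""
    if not result.clusters:
        raise ValueError("no clusters to stack")
    M = np.vstack([c.center for c in result.clusters])
    return M / M.sum(axis=1, keepdims=True)
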