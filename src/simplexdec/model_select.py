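"""Floating-search model selection: per-K best simplex and MDL choice of K.

Given the LP vertex candidates, the best K-vertex simplex for each K is
found by sequential floating searches (SFFS growing from the empty set,
SBFS shrinking from the full candidate set, keeping the better result),
scoring subsets by a weighted non-negative-least-squares cone-fit error
over the cluster centers.  The number of cell types K is then chosen by
a two-part minimum-description-length score computed over all retained
genes: a Gaussian residual code plus a parameter code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear, nnls
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io_core import NormalizedScatter
from .rfc import GeneCluster, RFCResult, _angles_to, _l1_normalize, cluster_center_matrix
from .simplex_lp import VertexCandidateSet

logger = logging.getLogger("simplexdec")

__all__ = [
    "SimplexModel",
    "ModelSelectionTrace",
    "merge_adjacent_clusters",
    "cone_residuals",
    "cone_fit_error",
    "floating_search_best_subset",
    "exhaustive_best_subset",
    "mdl_score",
    "select_model",
]

#: relative floor applied to the residual sum of squares inside the MDL
#: residual code, preventing ln(0) on noise-free data
RSS_FLOOR = 1e-12


@dataclass(frozen=True)
class SimplexModel:
    """A K-vertex simplex drawn from the candidate clusters.

    ``reconstruction_error`` is the size-weighted cone-fit error over
    cluster centers (the floating-search objective); ``rss_genes`` the
    unit-weight cone-fit error over all retained genes that enters MDL.
    """

    K: int
    vertex_cluster_indices: tuple[int, ...]
    vertex_matrix: np.ndarray
    reconstruction_error: float
    mdl: float = float("nan")
    rss_genes: float = float("nan")

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertex_matrix",
                           np.asarray(self.vertex_matrix, dtype=float))
        object.__setattr__(self, "vertex_cluster_indices",
                           tuple(int(i) for i in self.vertex_cluster_indices))
        if self.K != len(self.vertex_cluster_indices):
            raise ValueError("K must equal the number of vertex clusters")


@dataclass(frozen=True)
class ModelSelectionTrace:
    per_K_models: dict[int, SimplexModel]
    selected_K: int
    merge_log: list[tuple[int, int]] = field(default_factory=list)

    @property
    def selected(self) -> SimplexModel:
        return self.per_K_models[self.selected_K]

    def to_table(self) -> pd.DataFrame:
        rows = [
            (K, m.reconstruction_error, m.mdl,
             ";".join(str(i + 1) for i in m.vertex_cluster_indices))
            for K, m in sorted(self.per_K_models.items())
        ]
        return pd.DataFrame(rows, columns=["K", "reconstruction_error", "mdl",
                                           "vertex_cluster_ids"])


def merge_adjacent_clusters(
    clusters: RFCResult,
    merge_angle: float,
    scatter: NormalizedScatter | None = None,
) -> tuple[RFCResult, list[tuple[int, int]]]:
    """Single-linkage merge of clusters whose centers lie within
    ``merge_angle`` radians of each other.

    Merged members are unioned; the merged center is the normalized mean
    of the member points when ``scatter`` is given, otherwise the
    size-weighted normalized mean of the constituent centers.  Returns
    the merged result plus the log of merged cluster-index pairs
    (indices into the input ordering).
    """
    if merge_angle < 0:
        raise ValueError("merge_angle must be >= 0")
    n = clusters.n_clusters
    if n == 0 or merge_angle == 0:
        return clusters, []
    centers = cluster_center_matrix(clusters)
    U = centers / np.linalg.norm(centers, axis=1, keepdims=True)
    ang = np.arccos(np.clip(U @ U.T, -1.0, 1.0))
    adj = ang <= merge_angle
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    merge_log = [(int(i), int(j)) for i, j in zip(*np.nonzero(np.triu(adj)))]
    if n_comp == n:
        return clusters, []

    merged: list[GeneCluster] = []
    for comp in range(n_comp):
        members_of = [clusters.clusters[i] for i in np.flatnonzero(labels == comp)]
        rows = np.sort(np.concatenate([c.member_rows for c in members_of]))
        if scatter is not None:
            center = _l1_normalize(scatter.points[rows].mean(axis=0))
            mean_angle = float(_angles_to(scatter.points[rows], center).mean())
        else:
            sizes = np.array([c.size for c in members_of], dtype=float)
            center = _l1_normalize(
                (sizes[:, None] * np.vstack([c.center for c in members_of])).sum(0)
            )
            mean_angle = float(np.average([c.mean_angle for c in members_of],
                                          weights=sizes))
        merged.append(GeneCluster(member_rows=rows, center=center,
                                  size=int(rows.size), mean_angle=mean_angle))
    merged.sort(key=lambda c: (-c.size, c.mean_angle, int(c.member_rows[0])))
    logger.info("merged %d clusters into %d (merge_angle=%g)", n, n_comp, merge_angle)
    result = RFCResult(clusters=merged, outlier_rows=clusters.outlier_rows,
                       radius=clusters.radius, min_members=clusters.min_members)
    return result, merge_log


def nnls_fit(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Non-negative least squares with a bounded-variable fallback.

    The active-set solver occasionally stalls on near-collinear designs;
    in that case fall back to the slower but robust BVLS solver.
    """
    try:
        x, rnorm = nnls(A, b, maxiter=50 * max(A.shape))
        return x, float(rnorm)
    except RuntimeError:
        res = lsq_linear(A, b, bounds=(0.0, np.inf), method="bvls")
        return res.x, float(np.linalg.norm(A @ res.x - b))


def cone_residuals(V: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Squared NNLS residual of each point projected onto cone(V rows)."""
    V = np.atleast_2d(np.asarray(V, dtype=float))
    A = V.T  # samples x K design
    out = np.empty(points.shape[0])
    for i, p in enumerate(points):
        _, rnorm = nnls_fit(A, p)
        out[i] = rnorm * rnorm
    return out


def cone_fit_error(
    vertex_rows: tuple[int, ...] | list[int] | np.ndarray,
    centers: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Weighted sum of squared NNLS residuals of every center onto the
    cone spanned by the selected vertex rows."""
    vertex_rows = np.asarray(list(vertex_rows), dtype=int)
    if vertex_rows.size < 1:
        raise ValueError("need at least one vertex row")
    res = cone_residuals(centers[vertex_rows], centers)
    if weights is None:
        return float(res.sum())
    return float(np.dot(np.asarray(weights, dtype=float), res))


class _SubsetScorer:
    """Memoized cone-fit objective over candidate subsets."""

    def __init__(self, centers: np.ndarray, weights: np.ndarray | None):
        self.centers = centers
        self.weights = weights
        self._cache: dict[frozenset[int], float] = {}

    def __call__(self, subset) -> float:
        key = frozenset(subset)
        if key not in self._cache:
            self._cache[key] = cone_fit_error(sorted(key), self.centers, self.weights)
        return self._cache[key]


def _unexplainable_portion(scorer: _SubsetScorer, subset: list[int]) -> dict[int, float]:
    """One NNLS pass per member: weighted squared residual of each selected
    vertex onto the cone of the other selected vertices.  Cheap proxy for
    each member's residue-error contribution used to rank SBFS removals."""
    out: dict[int, float] = {}
    for j in subset:
        rest = [i for i in subset if i != j]
        res = cone_residuals(scorer.centers[rest], scorer.centers[[j]])[0]
        w = 1.0 if scorer.weights is None else float(scorer.weights[j])
        out[j] = w * res
    return out


def _sffs(scorer: _SubsetScorer, pool: list[int], K: int,
          best: dict[int, tuple[float, tuple[int, ...]]]) -> None:
    """Sequential forward floating search from the empty set up to K."""
    cur: list[int] = []
    guard = 0
    while len(cur) < K and guard < 50 * (K + 1):
        guard += 1
        outside = [x for x in pool if x not in cur]
        errs = [(scorer(cur + [x]), x) for x in outside]
        err, x = min(errs, key=lambda t: (t[0], t[1]))
        cur.append(x)
        k = len(cur)
        if k not in best or err < best[k][0] - 1e-15:
            best[k] = (err, tuple(sorted(cur)))
        else:
            cur = list(best[k][1])  # continue from recorded best of this size
        # conditional exclusions while they beat the recorded smaller subsets
        while len(cur) > 2:
            k = len(cur)
            drops = [(scorer([y for y in cur if y != z]), z) for z in cur]
            derr, z = min(drops, key=lambda t: (t[0], t[1]))
            if derr < best.get(k - 1, (np.inf,))[0] - 1e-15:
                cur.remove(z)
                best[k - 1] = (derr, tuple(sorted(cur)))
            else:
                break


def _sbfs(scorer: _SubsetScorer, pool: list[int], K: int,
          best: dict[int, tuple[float, tuple[int, ...]]]) -> None:
    """Sequential backward floating search from the full pool down to K.

    Removal candidates are ranked by the one-NNLS "unexplainable portion"
    proxy; the chosen subset is then scored exactly.
    """
    cur = list(pool)
    n = len(pool)
    full_err = scorer(cur)
    if n not in best or full_err < best[n][0] - 1e-15:
        best[n] = (full_err, tuple(sorted(cur)))
    guard = 0
    while len(cur) > K and guard < 50 * (n + 1):
        guard += 1
        contrib = _unexplainable_portion(scorer, cur)
        z = min(cur, key=lambda j: (contrib[j], j))
        cur.remove(z)
        k = len(cur)
        err = scorer(cur)
        if k not in best or err < best[k][0] - 1e-15:
            best[k] = (err, tuple(sorted(cur)))
        elif best[k][0] < err - 1e-15:
            cur = list(best[k][1])
        # conditional re-inclusions while they beat the recorded larger subsets
        while len(cur) < n:
            k = len(cur)
            outside = [x for x in pool if x not in cur]
            adds = [(scorer(cur + [x]), x) for x in outside]
            aerr, x = min(adds, key=lambda t: (t[0], t[1]))
            if aerr < best.get(k + 1, (np.inf,))[0] - 1e-15:
                cur.append(x)
                best[k + 1] = (aerr, tuple(sorted(cur)))
            else:
                break


def _swap_refine(scorer: _SubsetScorer, pool: list[int], K: int,
                 best: dict[int, tuple[float, tuple[int, ...]]]) -> None:
    """Conditional exchange sweeps at size K.

    While an exchange of one — or, once single exchanges are exhausted,
    two — members for outsiders improves the recorded best K-subset,
    apply the best improving exchange.  Pair exchanges let the search
    hop between local optima that single replacements cannot connect.
    """
    if K not in best:
        return
    guard = 0
    while guard < 20 * len(pool):
        guard += 1
        err, subset = best[K]
        cur = list(subset)
        outside = [x for x in pool if x not in cur]
        if not outside:
            return
        swaps = [(scorer([c for c in cur if c != z] + [x]), (z,), (x,))
                 for z in cur for x in outside]
        if len(cur) >= 2 and len(outside) >= 2:
            swaps += [
                (scorer([c for c in cur if c not in zz] + list(xx)), zz, xx)
                for zz in combinations(cur, 2) for xx in combinations(outside, 2)
            ]
        serr, zz, xx = min(swaps, key=lambda t: (t[0], t[1], t[2]))
        if serr < err - 1e-15:
            best[K] = (serr, tuple(sorted(
                [c for c in cur if c not in zz] + list(xx))))
        else:
            return


def floating_search_best_subset(
    candidates: VertexCandidateSet,
    centers: np.ndarray,
    weights: np.ndarray | None,
    K: int,
    _best: dict[int, tuple[float, tuple[int, ...]]] | None = None,
    _scorer: _SubsetScorer | None = None,
) -> SimplexModel:
    """Best K-vertex subset of the candidates by SFFS + SBFS.

    Both passes share a table of the best subset found at every size;
    the returned model is the better of the two at size ``K``.  The
    ``_best``/``_scorer`` arguments let ``select_model`` share the table
    and memo cache across the whole K range.
    """
    pool = [int(i) for i in candidates.candidate_indices]
    if not 2 <= K <= len(pool):
        raise ValueError(f"K={K} out of range [2, {len(pool)}]")
    scorer = _scorer if _scorer is not None else _SubsetScorer(centers, weights)
    best = _best if _best is not None else {}
    if K == len(pool):
        best[K] = (scorer(pool), tuple(sorted(pool)))
    else:
        _sffs(scorer, pool, K, best)
        _sbfs(scorer, pool, K, best)
        _swap_refine(scorer, pool, K, best)
    err, subset = best[K]
    V = centers[list(subset)]
    return SimplexModel(K=K, vertex_cluster_indices=subset,
                        vertex_matrix=V / V.sum(axis=1, keepdims=True),
                        reconstruction_error=err)


def exhaustive_best_subset(
    candidates: VertexCandidateSet,
    centers: np.ndarray,
    weights: np.ndarray | None,
    K: int,
) -> tuple[float, tuple[int, ...]]:
    """Brute-force optimum over all C(n, K) subsets — test oracle only."""
    pool = [int(i) for i in candidates.candidate_indices]
    scorer = _SubsetScorer(centers, weights)
    return min(
        ((scorer(list(sub)), sub) for sub in combinations(pool, K)),
        key=lambda t: (t[0], t[1]),
    )


def mdl_score(scatter: NormalizedScatter, model: SimplexModel) -> float:
    """Two-part MDL of a K-vertex model on the full retained scatter.

    ``(L/2)·ln(RSS/L) + (P/2)·ln(L)`` with ``L = genes·samples``, RSS the
    unit-weight gene-level cone-fit error (floored at ``L·RSS_FLOOR``),
    and ``P = samples·(K−1) + K·genes`` free parameters (a row-stochastic
    proportion matrix plus a full expression signature matrix).
    """
    G, N = scatter.points.shape
    L = G * N
    rss = model.rss_genes
    if np.isnan(rss):
        rss = float(cone_residuals(model.vertex_matrix, scatter.points).sum())
    rss = max(rss, L * RSS_FLOOR)
    P = N * (model.K - 1) + model.K * G
    return float(0.5 * L * np.log(rss / L) + 0.5 * P * np.log(L))


def select_model(
    scatter: NormalizedScatter,
    candidates: VertexCandidateSet,
    centers: np.ndarray,
    weights: np.ndarray | None,
    K_min: int,
    K_max: int,
    merge_log: list[tuple[int, int]] | None = None,
) -> ModelSelectionTrace:
    """Survey MDL over K in [K_min, K_max] and pick the minimum.

    The floating searches for all K share one best-subset table, and each
    K's entry is additionally seeded with the best (K−1)-subset plus its
    best single extension, which guarantees the per-K reconstruction
    error is non-increasing in K.  MDL ties break toward smaller K.
    """
    n_cand = candidates.n_candidates
    if not 2 <= K_min <= K_max <= n_cand:
        raise ValueError(
            f"need 2 <= K_min <= K_max <= #candidates ({n_cand}); "
            f"got K_min={K_min}, K_max={K_max}"
        )
    scorer = _SubsetScorer(centers, weights)
    best: dict[int, tuple[float, tuple[int, ...]]] = {}
    pool = [int(i) for i in candidates.candidate_indices]
    per_K: dict[int, SimplexModel] = {}
    for K in range(K_min, K_max + 1):
        if K - 1 in best:  # monotonicity seed: extend the previous best
            prev = list(best[K - 1][1])
            outside = [x for x in pool if x not in prev]
            if outside:
                err, x = min(((scorer(prev + [x]), x) for x in outside),
                             key=lambda t: (t[0], t[1]))
                if K not in best or err < best[K][0] - 1e-15:
                    best[K] = (err, tuple(sorted(prev + [x])))
        model = floating_search_best_subset(candidates, centers, weights, K,
                                            _best=best, _scorer=scorer)
        rss = float(cone_residuals(model.vertex_matrix, scatter.points).sum())
        model = SimplexModel(
            K=model.K,
            vertex_cluster_indices=model.vertex_cluster_indices,
            vertex_matrix=model.vertex_matrix,
            reconstruction_error=model.reconstruction_error,
            rss_genes=rss,
        )
        object.__setattr__(model, "mdl", mdl_score(scatter, model))
        per_K[K] = model
        logger.info("K=%d: search error %.4g, gene RSS %.4g, MDL %.6g",
                    K, model.reconstruction_error, rss, model.mdl)
    selected_K = min(per_K, key=lambda K: (per_K[K].mdl, K))
    logger.info("MDL selects K=%d", selected_K)
    return ModelSelectionTrace(per_K_models=per_K, selected_K=selected_K,
                               merge_log=list(merge_log or []))
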