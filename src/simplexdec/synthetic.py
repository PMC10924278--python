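"""Seeded ground-truth mixture simulator and evaluation metrics.

Emulates designed-mixture benchmarks: K cell types with designated
single-type marker genes, sample proportions drawn from a Dirichlet (or
supplied as an explicit design table), bulk expression formed as
``X = S_true · A_trueᵀ`` with optional multiplicative log-normal or
additive Gaussian noise.  All randomness flows through
``numpy.random.default_rng`` (PCG64), so a seed pins every fixture
bit-for-bit across runs and platforms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .io_core import ExpressionMatrix

logger = logging.getLogger("simplexdec")

__all__ = [
    "SyntheticTruth",
    "simulate_signatures",
    "simulate_proportions",
    "mix",
    "simulate_dataset",
    "match_columns",
    "rmse_A",
    "marker_recovery",
]

NOISE_MODELS = ("none", "multiplicative_lognormal", "additive_gaussian")

# log-normal magnitude defaults chosen to mimic microarray/RNA-seq
# dynamic range; markers get an extra fold-change on top
DEFAULT_MEANLOG = 3.0
DEFAULT_SDLOG = 1.0
DEFAULT_MARKER_SCALE = 5.0


@dataclass(frozen=True)
class SyntheticTruth:
    S_true: np.ndarray            # genes x K
    A_true: np.ndarray            # samples x K, rows sum to 1
    marker_map: dict[str, int]    # gene_id -> cell type (0-based column of S_true)
    noise: dict                   # {"model": ..., "sigma": ...}
    seed: int
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.S_true.shape[1]


def simulate_signatures(
    K: int,
    G: int,
    markers_per_type: int,
    expr_scale: float = DEFAULT_MARKER_SCALE,
    seed: int = 0,
    meanlog: float = DEFAULT_MEANLOG,
    sdlog: float = DEFAULT_SDLOG,
) -> tuple[np.ndarray, dict[int, int]]:
    """Draw a genes x K signature matrix with designated markers.

    The first ``K * markers_per_type`` rows are markers: log-normal
    magnitude (scaled by ``expr_scale``) in exactly one column, zero
    elsewhere.  Remaining rows get K independent log-normal values.
    Returns ``(S_true, marker_map)`` with ``marker_map`` row -> type.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if G < K * markers_per_type:
        raise ValueError(
            f"G={G} too small for {K} x {markers_per_type} markers"
        )
    rng = np.random.default_rng(seed)
    S = rng.lognormal(mean=meanlog, sigma=sdlog, size=(G, K))
    marker_map: dict[int, int] = {}
    for k in range(K):
        rows = range(k * markers_per_type, (k + 1) * markers_per_type)
        for g in rows:
            S[g] = 0.0
            S[g, k] = expr_scale * rng.lognormal(mean=meanlog, sigma=sdlog)
            marker_map[g] = k
    return S, marker_map


def simulate_proportions(
    N: int,
    K: int,
    dirichlet_alpha: float = 1.0,
    seed: int = 0,
    designed: np.ndarray | None = None,
) -> np.ndarray:
    """Row-stochastic samples x K proportion matrix.

    Rows are i.i.d. symmetric Dirichlet(alpha); pass ``designed`` (an
    explicit N x K table, rows summing to 1) to mimic a designed mixing
    experiment instead.
    """
    if designed is not None:
        A = np.asarray(designed, dtype=float)
        if A.shape != (N, K):
            raise ValueError(f"designed table must be {N} x {K}, got {A.shape}")
        if np.any(A < 0) or np.max(np.abs(A.sum(axis=1) - 1.0)) > 1e-6:
            raise ValueError("designed proportions must be non-negative rows summing to 1")
        return A
    if dirichlet_alpha <= 0:
        raise ValueError("dirichlet_alpha must be > 0")
    if N < K:
        warnings.warn(f"N={N} < K={K}: proportion columns may be poorly spread",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.full(K, dirichlet_alpha), size=N)


def mix(
    S_true: np.ndarray,
    A_true: np.ndarray,
    noise: dict | None = None,
    seed: int = 0,
    gene_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> ExpressionMatrix:
    """Form the bulk matrix ``X[g, n] = sum_k S[g, k] A[n, k]`` + noise.

    ``multiplicative_lognormal`` multiplies each entry by ``exp(eps)``
    with ``eps ~ N(0, sigma^2)``; ``additive_gaussian`` adds
    ``eps * mean(X)`` and clips at zero.
    """
    S_true = np.asarray(S_true, dtype=float)
    A_true = np.asarray(A_true, dtype=float)
    if S_true.shape[1] != A_true.shape[1]:
        raise ValueError(
            f"shape mismatch: S has {S_true.shape[1]} types, A has {A_true.shape[1]}"
        )
    noise = dict(noise or {"model": "none", "sigma": 0.0})
    model = noise.get("model", "none")
    sigma = float(noise.get("sigma", 0.0))
    if model not in NOISE_MODELS:
        raise ValueError(f"unknown noise model {model!r}; choose from {NOISE_MODELS}")
    X = S_true @ A_true.T
    if model != "none" and sigma > 0:
        rng = np.random.default_rng(seed)
        eps = rng.normal(0.0, sigma, size=X.shape)
        if model == "multiplicative_lognormal":
            X = X * np.exp(eps)
        else:
            X = np.clip(X + eps * X.mean(), 0.0, None)
    G, N = X.shape
    gene_ids = gene_ids or [f"gene{g + 1:05d}" for g in range(G)]
    sample_ids = sample_ids or [f"sample{n + 1:02d}" for n in range(N)]
    return ExpressionMatrix(X, gene_ids, sample_ids)


def simulate_dataset(
    K: int = 3,
    G: int = 3000,
    N: int = 12,
    markers_per_type: int = 50,
    noise_model: str = "none",
    sigma: float = 0.0,
    dirichlet_alpha: float = 1.0,
    expr_scale: float = DEFAULT_MARKER_SCALE,
    seed: int = 0,
    designed_proportions: np.ndarray | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """One-call benchmark fixture: signatures + proportions + mixing.

    Sub-seeds for the three draws are spawned deterministically from
    ``seed`` so fixtures are reproducible yet the draws independent.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    S_true, marker_rows = simulate_signatures(
        K, G, markers_per_type, expr_scale=expr_scale, seed=sub[0]
    )
    A_true = simulate_proportions(N, K, dirichlet_alpha, seed=sub[1],
                                  designed=designed_proportions)
    noise = {"model": noise_model, "sigma": sigma}
    X = mix(S_true, A_true, noise, seed=sub[2])
    marker_map = {X.gene_ids[g]: k for g, k in marker_rows.items()}
    truth = SyntheticTruth(S_true=S_true, A_true=A_true, marker_map=marker_map,
                           noise=noise, seed=seed, gene_ids=X.gene_ids,
                           sample_ids=X.sample_ids)
    return X, truth


def match_columns(A_hat: np.ndarray, A_true: np.ndarray) -> np.ndarray:
    """Permutation ``p`` maximizing total per-pair Pearson correlation,
    such that ``A_hat[:, p]`` aligns with ``A_true`` column-for-column.

    Solved as an optimal assignment; deterministic.
    """
    A_hat = np.asarray(A_hat, dtype=float)
    A_true = np.asarray(A_true, dtype=float)
    if A_hat.shape != A_true.shape:
        raise ValueError(f"shape mismatch: {A_hat.shape} vs {A_true.shape}")
    K = A_hat.shape[1]

    def _std_cols(M):
        C = M - M.mean(axis=0)
        norms = np.linalg.norm(C, axis=0)
        norms[norms == 0] = 1.0
        return C / norms

    corr = _std_cols(A_true).T @ _std_cols(A_hat)  # true x hat
    row_ind, col_ind = linear_sum_assignment(-corr)
    perm = np.empty(K, dtype=int)
    perm[row_ind] = col_ind
    return perm


def rmse_A(A_hat: np.ndarray, A_true: np.ndarray) -> float:
    """Root-mean-square error over all N x K entries (columns pre-matched)."""
    A_hat = np.asarray(A_hat, dtype=float)
    A_true = np.asarray(A_true, dtype=float)
    if A_hat.shape != A_true.shape:
        raise ValueError(f"shape mismatch: {A_hat.shape} vs {A_true.shape}")
    return float(np.sqrt(np.mean((A_hat - A_true) ** 2)))


def marker_recovery(
    markers_hat: pd.DataFrame,
    marker_map: dict[str, int],
    perm: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-cell-type precision/recall of recovered markers.

    ``markers_hat`` is the pipeline's marker table (1-based
    ``cell_type_index``); ``perm`` is the column matching from
    ``match_columns`` (estimated column for each true type), identity if
    omitted.  A type with an empty predicted set gets precision 0 with
    ``undefined_precision=True``.
    """
    K = max(marker_map.values()) + 1 if marker_map else 0
    if perm is None:
        perm = np.arange(K)
    true_sets = {k: {g for g, t in marker_map.items() if t == k} for k in range(K)}
    pred_sets = {
        k: set(markers_hat.loc[markers_hat["cell_type_index"] == int(perm[k]) + 1,
                               "gene_id"])
        for k in range(K)
    }
    rows = []
    for k in range(K):
        tp = len(true_sets[k] & pred_sets[k])
        npred, ntrue = len(pred_sets[k]), len(true_sets[k])
        undefined = npred == 0
        precision = 0.0 if undefined else tp / npred
        recall = 0.0 if ntrue == 0 else tp / ntrue
        rows.append((k, precision, recall, npred, ntrue, undefined))
    return pd.DataFrame(rows, columns=["cell_type", "precision", "recall",
                                       "n_predicted", "n_true",
                                       "undefined_precision"])
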