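from itertools import combinations

import numpy as np
import pytest
from scipy.optimize import nnls

from simplexdec import (
    NormalizedScatter,
    SimplexModel,
    cone_fit_error,
    floating_search_best_subset,
    mdl_score,
    merge_adjacent_clusters,
    radius_fixed_cluster,
    select_model,
)
from simplexdec.model_select import exhaustive_best_subset
from simplexdec.simplex_lp import VertexCandidateSet
from conftest import make_axis_bundle_scatter


def all_candidates(n):
    return VertexCandidateSet(candidate_indices=np.arange(n),
                              margins=np.ones(n), tolerance=1e-6)


def simplex_points(rng, dim, n):
    return rng.dirichlet(np.ones(dim), size=n)


class TestMergeAdjacentClusters:
    def _two_close_clusters(self):
        # two bundles 0.01 rad apart plus one far bundle
        base = np.array([1.0, 0.02, 0.02])
        near = np.array([1.0, 0.032, 0.02])  # ~0.01 rad from base
        far = np.array([0.02, 0.02, 1.0])
        pts = []
        for v, n in ((base, 20), (near, 15), (far, 10)):
            for i in range(n):
                p = v + 1e-4 * np.array([i % 3, (i + 1) % 3, (i + 2) % 3])
                pts.append(p / p.sum())
        P = np.array(pts)
        scatter = NormalizedScatter(points=P, retained_gene_index=np.arange(len(pts)))
        return scatter, radius_fixed_cluster(scatter, radius=0.002, min_members=5)

    def test_pair_below_threshold_merges(self):
        scatter, rfc = self._two_close_clusters()
        assert rfc.n_clusters == 3
        merged, log = merge_adjacent_clusters(rfc, 0.05, scatter)
        assert merged.n_clusters == 2
        assert sorted(c.size for c in merged.clusters) == [10, 35]
        assert len(log) == 1

    def test_zero_angle_is_identity(self):
        scatter, rfc = self._two_close_clusters()
        merged, log = merge_adjacent_clusters(rfc, 0.0, scatter)
        assert merged is rfc and log == []

    def test_chain_merges_by_single_linkage(self):
        # chain A-B-C with consecutive gaps ~0.04 and A-C gap ~0.08
        def bundle(direction, n):
            return [direction + 1e-5 * np.arange(3) * (i + 1) for i in range(n)]

        a = np.array([1.0, 0.0, 0.05])
        b = np.array([1.0, 0.04, 0.05])   # ~0.04 rad from a
        c = np.array([1.0, 0.08, 0.05])   # ~0.04 from b, ~0.08 from a
        pts = np.array(bundle(a, 10) + bundle(b, 9) + bundle(c, 8))
        pts = pts / pts.sum(axis=1, keepdims=True)
        scatter = NormalizedScatter(points=pts, retained_gene_index=np.arange(len(pts)))
        rfc = radius_fixed_cluster(scatter, radius=0.002, min_members=5)
        assert rfc.n_clusters == 3
        # brute-force transitive closure of the proximity graph says: one component
        merged, _ = merge_adjacent_clusters(rfc, 0.05, scatter)
        assert merged.n_clusters == 1
        assert merged.clusters[0].size == 27


class TestConeFitError:
    def test_self_representation_is_zero(self):
        rng = np.random.default_rng(0)
        centers = simplex_points(rng, 4, 6)
        assert cone_fit_error(range(6), centers) == pytest.approx(0.0, abs=1e-12)

    def test_exact_convex_combination_has_zero_residual(self):
        v1, v2 = np.array([0.8, 0.1, 0.1]), np.array([0.1, 0.1, 0.8])
        centers = np.vstack([v1, v2, 0.5 * v1 + 0.5 * v2])
        assert cone_fit_error([0, 1], centers) == pytest.approx(0.0, abs=1e-12)

    def test_held_out_vertex_matches_independent_nnls(self):
        rng = np.random.default_rng(1)
        vertices = 0.7 * np.eye(4) + 0.3 * rng.dirichlet(np.ones(4), size=4)
        weights = np.array([10.0, 20, 30, 40])
        err = cone_fit_error([0, 1, 2], vertices, weights)
        # independent NNLS of the single held-out center onto the cone of the rest
        _, rnorm = nnls(vertices[[0, 1, 2]].T, vertices[3])
        assert err == pytest.approx(weights[3] * rnorm**2, rel=1e-9)

    def test_full_set_lower_bounds_subsets(self):
        rng = np.random.default_rng(2)
        centers = simplex_points(rng, 4, 8)
        full = cone_fit_error(range(8), centers)
        for sub in combinations(range(8), 5):
            assert full <= cone_fit_error(sub, centers) + 1e-12


class TestFloatingSearch:
    def test_full_candidate_set_is_forced(self):
        rng = np.random.default_rng(3)
        centers = simplex_points(rng, 4, 5)
        model = floating_search_best_subset(all_candidates(5), centers, None, 5)
        assert sorted(model.vertex_cluster_indices) == [0, 1, 2, 3, 4]
        assert model.reconstruction_error == pytest.approx(
            cone_fit_error(range(5), centers), abs=1e-12)

    def test_recovers_true_vertices_among_interior(self):
        rng = np.random.default_rng(4)
        vertices = 0.7 * np.eye(5) + 0.3 * rng.dirichlet(np.ones(5), size=5)
        interior = rng.dirichlet(np.ones(5), size=10) @ vertices
        centers = np.vstack([vertices, interior])
        model = floating_search_best_subset(all_candidates(15), centers, None, 5)
        assert sorted(model.vertex_cluster_indices) == [0, 1, 2, 3, 4]
        assert model.reconstruction_error < 1e-12
        # exhaustive search over all C(15,5) subsets agrees
        err, subset = exhaustive_best_subset(all_candidates(15), centers, None, 5)
        assert sorted(subset) == [0, 1, 2, 3, 4]

    def test_k2_picks_widest_pair(self, triangle_centers):
        model = floating_search_best_subset(all_candidates(3), triangle_centers, None, 2)
        # enumerate all 3 pairs: the two corners minimize the error
        errs = {pair: cone_fit_error(pair, triangle_centers)
                for pair in combinations(range(3), 2)}
        best_pair = min(errs, key=lambda p: (errs[p], p))
        assert tuple(sorted(model.vertex_cluster_indices)) == best_pair == (0, 1)

    def test_k_out_of_range(self, triangle_centers):
        with pytest.raises(ValueError):
            floating_search_best_subset(all_candidates(3), triangle_centers, None, 4)


class TestMDL:
    def _scatter(self, rng, G=60, N=5):
        return NormalizedScatter(points=simplex_points(rng, N, G),
                                 retained_gene_index=np.arange(G))

    def _model(self, centers, subset, rss):
        V = centers[list(subset)]
        return SimplexModel(K=len(subset), vertex_cluster_indices=tuple(subset),
                            vertex_matrix=V / V.sum(axis=1, keepdims=True),
                            reconstruction_error=0.0, rss_genes=rss)

    def test_equal_rss_prefers_smaller_k(self):
        rng = np.random.default_rng(5)
        scatter = self._scatter(rng)
        centers = simplex_points(rng, 5, 6)
        rss = 1.0
        m3 = self._model(centers, (0, 1, 2), rss)
        m4 = self._model(centers, (0, 1, 2, 3), rss)
        assert mdl_score(scatter, m3) < mdl_score(scatter, m4)

    def test_rss_at_floor_penalty_decides(self):
        rng = np.random.default_rng(6)
        scatter = self._scatter(rng)
        centers = simplex_points(rng, 5, 6)
        m3 = self._model(centers, (0, 1, 2), 0.0)
        m4 = self._model(centers, (0, 1, 2, 3), 0.0)
        assert mdl_score(scatter, m3) < mdl_score(scatter, m4)

    def test_noise_free_k3_minimum_at_three(self):
        # K=3 noise-free fixture scored at K in {2,3,4}: independent
        # recomputation of the two-part score for each K
        rng = np.random.default_rng(7)
        vertices = 0.7 * np.eye(6)[:3] + 0.3 * rng.dirichlet(np.ones(6), size=3)
        weights = rng.dirichlet(np.ones(3), size=200)
        scatter = NormalizedScatter(points=weights @ vertices,
                                    retained_gene_index=np.arange(200))
        extra = rng.dirichlet(np.ones(3), size=2) @ vertices  # interior decoys
        centers = np.vstack([vertices, extra])
        cands = all_candidates(5)
        trace = select_model(scatter, cands, centers, None, 2, 4)
        assert trace.selected_K == 3

        # independent script: exhaustive subset + direct formula
        G, N = scatter.points.shape
        L = G * N
        scores = {}
        for K in (2, 3, 4):
            err, subset = exhaustive_best_subset(cands, centers, None, K)
            V = centers[list(subset)]
            V = V / V.sum(axis=1, keepdims=True)
            rss = 0.0
            for p in scatter.points:
                _, rn = nnls(V.T, p)
                rss += rn * rn
            rss = max(rss, L * 1e-12)
            P = N * (K - 1) + K * G
            scores[K] = 0.5 * L * np.log(rss / L) + 0.5 * P * np.log(L)
        assert min(scores, key=scores.get) == 3
        for K in (2, 3, 4):
            assert trace.per_K_models[K].mdl == pytest.approx(scores[K], rel=1e-6)


class TestSelectModel:
    def test_forced_single_k(self, triangle_centers):
        rng = np.random.default_rng(8)
        scatter = NormalizedScatter(points=rng.dirichlet(np.ones(2), size=30),
                                    retained_gene_index=np.arange(30))
        trace = select_model(scatter, all_candidates(3), triangle_centers, None, 3, 3)
        assert trace.selected_K == 3 and set(trace.per_K_models) == {3}

    def test_error_non_increasing_in_k(self):
        rng = np.random.default_rng(9)
        centers = simplex_points(rng, 5, 12)
        scatter = NormalizedScatter(points=simplex_points(rng, 5, 100),
                                    retained_gene_index=np.arange(100))
        trace = select_model(scatter, all_candidates(12), centers, None, 2, 8)
        errs = [trace.per_K_models[K].reconstruction_error for K in range(2, 9)]
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errs, errs[1:]))

    def test_k_range_validation(self, triangle_centers):
        rng = np.random.default_rng(10)
        scatter = NormalizedScatter(points=rng.dirichlet(np.ones(2), size=10),
                                    retained_gene_index=np.arange(10))
        with pytest.raises(ValueError):
            select_model(scatter, all_candidates(3), triangle_centers, None, 2, 5)

    def test_trace_table_columns(self, triangle_centers):
        rng = np.random.default_rng(11)
        scatter = NormalizedScatter(points=rng.dirichlet(np.ones(2), size=30),
                                    retained_gene_index=np.arange(30))
        trace = select_model(scatter, all_candidates(3), triangle_centers, None, 2, 3)
        table = trace.to_table()
        assert list(table.columns) == ["K", "reconstruction_error", "mdl",
                                       "vertex_cluster_ids"]
        assert table["K"].tolist() == [2, 3]
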