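import numpy as np
import pytest

from simplexdec import (
    DeconvolutionConfig,
    NormalizedScatter,
    run_pipeline,
    simulate_dataset,
)


def make_axis_bundle_scatter(n_per_axis=50, spread=0.02, dim=3, seed=42):
    """Three tight bundles of points, one within `spread` radians of each
    coordinate axis in `dim`-d, projected onto the standard simplex."""
    rng = np.random.default_rng(seed)
    pts = []
    for axis in range(dim):
        for _ in range(n_per_axis):
            v = np.zeros(dim)
            v[axis] = 1.0
            # perpendicular perturbation with a controlled angular size
            angle = rng.uniform(0, spread)
            perp = rng.uniform(0, 1, size=dim)
            perp[axis] = 0.0
            norm = np.linalg.norm(perp)
            if norm > 0:
                v = v + np.tan(angle) * perp / norm
            pts.append(v / v.sum())
    P = np.array(pts)
    return NormalizedScatter(points=P, retained_gene_index=np.arange(len(pts)))


@pytest.fixture(scope="session")
def axis_bundle_scatter():
    return make_axis_bundle_scatter()


@pytest.fixture(scope="session")
def triangle_centers():
    """Two corners of the 1-simplex plus their midpoint."""
    return np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])


# Tight cluster radius used on noise-free fixtures, where marker genes
# coincide exactly at the vertices (angular spread ~ float epsilon).
NOISE_FREE_CONFIG = DeconvolutionConfig(radius=1e-3, min_members=25, K_min=2, K_max=8)


@pytest.fixture(scope="session")
def noise_free_run():
    """Shared end-to-end run on the designed noise-free benchmark fixture:
    K=3 cell types, 3000 genes, 12 samples, 50 markers per type."""
    X, truth = simulate_dataset(K=3, G=3000, N=12, markers_per_type=50, seed=0)
    result = run_pipeline(X, NOISE_FREE_CONFIG)
    return X, truth, result
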