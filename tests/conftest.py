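import numpy as np
import pytest

import pertattn as pa


@pytest.fixture(scope="session")
def small_spec():
    """A miniature synthetic screen: 20 genes, 8 singles, 4 doubles."""
    return pa.SyntheticSpec(
        k_genes=20, n_terms=40, n_modules=4, n_single=8, n_double=4,
        cells_per_condition=10, n_control_cells=30, noise_sd=0.1,
        interaction_fraction=0.5, seed=11)


@pytest.fixture(scope="session")
def small_data(small_spec):
    return pa.simulate_dataset(small_spec)


@pytest.fixture(scope="session")
def small_annotations(small_spec):
    return pa.simulate_annotations(small_spec)


@pytest.fixture(scope="session")
def small_graphs(small_annotations, small_data):
    data, _ = small_data
    g = pa.build_go_graph(small_annotations, data.gene_index, k=5)
    return g, pa.augment_graph(g, alpha=0.75)


@pytest.fixture(scope="session")
def small_props(small_graphs):
    g, aug = small_graphs
    return pa.normalize_adjacency(g, hops=1), pa.normalize_adjacency(aug, hops=1)


@pytest.fixture(scope="session")
def small_model_config():
    return pa.ModelConfig(n_genes=20, d_embed=16, d_hidden=8, n_heads=2,
                          d_qk=8, d_v=8, d_p=8, d_b=8)


@pytest.fixture(scope="session")
def small_model(small_model_config):
    return pa.init_model(small_model_config, seed=3)


def random_graph(rng, n, density=0.4) -> pa.WeightedGeneGraph:
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                edges[(i, j)] = float(rng.uniform(0.05, 1.0))
    return pa.WeightedGeneGraph(n, edges)


def numeric_gradient(fn, arrays, eps=1e-6):
    """Central-difference gradients of a scalar function of numpy arrays."""
    grads = []
    for a in arrays:
        g = np.zeros_like(a)
        flat = a.ravel()
        gflat = g.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = fn(arrays)
            flat[i] = orig - eps
            lo = fn(arrays)
            flat[i] = orig
            gflat[i] = (hi - lo) / (2 * eps)
        grads.append(g)
    return grads
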