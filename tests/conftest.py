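import numpy as np
import pytest

import causalemb as ce


@pytest.fixture(scope="session")
def small_model():
    return ce.LatentModel(n_genes=60, n_targets=200, n_functions=30, d=5,
                          density=0.15, noise_rate=0.0, seed=11)


@pytest.fixture(scope="session")
def small_graph(small_model):
    graph, gene_vectors = ce.generate_expression_graph(small_model)
    return graph, gene_vectors


@pytest.fixture(scope="session")
def small_W(small_graph):
    graph, _ = small_graph
    return ce.build_weight_matrix(graph)


@pytest.fixture(scope="session")
def small_emb(small_W):
    return ce.spectral_embed(small_W, 8)


@pytest.fixture(scope="session")
def small_Y(small_model, small_graph):
    graph, _ = small_graph
    return ce.generate_function_associations(small_model, 10,
                                             genes=graph.regulators)


def random_sign_matrix(rng, n, m, density=0.5):
    """Dense random {-1,0,+1} matrix with every row nonzero."""
    s = rng.choice([-1, 1], size=(n, m)) * (rng.random((n, m)) < density)
    for i in range(n):
        if not s[i].any():
            s[i, rng.integers(m)] = 1
    return s.astype(int)


def graph_from_signs(signs):
    regs = [f"r{i}" for i in range(signs.shape[0])]
    tgts = [f"t{j}" for j in range(signs.shape[1])]
    edges = [ce.SignedEdge(regs[i], tgts[j], int(signs[i, j]))
             for i, j in zip(*np.nonzero(signs))]
    return ce.CausalGraph(regs, tgts, edges)
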