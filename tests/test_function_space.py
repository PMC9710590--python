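"""Function embeddings, scoring, similarity threshold, latent analyses."""

import numpy as np
import pytest
from scipy import sparse, stats

import causalemb as ce
from causalemb.function_space import FunctionEmbeddings


def make_assoc(genes, functions, dense):
    return ce.AssociationMatrix(genes, functions,
                                sparse.csr_matrix(np.asarray(dense, dtype=np.int8)))


def random_orthonormal(rng, n, k):
    q, _ = np.linalg.qr(rng.standard_normal((n, k)))
    return q


class TestFitFunctionEmbeddings:
    def test_single_gene_function_recovers_gene_vector(self):
        rng = np.random.default_rng(0)
        U = ce.EmbeddingMatrix([f"g{i}" for i in range(6)],
                               random_orthonormal(rng, 6, 3))
        y = np.zeros((6, 1), dtype=int)
        y[2, 0] = 1
        Y = make_assoc(U.ids, ["f0"], y)
        F = ce.fit_function_embeddings(U, Y)
        x = U.U[2]
        assert np.allclose(F.P[0], x, atol=1e-12)
        assert np.allclose(F.P_norm[0], x / np.linalg.norm(x), atol=1e-12)
        S = ce.score_genes(U, F)
        assert np.isclose(S.scores[2, 0], np.linalg.norm(x), atol=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10, 3))  # deliberately non-orthonormal
        U = ce.EmbeddingMatrix([f"g{i}" for i in range(10)], X)
        y = rng.choice([-1, 0, 1], size=(10, 4))
        Y = make_assoc(U.ids, [f"f{j}" for j in range(4)], y)
        F = ce.fit_function_embeddings(U, Y)
        for j in range(4):
            p_oracle, *_ = np.linalg.lstsq(X, y[:, j].astype(float),
                                           rcond=None)
            assert np.allclose(F.P[j], p_oracle, atol=1e-10)

    def test_orthonormal_shortcut_equals_general_solution(self):
        rng = np.random.default_rng(2)
        Q = random_orthonormal(rng, 12, 4)
        U = ce.EmbeddingMatrix([f"g{i}" for i in range(12)], Q)
        y = rng.choice([-1, 0, 1], size=(12, 3))
        Y = make_assoc(U.ids, [f"f{j}" for j in range(3)], y)
        F = ce.fit_function_embeddings(U, Y)  # uses shortcut internally
        for j in range(3):
            general = np.linalg.solve(Q.T @ Q, Q.T @ y[:, j].astype(float))
            assert np.allclose(F.P[j], general, atol=1e-10)

    def test_empty_function_flagged(self):
        rng = np.random.default_rng(3)
        U = ce.EmbeddingMatrix([f"g{i}" for i in range(5)],
                               random_orthonormal(rng, 5, 2))
        Y = make_assoc(U.ids, ["f0"], np.zeros((5, 1)))
        F = ce.fit_function_embeddings(U, Y)
        assert F.degenerate[0]
        assert np.allclose(F.P_norm[0], 0)

    def test_singular_gram_rejected(self):
        X = np.zeros((4, 3))
        X[:, 0] = 1.0  # rank-1: U^T U singular
        U = ce.EmbeddingMatrix([f"g{i}" for i in range(4)], X)
        Y = make_assoc(U.ids, ["f0"], [[1], [0], [0], [-1]])
        with pytest.raises(np.linalg.LinAlgError, match="dimension"):
            ce.fit_function_embeddings(U, Y)

    def test_scaling_y_leaves_normalized_vector_unchanged(self):
        # p_j is linear in y_j, so a positive rescaling cannot move p~_j
        rng = np.random.default_rng(4)
        X = rng.standard_normal((8, 3))
        y = rng.choice([-1.0, 0.0, 1.0], size=8)
        p1, *_ = np.linalg.lstsq(X, y, rcond=None)
        p2, *_ = np.linalg.lstsq(X, 3.7 * y, rcond=None)
        assert np.allclose(p1 / np.linalg.norm(p1),
                           p2 / np.linalg.norm(p2), atol=1e-12)


class TestScoring:
    def test_zero_gene_vector_scores_zero(self, small_emb, small_Y):
        F = ce.fit_function_embeddings(small_emb, small_Y)
        U0 = ce.EmbeddingMatrix(small_emb.ids, np.zeros_like(small_emb.U))
        S = ce.score_genes(U0, F)
        assert np.all(S.scores == 0)

    def test_antisymmetry_under_gene_negation(self, small_emb, small_Y):
        F = ce.fit_function_embeddings(small_emb, small_Y)
        S = ce.score_genes(small_emb, F)
        flipped = ce.EmbeddingMatrix(small_emb.ids, -small_emb.U)
        S2 = ce.score_genes(flipped, F)
        assert np.array_equal(S2.scores, -S.scores)

    def test_antisymmetry_under_function_negation(self, small_emb, small_Y):
        F = ce.fit_function_embeddings(small_emb, small_Y)
        S = ce.score_genes(small_emb, F)
        Fneg = FunctionEmbeddings(F.functions, -F.P, -F.P_norm, F.degenerate)
        S2 = ce.score_genes(small_emb, Fneg)
        assert np.array_equal(S2.scores, -S.scores)

    def test_planted_scores_ordered_by_association(self, small_emb, small_Y):
        F = ce.fit_function_embeddings(small_emb, small_Y)
        S = ce.score_genes(small_emb, F).scores
        dense = np.asarray(small_Y.matrix.todense())
        assert S[dense == 1].mean() > S[dense == 0].mean() \
            > S[dense == -1].mean()


class TestZScores:
    def test_analytic_value_at_unit_norm(self):
        U = ce.EmbeddingMatrix(["g0"], np.zeros((1, 500)))
        U.U[0, 0] = 1.0  # |x| = 1
        S = ce.ScoreMatrix(["g0"], ["f0"], np.array([[0.0894]]))
        Z = ce.score_zscores(S, U)
        assert np.isclose(Z.zscores[0, 0], 0.0894 * np.sqrt(500), atol=1e-12)
        assert abs(Z.zscores[0, 0] - 2.0) < 0.01

    def test_zero_score_zero_z(self, small_emb):
        S = ce.ScoreMatrix(small_emb.ids, ["f0"],
                           np.zeros((len(small_emb.ids), 1)))
        Z = ce.score_zscores(S, small_emb)
        assert np.all(Z.zscores == 0)

    def test_standard_normal_under_random_function_null(self):
        rng = np.random.default_rng(8)
        K = 50
        x = rng.standard_normal(K)
        p = rng.standard_normal((10_000, K))
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        z = (p @ x) * np.sqrt(K) / np.linalg.norm(x)
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_monotone_in_score_per_gene(self, small_emb, small_Y):
        F = ce.fit_function_embeddings(small_emb, small_Y)
        S = ce.score_zscores(ce.score_genes(small_emb, F), small_emb)
        for i in range(0, len(S.genes), 13):
            order_s = np.argsort(S.scores[i])
            order_z = np.argsort(S.zscores[i])
            assert np.array_equal(order_s, order_z)

    def test_empirical_column_standardization(self, small_emb, small_Y):
        F = ce.fit_function_embeddings(small_emb, small_Y)
        Z = ce.score_zscores(ce.score_genes(small_emb, F), small_emb,
                             empirical=True)
        assert np.allclose(Z.zscores.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(Z.zscores.std(axis=0), 1, atol=1e-10)


class TestCosineSimilarity:
    def test_self_similarity_one(self, small_emb, small_Y):
        F = ce.fit_function_embeddings(small_emb, small_Y)
        f = F.functions[0]
        assert np.isclose(ce.cosine_similarity(f, f, F), 1.0, atol=1e-12)

    def test_negated_vector_gives_minus_one(self):
        rng = np.random.default_rng(9)
        p = rng.standard_normal(6)
        p /= np.linalg.norm(p)
        F = FunctionEmbeddings(["f0", "f1"], np.vstack([p, -p]),
                               np.vstack([p, -p]), np.zeros(2, bool))
        assert np.isclose(ce.cosine_similarity("f0", "f1", F), -1.0)

    def test_matches_dot_product(self, small_emb, small_Y):
        F = ce.fit_function_embeddings(small_emb, small_Y)
        a, b = F.functions[0], F.functions[1]
        assert np.isclose(ce.cosine_similarity(a, b, F),
                          float(F.P_norm[0] @ F.P_norm[1]), atol=1e-15)


class TestSimilarityThreshold:
    def test_paper_dimension(self):
        assert round(ce.similarity_threshold(500), 2) == 0.09

    def test_closed_form_small_K(self):
        assert ce.similarity_threshold(4) == 1.0

    def test_sigma_c_monte_carlo(self):
        rng = np.random.default_rng(10)
        K = 500
        v = rng.standard_normal((100_000, K))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        sigma_c = v[:, 0].std()
        assert abs(sigma_c - K ** -0.5) / K ** -0.5 < 0.02


def make_pair_embedding(seed=0, n_contexts=12, noise=0.05, d=30):
    """Compositional "process of context" vectors: f = v_process + w_context."""
    rng = np.random.default_rng(seed)
    vX = rng.standard_normal((2, d))
    wY = rng.standard_normal((n_contexts, d))
    ids, vecs, pairs = [], [], []
    for y in range(n_contexts):
        for x in range(2):
            v = vX[x] + wY[y] + noise * rng.standard_normal(d)
            ids.append(f"p{x}_of_c{y}")
            vecs.append(v / np.linalg.norm(v))
        pairs.append((f"p0_of_c{y}", f"p1_of_c{y}"))
    P = np.vstack(vecs)
    F = FunctionEmbeddings(ids, P, P, np.zeros(len(ids), bool))
    return F, pairs


class TestProjection:
    def test_matches_eigendecomposition_oracle(self):
        F, pairs = make_pair_embedding()
        coords, ids = ce.project_process_pairs(F, pairs)
        X = np.vstack([F.vector(f) for f in ids])
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        top2 = evecs[:, ::-1][:, :2]
        oracle = Xc @ top2
        for k in range(2):  # PC sign is a convention; compare up to sign
            assert (np.allclose(coords[:, k], oracle[:, k], atol=1e-8)
                    or np.allclose(coords[:, k], -oracle[:, k], atol=1e-8))

    def test_centered_and_variance_ordered(self):
        F, pairs = make_pair_embedding(seed=3)
        coords, _ = ce.project_process_pairs(F, pairs)
        assert np.allclose(coords.sum(axis=0), 0, atol=1e-9)
        assert coords[:, 0].var() >= coords[:, 1].var()


class TestAngleParallelism:
    def test_exactly_parallel_reaches_minimal_p(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((8, 2))
        b = a + np.array([1.0, 0.5])
        coords = np.vstack([a, b])
        ids = [f"A{i}" for i in range(8)] + [f"B{i}" for i in range(8)]
        pairs = [(f"A{i}", f"B{i}") for i in range(8)]
        sd, p = ce.angle_parallelism_test(coords, ids, pairs,
                                          n_permutations=999, seed=1)
        assert sd == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1 / 1000)

    def test_null_p_values_uniform(self):
        ps = []
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            coords = rng.standard_normal((16, 2))
            ids = [f"n{i}" for i in range(16)]
            pairs = [(f"n{2 * i}", f"n{2 * i + 1}") for i in range(8)]
            _, p = ce.angle_parallelism_test(coords, ids, pairs,
                                             n_permutations=199, seed=s)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_additive_structure_detected(self):
        F, pairs = make_pair_embedding(seed=0)
        coords, ids = ce.project_process_pairs(F, pairs)
        _, p = ce.angle_parallelism_test(coords, ids, pairs,
                                         n_permutations=9999, seed=2)
        assert p < 0.01

    def test_coincident_endpoints_dropped_with_warning(self):
        coords = np.array([[0, 0], [1, 1], [2, 2], [3, 3],
                           [0, 1], [1, 2], [2, 3], [3, 3]], dtype=float)
        ids = list("abcdefgh")
        pairs = [("a", "e"), ("b", "f"), ("c", "g"), ("d", "h")]
        with pytest.warns(RuntimeWarning, match="coincident"):
            ce.angle_parallelism_test(coords, ids, pairs,
                                      n_permutations=99, seed=0)

    def test_too_few_pairs_rejected(self):
        coords = np.zeros((4, 2))
        with pytest.raises(ValueError):
            ce.angle_parallelism_test(coords, list("abcd"),
                                      [("a", "b"), ("c", "d")], 100, 0)


class TestDiseaseMap:
    def test_pca_stage_matches_oracle_and_layout_deterministic(self):
        rng = np.random.default_rng(5)
        P = rng.standard_normal((40, 30))
        P /= np.linalg.norm(P, axis=1, keepdims=True)
        ids = [f"d{i}" for i in range(40)]
        F = FunctionEmbeddings(ids, P, P, np.zeros(40, bool))
        reduced, layout = ce.disease_map_coordinates(F, ids, n_pca=20, seed=0)
        assert reduced.shape == (40, 20) and layout.shape == (40, 2)
        X = P - P.mean(axis=0)
        evals, evecs = np.linalg.eigh(X.T @ X)
        oracle = X @ evecs[:, ::-1][:, :20]
        for k in range(20):
            assert (np.allclose(reduced[:, k], oracle[:, k], atol=1e-8)
                    or np.allclose(reduced[:, k], -oracle[:, k], atol=1e-8))
        _, layout2 = ce.disease_map_coordinates(F, ids, n_pca=20, seed=0)
        assert np.array_equal(layout, layout2)
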