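"""Candidate construction, retrieval accuracy and prediction metrics."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from spotfusion.evaluation import (
    CandidateSet,
    adjacent_candidates,
    alignment_accuracy,
    correlation_histogram,
    mse_mae,
    pearson,
    pearson_per_gene,
    pearson_per_spot,
    random_candidates,
)


def grid_coords(rows, cols, spacing=1.0):
    rr, cc = np.divmod(np.arange(rows * cols), cols)
    return np.stack([cc * spacing, rr * spacing], axis=1)


class TestAdjacentCandidates:
    def test_interior_spot_nearest_neighbors(self):
        coords = grid_coords(5, 5)
        query = 12  # center of the grid
        cs = adjacent_candidates(coords, query, k=5)
        d = np.linalg.norm(coords - coords[query], axis=1)
        oracle = sorted((i for i in range(25) if i != query), key=lambda i: (d[i], i))[:5]
        assert cs.candidate_indices == [query] + oracle
        # 4 rook neighbors at distance 1, 5th is the first diagonal by index
        assert set(cs.candidate_indices[1:5]) == {7, 11, 13, 17}
        assert cs.candidate_indices[5] == 6

    def test_k_equals_n_minus_one_includes_everyone(self):
        coords = grid_coords(2, 3)
        cs = adjacent_candidates(coords, 0, k=5)
        assert sorted(cs.candidate_indices) == list(range(6))

    def test_query_always_among_candidates(self):
        coords = grid_coords(3, 3)
        for q in range(9):
            assert q in adjacent_candidates(coords, q, k=3).candidate_indices

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            adjacent_candidates(grid_coords(2, 2), 0, k=4)


class TestRandomCandidates:
    def test_deterministic_under_seed(self):
        a = random_candidates(20, 3, 5, rng_seed=7)
        b = random_candidates(20, 3, 5, rng_seed=7)
        assert a.candidate_indices == b.candidate_indices

    def test_forced_candidate_when_n_two(self):
        cs = random_candidates(2, 0, 1, rng_seed=0)
        assert sorted(cs.candidate_indices) == [0, 1]

    def test_marginal_inclusion_frequency(self):
        n, k, target = 6, 2, 4
        hits = sum(target in random_candidates(n, 0, k, rng_seed=s).candidate_indices
                   for s in range(10_000))
        p = k / (n - 1)
        se = np.sqrt(p * (1 - p) / 10_000)
        assert abs(hits / 10_000 - p) < 3 * se


class TestAlignmentAccuracy:
    def test_identical_embeddings_are_perfectly_aligned(self, rng):
        V = rng.standard_normal((10, 16))
        sets = [adjacent_candidates(grid_coords(2, 5), q, 3) for q in range(10)]
        assert alignment_accuracy(V, V.copy(), sets) == 1.0

    def test_fraction_arithmetic(self):
        # E matches V on rows 0-2; rows 3-4 point at the wrong partner
        V = np.eye(5)
        E = np.eye(5)
        E[3] = V[4]
        E[4] = V[3]
        sets = [CandidateSet(q, list(range(5)), "random", 4) for q in range(5)]
        assert alignment_accuracy(V, E, sets) == 0.6

    def test_chance_level_for_random_embeddings(self):
        rng = np.random.default_rng(0)
        k, trials = 4, 1000
        correct = 0
        for t in range(trials):
            V = rng.standard_normal((k + 1, 8))
            E = rng.standard_normal((k + 1, 8))
            sets = [CandidateSet(0, list(range(k + 1)), "random", k)]
            correct += alignment_accuracy(V, E, sets)
        p = 1 / (k + 1)
        se = np.sqrt(p * (1 - p) / trials)
        assert abs(correct / trials - p) < 3 * se

    def test_invariant_under_common_rotation(self, rng):
        V = rng.standard_normal((12, 8))
        E = rng.standard_normal((12, 8))
        Q, _ = np.linalg.qr(rng.standard_normal((8, 8)))
        sets = [adjacent_candidates(grid_coords(3, 4), q, 4) for q in range(12)]
        assert alignment_accuracy(V, E, sets) == alignment_accuracy(V @ Q, E @ Q, sets)

    def test_tie_counts_as_incorrect(self):
        V = np.array([[1.0, 0.0]])
        E = np.array([[1.0, 0.0], [2.0, 0.0]])  # equal cosine to the query
        sets = [CandidateSet(0, [0, 1], "random", 1)]
        assert alignment_accuracy(V, E, sets) == 0.0


class TestPearson:
    def test_affine_identities(self, rng):
        x = rng.standard_normal(50)
        assert np.isclose(pearson(x, 2 * x + 3), 1.0, atol=1e-10)
        assert np.isclose(pearson(x, -x), -1.0, atol=1e-10)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1),
           st.floats(-5, 5).filter(lambda a: abs(a) > 1e-3),
           st.floats(-5, 5))
    def test_sign_of_slope(self, seed, a, b):
        x = np.random.default_rng(seed).standard_normal(20)
        assert np.isclose(pearson(x, a * x + b), np.sign(a), atol=1e-8)

    def test_matches_scipy_oracle(self, rng):
        x, y = rng.standard_normal(40), rng.standard_normal(40)
        assert abs(pearson(x, y) - stats.pearsonr(x, y).statistic) < 1e-10

    def test_constant_vector_warns_and_returns_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            out = pearson(np.ones(5), np.arange(5.0))
        assert np.isnan(out)

    def test_per_gene_and_per_spot_layouts(self, rng):
        X = rng.standard_normal((6, 4))
        Xp = rng.standard_normal((6, 4))
        per_gene = pearson_per_gene(X, Xp)
        per_spot = pearson_per_spot(X, Xp)
        assert per_gene.shape == (4,) and per_spot.shape == (6,)
        assert np.isclose(per_gene[1], pearson(X[:, 1], Xp[:, 1]))
        assert np.isclose(per_spot[2], pearson(X[2], Xp[2]))


class TestErrorMetrics:
    def test_identical_matrices(self, rng):
        x = rng.standard_normal((3, 5))
        assert mse_mae(x, x.copy()) == (0.0, 0.0)

    def test_unit_differences(self, rng):
        x = rng.standard_normal((4, 4))
        signs = np.where(np.random.default_rng(1).random((4, 4)) < 0.5, -1.0, 1.0)
        assert mse_mae(x, x + signs) == (1.0, 1.0)

    def test_matches_loop_oracle(self, rng):
        x, y = rng.standard_normal((3, 4)), rng.standard_normal((3, 4))
        mse = np.mean([(x[i, j] - y[i, j]) ** 2 for i in range(3) for j in range(4)])
        mae = np.mean([abs(x[i, j] - y[i, j]) for i in range(3) for j in range(4)])
        got = mse_mae(x, y)
        assert abs(got[0] - mse) < 1e-12 and abs(got[1] - mae) < 1e-12


class TestHistogram:
    def test_single_bin_occupancy(self):
        counts = correlation_histogram([0.25, 0.21, 0.29], [0.0, 0.2, 0.4, 0.6])
        assert counts.tolist() == [0, 3, 0]

    def test_total_conserves_values_above_first_edge(self, rng):
        values = rng.uniform(-1, 1.2, 200)
        edges = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
        counts = correlation_histogram(values, edges)
        assert counts.sum() == (values >= 0.0).sum()

    def test_matches_sort_and_count_oracle(self, rng):
        values = rng.uniform(-0.5, 1.0, 100)
        edges = np.array([0.0, 0.25, 0.5, 0.75])
        counts = correlation_histogram(values, edges)
        oracle = [
            ((values >= 0.0) & (values < 0.25)).sum(),
            ((values >= 0.25) & (values < 0.5)).sum(),
            (values >= 0.5).sum(),  # last bin unbounded above
        ]
        assert counts.tolist() == oracle
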