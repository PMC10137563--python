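import networkx as nx
import numpy as np
import pytest

from ndfawm import (
    ModularityCurve,
    build_omega,
    modularity_curve,
    modularity_signed,
    sign_split,
)
from ndfawm.modularity import UndefinedModularityError

from conftest import all_partitions, brute_force_modularity


class TestSignSplit:
    def test_all_positive_input(self):
        split = sign_split(np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert np.all(split.A_minus == 0)
        assert split.d_plus.tolist() == [2.0, 2.0]
        assert split.m_plus == 2.0 and split.m_minus == 0.0

    def test_all_negative_input(self):
        split = sign_split(np.array([[0.0, -1.0], [-1.0, 0.0]]))
        assert np.all(split.A_plus == 0)
        assert split.m_minus == 1.0

    def test_reconstruction_and_disjoint_support(self, signed_toy):
        split = sign_split(signed_toy)
        np.testing.assert_array_equal(split.A_plus - split.A_minus, signed_toy)
        assert np.all(split.A_plus * split.A_minus == 0)
        total = split.m_plus + split.m_minus
        assert total == pytest.approx(np.abs(np.triu(signed_toy, 1)).sum())


class TestModularitySigned:
    def test_single_community_is_zero(self, signed_toy):
        assert modularity_signed(signed_toy, np.ones(6, int)) == pytest.approx(0.0, abs=1e-15)

    def test_two_disjoint_triangles_give_half(self):
        A = np.zeros((6, 6))
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            A[i, j] = A[j, i] = 1.0
        labels = np.array([1, 1, 1, 2, 2, 2])
        assert modularity_signed(A, labels) == pytest.approx(0.5)
        assert brute_force_modularity(A, labels) == pytest.approx(0.5)

    def test_matches_brute_force_on_signed_toy(self, signed_toy):
        for labels in all_partitions(6, 3):
            q = modularity_signed(signed_toy, labels)
            assert q == pytest.approx(brute_force_modularity(signed_toy, labels), abs=1e-12)

    def test_reduces_to_newman_girvan_when_nonnegative(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            n = 12
            A = np.triu(rng.random((n, n)) * (rng.random((n, n)) < 0.4), 1)
            A = A + A.T
            if A.sum() == 0:
                continue
            labels = rng.integers(1, 4, size=n)
            G = nx.from_numpy_array(A)
            comms = [set(np.flatnonzero(labels == c)) for c in np.unique(labels)]
            expected = nx.community.modularity(G, comms, weight="weight")
            assert modularity_signed(A, labels) == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_relabeling_and_node_permutation(self, signed_toy):
        labels = np.array([1, 1, 2, 2, 3, 3])
        q = modularity_signed(signed_toy, labels)
        assert modularity_signed(signed_toy, 4 - labels) == pytest.approx(q, abs=1e-14)
        rng = np.random.default_rng(0)
        perm = rng.permutation(6)
        q_perm = modularity_signed(signed_toy[np.ix_(perm, perm)], labels[perm])
        assert q_perm == pytest.approx(q, abs=1e-14)

    def test_invariant_under_positive_rescaling(self, signed_toy):
        labels = np.array([1, 2, 1, 2, 3, 3])
        q = modularity_signed(signed_toy, labels)
        for c in (0.1, 7.3):
            assert modularity_signed(c * signed_toy, labels) == pytest.approx(q, abs=1e-12)

    def test_bounded_by_one_in_absolute_value(self, signed_toy):
        for labels in all_partitions(6, 3):
            assert abs(modularity_signed(signed_toy, labels)) <= 1.0

    def test_all_zero_network_is_undefined(self):
        with pytest.raises(UndefinedModularityError):
            modularity_signed(np.zeros((4, 4)), np.ones(4, int))

    def test_nonzero_diagonal_follows_literal_formula(self):
        A = np.array([[2.0, 1.0], [1.0, -3.0]])
        for labels in ([1, 1], [1, 2]):
            q = modularity_signed(A, np.array(labels))
            assert q == pytest.approx(brute_force_modularity(A, labels), abs=1e-12)


class TestModularityCurve:
    def test_single_candidate(self, signed_toy):
        curve = modularity_curve(signed_toy, K0=1)
        assert curve.K_hat == 1
        assert curve.Q_values == {1: 0.0}

    def test_noiseless_three_block_estimates_k(self, three_block_spec):
        omega = build_omega(three_block_spec)
        curve = modularity_curve(omega, K0=6, seed=0)
        assert curve.K_hat == 3
        assert curve.Q_values[3] == max(curve.Q_values.values())

    def test_precomputed_embedding_matches_per_k_decomposition(self, three_block_spec):
        from ndfawm import ndfa, sample_adjacency
        A = sample_adjacency(three_block_spec, seed=2).A
        curve = modularity_curve(A, K0=5, seed=1)
        direct = modularity_curve(
            A, K0=5, seed=1,
            clusterer=lambda A_, k_, **kw: ndfa(A_, k_, **kw))
        assert curve.Q_values == pytest.approx(direct.Q_values, abs=1e-12)
        assert curve.K_hat == direct.K_hat

    def test_early_stop_variant(self, three_block_spec):
        omega = build_omega(three_block_spec)
        curve = modularity_curve(omega, K0=10, seed=0, early_stop=True)
        assert curve.stopped_early_at is not None
        assert curve.K_hat <= curve.stopped_early_at

    def test_curve_export(self, tmp_path, signed_toy):
        curve = modularity_curve(signed_toy, K0=3, seed=0)
        path = tmp_path / "curve.tsv"
        curve.to_tsv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "k\tQ"
        assert len(lines) == 4

    def test_all_zero_network_raises(self):
        with pytest.raises(UndefinedModularityError):
            modularity_curve(np.zeros((5, 5)), K0=3)
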