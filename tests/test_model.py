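import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ndfawm import (
    ModelSpec,
    build_membership,
    build_omega,
    validate_spec,
)
from ndfawm.model import InvalidLabelsError


def make_spec(family="poisson", n=12, K=3, theta=None, P=None, **kw):
    rng = np.random.default_rng(7)
    labels = (np.arange(n) % K) + 1
    if theta is None:
        theta = rng.uniform(0.5, 1.5, n)
    if P is None:
        P = np.array([[1.0, 0.2, 0.3], [0.2, 0.8, 0.2], [0.3, 0.2, 0.9]])[:K, :K]
        P = P / np.abs(P).max()
    return ModelSpec(n=n, K=K, labels=labels, theta=theta, P=P, family=family, **kw)


class TestMembership:
    def test_definitional_example(self):
        Z = build_membership([1, 1, 2], 2)
        assert Z.tolist() == [[1, 0], [1, 0], [0, 1]]

    def test_identity_case(self):
        assert np.array_equal(build_membership([1, 2, 3], 3), np.eye(3))

    def test_label_out_of_range_rejected(self):
        with pytest.raises(InvalidLabelsError):
            build_membership([1, 2, 4], 3)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(1, 5), min_size=1, max_size=40))
    def test_column_sums_count_communities(self, labels):
        K = max(labels)
        Z = build_membership(labels, K)
        counts = [labels.count(k) for k in range(1, K + 1)]
        assert Z.sum(axis=0).tolist() == counts
        assert np.all(Z.sum(axis=1) == 1)


class TestOmega:
    def test_single_community_unit_parameters(self):
        spec = ModelSpec(n=2, K=1, labels=[1, 1], theta=[1.0, 1.0],
                         P=[[1.0]], family="poisson")
        assert np.array_equal(build_omega(spec), np.ones((2, 2)))

    def test_two_block_closed_form(self):
        rho, beta = 0.7, 0.3
        spec = ModelSpec(n=2, K=2, labels=[1, 2], theta=[rho, rho],
                         P=[[1, beta], [beta, 1]], family="bernoulli")
        expected = rho ** 2 * np.array([[1, beta], [beta, 1]])
        np.testing.assert_allclose(build_omega(spec), expected)

    def test_matches_matrix_product_and_rank(self):
        spec = make_spec(n=12, K=3)
        omega = build_omega(spec)
        oracle = spec.Theta @ spec.Z @ spec.P @ spec.Z.T @ spec.Theta
        np.testing.assert_allclose(omega, oracle, atol=1e-12)
        assert np.array_equal(omega, omega.T)
        s = np.linalg.svd(omega, compute_uv=False)
        assert np.linalg.matrix_rank(omega) == 3
        assert np.all(s[3:] < 1e-10 * s[0])

    def test_constant_theta_is_dfm_reduction(self):
        # theta_i = rho for all i collapses the degree correction:
        # Omega = rho^2 * Z P Z'
        rho = 0.6
        spec = make_spec(n=9, K=3, theta=np.full(9, rho))
        np.testing.assert_allclose(
            build_omega(spec), rho ** 2 * (spec.Z @ spec.P @ spec.Z.T), atol=1e-14)


class TestValidation:
    def test_valid_spec_accepted(self):
        assert validate_spec(make_spec()).ok

    def test_bernoulli_probability_out_of_range(self):
        spec = make_spec(family="bernoulli", theta=np.full(12, 1.2))
        rep = validate_spec(spec)
        assert not rep.ok
        assert any(f.code == "prob-range" for f in rep.errors)

    def test_geometric_needs_omega_at_least_one(self):
        spec = make_spec(family="geometric", theta=np.full(12, 0.9))
        rep = validate_spec(spec)
        assert any(f.code == "omega-range" for f in rep.errors)
        ok = make_spec(family="geometric", theta=np.full(12, 3.0))
        assert validate_spec(ok).ok

    def test_signed_accepts_bounded_omega(self):
        spec = make_spec(family="signed", theta=np.full(12, 0.8))
        assert validate_spec(spec).ok

    def test_signed_rejects_omega_above_one(self):
        spec = make_spec(family="signed", theta=np.full(12, 1.5))
        assert not validate_spec(spec).ok

    @pytest.mark.parametrize("family", ["bernoulli", "binomial", "uniform"])
    def test_nonnegative_p_families_reject_negative_p(self, family):
        P = np.array([[1.0, -0.2], [-0.2, 0.8]])
        spec = ModelSpec(n=8, K=2, labels=(np.arange(8) % 2) + 1,
                         theta=np.full(8, 0.5), P=P, family=family,
                         m=5 if family == "binomial" else None)
        assert any(f.code == "P-sign" for f in validate_spec(spec).errors)

    def test_normal_allows_negative_p_but_needs_sigma2(self):
        P = np.array([[1.0, -0.2], [-0.2, 0.8]])
        spec = ModelSpec(n=8, K=2, labels=(np.arange(8) % 2) + 1,
                         theta=np.full(8, 0.5), P=P, family="normal", sigma2=1.0)
        assert validate_spec(spec).ok
        spec.sigma2 = None
        assert not validate_spec(spec).ok

    def test_rank_deficient_p_rejected(self):
        P = np.array([[1.0, 1.0], [1.0, 1.0]])
        spec = ModelSpec(n=8, K=2, labels=(np.arange(8) % 2) + 1,
                         theta=np.full(8, 0.5), P=P, family="poisson")
        assert any(f.code == "P-rank" for f in validate_spec(spec).errors)

    def test_empty_community_rejected(self):
        spec = ModelSpec(n=6, K=3, labels=[1, 1, 2, 2, 1, 2],
                         theta=np.full(6, 0.5),
                         P=np.eye(3) * np.array([1, 0.9, 0.8]), family="poisson")
        assert any(f.code == "labels-empty-community" for f in validate_spec(spec).errors)

    def test_max_abs_p_convention_is_warning_not_error(self):
        spec = make_spec(theta=np.full(12, 0.5),
                         P=0.5 * np.array([[1.0, 0.2, 0.3], [0.2, 0.8, 0.2],
                                           [0.3, 0.2, 0.9]]))
        rep = validate_spec(spec)
        assert rep.ok
        assert any(f.code == "P-maxabs" for f in rep.warnings)
        assert not validate_spec(spec, strict_max_abs=True).ok


def test_spec_round_trips_through_json(tmp_path, three_block_spec):
    path = tmp_path / "spec.json"
    three_block_spec.save(path)
    loaded = ModelSpec.load(path)
    assert loaded.n == three_block_spec.n and loaded.K == three_block_spec.K
    assert np.array_equal(loaded.labels, three_block_spec.labels)
    np.testing.assert_array_equal(loaded.theta, three_block_spec.theta)
    np.testing.assert_array_equal(loaded.P, three_block_spec.P)
    assert loaded.family == three_block_spec.family
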