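"""Model family: constructors, full-state kernel, equilibria, perturbation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blockmc.models import (
    BMCModel,
    ClusterAssignment,
    HigherOrderClusterModel,
    cluster_equilibrium,
    make_bmc,
    make_higher_order,
    make_zeroth_order,
    perturb,
    read_model,
    state_equilibrium,
    state_transition_matrix,
    write_model,
)

from .conftest import power_iteration_equilibrium


class TestClusterAssignment:
    def test_sizes_and_relative_sizes_partition_the_states(self):
        a = ClusterAssignment(7, 3, np.array([0, 0, 1, 1, 1, 2, 2]))
        assert a.sizes.tolist() == [2, 3, 2]
        assert a.sizes.sum() == 7
        assert a.relative_sizes.sum() == pytest.approx(1.0)

    def test_empty_cluster_warns_but_is_tolerated(self):
        with pytest.warns(UserWarning, match="empty"):
            ClusterAssignment(3, 2, np.array([0, 0, 0]))

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            ClusterAssignment(3, 2, np.array([0, 1, 2]))


class TestConstructors:
    def test_single_cluster_model_is_valid(self):
        model = make_bmc(ClusterAssignment.balanced(5, 1), [[1.0]])
        assert model.K == 1

    def test_printed_three_cluster_matrix_is_valid(self, three_cluster_p):
        model = make_bmc(ClusterAssignment.balanced(6, 3), three_cluster_p)
        np.testing.assert_allclose(model.p.sum(axis=1), 1.0, atol=1e-12)

    def test_row_sum_violation_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            make_bmc(ClusterAssignment.balanced(4, 2), [[0.5, 0.3], [0.5, 0.5]])

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            make_bmc(ClusterAssignment.balanced(4, 2), [[1.2, -0.2], [0.5, 0.5]])

    def test_dimension_mismatch_rejected(self, three_cluster_p):
        with pytest.raises(ValueError, match="shape"):
            make_bmc(ClusterAssignment.balanced(4, 2), three_cluster_p)


class TestStateTransitionMatrix:
    def test_single_cluster_gives_uniform_kernel(self):
        model = make_bmc(ClusterAssignment.balanced(4, 1), [[1.0]])
        np.testing.assert_allclose(state_transition_matrix(model), 0.25)

    def test_entries_follow_cluster_matrix_over_sizes(self, three_cluster_model):
        P = state_transition_matrix(three_cluster_model)
        # cluster 1 -> cluster 1 entry is 0.9 / 2 with two states per cluster
        assert P[0, 0] == pytest.approx(0.45)
        assert P[0, 1] == pytest.approx(0.45)

    def test_rows_sum_to_one(self, three_cluster_model):
        P = state_transition_matrix(three_cluster_model)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_within_cluster_column_symmetry_is_exact(self, three_cluster_model):
        P = state_transition_matrix(three_cluster_model)
        labels = three_cluster_model.assignment.labels
        for k in range(3):
            cols = np.flatnonzero(labels == k)
            assert np.all(P[:, cols[0]][:, None] == P[:, cols])


class TestEquilibria:
    def test_three_cluster_equilibrium_matches_exact_fractions(self, three_cluster_p):
        pi = cluster_equilibrium(three_cluster_p)
        np.testing.assert_allclose(pi, np.array([27, 10, 9]) / 46, atol=1e-12)

    def test_agrees_with_power_iteration_oracle(self, three_cluster_p):
        oracle = power_iteration_equilibrium(three_cluster_p)
        np.testing.assert_allclose(
            cluster_equilibrium(three_cluster_p), oracle, atol=1e-10
        )

    def test_zeroth_order_equilibrium_is_eta(self):
        eta = np.array([0.2, 0.3, 0.5])
        model = make_zeroth_order(ClusterAssignment.balanced(9, 3), eta)
        np.testing.assert_allclose(cluster_equilibrium(model.p), eta, atol=1e-12)

    def test_identity_matrix_is_not_ergodic(self):
        with pytest.raises(ValueError, match="strongly connected"):
            cluster_equilibrium(np.eye(2))

    def test_periodic_chain_warns_but_solves(self):
        p = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="periodic"):
            pi = cluster_equilibrium(p)
        np.testing.assert_allclose(pi, [0.5, 0.5], atol=1e-12)

    def test_state_equilibrium_uniform_for_single_cluster(self):
        model = make_bmc(ClusterAssignment.balanced(10, 1), [[1.0]])
        np.testing.assert_allclose(state_equilibrium(model), 0.1, atol=1e-12)

    def test_state_equilibrium_divides_pi_by_cluster_size(self, three_cluster_model):
        Pi = state_equilibrium(three_cluster_model)
        assert Pi[0] == pytest.approx((27 / 46) / 2, abs=1e-12)
        assert Pi.sum() == pytest.approx(1.0)

    def test_state_equilibrium_is_left_eigenvector_of_full_kernel(
        self, three_cluster_model
    ):
        P = state_transition_matrix(three_cluster_model)
        oracle = power_iteration_equilibrium(P)
        np.testing.assert_allclose(
            state_equilibrium(three_cluster_model), oracle, atol=1e-10
        )

    def test_large_model_equilibrium_matches_power_iteration(self, three_cluster_p):
        model = BMCModel(ClusterAssignment.balanced(200, 3), three_cluster_p)
        P = state_transition_matrix(model)
        np.testing.assert_allclose(
            state_equilibrium(model), power_iteration_equilibrium(P), atol=1e-10
        )


class TestZerothOrder:
    def test_all_rows_equal_eta(self):
        eta = np.array([1.0, 0.0])
        model = make_zeroth_order(ClusterAssignment.balanced(4, 2), eta)
        assert np.all(model.p == model.p[0])
        assert model.is_zeroth_order

    def test_invalid_eta_rejected(self):
        with pytest.raises(ValueError):
            make_zeroth_order(ClusterAssignment.balanced(4, 2), [0.6, 0.6])


class TestPerturb:
    def test_endpoints_and_convexity(self):
        base = np.array([[0.7, 0.3], [0.2, 0.8]])
        delta = np.full((2, 2), 0.5)
        np.testing.assert_array_equal(perturb(base, delta, 0.0), base)
        np.testing.assert_array_equal(perturb(base, delta, 1.0), delta)
        np.testing.assert_array_equal(perturb(base, base, 0.5), base)

    def test_epsilon_outside_unit_interval_rejected(self):
        base = np.full((2, 2), 0.5)
        with pytest.raises(ValueError):
            perturb(base, base, 1.5)

    @settings(max_examples=25, deadline=None)
    @given(st.floats(min_value=0.0, max_value=1.0), st.integers(0, 2**31 - 1))
    def test_mixture_stays_row_stochastic(self, eps, seed):
        rng = np.random.default_rng(seed)
        base = rng.dirichlet(np.ones(4), size=4)
        delta = rng.dirichlet(np.ones(4), size=4)
        mixed = perturb(base, delta, eps)
        np.testing.assert_allclose(mixed.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(mixed >= 0)


class TestHigherOrder:
    def test_order_one_reduces_to_bmc_kernel(self, three_cluster_p):
        a = ClusterAssignment.balanced(6, 3)
        hi = make_higher_order(a, three_cluster_p, r=1)
        bmc = make_bmc(a, three_cluster_p)
        labels, sizes = a.labels, a.sizes
        full = hi.q[np.ix_(labels, labels)] / sizes[labels][None, :]
        np.testing.assert_allclose(full, state_transition_matrix(bmc), atol=1e-15)

    def test_order_zero_matches_zeroth_order_model(self):
        a = ClusterAssignment.balanced(4, 2)
        eta = np.array([0.3, 0.7])
        hi = make_higher_order(a, eta[None, :], r=0)
        np.testing.assert_allclose(hi.q[0], make_zeroth_order(a, eta).p[0])

    def test_context_indexing_is_lexicographic(self, three_cluster_p):
        a = ClusterAssignment.balanced(6, 3)
        q = np.tile(three_cluster_p, (3, 1))
        hi = make_higher_order(a, q, r=2)
        assert hi.context_index((0, 0)) == 0
        assert hi.context_index((1, 2)) == 5
        assert hi.context_index((2, 2)) == 8

    def test_wrong_context_count_rejected(self, three_cluster_p):
        with pytest.raises(ValueError):
            make_higher_order(ClusterAssignment.balanced(6, 3), three_cluster_p, r=2)


class TestSerialization:
    def test_bmc_roundtrip(self, tmp_path, three_cluster_model):
        f = tmp_path / "model.txt"
        write_model(three_cluster_model, str(f))
        back = read_model(str(f))
        assert isinstance(back, BMCModel)
        np.testing.assert_allclose(back.p, three_cluster_model.p)
        np.testing.assert_array_equal(
            back.assignment.labels, three_cluster_model.assignment.labels
        )

    def test_higher_order_roundtrip(self, tmp_path, three_cluster_p):
        a = ClusterAssignment.balanced(6, 3)
        model = make_higher_order(a, np.tile(three_cluster_p, (3, 1)), r=2)
        f = tmp_path / "model.txt"
        write_model(model, str(f))
        back = read_model(str(f))
        assert isinstance(back, HigherOrderClusterModel)
        assert back.order == 2
        np.testing.assert_allclose(back.q, model.q)
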