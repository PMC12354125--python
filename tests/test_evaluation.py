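"""KL-rate comparison, CAIC order selection, and the error metrics."""

import math

import numpy as np
import pytest

from blockmc.evaluation import (
    EmpiricalProcedure,
    FirstOrderBMCProcedure,
    ZerothOrderBMCProcedure,
    caic,
    degrees_of_freedom,
    estimation_error,
    holdout_compare,
    kl_rate_difference,
    misclassification_rate,
    select_order,
)
from blockmc.models import (
    ClusterAssignment,
    make_bmc,
    make_zeroth_order,
    state_transition_matrix,
)
from blockmc.paths import SamplePath
from blockmc.simulate import SimulationConfig, sample_model_path


def path_of(states, n):
    return SamplePath(np.asarray(states), n=n)


class TestKLRateDifference:
    def test_equal_models_give_exactly_zero(self):
        P = np.array([[0.5, 0.5], [0.25, 0.75]])
        assert kl_rate_difference(path_of([0, 1, 0], 2), P, P) == 0.0

    def test_forced_two_transition_arithmetic(self):
        P = np.full((2, 2), 0.5)
        Q = np.array([[0.75, 0.25], [0.25, 0.75]])
        # both transitions get 0.5 under P and 0.25 under Q
        d = kl_rate_difference(path_of([0, 1, 0], 2), P, Q)
        assert d == pytest.approx(math.log(2), abs=1e-12)

    def test_nonnegative_when_scoring_the_generating_model(
        self, three_cluster_model
    ):
        P = state_transition_matrix(three_cluster_model)
        Q = np.full((6, 6), 1 / 6)
        for seed in range(5):
            path = sample_model_path(
                three_cluster_model, SimulationConfig(length=100_000, seed=seed)
            )
            assert kl_rate_difference(path, P, Q) > 0

    def test_zero_probability_transition_warns_and_is_infinite(self):
        P = np.array([[1.0, 0.0], [0.5, 0.5]])
        Q = np.full((2, 2), 0.5)
        with pytest.warns(UserWarning, match="zero transition probability"):
            d = kl_rate_difference(path_of([0, 1], 2), P, Q)
        assert d == float("-inf")


class TestHoldoutCompare:
    def test_same_procedure_gives_exactly_zero(self, three_cluster_model):
        path = sample_model_path(
            three_cluster_model, SimulationConfig(length=2_000, seed=0)
        )
        proc = FirstOrderBMCProcedure(3, seed=0)
        report = holdout_compare(path, proc, proc, n_boot=50, seed=0)
        assert report.dhat == 0.0

    def test_first_order_beats_zeroth_on_first_order_data(self):
        model = make_bmc(
            ClusterAssignment.balanced(60, 3),
            np.array([[0.9, 0.1, 0.0], [0.0, 0.1, 0.9], [0.3, 0.7, 0.0]]),
        )
        path = sample_model_path(model, SimulationConfig(length=100_000, seed=3))
        report = holdout_compare(
            path,
            FirstOrderBMCProcedure(3, seed=0),
            ZerothOrderBMCProcedure(3, seed=0),
            seed=0,
        )
        assert report.dhat > 0
        assert report.ci_low > 0  # CI excludes zero

    def test_no_detectable_gain_on_iid_data(self):
        model = make_zeroth_order(
            ClusterAssignment.balanced(60, 3), np.array([0.2, 0.3, 0.5])
        )
        path = sample_model_path(model, SimulationConfig(length=100_000, seed=4))
        report = holdout_compare(
            path,
            FirstOrderBMCProcedure(3, seed=0),
            ZerothOrderBMCProcedure(3, seed=0),
            seed=0,
        )
        assert report.ci_low <= 0.0 <= report.ci_high
        assert abs(report.dhat) <= report.ci_high - report.ci_low

    def test_ci_contains_point_estimate(self, three_cluster_model):
        path = sample_model_path(
            three_cluster_model, SimulationConfig(length=5_000, seed=5)
        )
        report = holdout_compare(
            path,
            FirstOrderBMCProcedure(3, seed=0),
            EmpiricalProcedure(),
            n_boot=200,
            seed=0,
        )
        assert report.ci_low <= report.dhat <= report.ci_high

    def test_too_short_path_rejected(self):
        with pytest.raises(ValueError):
            holdout_compare(
                path_of([0, 1, 0], 2), EmpiricalProcedure(), EmpiricalProcedure()
            )


class TestCAIC:
    def test_hand_computed_value_for_iid_fit(self):
        # marginal (1/2, 1/2) over 4 symbols; DF(2, 0) = 1
        path = path_of([0, 1, 0, 1], 2)
        expected = -8 * math.log(0.5) + 2 * 1 * (1 + math.log(4))
        assert caic(path, K=2, r=0) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(10.3178, abs=5e-4)

    def test_deterministic_alternation_reduces_to_penalty(self):
        path = path_of([0, 1] * 20, 2)
        penalty = 2 * degrees_of_freedom(None, 2, "clustered", r=1) * (
            1 + math.log(len(path) - 1)
        )
        assert caic(path, K=2, r=1) == pytest.approx(penalty, abs=1e-10)

    def test_order_exceeding_length_rejected(self):
        with pytest.raises(ValueError):
            caic(path_of([0, 1], 2), K=2, r=3)


class TestSelectOrder:
    @pytest.mark.parametrize("true_r", [0, 1, 2])
    def test_recovers_the_generating_order(self, true_r, three_cluster_p):
        ident = ClusterAssignment(3, 3, np.arange(3))
        if true_r == 0:
            model = make_zeroth_order(ident, np.array([0.2, 0.3, 0.5]))
            path = sample_model_path(model, SimulationConfig(length=50_000, seed=1))
        elif true_r == 1:
            model = make_bmc(ident, three_cluster_p)
            path = sample_model_path(model, SimulationConfig(length=50_000, seed=1))
        else:
            from blockmc.models import make_higher_order
            from blockmc.simulate import sample_path_higher_order

            # next cluster drawn from the row of the cluster two steps back
            q = np.array([three_cluster_p[i] for i in range(3) for _ in range(3)])
            model = make_higher_order(ident, q, r=2)
            path = sample_path_higher_order(
                model, SimulationConfig(length=50_000, seed=1, initial="uniform")
            )
        result = select_order(path, K=3, r_max=4)
        assert result.selected == true_r

    def test_table_has_percent_increase_column(self):
        path = path_of(np.random.default_rng(0).integers(0, 2, 500), 2)
        frame = select_order(path, K=2, r_max=2).to_frame()
        assert {"r", "CAIC", "DF", "increase_vs_best_pct"} <= set(frame.columns)
        assert frame["increase_vs_best_pct"].min() == 0.0


class TestDegreesOfFreedom:
    def test_first_order_excess_is_k_times_k_minus_one(self):
        assert degrees_of_freedom(300, 3, "first") == 306

    def test_zeroth_order_with_one_cluster_is_n(self):
        assert degrees_of_freedom(50, 1, "zeroth") == 50

    def test_clustered_formula(self):
        assert degrees_of_freedom(None, 3, "clustered", r=2) == 18
        assert degrees_of_freedom(None, 3, "clustered", r=1) == 6
        assert degrees_of_freedom(None, 2, "clustered", r=0) == 1


class TestMisclassification:
    def test_identical_assignments(self):
        a = ClusterAssignment(4, 2, np.array([0, 0, 1, 1]))
        assert misclassification_rate(a, a) == 0.0

    def test_label_swap_is_free(self):
        a = ClusterAssignment(4, 2, np.array([0, 0, 1, 1]))
        b = ClusterAssignment(4, 2, np.array([1, 1, 0, 0]))
        assert misclassification_rate(a, b) == 0.0

    def test_single_mismatch(self):
        a = ClusterAssignment(4, 2, np.array([0, 0, 1, 1]))
        b = ClusterAssignment(4, 2, np.array([0, 1, 1, 1]))
        assert misclassification_rate(a, b) == 0.25

    def test_brute_force_agrees_with_assignment_solver(self):
        # same metric computed by the K! search and the Hungarian route
        import itertools

        rng = np.random.default_rng(0)
        for _ in range(20):
            la = rng.integers(0, 4, size=12)
            lb = rng.integers(0, 4, size=12)
            la[:4] = np.arange(4)
            lb[:4] = np.arange(4)  # keep all clusters nonempty
            a = ClusterAssignment(12, 4, la)
            b = ClusterAssignment(12, 4, lb)
            conf = np.zeros((4, 4), dtype=int)
            np.add.at(conf, (la, lb), 1)
            brute = 1 - max(
                sum(conf[perm[j], j] for j in range(4))
                for perm in itertools.permutations(range(4))
            ) / 12
            assert misclassification_rate(a, b) == pytest.approx(brute, abs=1e-12)

    def test_pseudometric_on_random_triples(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            asgs = []
            for _ in range(3):
                labels = rng.integers(0, 3, size=9)
                labels[:3] = np.arange(3)
                asgs.append(ClusterAssignment(9, 3, labels))
            a, b, c = asgs
            dab = misclassification_rate(a, b)
            assert dab == pytest.approx(misclassification_rate(b, a), abs=1e-12)
            assert dab <= misclassification_rate(a, c) + misclassification_rate(
                c, b
            ) + 1e-12


class TestEstimationError:
    def test_zero_for_equal_matrices(self):
        P = np.full((3, 3), 1 / 3)
        assert estimation_error(P, P) == 0.0

    def test_rank_one_perturbation_has_unit_norm(self):
        rng = np.random.default_rng(2)
        P = rng.dirichlet(np.ones(5), size=5)
        u = rng.normal(size=5)
        u /= np.linalg.norm(u)
        v = rng.normal(size=5)
        v /= np.linalg.norm(v)
        assert estimation_error(P, P + np.outer(u, v)) == pytest.approx(1.0)

    def test_matches_svd_oracle_on_fixed_case(self, three_cluster_model):
        P = state_transition_matrix(three_cluster_model)
        U = np.full((6, 6), 1 / 6)
        oracle = np.linalg.svd(P - U, compute_uv=False)[0]
        assert estimation_error(P, U) == pytest.approx(oracle, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            estimation_error(np.eye(2), np.eye(3))
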