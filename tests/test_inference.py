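"""Random-network null, permutation tests, Fisher edge comparison, BH-FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covmod.cohort import Partition, ThicknessCohort
from covmod.inference import (
    bh_fdr,
    fisher_edge_comparison,
    fisher_z_statistic,
    network_statistic,
    permutation_group_test,
    random_modularity_null,
)
from covmod.modularity import optimize_partition
from covmod.network import apply_weight_policy, build_correlation_network
from covmod.residualize import residualize
from covmod.synth import CohortSpec, generate_cohort, make_autism_like_pair
from tests.conftest import make_network, symmetric_weights


def planted_network(n_subjects=100, seed=0):
    spec = CohortSpec(n_subjects=n_subjects, seed=seed)
    cohort = generate_cohort(spec)
    net = build_correlation_network(residualize(cohort)["control"])
    return apply_weight_policy(net, "truncate_negative"), spec


class TestRandomModularityNull:
    def test_uniform_weights_give_degenerate_null(self):
        w = np.full((10, 10), 0.4)
        np.fill_diagonal(w, 0.0)
        partition = Partition.from_labels([1 + i % 2 for i in range(10)])
        result = random_modularity_null(w, partition, n_reps=100, seed=1)
        np.testing.assert_allclose(result.null_q, result.observed_q, atol=1e-14)
        assert result.p_two_sided == 1.0

    def test_planted_structure_beats_every_random_network(self):
        net, _ = planted_network(seed=3)
        best = optimize_partition(net, n_restarts=30, seed=0)
        result = random_modularity_null(net, best.partition, n_reps=1000, seed=5)
        assert result.observed_q > result.null_q.max()
        assert result.p_one_sided < 0.001

    def test_replicates_conserve_total_weight(self):
        from covmod.inference import _shuffled_network

        rng = np.random.default_rng(2)
        w = symmetric_weights(rng, 12)
        iu = np.triu_indices(12, 1)
        for _ in range(10):
            shuffled = _shuffled_network(w, rng)
            assert shuffled[iu].sum() == pytest.approx(w[iu].sum(), abs=1e-12)
            # the multiset of weights is preserved exactly
            np.testing.assert_allclose(np.sort(shuffled[iu]), np.sort(w[iu]))

    def test_minimum_replicates_enforced(self):
        w = symmetric_weights(np.random.default_rng(0), 5)
        with pytest.raises(ValueError, match="100"):
            random_modularity_null(w, Partition.from_labels([1] * 5), n_reps=10)


class TestPermutationTest:
    def test_constant_statistic_gives_p_one(self):
        case, control = make_autism_like_pair(CohortSpec(n_subjects=10, seed=1))
        result = permutation_group_test(case, control, lambda c: 1.0, n_perm=50, seed=0)
        assert result.p_value == 1.0
        assert result.observed_diff == 0.0

    def test_p_value_in_unit_interval_and_add_one_convention(self):
        case, control = make_autism_like_pair(CohortSpec(n_subjects=12, seed=2))
        stat = lambda c: float(c.thickness.to_numpy().mean())
        result = permutation_group_test(case, control, stat, n_perm=99, seed=3)
        assert 0 < result.p_value <= 1
        exceed = (np.abs(result.null_diffs) >= abs(result.observed_diff)).sum()
        assert result.p_value == pytest.approx((1 + exceed) / 100)
        plain = permutation_group_test(case, control, stat, n_perm=99, seed=3, add_one=False)
        assert plain.p_value == pytest.approx(exceed / 99)

    def test_module_connectivity_difference_detected(self):
        # module-I within-block correlation lowered by 0.3 in the case group
        spec = CohortSpec(n_subjects=100, seed=11)
        case, control = make_autism_like_pair(spec)
        stat = network_statistic("MC", spec.partition(), module_id=1)
        result = permutation_group_test(case, control, stat, n_perm=1000, seed=4)
        assert float(result.observed_diff[0]) < 0
        assert float(np.atleast_1d(result.p_value)[0]) < 0.01

    def test_non_finite_statistic_aborts_with_replicate_index(self):
        case, control = make_autism_like_pair(CohortSpec(n_subjects=8, seed=5))
        calls = {"n": 0}

        def bad_stat(cohort):
            calls["n"] += 1
            return np.nan if calls["n"] > 4 else 0.0

        with pytest.raises(FloatingPointError, match="permutation"):
            permutation_group_test(case, control, bad_stat, n_perm=20, seed=1)

    def test_group_sizes_preserved_across_permutations(self):
        case, control = make_autism_like_pair(CohortSpec(n_subjects=9, seed=6))
        stat = lambda c: float(c.n_subjects)
        result = permutation_group_test(case, control, stat, n_perm=30, seed=2)
        np.testing.assert_allclose(result.null_diffs, 0.0)  # 9 - 9 every time


class TestFisherComparison:
    @pytest.mark.parametrize(
        "r_case,r_control,printed_z",
        [(-0.45, 0.43, 4.61), (-0.76, 0.08, 5.21)],
    )
    def test_two_sample_z_against_published_values(self, r_case, r_control, printed_z):
        z = fisher_z_statistic(r_case, r_control, 49, 51)
        assert abs(abs(z) - printed_z) < 0.06

    def test_equal_correlations_give_zero(self):
        assert fisher_z_statistic(0.37, 0.37, 20, 30) == 0.0

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(8)
        r_a = (lambda m: (m + m.T) / 2)(rng.uniform(-0.9, 0.9, (6, 6)))
        r_b = (lambda m: (m + m.T) / 2)(rng.uniform(-0.9, 0.9, (6, 6)))
        net_a, net_b = make_network(r_a, 40), make_network(r_b, 60)
        fwd = fisher_edge_comparison(net_a, net_b)
        rev = fisher_edge_comparison(net_b, net_a)
        np.testing.assert_allclose(fwd["Z"].to_numpy(), -rev["Z"].to_numpy(), atol=1e-12)

    def test_sign_convention_decrease_in_case_is_positive(self):
        r_a = np.array([[0.0, -0.4], [-0.4, 0.0]])
        r_b = np.array([[0.0, 0.5], [0.5, 0.0]])
        table = fisher_edge_comparison(make_network(r_a, 49), make_network(r_b, 51))
        assert table["Z"].iloc[0] > 0

    def test_degenerate_edges_flagged_and_excluded(self):
        r_a = np.array([[0.0, 1.0, 0.2], [1.0, 0.0, 0.1], [0.2, 0.1, 0.0]])
        r_b = np.zeros((3, 3))
        with pytest.warns(UserWarning, match="excluded"):
            table = fisher_edge_comparison(make_network(r_a, 30), make_network(r_b, 30))
        assert table["degenerate"].sum() == 1
        assert not table.loc[table["degenerate"], "fdr_significant"].any()
        assert table.loc[table["degenerate"], "p"].isna().all()

    def test_mismatched_node_sets_rejected(self):
        net_a = make_network(np.zeros((3, 3)), 30)
        net_b = make_network(np.zeros((4, 4)), 30)
        with pytest.raises(ValueError, match="node sets"):
            fisher_edge_comparison(net_a, net_b)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="3 subjects"):
            fisher_z_statistic(0.1, 0.2, 3, 50)

    def test_null_edges_calibrated_at_one_percent(self):
        # two halves of one homogeneous cohort: ~1% of |Z| should exceed 2.58
        spec = CohortSpec(n_subjects=400, seed=19)
        cohort = generate_cohort(spec)
        half = ThicknessCohort(
            covariates=cohort.covariates.iloc[:200].reset_index(drop=True),
            thickness=cohort.thickness.iloc[:200].reset_index(drop=True),
            atlas=cohort.atlas,
        )
        other = ThicknessCohort(
            covariates=cohort.covariates.iloc[200:].reset_index(drop=True),
            thickness=cohort.thickness.iloc[200:].reset_index(drop=True),
            atlas=cohort.atlas,
        )
        nets = [
            build_correlation_network(residualize(c)["control"]) for c in (half, other)
        ]
        table = fisher_edge_comparison(nets[0], nets[1])
        rate = float((table["Z"].abs() > 2.58).mean())
        assert 0.002 < rate < 0.03


class TestBHFDR:
    def test_all_tiny_pvalues_rejected(self):
        assert bh_fdr(np.full(10, 0.001), q=0.01).all()

    def test_step_up_worked_example(self):
        # i* = 4 because 0.041 <= 4 * 0.05 / 4
        flags = bh_fdr(np.array([0.001, 0.008, 0.039, 0.041]), q=0.05)
        assert flags.all()

    def test_matches_direct_step_up_definition(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            pvals = rng.uniform(size=40) ** rng.uniform(0.5, 3)
            q = 0.05
            order = np.argsort(pvals)
            sorted_p = pvals[order]
            m = len(pvals)
            below = np.flatnonzero(sorted_p <= (np.arange(1, m + 1) * q / m))
            expected = np.zeros(m, dtype=bool)
            if below.size:
                expected[order[: below[-1] + 1]] = True
            np.testing.assert_array_equal(bh_fdr(pvals, q), expected)

    def test_empty_input(self):
        assert bh_fdr([], q=0.01).size == 0

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2], q=0.05)


@given(st.integers(min_value=0, max_value=1_000))
@settings(max_examples=10)
def test_permutation_pvalues_superuniform_under_null(seed):
    # a fast scalar statistic on two cohorts from the same distribution
    spec = CohortSpec(n_subjects=15, seed=seed)
    a = generate_cohort(spec, "control")
    b = generate_cohort(
        CohortSpec.from_dict({**spec.to_dict(), "seed": seed + 100_000}), "control"
    )
    stat = lambda c: float(c.thickness.to_numpy().mean())
    result = permutation_group_test(a, b, stat, n_perm=39, seed=seed)
    assert 0 < result.p_value <= 1
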