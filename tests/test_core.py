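"""LPFS constraint construction, LP relaxation, exhaustive oracle, lambda path."""

import dataclasses

import numpy as np
import pytest

from lpfs.core import (
    LPFSProblem,
    accuracy_from_errors,
    build_loo_problem,
    build_resub_problem,
    distance_gap,
    lambda_path,
    posthoc_loo_accuracy,
    select_features,
    solve_ilp_exhaustive,
    solve_lp,
    export_lp,
)
from lpfs.io_profiles import GroupedDataset
from lpfs.synthetic import SyntheticSpec, generate, generate_null, planted_spec

from conftest import random_grouped

WORKED_G = np.array([[2.0, -1.0], [2.0, 0.0], [-1.0, 2.0], [0.0, 2.0]])


def worked_problem(lam=10.0):
    return LPFSProblem(G=WORKED_G, delta=1.0, lam=lam, x_upper=np.inf)


class TestDistanceGap:
    def test_case_sample_gap(self):
        g = distance_gap([0.0, 0.0], "case", [1.0, 0.0], [3.0, 0.0])
        np.testing.assert_allclose(g, [2.0, 0.0])

    def test_control_sample_flips_sign(self):
        g = distance_gap([0.0, 0.0], "control", [1.0, 0.0], [3.0, 0.0])
        np.testing.assert_allclose(g, [-2.0, 0.0])

    def test_midway_sample_has_zero_gap(self):
        g = distance_gap([2.0, 2.0], "case", [1.0, 3.0], [3.0, 1.0])
        np.testing.assert_allclose(g, [0.0, 0.0])

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            distance_gap([0.0], "case", [1.0, 2.0], [3.0, 4.0])


class TestProblemBuilders:
    def test_loo_row_for_tiny_instance(self, tiny4):
        prob = build_loo_problem(tiny4, lam=1.0, row_normalize=False)
        assert prob.G.shape == (4, 1)
        # case sample [0]: fold centroids mu_T=[2], mu_F=[11] -> |0-11|-|0-2| = 9
        assert prob.G[0, 0] == pytest.approx(9.0)

    def test_resub_row_uses_full_centroids(self, tiny4):
        prob = build_resub_problem(tiny4, lam=1.0, row_normalize=False)
        # case sample [0]: mu_T=[1], mu_F=[11] -> |0-11|-|0-1| = 10
        assert prob.G[0, 0] == pytest.approx(10.0)

    @pytest.mark.parametrize("builder", [build_loo_problem, build_resub_problem])
    def test_one_constraint_per_sample(self, builder, separated_ds):
        prob = builder(separated_ds, lam=1.0)
        assert prob.n_constraints == separated_ds.m1 + separated_ds.m2

    @pytest.mark.parametrize("builder", [build_loo_problem, build_resub_problem])
    def test_gap_rows_invariant_under_group_swap(self, builder, separated_ds):
        """Relabeling case<->control flips both the sample's sign convention and
        the centroid roles; the two cancel, so the constraint system is
        unchanged (validated-sample order differs only by block)."""
        swapped = GroupedDataset(
            T=separated_ds.F,
            F=separated_ds.T,
            feature_ids=separated_ds.feature_ids,
        )
        a = builder(separated_ds, lam=1.0, row_normalize=False)
        b = builder(swapped, lam=1.0, row_normalize=False)
        m1 = separated_ds.m1
        np.testing.assert_allclose(b.G, np.vstack([a.G[m1:], a.G[:m1]]), atol=1e-12)

    def test_row_normalization_records_scales(self, separated_ds):
        prob = build_loo_problem(separated_ds, lam=1.0)
        assert prob.row_scale is not None
        np.testing.assert_allclose(np.abs(prob.G).mean(axis=1), 1.0, atol=1e-12)

    def test_resub_optimum_no_harder_than_loo(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            ds = random_grouped(rng, 4, 4, 6)
            lo = solve_lp(build_loo_problem(ds, lam=2.0, row_normalize=False))
            re = solve_lp(build_resub_problem(ds, lam=2.0, row_normalize=False))
            assert re.objective <= lo.objective + 1e-7


class TestSolveLP:
    def test_worked_instance(self):
        sol = solve_lp(worked_problem())
        assert sol.solver_status == "optimal"
        assert sol.objective == pytest.approx(2.0, abs=1e-8)
        np.testing.assert_allclose(sol.x, [1.0, 1.0], atol=1e-8)
        np.testing.assert_allclose(sol.y, 0.0, atol=1e-8)

    def test_single_row_split_between_features(self):
        prob = LPFSProblem(G=np.array([[2.0, 2.0]]), delta=1.0, lam=10.0, x_upper=np.inf)
        sol = solve_lp(prob)
        assert sol.objective == pytest.approx(0.5, abs=1e-8)
        assert sol.x.sum() == pytest.approx(0.5, abs=1e-8)

    def test_vanishing_lambda_buys_all_error(self):
        prob = dataclasses.replace(worked_problem(), lam=1e-9)
        sol = solve_lp(prob)
        np.testing.assert_allclose(sol.x, 0.0, atol=1e-9)
        np.testing.assert_allclose(sol.y, prob.delta, atol=1e-9)

    def test_objective_identity(self):
        sol = solve_lp(worked_problem(lam=3.0))
        assert sol.objective == pytest.approx(sol.x.sum() + 3.0 * sol.y.sum(), abs=1e-8)


class TestExhaustiveOracle:
    def test_worked_instance(self):
        sol = solve_ilp_exhaustive(worked_problem())
        assert sol.objective == pytest.approx(2.0)
        np.testing.assert_array_equal(sol.x, [1.0, 1.0])
        np.testing.assert_allclose(sol.y, 0.0)

    def test_useless_features_buy_nothing(self):
        prob = LPFSProblem(G=np.zeros((3, 2)), delta=1.0, lam=1.0)
        sol = solve_ilp_exhaustive(prob)
        np.testing.assert_array_equal(sol.x, [0.0, 0.0])
        np.testing.assert_allclose(sol.y, [1.0, 1.0, 1.0])
        assert sol.objective == pytest.approx(3.0)

    def test_refuses_large_n(self):
        prob = LPFSProblem(G=np.ones((2, 25)), delta=1.0, lam=1.0)
        with pytest.raises(ValueError, match="refused"):
            solve_ilp_exhaustive(prob)

    def test_lp_relaxation_never_exceeds_ilp(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            ds = random_grouped(rng, 4, 4, int(rng.integers(2, 8)))
            prob = build_loo_problem(ds, lam=1.5, row_normalize=False)
            lp = solve_lp(prob)
            ilp = solve_ilp_exhaustive(prob)
            assert lp.objective <= ilp.objective + 1e-7


class TestSelectionAndAccuracy:
    def test_positive_support_only(self):
        sol = solve_lp(worked_problem())
        sol.x = np.array([0.5, 0.0, 1e-12])
        assert select_features(sol) == [0]

    def test_zero_scores_select_nothing(self):
        sol = solve_lp(worked_problem())
        sol.x = np.zeros(3)
        assert select_features(sol) == []

    def test_descending_score_order(self):
        sol = solve_lp(worked_problem())
        sol.x = np.array([0.002, 0.015, 0.006])
        assert select_features(sol) == [1, 2, 0]

    @pytest.mark.parametrize(
        "y, expected",
        [([0, 0, 0.5, 0], 0.75), ([0, 0], 1.0), ([1.0, 1.0, 1.0], 0.0)],
    )
    def test_accuracy_counts_zero_slacks(self, y, expected):
        sol = solve_lp(worked_problem())
        sol.y = np.array(y, dtype=float)
        assert accuracy_from_errors(sol, tol_correct=1e-6) == pytest.approx(expected)
        assert sol.n_correct + sol.n_wrong == len(y)


class TestPosthocLooAccuracy:
    def test_single_strong_marker_classifies_perfectly(self, separated_ds):
        ds, truth = generate(
            planted_spec(seed=7, n_features=30, m1=5, m2=5, n_planted=5, shift=6.0)
        )
        marker = sorted(truth.planted)[:1]
        assert posthoc_loo_accuracy(ds, marker) == 1.0

    def test_all_features_also_perfect(self, separated_ds):
        assert posthoc_loo_accuracy(separated_ds, range(separated_ds.n)) == 1.0

    def test_empty_selection_errors(self, separated_ds):
        with pytest.raises(ValueError, match="non-empty"):
            posthoc_loo_accuracy(separated_ds, [])

    def test_permuted_labels_score_near_chance(self):
        rng = np.random.default_rng(23)
        accs = []
        for seed in range(10):
            ds, _ = generate_null(SyntheticSpec(n_features=50, m1=8, m2=8, seed=seed))
            X = np.vstack([ds.T, ds.F])
            perm = rng.permutation(X.shape[0])
            shuffled = GroupedDataset(
                T=X[perm[: ds.m1]], F=X[perm[ds.m1 :]], feature_ids=ds.feature_ids
            )
            accs.append(posthoc_loo_accuracy(shuffled, range(ds.n)))
        assert 0.3 < np.mean(accs) < 0.7


class TestLambdaPath:
    def test_single_point_grid_is_chosen(self, separated_ds):
        path = lambda_path(separated_ds, grid=[5.0])
        assert path.chosen_lambda == 5.0

    def test_large_lambda_end_is_separable(self, separated_ds):
        path = lambda_path(separated_ds)
        last = path.solutions[-1]
        np.testing.assert_allclose(last.y, 0.0, atol=1e-7)

    def test_chosen_solution_has_perfect_accuracy_on_planted_data(self):
        for seed in range(4):
            ds, truth = generate(planted_spec(seed=seed, n_features=80, m1=8, m2=8))
            path = lambda_path(ds)
            assert path.chosen_accuracy == 1.0
            assert path.chosen_solution.selected, "no features selected"
            assert set(path.chosen_solution.selected) <= truth.planted

    def test_selection_size_roughly_nondecreasing_in_lambda(self):
        # solver ties can swap adjacent grid points; tolerate one adjacency
        violations_per_seed = []
        for seed in range(5):
            ds, _ = generate(planted_spec(seed=seed, n_features=60, m1=6, m2=6))
            path = lambda_path(ds)
            sizes = [s.n_selected for s in path.solutions]
            violations_per_seed.append(
                sum(1 for a, b in zip(sizes, sizes[1:]) if b < a)
            )
        assert np.mean(violations_per_seed) <= 1.5

    def test_degenerate_all_zero_not_optimal_at_large_lambda(self, separated_ds):
        sol = solve_lp(build_loo_problem(separated_ds, lam=1e3))
        assert sol.n_selected > 0


class TestScaleInvariance:
    def test_rescaled_intensities_give_same_selection(self, separated_ds):
        scaled = GroupedDataset(
            T=separated_ds.T * 1000.0,
            F=separated_ds.F * 1000.0,
            feature_ids=separated_ds.feature_ids,
        )
        a = lambda_path(separated_ds)
        b = lambda_path(scaled)
        assert a.chosen_solution.selected == b.chosen_solution.selected
        assert a.chosen_accuracy == b.chosen_accuracy


def test_export_lp_writes_cplex_dialect(tmp_path, tiny4):
    prob = build_loo_problem(tiny4, lam=2.0)
    out = tmp_path / "model.lp"
    export_lp(prob, out)
    text = out.read_text()
    assert text.startswith("Minimize")
    assert "Subject To" in text and "Bounds" in text and text.rstrip().endswith("End")
    assert f"c{prob.n_constraints - 1}:" in text
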