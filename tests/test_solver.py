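import itertools

import numpy as np
import pytest

from clonedemix import (
    CapExceededError,
    CloneTree,
    ConstraintSet,
    ErrorModelConfig,
    FirstGenerationTree,
    clone_frequencies,
    combine_partial_trees,
    enumerate_solutions,
    find_first_generation_trees,
    fit_frequencies_nnls,
    solve,
)
from clonedemix.oracle import brute_force_solve, optimal_set
from clonedemix.simulate import SimulationConfig, random_tree
from clonedemix.solver import PartialTree, joint_solve

from .conftest import (
    WEX_PARENTS,
    WEX_X,
    make_signal,
    random_exact_signal,
)

BOUND = ErrorModelConfig("bound")


def scan_fg_trees(signal, model):
    """Independent exhaustive scan of every (parent, subset) pair."""
    found = set()
    n = signal.n
    for i in range(n):
        rest = list(range(i + 1, n))
        for r in range(1, len(rest) + 1):
            for subset in itertools.combinations(rest, r):
                diff = signal.y[i] - sum(signal.y[j] for j in subset)
                allow = model.allowance(signal.eps[i], [signal.eps[j] for j in subset])
                if abs(diff) <= allow:
                    found.add((i, frozenset(subset)))
    return found


class TestFirstGenerationTrees:
    def test_wex_exact(self, wex_signal):
        fgs = find_first_generation_trees(wex_signal)
        assert {(t.parent, t.children) for t in fgs} == {
            (0, frozenset({1, 3})),
            (2, frozenset({4, 5})),
        }

    def test_wex_bound_matches_exhaustive_scan(self, wex_signal_bound):
        fgs = find_first_generation_trees(wex_signal_bound, BOUND)
        assert {(t.parent, t.children) for t in fgs} == scan_fg_trees(
            wex_signal_bound, BOUND
        )
        assert len(fgs) == 9

    def test_no_match(self):
        sig = make_signal([1.0, 0.4])
        assert find_first_generation_trees(sig) == []

    def test_cap_refusal(self):
        n = 27
        y = np.concatenate(([1.0], np.sort(np.linspace(0.01, 0.9, n - 1))[::-1]))
        with pytest.raises(CapExceededError):
            find_first_generation_trees(make_signal(y))

    def test_matches_scan_on_random_signals_all_models(self):
        rng = np.random.default_rng(3)
        for kind in ("exact", "bound", "normal"):
            model = ErrorModelConfig(kind)
            for _ in range(20):
                n = int(rng.integers(2, 8))
                y = np.concatenate(([1.0], np.sort(rng.uniform(0, 1, n - 1))[::-1]))
                eps = np.concatenate(([0.0], rng.uniform(0, 0.05, n - 1)))
                sig = make_signal(y, eps)
                fgs = find_first_generation_trees(sig, model)
                assert {(t.parent, t.children) for t in fgs} == scan_fg_trees(sig, model)

    def test_meet_in_middle_agrees_with_dfs(self):
        # exact model switches to meet-in-the-middle above 15 candidates
        rng = np.random.default_rng(11)
        truth = random_tree(SimulationConfig(N=18, P=6), rng)
        fgs = find_first_generation_trees(truth.signal)
        assert {(t.parent, t.children) for t in fgs} == scan_fg_trees(
            truth.signal, ErrorModelConfig("exact")
        )

    def test_monotone_in_eps(self):
        # enlarging every eps never removes a first-generation tree
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(3, 8))
            y = np.concatenate(([1.0], np.sort(rng.uniform(0, 1, n - 1))[::-1]))
            small = make_signal(y, np.concatenate(([0.0], np.full(n - 1, 0.01))))
            large = make_signal(y, np.concatenate(([0.0], np.full(n - 1, 0.03))))
            fg_small = {(t.parent, t.children) for t in find_first_generation_trees(small, BOUND)}
            fg_large = {(t.parent, t.children) for t in find_first_generation_trees(large, BOUND)}
            assert fg_small <= fg_large


class TestCombinePartialTrees:
    def test_wex_exact_single_maximal(self, wex_signal):
        fgs = find_first_generation_trees(wex_signal)
        partials = combine_partial_trees(fgs)
        assert len(partials) == 1
        assert partials[0].h == 2
        assert partials[0].frozen_parents() == {
            0: frozenset({1, 3}),
            2: frozenset({4, 5}),
        }

    def test_wex_bound_max_h_two(self, wex_signal_bound):
        fgs = find_first_generation_trees(wex_signal_bound, BOUND)
        partials = combine_partial_trees(fgs)
        assert all(pt.h == 2 for pt in partials)
        # independent check: no compatible triple exists
        def compat(a, b):
            return a.parent != b.parent and not (a.children & b.children)

        for trio in itertools.combinations(fgs, 3):
            assert not all(compat(a, b) for a, b in itertools.combinations(trio, 2))
        # and every returned pair is genuinely compatible
        for pt in partials:
            a, b = sorted(pt.fg_trees, key=lambda t: t.parent)
            assert compat(a, b)

    def test_empty(self):
        partials = combine_partial_trees([])
        assert len(partials) == 1 and partials[0].h == 0

    def test_slack_keeps_smaller_partials(self, wex_signal):
        fgs = find_first_generation_trees(wex_signal)
        partials = combine_partial_trees(fgs, slack=1)
        sizes = sorted(pt.h for pt in partials)
        assert sizes == [1, 1, 2]


class TestEnumerateSolutions:
    def test_wex_unique_tree(self, wex_signal):
        fgs = find_first_generation_trees(wex_signal)
        (partial,) = combine_partial_trees(fgs)
        trees = enumerate_solutions(wex_signal, partial)
        assert [t.parent for t in trees] == [WEX_PARENTS]

    def test_partial_tree_forces_star(self):
        sig = make_signal([1.0, 0.6, 0.4])
        partial = PartialTree(frozenset({FirstGenerationTree(0, frozenset({1, 2}))}))
        trees = enumerate_solutions(sig, partial)
        assert [t.parent for t in trees] == [(-1, 0, 0)]

    def test_empty_partial_rejects_new_unpopulatedness(self):
        # star would make x[0] = 0 at a non-frozen parent; only the chain remains
        sig = make_signal([1.0, 0.6, 0.4])
        trees = enumerate_solutions(sig, PartialTree(frozenset()))
        assert [t.parent for t in trees] == [(-1, 0, 1)]
        x = clone_frequencies(trees[0], sig)
        assert np.allclose(x, [0.4, 0.2, 0.4])

    def test_ancestor_constraint(self):
        sig = make_signal([1.0, 0.6, 0.4])
        trees = enumerate_solutions(
            sig,
            PartialTree(frozenset({FirstGenerationTree(0, frozenset({1, 2}))})),
            ConstraintSet(ancestor_pairs=frozenset({(1, 2)})),
        )
        assert trees == []  # the only tree is the star, which violates 1 -> 2

    def test_exclusive_constraint(self, wex_signal):
        fgs = find_first_generation_trees(wex_signal)
        (partial,) = combine_partial_trees(fgs)
        # in the unique WEX tree clone 1 is an ancestor of clone 4
        trees = enumerate_solutions(
            wex_signal, partial, ConstraintSet(exclusive_pairs=frozenset({(1, 4)}))
        )
        assert trees == []

    def test_unsatisfiable_ancestor_order(self):
        sig = make_signal([1.0, 0.6, 0.4])
        trees = enumerate_solutions(
            sig,
            PartialTree(frozenset()),
            ConstraintSet(ancestor_pairs=frozenset({(2, 1)})),
        )
        assert trees == []


class TestFitFrequencies:
    def test_wex_matches_back_substitution(self, wex_signal, wex_tree):
        x, residual = fit_frequencies_nnls(wex_signal, wex_tree, unpopulated={0, 2})
        assert np.allclose(x, WEX_X, atol=1e-9)
        assert residual < 1e-9

    def test_perturbed_entry(self, wex_tree):
        y = [1.00, 0.73, 0.40, 0.28, 0.25, 0.15]
        sig = make_signal(y, eps=[0] + [0.02] * 5)
        x, residual = fit_frequencies_nnls(sig, wex_tree, unpopulated={0, 2})
        assert np.all(x >= 0)
        assert x[0] == 0.0 and x[2] == 0.0
        assert residual <= 0.01 + 1e-9

    def test_degenerate_tie(self):
        sig = make_signal([1.0, 1.0], labels=("dummy", "a"))
        tree = CloneTree([-1, 0])
        x, _ = fit_frequencies_nnls(sig, tree, unpopulated={0})
        assert x[0] == 0.0 and np.all(x >= 0)
        assert x[1] == pytest.approx(1.0, abs=1e-6)

    def test_sum_preserved_under_noise(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            truth = random_tree(SimulationConfig(N=7, P=4), rng)
            noisy = np.clip(truth.y_clean + rng.uniform(-0.03, 0.03, 7), 0, 1)
            noisy[0] = 1.0
            order = np.argsort(-noisy, kind="stable")
            sig = make_signal(noisy[order], eps=[0.0] + [0.03] * 6)
            tree = CloneTree([-1] + [0] * 6)
            x, _ = fit_frequencies_nnls(sig, tree)
            assert x.sum() == pytest.approx(1.0, abs=1e-6)


class TestSolve:
    def test_wildtype_only(self):
        res = solve(make_signal([1.0]))
        assert len(res.optimal) == 1
        sol = res.optimal[0]
        assert sol.P == 1 and sol.depth == 0
        assert np.allclose(sol.x, [1.0])

    def test_wex_exact_unique(self, wex_signal):
        res = solve(wex_signal)
        assert len(res.optimal) == 1
        sol = res.optimal[0]
        assert sol.tree.parent == WEX_PARENTS
        assert sol.P == 4 and sol.depth == 3
        assert np.allclose(sol.x, WEX_X, atol=1e-12)
        # confirmed against the 120-tree oracle
        oracle_best = optimal_set(brute_force_solve(wex_signal))
        assert [s.tree.parent for s in oracle_best] == [WEX_PARENTS]

    def test_wex_bound_multiple_optima(self, wex_signal_bound):
        res = solve(wex_signal_bound, BOUND)
        assert len(res.optimal) > 1
        assert all(s.P == 4 for s in res.optimal)
        for s in res.optimal:
            assert np.all(s.x >= 0)
            assert s.x.sum() == pytest.approx(1.0, abs=1e-6)
            # exactly N - h* zeros at the frozen first-generation parents
            assert int(np.sum(s.x == 0.0)) >= res.signal.n - 4

    def test_exact_zero_count_matches_populated_count(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            truth = random_tree(SimulationConfig(N=7, P=4), rng)
            res = solve(truth.signal)
            for s in res.optimal:
                # exact model: zeros sit exactly at the N - P frozen parents
                assert int(np.sum(s.x == 0.0)) == truth.signal.n - s.P

    def test_solution_cap_truncates(self):
        # low, well-separated frequencies admit many feasible trees
        y = [1.0, 0.20, 0.18, 0.16, 0.14, 0.12, 0.10]
        res = solve(make_signal(y), max_solutions=3)
        assert res.truncated
        assert len(res.candidates) <= 3

    def test_rescore_hook(self, wex_signal_bound):
        res = solve(
            wex_signal_bound,
            BOUND,
            rescore=lambda s, sig: (round(s.fit_residual, 12), s.P),
        )
        residuals = [s.fit_residual for s in res.optimal]
        assert all(r == pytest.approx(residuals[0], abs=1e-9) for r in residuals)

    def test_count_populated_from_fit(self, wex_signal):
        res = solve(wex_signal, count_populated_from_fit=True)
        assert res.optimal[0].P == 4


class TestSolverOracleEquivalence:
    def test_equivalence_on_random_instances(self):
        rng = np.random.default_rng(100)
        for i in range(100):
            n = int(rng.integers(2, 8))
            if i % 2 == 0:
                sig = random_exact_signal(rng, n)
            else:
                p = int(rng.integers(1, n + 1))
                sig = random_tree(SimulationConfig(N=n, P=p), rng).signal
            res = solve(sig)
            oracle_best = optimal_set(brute_force_solve(sig))
            assert sorted(s.tree.parent for s in res.optimal) == sorted(
                s.tree.parent for s in oracle_best
            ), sig.y
            # identical (P, D) per tree
            oracle_by_tree = {s.tree.parent: (s.P, s.depth) for s in oracle_best}
            for s in res.optimal:
                assert oracle_by_tree[s.tree.parent] == (s.P, s.depth)

    def test_solver_subset_of_oracle_under_bound_model(self):
        rng = np.random.default_rng(200)
        for _ in range(25):
            n = int(rng.integers(2, 7))
            truth = random_tree(SimulationConfig(N=n, P=max(1, n // 2)), rng)
            noisy = np.clip(truth.y_clean + rng.uniform(-0.02, 0.02, n), 0, 1)
            noisy[0] = 1.0
            order = np.argsort(-noisy, kind="stable")
            sig = make_signal(noisy[order], eps=[0.0] + [0.02] * (n - 1))
            res = solve(sig, BOUND)
            oracle_trees = {s.tree.parent for s in brute_force_solve(sig, BOUND)}
            for s in res.optimal:
                assert s.tree.parent in oracle_trees

    def test_solution_count_never_exceeds_factorial_bound(self):
        import math

        rng = np.random.default_rng(300)
        for _ in range(50):
            n = int(rng.integers(2, 7))
            sig = random_exact_signal(rng, n)
            res = solve(sig)
            assert len(res.candidates) <= math.factorial(n - 1)


class TestConservation:
    def test_every_solution_well_formed(self):
        rng = np.random.default_rng(400)
        for _ in range(200):
            n = int(rng.integers(2, 8))
            p = int(rng.integers(max(1, n // 2), n + 1))
            truth = random_tree(SimulationConfig(N=n, P=p), rng)
            res = solve(truth.signal)
            for s in res.candidates:
                assert np.all(s.x >= 0)
                assert s.x.sum() == pytest.approx(1.0, abs=1e-6)
                assert np.allclose(s.aggregate(), truth.signal.y, atol=1e-9)


class TestJointSolve:
    def test_single_sample_matches_solve(self, wex_signal):
        jr = joint_solve([wex_signal])
        direct = solve(wex_signal)
        assert [s.tree.parent for s in jr.per_sample[0]] == [
            s.tree.parent for s in direct.optimal
        ]

    def test_two_samples_recover_global_tree(self):
        # ground truth over labels: a at the top, b/c and d/e on separate
        # branches below it; each sample sees a label subset whose
        # restricted frequencies force a unique per-sample optimum.
        s1 = make_signal([1.0, 0.9, 0.5, 0.2], labels=("dummy", "a", "b", "c"))
        s2 = make_signal([1.0, 0.9, 0.6, 0.3], labels=("dummy", "a", "d", "e"))
        jr = joint_solve([s1, s2])
        assert jr.global_parent is not None
        assert jr.global_parent["a"] is None
        assert jr.global_parent["b"] == "a"
        assert jr.global_parent["d"] == "a"

    def test_contradictory_chains_yield_empty(self):
        s1 = make_signal([1.0, 0.8, 0.5], labels=("dummy", "p", "q"))
        s2 = make_signal([1.0, 0.8, 0.5], labels=("dummy", "q", "p"))
        jr = joint_solve([s1, s2])
        assert jr.per_sample == [[], []]
        assert jr.global_parent is None
        assert jr.conflicts
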