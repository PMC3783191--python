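"""Five-step deconvolution of an aggregate signal into optimal clone trees.

1. detect all first-generation trees (unpopulated parent + complete child
   set certified by the frequency-sum criterion under the active error
   model);
2. combine them into partial trees (maximal mutually compatible
   collections);
3. keep the partial trees with the maximum number of first-generation
   trees (minimum populated count P = N - h);
4. grow every full evolutionary tree consistent with each retained
   partial tree, inserting clones in frequency order;
5. fit frequencies (back-substitution when exact, constrained NNLS under
   an error model) and rank by populated count, then tree depth.
"""

from __future__ import annotations

import bisect
import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import nnls

from .errormodel import EXACT, ErrorModelConfig
from .exceptions import CapExceededError, InputError, NumericalError
from .model import (
    ROOT,
    AggregateSignal,
    CloneTree,
    Solution,
    aggregate_from_solution,
    clone_frequencies,
    genotype_matrix,
)

logger = logging.getLogger(__name__)

#: Default hard cap on signal size; larger inputs should be clustered first.
DEFAULT_MAX_N = 25
#: Default cap on the number of enumerated full trees.
DEFAULT_MAX_SOLUTIONS = 10_000
#: Weight applied to the dummy row during NNLS; eps[0] = 0 makes the
#: total-frequency equation y[0] = sum(x) = 1 exact, so it is enforced
#: (numerically) as a hard constraint.
DUMMY_ROW_WEIGHT = 1e6


@dataclass(frozen=True)
class FirstGenerationTree:
    """An unpopulated parent clone with its complete set of direct
    descendants, certified by the frequency-sum criterion."""

    parent: int
    children: frozenset[int]

    def __post_init__(self):
        if not self.children:
            raise InputError("first-generation tree needs at least one child")
        if any(c <= self.parent for c in self.children):
            raise InputError("children must have higher index than the parent")

    def __repr__(self) -> str:
        return f"FG({self.parent};{{{','.join(map(str, sorted(self.children)))}}})"


@dataclass(frozen=True)
class PartialTree:
    """A mutually compatible collection of first-generation trees."""

    fg_trees: frozenset[FirstGenerationTree]

    @property
    def h(self) -> int:
        return len(self.fg_trees)

    def frozen_parents(self) -> dict[int, frozenset[int]]:
        return {t.parent: t.children for t in self.fg_trees}

    def child_parent(self) -> dict[int, int]:
        return {c: t.parent for t in self.fg_trees for c in t.children}

    def unpopulated(self) -> frozenset[int]:
        return frozenset(t.parent for t in self.fg_trees)


@dataclass(frozen=True)
class ConstraintSet:
    """User constraints applied during tree enumeration.

    ``ancestor_pairs``: (a, b) means clone a must be a strict ancestor of
    clone b.  ``exclusive_pairs``: (a, b) means neither may be an ancestor
    of the other (separate branches); stored unordered.
    """

    ancestor_pairs: frozenset[tuple[int, int]] = frozenset()
    exclusive_pairs: frozenset[tuple[int, int]] = frozenset()

    def __post_init__(self):
        excl = frozenset(tuple(sorted(p)) for p in self.exclusive_pairs)
        object.__setattr__(self, "exclusive_pairs", excl)
        for a, b in self.ancestor_pairs:
            if a == b:
                raise InputError(f"ancestor constraint ({a},{b}) is degenerate")
            if tuple(sorted((a, b))) in excl:
                raise InputError(
                    f"pair ({a},{b}) appears in both ancestor and exclusive sets"
                )

    def __bool__(self) -> bool:
        return bool(self.ancestor_pairs) or bool(self.exclusive_pairs)


NO_CONSTRAINTS = ConstraintSet()


# ---------------------------------------------------------------------------
# Step 1: first-generation tree detection
# ---------------------------------------------------------------------------

def _fg_children_exact_mim(y: np.ndarray, i: int, cands: list[int], atol: float):
    """Meet-in-the-middle subset-sum search for the exact model.

    Finds every non-empty subset S of ``cands`` with ``|y[i] - sum(y[S])|
    <= atol``.  Complete (no pruning heuristics), used when the candidate
    list is too long for depth-first search.
    """
    half = len(cands) // 2
    left, right = cands[:half], cands[half:]

    def subset_sums(items: list[int]):
        sums = [(0.0, frozenset())]
        for j in items:
            sums += [(s + y[j], mask | {j}) for s, mask in sums]
        return sums

    left_sums = subset_sums(left)
    right_sums = sorted(subset_sums(right), key=lambda t: t[0])
    right_keys = [s for s, _ in right_sums]
    target = y[i]
    out = []
    for s, mask in left_sums:
        lo = bisect.bisect_left(right_keys, target - s - atol)
        hi = bisect.bisect_right(right_keys, target - s + atol)
        for k in range(lo, hi):
            combined = mask | right_sums[k][1]
            if combined:
                out.append(combined)
    return out


def _fg_children_for_parent(
    signal: AggregateSignal, i: int, model: ErrorModelConfig
) -> list[frozenset[int]]:
    """All child sets S (subsets of {j > i}) satisfying the unpopulatedness
    criterion for parent ``i`` under ``model``."""
    y, eps = signal.y, signal.eps
    n = signal.n
    cands = sorted(range(i + 1, n), key=lambda j: (-y[j], j))
    if not cands:
        return []
    if model.kind == "exact" and len(cands) > 15:
        return _fg_children_exact_mim(y, i, cands, model.atol)

    # DFS over include/exclude decisions with two prunes: the partial sum
    # can no longer reach the target, or has overshot beyond the maximum
    # allowance attainable by any superset.
    suffix_y = np.zeros(len(cands) + 1)
    for k in range(len(cands) - 1, -1, -1):
        suffix_y[k] = suffix_y[k + 1] + y[cands[k]]
    eps_total = float(sum(eps[j] for j in cands))
    eps2_total = float(sum(eps[j] ** 2 for j in cands))
    max_allow = model.sum_allowance(eps[i], eps_total, eps2_total)
    target = y[i]
    results: list[frozenset[int]] = []
    chosen: list[int] = []

    def dfs(k: int, s_y: float, s_e: float, s_e2: float):
        if s_y - target > max_allow:
            return
        if s_y + suffix_y[k] < target - max_allow:
            return
        if k == len(cands):
            return
        j = cands[k]
        # include j
        chosen.append(j)
        ny, ne, ne2 = s_y + y[j], s_e + eps[j], s_e2 + eps[j] ** 2
        if abs(target - ny) <= model.sum_allowance(eps[i], ne, ne2):
            results.append(frozenset(chosen))
        dfs(k + 1, ny, ne, ne2)
        chosen.pop()
        # exclude j
        dfs(k + 1, s_y, s_e, s_e2)

    dfs(0, 0.0, 0.0, 0.0)
    return results


def find_first_generation_trees(
    signal: AggregateSignal,
    model: ErrorModelConfig = EXACT,
    max_n: int = DEFAULT_MAX_N,
) -> list[FirstGenerationTree]:
    """Every (parent, child set) pair satisfying the unpopulatedness
    criterion of the active error model, in deterministic order."""
    if signal.n > max_n:
        raise CapExceededError(
            f"signal has N={signal.n} aberrations, above the cap of {max_n}",
            hint="cluster aberrations with similar frequencies first "
            "(cluster_frequencies) or raise max_n",
        )
    out: list[FirstGenerationTree] = []
    for i in range(signal.n):
        for children in _fg_children_for_parent(signal, i, model):
            out.append(FirstGenerationTree(i, children))
    out.sort(key=lambda t: (t.parent, sorted(t.children)))
    for t in out:
        if len(t.children) == 1:
            logger.info(
                "single-child first-generation tree %s: two aberrations have "
                "indistinguishable frequencies; consider clustering them", t
            )
            break
    return out


# ---------------------------------------------------------------------------
# Step 2-3: partial-tree combination
# ---------------------------------------------------------------------------

def _compatible(a: FirstGenerationTree, b: FirstGenerationTree) -> bool:
    """Two first-generation trees can coexist in one full tree iff their
    parents differ and no clone is a child in both.  Edges always point
    from a lower to a higher index, so the union is automatically acyclic.
    """
    return a.parent != b.parent and not (a.children & b.children)


def _by_parent(fg_trees: Iterable[FirstGenerationTree]) -> list[list[FirstGenerationTree]]:
    grouped: dict[int, list[FirstGenerationTree]] = {}
    for t in dict.fromkeys(fg_trees):
        grouped.setdefault(t.parent, []).append(t)
    return [grouped[p] for p in sorted(grouped)]


def _max_selection_size(groups: list[list[FirstGenerationTree]]) -> int:
    """Branch-and-bound for h*: the largest number of first-generation
    trees (at most one per parent, pairwise disjoint child sets) that can
    coexist."""
    best = 0
    used: set[int] = set()

    def dfs(k: int, count: int):
        nonlocal best
        if count + (len(groups) - k) <= best:
            return
        if k == len(groups):
            best = max(best, count)
            return
        for t in groups[k]:
            if not (t.children & used):
                used.update(t.children)
                dfs(k + 1, count + 1)
                used.difference_update(t.children)
        dfs(k + 1, count)  # skip this parent

    dfs(0, 0)
    return best


def _collect_selections(
    groups: list[list[FirstGenerationTree]],
    lo: int,
    cap: int | None = None,
) -> tuple[list[PartialTree], bool]:
    """All selections (one tree per chosen parent, disjoint children) of
    size >= ``lo``; returns (partial trees, truncated?)."""
    out: list[PartialTree] = []
    used: set[int] = set()
    chosen: list[FirstGenerationTree] = []
    truncated = False

    def dfs(k: int):
        nonlocal truncated
        if truncated:
            return
        if len(chosen) + (len(groups) - k) < lo:
            return
        if k == len(groups):
            if cap is not None and len(out) >= cap:
                truncated = True
                return
            out.append(PartialTree(frozenset(chosen)))
            return
        for t in groups[k]:
            if not (t.children & used):
                used.update(t.children)
                chosen.append(t)
                dfs(k + 1)
                chosen.pop()
                used.difference_update(t.children)
        dfs(k + 1)

    dfs(0)
    return out, truncated


def combine_partial_trees(
    fg_trees: Iterable[FirstGenerationTree],
    slack: int = 0,
    cap: int | None = None,
) -> list[PartialTree]:
    """All partial trees of maximal size h* (plus, with ``slack`` s > 0,
    all of size >= h* - s).

    Compatibility is pairwise (distinct parents, disjoint child sets;
    acyclicity is automatic because edges always point from lower to
    higher index), so partial trees form an independence system searched
    by branch-and-bound over parents.
    """
    groups = _by_parent(fg_trees)
    if not groups:
        return [PartialTree(frozenset())]
    h_star = _max_selection_size(groups)
    lo = max(h_star - slack, 0)
    out, truncated = _collect_selections(groups, lo, cap)
    if truncated:
        logger.warning("partial-tree cap %s reached; combination truncated", cap)
    out.sort(key=lambda pt: (-pt.h, sorted((t.parent, sorted(t.children)) for t in pt.fg_trees)))
    return out if out else [PartialTree(frozenset())]


# ---------------------------------------------------------------------------
# Step 4: constrained enumeration of full trees
# ---------------------------------------------------------------------------

class _Budget:
    """Shared enumeration budget across partial trees."""

    def __init__(self, limit: int | None):
        self.limit = limit
        self.used = 0
        self.truncated = False

    def take(self) -> bool:
        if self.limit is not None and self.used >= self.limit:
            self.truncated = True
            return False
        self.used += 1
        return True


def enumerate_solutions(
    signal: AggregateSignal,
    partial: PartialTree,
    constraints: ConstraintSet = NO_CONSTRAINTS,
    model: ErrorModelConfig = EXACT,
    budget: _Budget | None = None,
) -> list[CloneTree]:
    """All full evolutionary trees consistent with one partial tree.

    Clones are inserted in index (frequency) order.  Children of a
    first-generation parent are frozen: the clone attaches to its
    designated parent and no extra children may attach there.  Any other
    clone may attach to any placed clone with an unfrozen child set,
    subject to feasibility (the parent's running frequency stays above
    the model's negative slack), the user constraints, and — under the
    exact model — the rule that an attachment may not drive a non-frozen
    parent's frequency to exactly zero (such a tree belongs to a larger
    partial tree and would be a duplicate or a sparser solution).
    """
    n = signal.n
    y, eps = signal.y, signal.eps
    frozen = partial.frozen_parents()
    child_parent = partial.child_parent()
    for p, kids in frozen.items():
        if p >= n or any(c >= n for c in kids):
            raise InputError("partial tree references clones outside the signal")

    anc_req: dict[int, list[int]] = {}
    for a, b in constraints.ancestor_pairs:
        if a >= b:
            return []  # descent ordering makes a >= b unsatisfiable
        anc_req.setdefault(b, []).append(a)
    excl_req: dict[int, list[int]] = {}
    for a, b in constraints.exclusive_pairs:
        excl_req.setdefault(max(a, b), []).append(min(a, b))

    parent_arr = [ROOT] + [-2] * (n - 1)
    x_cur = [float(v) for v in y]
    ch_eps_sum = [0.0] * n
    ch_eps2_sum = [0.0] * n
    results: list[CloneTree] = []
    exact = model.kind == "exact"

    def slack(p: int) -> float:
        return model.sum_allowance(eps[p], ch_eps_sum[p], ch_eps2_sum[p])

    def ancestors_of(j: int) -> set[int]:
        out = set()
        p = parent_arr[j]
        while p != ROOT:
            out.add(p)
            p = parent_arr[p]
        return out

    def place(j: int) -> bool:
        """Returns False when the enumeration budget ran out."""
        if j == n:
            if budget is not None and not budget.take():
                return False
            results.append(CloneTree(parent_arr))
            return True
        if j in child_parent:
            candidates: Sequence[int] = (child_parent[j],)
        else:
            candidates = [p for p in range(j) if p not in frozen]
        for p in candidates:
            new_x = x_cur[p] - y[j]
            is_frozen_parent = p in frozen
            if not is_frozen_parent:
                # feasibility against the model's negative slack
                allow = model.sum_allowance(
                    eps[p], ch_eps_sum[p] + eps[j], ch_eps2_sum[p] + eps[j] ** 2
                )
                if new_x < -allow:
                    continue
                if exact and abs(new_x) <= model.atol:
                    continue  # would create unpopulatedness outside the partial tree
            parent_arr[j] = p
            if j in anc_req or j in excl_req:
                anc = ancestors_of(j)
                if any(a not in anc for a in anc_req.get(j, ())):
                    parent_arr[j] = -2
                    continue
                if any(o in anc for o in excl_req.get(j, ())):
                    parent_arr[j] = -2
                    continue
            x_cur[p] = new_x
            ch_eps_sum[p] += eps[j]
            ch_eps2_sum[p] += eps[j] ** 2
            ok = place(j + 1)
            x_cur[p] += y[j]
            ch_eps_sum[p] -= eps[j]
            ch_eps2_sum[p] -= eps[j] ** 2
            parent_arr[j] = -2
            if not ok:
                return False
        return True

    if n == 1:
        if budget is None or budget.take():
            results.append(CloneTree(parent_arr))
    else:
        place(1)
    return results


# ---------------------------------------------------------------------------
# Step 5: frequency fitting and ranking
# ---------------------------------------------------------------------------

def fit_frequencies_nnls(
    signal: AggregateSignal,
    tree: CloneTree,
    unpopulated: Iterable[int] = (),
    dummy_weight: float = DUMMY_ROW_WEIGHT,
) -> tuple[np.ndarray, float]:
    """Minimize ``||y - C x||_2`` subject to ``x >= 0`` and ``x[k] = 0``
    for every unpopulated clone ``k``.

    The dummy row (which states ``sum(x) = y[0] = 1`` with zero
    measurement error) is up-weighted so the total frequency is conserved
    to numerical precision.  Returns ``(x, residual)`` where the residual
    is computed on the unweighted system.
    """
    unpop = set(unpopulated)
    C = genotype_matrix(tree).astype(float)
    y = signal.y.astype(float)
    free = [j for j in range(tree.n) if j not in unpop]
    if not free:
        raise InputError("all clones marked unpopulated; nothing to fit")
    A = C[:, free].copy()
    b = y.copy()
    A[0, :] *= dummy_weight
    b[0] *= dummy_weight
    try:
        x_free, _ = nnls(A, b)
    except Exception as exc:  # pragma: no cover - scipy failure path
        raise NumericalError(
            f"NNLS failed for tree {list(tree.parent)}: {exc}"
        ) from exc
    x = np.zeros(tree.n)
    x[free] = x_free
    residual = float(np.linalg.norm(y - C @ x))
    return x, residual


@dataclass
class SolveResult:
    """Outcome of :func:`solve`.

    ``optimal`` is the set of solutions with minimal populated count P and,
    among those, minimal depth D; ``candidates`` is every enumerated
    sparse solution (a superset of ``optimal``), sorted by (P, D, parent
    array).  ``h_star`` is the maximum partial-tree size and ``fg_count``
    the number of detected first-generation trees.
    """

    optimal: list[Solution]
    candidates: list[Solution]
    h_star: int
    fg_count: int
    truncated: bool
    signal: AggregateSignal
    model: ErrorModelConfig

    def __len__(self) -> int:
        return len(self.optimal)

    def __iter__(self):
        return iter(self.optimal)


def _solution_from_tree(
    signal: AggregateSignal,
    tree: CloneTree,
    partial: PartialTree,
    model: ErrorModelConfig,
    count_populated_from_fit: bool,
) -> Solution:
    if model.kind == "exact":
        x = clone_frequencies(tree, signal)
        x = np.where(np.abs(x) <= model.atol, 0.0, x)
        residual = float(np.linalg.norm(signal.y - genotype_matrix(tree) @ x))
    else:
        x, residual = fit_frequencies_nnls(signal, tree, partial.unpopulated())
    if count_populated_from_fit:
        kids = tree.children()
        populated = 0
        for j in range(tree.n):
            allow = model.allowance(signal.eps[j], [signal.eps[c] for c in kids[j]])
            if x[j] > allow:
                populated += 1
        p_count = populated
    else:
        p_count = tree.n - partial.h
    return Solution(
        tree=tree,
        x=x,
        P=p_count,
        depth=tree.depth(),
        fit_residual=residual,
        method=model.kind,
    )


def solve(
    signal: AggregateSignal,
    model: ErrorModelConfig = EXACT,
    constraints: ConstraintSet = NO_CONSTRAINTS,
    *,
    slack: int = 0,
    max_solutions: int = DEFAULT_MAX_SOLUTIONS,
    max_n: int = DEFAULT_MAX_N,
    count_populated_from_fit: bool = False,
    rescore: Callable[[Solution, AggregateSignal], tuple] | None = None,
) -> SolveResult:
    """Run the full five-step deconvolution and rank the solutions.

    ``slack`` relaxes the sparsity constraint: partial trees of size down
    to ``h* - slack`` are also expanded and reported among the candidates.
    If every partial tree at the requested sizes is infeasible (possible
    only under user constraints), progressively smaller partial trees are
    tried.  ``rescore`` replaces the default (P, D, residual) ranking.
    """
    fgs = find_first_generation_trees(signal, model, max_n=max_n)
    groups = _by_parent(fgs)
    h_star = _max_selection_size(groups) if groups else 0

    budget = _Budget(max_solutions)
    found: dict[tuple, tuple[CloneTree, PartialTree]] = {}
    lo = max(h_star - slack, 0)
    while lo >= 0:
        partials, pt_truncated = _collect_selections(groups, lo, cap=max_solutions) if groups else (
            [PartialTree(frozenset())], False
        )
        if pt_truncated:
            budget.truncated = True
        # largest partial trees first so duplicates keep their maximal origin
        partials.sort(key=lambda pt: -pt.h)
        for pt in partials:
            for tree in enumerate_solutions(signal, pt, constraints, model, budget):
                key = tree.parent
                prev = found.get(key)
                if prev is None or prev[1].h < pt.h:
                    found[key] = (tree, pt)
            if budget.truncated:
                break
        if found or budget.truncated or lo == 0:
            break
        lo -= 1  # constrained infeasibility fallback: relax sparsity further

    candidates = [
        _solution_from_tree(signal, tree, pt, model, count_populated_from_fit)
        for tree, pt in found.values()
    ]
    if not candidates:
        if not constraints:
            raise AssertionError(
                "no feasible tree found without constraints; a chain tree "
                "should always exist"
            )
        return SolveResult([], [], h_star, len(fgs), budget.truncated, signal, model)

    if rescore is not None:
        candidates.sort(key=lambda s: (rescore(s, signal), s.tree.parent))
        best = rescore(candidates[0], signal)
        optimal = [s for s in candidates if rescore(s, signal) == best]
    else:
        candidates.sort(key=lambda s: (s.P, s.depth, s.tree.parent))
        best_p = candidates[0].P
        best_d = min(s.depth for s in candidates if s.P == best_p)
        optimal = [s for s in candidates if s.P == best_p and s.depth == best_d]
    if budget.truncated:
        logger.warning(
            "solution cap of %d reached; result truncated", max_solutions
        )
    return SolveResult(
        optimal, candidates, h_star, len(fgs), budget.truncated, signal, model
    )


# ---------------------------------------------------------------------------
# Multi-sample joint solving
# ---------------------------------------------------------------------------

ANC, DESC, SEP = "anc", "desc", "sep"


def _relations(solution: Solution, signal: AggregateSignal) -> dict[tuple[str, str], str]:
    """Pairwise evolutionary relations over the sample's aberration labels.

    For each unordered label pair (a, b) with a < b lexicographically:
    ``anc`` if a's clone is an ancestor of b's, ``desc`` if the converse,
    ``sep`` if they sit on separate branches.
    """
    out: dict[tuple[str, str], str] = {}
    labels = signal.labels
    anc_sets = {j: solution.tree.ancestors(j) for j in range(1, signal.n)}
    for i in range(1, signal.n):
        for j in range(i + 1, signal.n):
            a, b = labels[i], labels[j]
            key = (a, b) if a < b else (b, a)
            if i in anc_sets[j]:
                rel = ANC if key == (a, b) else DESC
            elif j in anc_sets[i]:
                rel = DESC if key == (a, b) else ANC
            else:
                rel = SEP
            out[key] = rel
    return out


def _assemble_global_tree(
    merged: dict[tuple[str, str], str], labels: list[str]
) -> dict[str, str | None] | None:
    """Build a label-level tree honoring all merged pairwise relations;
    returns None when no consistent tree exists."""
    anc: dict[str, set[str]] = {l: set() for l in labels}
    for (a, b), rel in merged.items():
        if rel == ANC:
            anc[b].add(a)
        elif rel == DESC:
            anc[a].add(b)
    # transitive closure
    changed = True
    while changed:
        changed = False
        for l in labels:
            extra = set().union(*(anc[a] for a in anc[l])) - anc[l] if anc[l] else set()
            if extra:
                anc[l] |= extra
                changed = True
    for l in labels:
        if l in anc[l]:
            return None
    for (a, b), rel in merged.items():
        if rel == SEP and (a in anc[b] or b in anc[a]):
            return None
    parent: dict[str, str | None] = {}
    for l in labels:
        if not anc[l]:
            parent[l] = None
            continue
        deepest = max(sorted(anc[l]), key=lambda a: len(anc[a]))
        parent[l] = deepest
    # verify the built tree reproduces every known relation
    def is_anc(a: str, b: str) -> bool:
        p = parent[b]
        while p is not None:
            if p == a:
                return True
            p = parent[p]
        return False

    for (a, b), rel in merged.items():
        ok = {
            ANC: is_anc(a, b),
            DESC: is_anc(b, a),
            SEP: not is_anc(a, b) and not is_anc(b, a),
        }[rel]
        if not ok:
            return None
    return parent


@dataclass
class JointResult:
    """Outcome of :func:`joint_solve`: per-sample surviving solutions, the
    label-level global tree of the first compatible tuple, and a conflict
    report (pairs of samples with contradictory relations) when empty."""

    per_sample: list[list[Solution]]
    global_parent: dict[str, str | None] | None
    compatible_tuples: list[tuple[int, ...]]
    conflicts: list[str]


def joint_solve(
    signals: Sequence[AggregateSignal],
    model: ErrorModelConfig = EXACT,
    *,
    max_tuples: int = 100_000,
    **solve_options,
) -> JointResult:
    """Solve each sample, then keep only per-sample solutions that can
    coexist inside one global evolutionary tree over the label union."""
    results = [solve(s, model, **solve_options) for s in signals]
    per_sample_rel = [
        [(sol, _relations(sol, sig)) for sol in res.optimal]
        for sig, res in zip(signals, results)
    ]
    if len(signals) == 1:
        return JointResult(
            [list(results[0].optimal)],
            _assemble_global_tree(
                per_sample_rel[0][0][1], [l for l in signals[0].labels[1:]]
            )
            if results[0].optimal
            else None,
            [(i,) for i in range(len(results[0].optimal))],
            [],
        )

    label_union = sorted({l for s in signals for l in s.labels[1:]})
    sizes = [len(r) for r in per_sample_rel]
    total = 1
    for s in sizes:
        total *= max(s, 1)
    if total > max_tuples:
        raise CapExceededError(
            f"{total} solution tuples to screen, above the cap of {max_tuples}",
            hint="tighten the per-sample solve (constraints, clustering) first",
        )

    survivors: list[set[int]] = [set() for _ in signals]
    compatible: list[tuple[int, ...]] = []
    global_parent = None
    conflicts: list[str] = []
    for combo in itertools.product(*(range(len(r)) for r in per_sample_rel)):
        merged: dict[tuple[str, str], str] = {}
        ok = True
        for s_idx, sol_idx in enumerate(combo):
            rels = per_sample_rel[s_idx][sol_idx][1]
            for key, rel in rels.items():
                if key in merged and merged[key] != rel:
                    ok = False
                    conflicts.append(
                        f"samples disagree on pair {key}: {merged[key]} vs {rel}"
                    )
                    break
                merged[key] = rel
            if not ok:
                break
        if not ok:
            continue
        tree = _assemble_global_tree(merged, label_union)
        if tree is None:
            conflicts.append(f"tuple {combo}: relations admit no single tree")
            continue
        compatible.append(combo)
        if global_parent is None:
            global_parent = tree
        for s_idx, sol_idx in enumerate(combo):
            survivors[s_idx].add(sol_idx)

    per_sample = [
        [per_sample_rel[s][i][0] for i in sorted(idx)] for s, idx in enumerate(survivors)
    ]
    return JointResult(per_sample, global_parent, compatible, sorted(set(conflicts)))
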