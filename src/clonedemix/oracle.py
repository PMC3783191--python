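"""Brute-force enumeration of every ordered evolutionary tree.

Deliberately naive and structured differently from the solver (populated
counts come from thresholding the back-substituted frequencies, not from
first-generation bookkeeping) so that solver-vs-oracle equivalence tests
exercise two independent code paths.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterator

import numpy as np

from .errormodel import EXACT, ErrorModelConfig
from .exceptions import InputError
from .model import AggregateSignal, CloneTree, Solution, clone_frequencies

#: Hard cap: the number of trees is (N-1)!, so N=9 already yields 40320.
MAX_ORACLE_N = 9


def enumerate_all_trees(n: int, max_n: int = MAX_ORACLE_N) -> Iterator[CloneTree]:
    """Yield every parent array with ``parent[j] < j``; there are exactly
    ``(N-1)!`` of them."""
    if not 1 <= n <= max_n:
        raise InputError(f"oracle enumeration supports 1 <= N <= {max_n}, got {n}")
    if n == 1:
        yield CloneTree([-1])
        return
    for tail in itertools.product(*(range(j) for j in range(1, n))):
        yield CloneTree((-1,) + tail)


def tree_count(n: int) -> int:
    """Closed form for the number of ordered trees: (N-1)!."""
    return math.factorial(n - 1)


def brute_force_solve(
    signal: AggregateSignal, model: ErrorModelConfig = EXACT
) -> list[Solution]:
    """Evaluate every ordered tree against the signal.

    A tree is feasible when every back-substituted frequency stays above
    the model's negative slack for that clone; P counts the entries
    distinguishable from zero under the model.  All feasible trees are
    returned (unranked); callers re-rank to compare with the solver.
    """
    y, eps = signal.y, signal.eps
    out: list[Solution] = []
    for tree in enumerate_all_trees(signal.n):
        x = clone_frequencies(tree, signal)
        kids = tree.children()
        feasible = True
        populated = 0
        for j in range(tree.n):
            allow = model.allowance(eps[j], [eps[c] for c in kids[j]])
            if x[j] < -allow:
                feasible = False
                break
            if x[j] > allow:
                populated += 1
        if not feasible:
            continue
        x_clean = np.where(np.abs(x) <= model.atol, 0.0, x)
        out.append(
            Solution(
                tree=tree,
                x=x_clean,
                P=populated,
                depth=tree.depth(),
                fit_residual=0.0,
                method=f"oracle-{model.kind}",
            )
        )
    return out


def optimal_set(solutions: list[Solution]) -> list[Solution]:
    """Filter a brute-force result to minimal P, then minimal depth."""
    if not solutions:
        return []
    best_p = min(s.P for s in solutions)
    pool = [s for s in solutions if s.P == best_p]
    best_d = min(s.depth for s in pool)
    return sorted(
        (s for s in pool if s.depth == best_d), key=lambda s: s.tree.parent
    )
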