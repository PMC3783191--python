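"""Core domain types and exact-model tree arithmetic.

Conventions used throughout the package:

* Clones are indexed ``0..N-1``.  Clone ``i`` is *the subclone in which
  aberration ``i`` first occurs*; index 0 is the dummy aberration carried
  by every cell, so clone 0 is the wildtype and the root of every tree.
* Parent arrays satisfy the descent-ordering property ``parent[j] < j``
  for every ``j > 0`` (frequencies are sorted non-increasing, and a clone
  can only descend from a clone whose aberration is at least as frequent).
* Depth counts edges, so the wildtype-only tree has depth 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .exceptions import InputError

#: Sentinel parent value for the root clone.
ROOT = -1

#: Label automatically given to the dummy aberration (index 0).
DUMMY_LABEL = "dummy"

#: Absolute tolerance for exact-model float comparisons.
ATOL = 1e-12


class CloneTree:
    """An evolutionary tree over ``N`` clones, stored as a parent array.

    ``parent[0] == ROOT`` and ``0 <= parent[j] < j`` for ``j > 0``; the
    ordering constraint makes the tree acyclic by construction and single
    rooted at clone 0.
    """

    __slots__ = ("parent",)

    def __init__(self, parent: Iterable[int]):
        parent = tuple(int(p) for p in parent)
        if not parent:
            raise InputError("parent array must be non-empty")
        if parent[0] != ROOT:
            raise InputError(f"parent[0] must be {ROOT} (root), got {parent[0]}")
        for j, p in enumerate(parent[1:], start=1):
            if not 0 <= p < j:
                raise InputError(
                    f"parent[{j}]={p} violates descent ordering (need 0 <= p < {j})"
                )
        self.parent = parent

    @property
    def n(self) -> int:
        return len(self.parent)

    def children(self) -> list[list[int]]:
        """Child lists, indexed by clone."""
        kids: list[list[int]] = [[] for _ in range(self.n)]
        for j in range(1, self.n):
            kids[self.parent[j]].append(j)
        return kids

    def depths(self) -> list[int]:
        """Edge-count distance from the root for every clone."""
        d = [0] * self.n
        for j in range(1, self.n):
            d[j] = d[self.parent[j]] + 1
        return d

    def depth(self) -> int:
        """Maximum edge-count from the root to any clone (tree depth D)."""
        return max(self.depths())

    def root_path(self, j: int) -> list[int]:
        """Clones on the path root -> ``j``, inclusive of both ends."""
        path = [j]
        while self.parent[path[-1]] != ROOT:
            path.append(self.parent[path[-1]])
        path.reverse()
        return path

    def ancestors(self, j: int) -> set[int]:
        """Strict ancestors of clone ``j``."""
        out: set[int] = set()
        p = self.parent[j]
        while p != ROOT:
            out.add(p)
            p = self.parent[p]
        return out

    def is_ancestor(self, a: int, b: int) -> bool:
        """True iff ``a`` is a strict ancestor of ``b``."""
        return a in self.ancestors(b)

    def __eq__(self, other) -> bool:
        return isinstance(other, CloneTree) and self.parent == other.parent

    def __hash__(self) -> int:
        return hash(self.parent)

    def __repr__(self) -> str:
        return f"CloneTree({list(self.parent)})"


@dataclass(frozen=True, eq=False)
class AggregateSignal:
    """A validated, sorted aggregate frequency vector with per-entry errors.

    ``labels[0]`` is the dummy aberration (frequency exactly 1, error 0);
    ``y`` is non-increasing; ``provenance`` records original identifiers
    of merged/removed entries (keys ``"ubiquitous"``, ``"absent"``,
    ``"clusters"`` are used by the preprocessing pipeline).
    """

    labels: tuple[str, ...]
    y: np.ndarray
    eps: np.ndarray
    provenance: Mapping = field(default_factory=dict)

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float).copy()
        eps = np.asarray(self.eps, dtype=float).copy()
        labels = tuple(str(l) for l in self.labels)
        if not (len(labels) == y.shape[0] == eps.shape[0]):
            raise InputError("labels, y and eps must have equal length")
        if y.ndim != 1:
            raise InputError("y must be one-dimensional")
        if y[0] != 1.0:
            raise InputError(f"y[0] must be exactly 1 (dummy), got {y[0]}")
        if eps[0] != 0.0:
            raise InputError("eps[0] must be 0 (dummy is exact)")
        if np.any(y < 0) or np.any(y > 1):
            raise InputError("frequencies must lie in [0, 1]")
        if np.any(eps < 0):
            raise InputError("measurement errors must be nonnegative")
        if np.any(np.diff(y) > 0):
            raise InputError("y must be sorted non-increasing")
        if len(set(labels)) != len(labels):
            raise InputError("labels must be unique")
        y.setflags(write=False)
        eps.setflags(write=False)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "eps", eps)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise InputError(f"label {label!r} not present in signal") from None

    def equivalent(self, other: "AggregateSignal", atol: float = ATOL) -> bool:
        """Structural equality up to float tolerance (ignores provenance)."""
        return (
            self.labels == other.labels
            and np.allclose(self.y, other.y, atol=atol)
            and np.allclose(self.eps, other.eps, atol=atol)
        )


@dataclass(frozen=True)
class PopulatednessTest:
    """Outcome of the unpopulatedness criterion for one (parent, children) pair.

    ``r_mean = y[i] - sum(y[j] for j in children)``;
    ``r_var = eps[i]**2 + sum(eps[j]**2)``.
    """

    r_mean: float
    r_var: float
    alpha: float
    decision: str  # "populated" | "unpopulated"

    def __post_init__(self):
        if self.r_var < 0:
            raise InputError("r_var must be nonnegative")
        if self.decision not in ("populated", "unpopulated"):
            raise InputError(f"invalid decision {self.decision!r}")


def clone_frequencies(tree: CloneTree, signal: AggregateSignal | np.ndarray) -> np.ndarray:
    """Back-substitute subclone frequencies from the aggregate vector.

    ``x[i] = y[i] - sum(y[j] for children j of i)``.  The result may
    contain negative entries; feasibility is the caller's decision.
    """
    y = signal.y if isinstance(signal, AggregateSignal) else np.asarray(signal, float)
    if tree.n != y.shape[0]:
        raise InputError(f"tree has {tree.n} clones but signal has {y.shape[0]} entries")
    x = y.astype(float).copy()
    for j in range(1, tree.n):
        x[tree.parent[j]] -= y[j]
    return x


def genotype_matrix(tree: CloneTree) -> np.ndarray:
    """Binary N x N matrix with ``C[i, j] = 1`` iff clone ``i`` is an
    ancestor-or-self of clone ``j`` (aberration ``i`` present in clone ``j``).

    Row 0 (the dummy aberration) is all ones; under the sorted clone
    ordering the matrix is upper triangular with a unit diagonal.
    """
    n = tree.n
    C = np.zeros((n, n), dtype=np.int8)
    C[0, 0] = 1
    for j in range(1, n):
        C[:, j] = C[:, tree.parent[j]]
        C[j, j] = 1
    return C


def aggregate_from_solution(C: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Forward model: aggregate frequencies ``y = C @ x``."""
    C = np.asarray(C)
    x = np.asarray(x, dtype=float)
    if C.ndim != 2 or C.shape[1] != x.shape[0]:
        raise InputError(f"dimension mismatch: C is {C.shape}, x has length {x.shape[0]}")
    return C.astype(float) @ x


def tree_depth(tree: CloneTree) -> int:
    """Number of generations of the tree (edge count; root-only tree -> 0)."""
    return tree.depth()


@dataclass(eq=False)
class Solution:
    """A deconvolution solution: a tree plus fitted subclone frequencies.

    ``P`` counts populated subclones, ``depth`` is the tree depth ``D``,
    ``fit_residual`` is ``||y - C x||_2`` and ``method`` records the error
    model under which the solution was produced.
    """

    tree: CloneTree
    x: np.ndarray
    P: int
    depth: int
    fit_residual: float
    method: str = "exact"

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)

    @property
    def C(self) -> np.ndarray:
        return genotype_matrix(self.tree)

    def aggregate(self) -> np.ndarray:
        return aggregate_from_solution(self.C, self.x)

    def populated(self, tol: float = ATOL) -> list[int]:
        """Indices of clones with frequency distinguishable from zero."""
        return [j for j in range(self.tree.n) if self.x[j] > tol]

    def clone_labels(self, signal: AggregateSignal, j: int) -> frozenset[str]:
        """Aberration labels carried by clone ``j`` (dummy excluded)."""
        return frozenset(signal.labels[i] for i in self.tree.root_path(j) if i != 0)

    def composition(
        self, signal: AggregateSignal, tol: float = ATOL
    ) -> dict[frozenset[str], float]:
        """Map populated-clone genotypes (as label sets) to frequencies."""
        out: dict[frozenset[str], float] = {}
        for j in self.populated(tol):
            out[self.clone_labels(signal, j)] = out.get(
                self.clone_labels(signal, j), 0.0
            ) + float(self.x[j])
        return out

    def parent_labels(self, signal: AggregateSignal) -> dict[str, str | None]:
        """Tree topology as a label -> parent-label map (root -> None)."""
        out: dict[str, str | None] = {}
        for j in range(self.tree.n):
            p = self.tree.parent[j]
            out[signal.labels[j]] = None if p == ROOT else signal.labels[p]
        return out

    def __repr__(self) -> str:
        return (
            f"Solution(parents={list(self.tree.parent)}, P={self.P}, "
            f"D={self.depth}, residual={self.fit_residual:.3g})"
        )
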