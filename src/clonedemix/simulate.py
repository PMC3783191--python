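"""Synthetic-data generators and evaluation metrics.

Three validation protocols at configurable scale: random noisy trees
(uniform perturbation + bound error model), genotype-matrix mixtures with
Dirichlet weights, and mutation-sequence mixtures (driven through the
polyallelic pipeline by the tests).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errormodel import ErrorModelConfig
from .exceptions import InputError
from .model import (
    ROOT,
    AggregateSignal,
    CloneTree,
    DUMMY_LABEL,
    Solution,
    aggregate_from_solution,
    genotype_matrix,
)
from .preprocess import build_signal
from .solver import SolveResult, solve

logger = logging.getLogger(__name__)

_MAX_RESAMPLES = 1000


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the random-tree protocol: N aberrations, P populated
    subclones, uniform noise half-width E, repetition count and seed."""

    N: int
    P: int
    E: float = 0.0
    runs: int = 1
    seed: int | None = None

    def __post_init__(self):
        if not 1 <= self.P <= self.N:
            raise InputError(f"need 1 <= P <= N, got P={self.P}, N={self.N}")
        if self.E < 0:
            raise InputError("noise half-width E must be nonnegative")
        if self.runs < 1:
            raise InputError("runs must be >= 1")


@dataclass
class GroundTruth:
    """A planted instance: tree and frequencies in sorted-signal index
    space, the exact aggregate, and label-level views used for scoring."""

    tree: CloneTree
    x: np.ndarray
    y_clean: np.ndarray
    signal: AggregateSignal
    populated: int
    composition: dict[frozenset[str], float]
    parent_labels: dict[str, str | None]

    @property
    def P(self) -> int:
        return self.populated

    @property
    def depth(self) -> int:
        return self.tree.depth()


def _truth_views(
    tree: CloneTree, x: np.ndarray, labels: tuple[str, ...]
) -> tuple[dict[frozenset[str], float], dict[str, str | None]]:
    comp: dict[frozenset[str], float] = {}
    for j in range(tree.n):
        if x[j] > 0:
            key = frozenset(labels[i] for i in tree.root_path(j) if i != 0)
            comp[key] = comp.get(key, 0.0) + float(x[j])
    parents = {
        labels[j]: (None if tree.parent[j] == ROOT else labels[tree.parent[j]])
        for j in range(tree.n)
    }
    return comp, parents


def random_tree(config: SimulationConfig, rng: np.random.Generator) -> GroundTruth:
    """Sample a uniform random ordered tree with P populated subclones.

    Parents are uniform over lower indices; the populated set is all
    leaves plus uniformly chosen extras; populated frequencies come from
    a flat Dirichlet.  Trees with more leaves than P are resampled.  The
    aggregate is computed exactly and the signal re-sorted (stable, so
    the dummy stays first and ties keep ancestor before descendant).
    """
    n, p = config.N, config.P
    for _ in range(_MAX_RESAMPLES):
        parent = [ROOT] + [int(rng.integers(0, j)) for j in range(1, n)]
        tree = CloneTree(parent)
        kids = tree.children()
        leaves = [j for j in range(n) if not kids[j]]
        if len(leaves) <= p:
            break
    else:
        raise InputError(
            f"could not sample a tree with <= {p} leaves for N={n} "
            f"in {_MAX_RESAMPLES} attempts"
        )
    extras = [j for j in range(n) if kids[j]]
    rng.shuffle(extras)
    populated = sorted(leaves + extras[: p - len(leaves)])
    x = np.zeros(n)
    x[populated] = rng.dirichlet(np.ones(len(populated)))
    # clip float drift from the matrix product (entries near 1 can
    # overshoot by ~1e-16, which the signal validator rejects)
    y = np.clip(aggregate_from_solution(genotype_matrix(tree), x), 0.0, 1.0)

    labels = tuple([DUMMY_LABEL] + [f"m{j}" for j in range(1, n)])
    order = np.argsort(-y, kind="stable")
    pos = np.empty(n, dtype=int)
    pos[order] = np.arange(n)
    new_parent = [ROOT] * n
    for j in range(1, n):
        new_parent[pos[j]] = pos[tree.parent[j]]
    new_tree = CloneTree(new_parent)
    new_labels = tuple(labels[i] for i in order)
    y_sorted = y[order]
    y_sorted[0] = 1.0  # guard against float drift on the dummy row
    x_sorted = x[order]
    signal = AggregateSignal(new_labels, y_sorted, np.zeros(n))
    comp, parents = _truth_views(new_tree, x_sorted, new_labels)
    return GroundTruth(
        tree=new_tree,
        x=x_sorted,
        y_clean=y_sorted,
        signal=signal,
        populated=len(populated),
        composition=comp,
        parent_labels=parents,
    )


def perturb_signal(
    y: np.ndarray, E: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Add independent Uniform(-E, E) noise to every entry except the
    dummy, clip to [0, 1], and return the paired eps vector (all E)."""
    if E < 0:
        raise InputError("noise half-width E must be nonnegative")
    y = np.asarray(y, dtype=float)
    noisy = y.copy()
    if E > 0 and y.shape[0] > 1:
        noisy[1:] = np.clip(y[1:] + rng.uniform(-E, E, size=y.shape[0] - 1), 0.0, 1.0)
    eps = np.full(y.shape[0], float(E))
    eps[0] = 0.0
    return noisy, eps


def noisy_signal(
    truth: GroundTruth, E: float, rng: np.random.Generator
) -> AggregateSignal:
    """Perturb a ground truth's aggregate and rebuild a sorted signal.

    All entries are kept (no homogeneity removal) so the truth stays
    comparable; labels track the re-sorting.
    """
    noisy, eps = perturb_signal(truth.y_clean, E, rng)
    order = np.argsort(-noisy, kind="stable")
    order = np.concatenate(([0], order[order != 0]))  # dummy always first
    return AggregateSignal(
        tuple(truth.signal.labels[i] for i in order), noisy[order], eps[order]
    )


def mix_genotypes(
    genotypes: pd.DataFrame | np.ndarray,
    weights: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
    *,
    labels: Sequence[str] | None = None,
    include_wildtype: bool = True,
) -> tuple[AggregateSignal, list[frozenset[str]], np.ndarray]:
    """Mix binary subclone genotypes into an aggregate signal.

    ``genotypes``: rows = aberrations, columns = subclones (0/1).  When
    ``weights`` is omitted they are drawn from a flat Dirichlet over the
    subclones (plus a wildtype component when ``include_wildtype``).
    Returns the built signal, the true genotypes as label sets, and the
    subclone weights used.
    """
    if isinstance(genotypes, pd.DataFrame):
        labels = list(genotypes.index.astype(str))
        G = genotypes.to_numpy()
    else:
        G = np.asarray(genotypes)
        if labels is None:
            labels = [f"a{i+1}" for i in range(G.shape[0])]
        labels = list(labels)
    if G.ndim != 2:
        raise InputError("genotype matrix must be two-dimensional")
    n_ab, n_sub = G.shape
    if np.any((G != 0) & (G != 1)):
        raise InputError("genotype matrix entries must be 0/1")
    for j in range(n_sub):
        if not G[:, j].any():
            raise InputError(
                f"subclone column {j} carries no aberration; drop it or model "
                "the wildtype via include_wildtype"
            )
    if weights is None:
        if rng is None:
            raise InputError("an rng is required when weights are not given")
        k = n_sub + (1 if include_wildtype else 0)
        w_full = rng.dirichlet(np.ones(k))
        w = w_full[:n_sub]
    else:
        w = np.asarray(list(weights), dtype=float)
        if w.shape[0] != n_sub or np.any(w < 0):
            raise InputError("weights must be nonnegative, one per subclone")
        if w.sum() > 1 + 1e-9:
            raise InputError("weights must sum to at most 1")
    y = np.clip(G.astype(float) @ w, 0.0, 1.0)
    signal = build_signal([(labels[i], float(y[i]), 0.0) for i in range(n_ab)])
    true_sets = [
        frozenset(labels[i] for i in range(n_ab) if G[i, j]) for j in range(n_sub)
    ]
    return signal, true_sets, w


def _reduced(genotype: frozenset[str], signal: AggregateSignal) -> frozenset[str]:
    """Drop labels removed from deconvolution (ubiquitous/absent)."""
    removed = set(signal.provenance.get("ubiquitous", ())) | set(
        signal.provenance.get("absent", ())
    )
    return frozenset(genotype - removed)


def evaluate_run(
    truth: GroundTruth,
    result: SolveResult,
    all_candidates: Iterable[Solution] | None = None,
    tol: float = 1e-9,
) -> tuple[bool, bool, bool]:
    """Score one simulation run.

    Returns (truth_is_sparsest, truth_in_optimal, truth_unique):
    the truth has the minimum populated count among candidates; the
    truth's tree and frequencies (within ``tol``) are in the optimal set;
    the optimal set is exactly the truth.
    """
    if all_candidates is not None:
        pool = list(all_candidates)
        min_p = min(s.P for s in pool) if pool else truth.P
    else:
        min_p = min(s.P for s in result.candidates) if result.candidates else truth.P
    sparsest = truth.P <= min_p

    def matches(sol: Solution) -> bool:
        if sol.parent_labels(result.signal) != truth.parent_labels:
            return False
        sol_x = {result.signal.labels[j]: float(sol.x[j]) for j in range(sol.tree.n)}
        truth_x = {
            truth.signal.labels[j]: float(truth.x[j]) for j in range(truth.tree.n)
        }
        return all(abs(sol_x[l] - truth_x[l]) <= tol for l in truth_x)

    in_trap = any(matches(s) for s in result.optimal)
    unique = len(result.optimal) == 1 and in_trap
    return sparsest, in_trap, unique


def recovery_check(
    solutions: Iterable[Solution],
    signal: AggregateSignal,
    true_genotypes: Sequence[frozenset[str]],
    true_weights: Sequence[float],
    tol: float = 1e-9,
) -> bool:
    """True iff at least one solution contains every true subclone
    genotype with its mixing weight matched to within ``tol``."""
    targets = [
        (_reduced(g, signal), float(w)) for g, w in zip(true_genotypes, true_weights)
    ]
    for sol in solutions:
        comp = sol.composition(signal, tol=0.0)
        if all(g in comp and abs(comp[g] - w) <= tol for g, w in targets):
            return True
    return False


def cooccurrence_fraction(
    solution: Solution,
    signal: AggregateSignal,
    reference_genotypes: Sequence[Iterable[str]],
) -> float | None:
    """Of all unordered aberration pairs co-occurring in at least one
    populated clone of the solution, the fraction also co-occurring in at
    least one reference genotype.  Returns None (flagged) when the
    solution has no co-occurring pairs."""
    sol_pairs: set[frozenset[str]] = set()
    for genotype in solution.composition(signal).keys():
        for a, b in itertools.combinations(sorted(genotype), 2):
            sol_pairs.add(frozenset((a, b)))
    if not sol_pairs:
        logger.warning("solution has no co-occurring aberration pairs")
        return None
    if not reference_genotypes:
        logger.warning("empty reference genotype list; co-occurrence fraction is 0")
        return 0.0
    ref_pairs: set[frozenset[str]] = set()
    for genotype in reference_genotypes:
        for a, b in itertools.combinations(sorted(set(genotype)), 2):
            ref_pairs.add(frozenset((a, b)))
    return len(sol_pairs & ref_pairs) / len(sol_pairs)


def run_cell(
    N: int,
    P: int,
    E: float,
    runs: int,
    rng: np.random.Generator,
    *,
    use_oracle_candidates: bool = False,
) -> tuple[float, float, float]:
    """Percentages (sparsest, in-solution-set, unique) over ``runs``
    simulations of one (N, P, E) cell, using the bound error model with
    per-entry error E."""
    from .oracle import brute_force_solve  # local import; oracle is optional here

    model = ErrorModelConfig("bound") if E > 0 else ErrorModelConfig("exact")
    hits = np.zeros(3)
    for _ in range(runs):
        truth = random_tree(SimulationConfig(N=N, P=P, E=E), rng)
        signal = noisy_signal(truth, E, rng) if E > 0 else truth.signal
        result = solve(signal, model)
        cands = brute_force_solve(signal, model) if use_oracle_candidates else None
        scores = evaluate_run(truth, result, cands, tol=max(E * (N + 1), 1e-9))
        hits += np.array(scores, dtype=float)
    return tuple(100.0 * hits / runs)


def benchmark_grid(
    Ns: Sequence[int],
    Ps: Sequence[int],
    Es: Sequence[float],
    runs: int,
    seed: int,
    *,
    csv_path: str | None = None,
    heatmap_path: str | None = None,
) -> pd.DataFrame:
    """Full factorial benchmark over (N, P, E) cells.

    Each cell gets an independent, deterministic RNG stream derived from
    ``seed`` and the cell coordinates, so the grid is reproducible
    bit-for-bit regardless of iteration order.
    """
    total = sum(1 for N in Ns for P in Ps if P <= N for _ in Es) * runs
    if total > 1_000_000:
        logger.warning("benchmark grid requests %d solves; this may take long", total)
    rows = []
    for N in Ns:
        for P in Ps:
            if P > N:
                continue
            for e_idx, E in enumerate(Es):
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=seed, spawn_key=(N, P, e_idx))
                )
                pct = run_cell(N, P, E, runs, rng)
                rows.append(
                    {
                        "N": N,
                        "P": P,
                        "E": E,
                        "pct_sparsest": pct[0],
                        "pct_in_solutions": pct[1],
                        "pct_unique": pct[2],
                        "runs": runs,
                    }
                )
    table = pd.DataFrame(rows)
    if csv_path:
        table.to_csv(csv_path, index=False)
    if heatmap_path:
        _plot_heatmaps(table, heatmap_path)
    return table


def _plot_heatmaps(table: pd.DataFrame, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = ["pct_sparsest", "pct_in_solutions", "pct_unique"]
    es = sorted(table["E"].unique())
    fig, axes = plt.subplots(
        len(es), len(metrics), figsize=(4 * len(metrics), 3 * len(es)), squeeze=False
    )
    for r, E in enumerate(es):
        sub = table[table["E"] == E]
        for c, metric in enumerate(metrics):
            pivot = sub.pivot(index="N", columns="P", values=metric)
            ax = axes[r][c]
            im = ax.imshow(pivot.to_numpy(), vmin=0, vmax=100, cmap="viridis")
            ax.set_xticks(range(len(pivot.columns)), pivot.columns)
            ax.set_yticks(range(len(pivot.index)), pivot.index)
            ax.set_xlabel("P")
            ax.set_ylabel("N")
            ax.set_title(f"{metric} (E={E})")
            fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
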