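"""Reduction of polyallelic loci to families of binary problems.

A locus where several distinct derived alleles are observed (e.g. an
adenine mutated to guanine in some cells and to cytosine in others, or
mutated twice in succession) cannot be encoded as one binary aberration.
Each *phasing hypothesis* — an assignment of the derived alleles to
ordered mutation chains hanging off the reference — induces one binary
problem: one event per mutation step, with serial events constrained as
ancestors and events of different chains constrained to separate
branches.  Event frequencies follow conservation: an upstream event is
carried by every cell holding any downstream allele of its chain, so its
frequency is the sum of the downstream allele frequencies.

Hypotheses are enumerated exhaustively (all orderings of all chain
partitions), solved independently, and ranked together, so the caller
can inspect which phasing won.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errormodel import EXACT, ErrorModelConfig
from .exceptions import CapExceededError, InputError
from .model import AggregateSignal, Solution
from .preprocess import build_signal
from .solver import ConstraintSet, SolveResult, solve

#: Default cap on the number of combined hypotheses (3 biallelic sites -> 27).
DEFAULT_HYPOTHESIS_CAP = 729


@dataclass(frozen=True)
class MultiAllelicSite:
    """A locus with one or more derived alleles and their frequencies.

    ``derived`` holds ``(allele, frequency, eps)`` triples.
    ``known_chains`` optionally declares serial orders established from
    outside evidence, e.g. ``("G", "C")`` for ref->G->C; hypotheses not
    containing each declared chain as one of their blocks are pruned.
    """

    position: str
    ref_allele: str
    derived: tuple[tuple[str, float, float], ...]
    known_chains: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self):
        if not self.derived:
            raise InputError(f"site {self.position}: needs at least one derived allele")
        alleles = [a for a, _, _ in self.derived]
        if len(set(alleles)) != len(alleles):
            raise InputError(f"site {self.position}: duplicate derived alleles")
        total, slop = 0.0, 0.0
        for allele, freq, eps in self.derived:
            if not 0 <= freq <= 1:
                raise InputError(
                    f"site {self.position}: frequency {freq} for allele {allele} "
                    "outside [0, 1]"
                )
            if eps < 0:
                raise InputError(f"site {self.position}: negative eps for {allele}")
            total += freq
            slop += eps
        if total > 1 + slop + 1e-9:
            raise InputError(
                f"site {self.position}: derived allele frequencies sum to {total:.4g} > 1"
            )

    def freq_of(self, allele: str) -> tuple[float, float]:
        for a, f, e in self.derived:
            if a == allele:
                return f, e
        raise InputError(f"site {self.position}: unknown allele {allele!r}")


@dataclass(frozen=True)
class BinaryReduction:
    """One phasing hypothesis rendered as a binary problem fragment.

    ``events`` are (label, frequency, eps) records; constraints are kept
    as label pairs and translated to clone indices after the signal is
    built and sorted.
    """

    events: tuple[tuple[str, float, float], ...]
    ancestor_pairs: tuple[tuple[str, str], ...]
    exclusive_pairs: tuple[tuple[str, str], ...]
    hypothesis_label: str


def _chain_partitions(items: Sequence[str]):
    """Yield all partitions of ``items`` into ordered chains.

    Each partition is a tuple of tuples; blocks are chains read root-out.
    Counts: 1 item -> 1, 2 -> 3, 3 -> 13 hypotheses.
    """
    items = list(items)
    if not items:
        yield ()
        return
    head, rest = items[0], items[1:]
    for part in _chain_partitions(rest):
        # head as its own new chain
        yield part + ((head,),)
        # head inserted into an existing chain, at any position
        for b_idx, block in enumerate(part):
            for pos in range(len(block) + 1):
                new_block = block[:pos] + (head,) + block[pos:]
                yield part[:b_idx] + (new_block,) + part[b_idx + 1 :]


def event_label(position: str, ref: str, chain_prefix: Sequence[str]) -> str:
    """Mutation-event notation, e.g. ``170A>G`` and chained ``170A>G>C``."""
    return f"{position}{ref}>" + ">".join(chain_prefix)


def _site_hypotheses(site: MultiAllelicSite) -> list[BinaryReduction]:
    alleles = [a for a, _, _ in site.derived]
    out: list[BinaryReduction] = []
    seen: set[tuple] = set()
    for part in _chain_partitions(alleles):
        canon = tuple(sorted(part))
        if canon in seen:
            continue
        seen.add(canon)
        if any(kc not in part for kc in site.known_chains):
            continue
        events: list[tuple[str, float, float]] = []
        anc: list[tuple[str, str]] = []
        excl: list[tuple[str, str]] = []
        chain_event_labels: list[list[str]] = []
        for chain in canon:
            labels_here: list[str] = []
            for k in range(len(chain)):
                lbl = event_label(site.position, site.ref_allele, chain[: k + 1])
                freq = sum(site.freq_of(a)[0] for a in chain[k:])
                eps = math.sqrt(sum(site.freq_of(a)[1] ** 2 for a in chain[k:]))
                events.append((lbl, freq, eps))
                labels_here.append(lbl)
            for up, down in zip(labels_here, labels_here[1:]):
                anc.append((up, down))
            chain_event_labels.append(labels_here)
        for la, lb in itertools.combinations(range(len(chain_event_labels)), 2):
            for ea in chain_event_labels[la]:
                for eb in chain_event_labels[lb]:
                    excl.append((ea, eb))
        hyp = ",".join(
            f"{site.position}:{site.ref_allele}>" + ">".join(chain) for chain in canon
        )
        out.append(
            BinaryReduction(tuple(events), tuple(anc), tuple(excl), hyp)
        )
    return out


def expand_polyallelic(
    sites: Iterable[MultiAllelicSite], cap: int = DEFAULT_HYPOTHESIS_CAP
) -> list[BinaryReduction]:
    """Cartesian product of per-site phasing hypotheses."""
    per_site = [_site_hypotheses(s) for s in sites]
    total = 1
    for hyps in per_site:
        total *= len(hyps)
    if total > cap:
        raise CapExceededError(
            f"{total} combined phasing hypotheses, above the cap of {cap}",
            hint="declare known serial chains on the sites to prune hypotheses, "
            "or raise the cap",
        )
    out: list[BinaryReduction] = []
    for combo in itertools.product(*per_site):
        events = tuple(e for red in combo for e in red.events)
        anc = tuple(p for red in combo for p in red.ancestor_pairs)
        excl = tuple(p for red in combo for p in red.exclusive_pairs)
        label = ";".join(red.hypothesis_label for red in combo) or "binary-only"
        out.append(BinaryReduction(events, anc, excl, label))
    return out


def _translate_constraints(
    signal: AggregateSignal,
    ancestor_pairs: Iterable[tuple[str, str]],
    exclusive_pairs: Iterable[tuple[str, str]],
) -> ConstraintSet | None:
    """Map label constraints to clone indices; None marks the hypothesis
    infeasible outright (e.g. a required ancestor was dropped as absent)."""
    labels = set(signal.labels)
    absent = set(signal.provenance.get("absent", ()))
    ubiquitous = set(signal.provenance.get("ubiquitous", ()))
    anc_idx: set[tuple[int, int]] = set()
    for a, b in ancestor_pairs:
        if b in absent:
            continue  # vacuous: the descendant event does not occur
        if a in ubiquitous:
            continue  # vacuous: the ancestor event is in every cell
        if a in absent or b in ubiquitous:
            return None
        if a in labels and b in labels:
            anc_idx.add((signal.index_of(a), signal.index_of(b)))
    excl_idx: set[tuple[int, int]] = set()
    for a, b in exclusive_pairs:
        if a in absent or b in absent:
            continue
        if a in ubiquitous or b in ubiquitous:
            return None  # a ubiquitous event co-occurs with everything
        if a in labels and b in labels:
            excl_idx.add((signal.index_of(a), signal.index_of(b)))
    return ConstraintSet(frozenset(anc_idx), frozenset(excl_idx))


@dataclass
class NonbinaryResult:
    """Pooled outcome across phasing hypotheses, ranked by
    (P, D, residual)."""

    optimal: list[tuple[str, Solution]]
    per_hypothesis: dict[str, SolveResult | str] = field(default_factory=dict)
    signals: dict[str, AggregateSignal] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.optimal)


def solve_nonbinary(
    sites: Sequence[MultiAllelicSite],
    records: Iterable[tuple] = (),
    model: ErrorModelConfig = EXACT,
    cap: int = DEFAULT_HYPOTHESIS_CAP,
    **solve_options,
) -> NonbinaryResult:
    """Solve every phasing hypothesis merged with the ordinary binary
    aberrations and pool the outcomes.

    With no polyallelic sites this reduces to the plain binary pipeline.
    """
    records = list(records)
    reductions = expand_polyallelic(sites, cap=cap)
    per_hyp: dict[str, SolveResult | str] = {}
    signals: dict[str, AggregateSignal] = {}
    pool: list[tuple[str, Solution]] = []
    for red in reductions:
        recs = records + [tuple(e) for e in red.events]
        try:
            signal = build_signal(recs, model)
        except InputError as exc:
            per_hyp[red.hypothesis_label] = f"invalid: {exc}"
            continue
        constraints = _translate_constraints(
            signal, red.ancestor_pairs, red.exclusive_pairs
        )
        if constraints is None:
            per_hyp[red.hypothesis_label] = "infeasible: constraint on removed event"
            continue
        res = solve(signal, model, constraints, **solve_options)
        per_hyp[red.hypothesis_label] = res
        signals[red.hypothesis_label] = signal
        pool.extend((red.hypothesis_label, s) for s in res.optimal)

    if not pool:
        return NonbinaryResult([], per_hyp, signals)
    key = lambda hs: (hs[1].P, hs[1].depth, hs[1].fit_residual)
    pool.sort(key=lambda hs: key(hs) + (hs[0],))
    best = key(pool[0])
    optimal = [hs for hs in pool if key(hs) == best]
    return NonbinaryResult(optimal, per_hyp, signals)
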