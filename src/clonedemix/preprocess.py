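"""Turn raw per-aberration measurements into a valid :class:`AggregateSignal`.

Pipeline pieces: homogeneous-entry removal, dummy insertion, deterministic
sorting, single-linkage frequency clustering, and the two summary-statistic
recipes (median/MAD for pre-clustered frequency groups, binomial normal
approximation for read counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .errormodel import EXACT, ErrorModelConfig
from .exceptions import InputError
from .model import DUMMY_LABEL, AggregateSignal

#: Scale factor turning a median absolute deviation into a normal sigma.
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class ReadCount:
    """Read support for one aberration: ``m`` mutated out of ``n`` total."""

    n: int
    m: int
    label: str
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self):
        if self.n < 0 or self.m < 0 or self.m > self.n:
            raise InputError(f"invalid read counts n={self.n}, m={self.m} for {self.label!r}")


@dataclass(frozen=True)
class FrequencyCluster:
    """A group of aberrations merged because their frequencies are
    indistinguishable under the active error model."""

    members: tuple[str, ...]
    y: float
    eps: float

    def __post_init__(self):
        if not self.members:
            raise InputError("cluster must have at least one member")
        if not 0 <= self.y <= 1:
            raise InputError("cluster frequency must lie in [0, 1]")


def _as_record(rec) -> tuple[str, float, float]:
    """Normalize (label, y[, eps]) tuples; eps defaults to 0."""
    if len(rec) == 2:
        label, y = rec
        eps = 0.0
    else:
        label, y, eps = rec[:3]
    return str(label), float(y), float(eps)


def build_signal(
    records: Iterable[tuple], model: ErrorModelConfig = EXACT
) -> AggregateSignal:
    """Validate, filter, sort and dummy-prepend raw records.

    Entries indistinguishable from 0 under ``model`` are dropped and
    recorded under ``provenance["absent"]``; entries indistinguishable
    from 1 are removed from deconvolution and recorded under
    ``provenance["ubiquitous"]`` (they hold in every cell and need no
    de-mixing).  Remaining entries are sorted by descending frequency,
    ties broken by ascending label, and the dummy entry is prepended.
    """
    kept: list[tuple[str, float, float]] = []
    absent: list[str] = []
    ubiquitous: list[str] = []
    seen: set[str] = set()
    for rec in records:
        label, y, eps = _as_record(rec)
        if label == DUMMY_LABEL:
            raise InputError(f"label {DUMMY_LABEL!r} is reserved for the dummy entry")
        if label in seen:
            raise InputError(f"duplicate aberration label {label!r}")
        seen.add(label)
        if not 0.0 <= y <= 1.0:
            raise InputError(f"frequency {y} for {label!r} outside [0, 1]")
        if eps < 0:
            raise InputError(f"negative error {eps} for {label!r}")
        if model.is_zero(y, model.single_allowance(eps)):
            absent.append(label)
        elif model.is_zero(1.0 - y, model.single_allowance(eps)):
            ubiquitous.append(label)
        else:
            kept.append((label, y, eps))
    kept.sort(key=lambda r: (-r[1], r[0]))
    labels = (DUMMY_LABEL,) + tuple(r[0] for r in kept)
    y_vec = np.array([1.0] + [r[1] for r in kept])
    eps_vec = np.array([0.0] + [r[2] for r in kept])
    return AggregateSignal(
        labels, y_vec, eps_vec,
        provenance={"absent": tuple(absent), "ubiquitous": tuple(ubiquitous)},
    )


def cluster_stats_median_mad(values: Sequence[float]) -> tuple[float, float]:
    """Representative (frequency, error) of a cluster of frequencies:
    location = median, scale = 1.4826 x median absolute deviation."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise InputError("cannot summarize an empty cluster")
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med, MAD_SCALE * mad


def cluster_frequencies(
    signal: AggregateSignal, model: ErrorModelConfig
) -> tuple[AggregateSignal, list[FrequencyCluster]]:
    """Merge aberrations with indistinguishable frequencies.

    Single-linkage: the transitive closure of pairwise indistinguishability
    under ``model``.  Each multi-member cluster is replaced by one entry
    whose (y, eps) come from :func:`cluster_stats_median_mad`; the dummy
    entry is never clustered.
    """
    n = signal.n
    # Union-find over entries 1..n-1.
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(1, n):
        for j in range(i + 1, n):
            if model.indistinguishable(
                signal.y[i], signal.eps[i], signal.y[j], signal.eps[j]
            ):
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(1, n):
        groups.setdefault(find(i), []).append(i)

    records: list[tuple[str, float, float]] = []
    clusters: list[FrequencyCluster] = []
    cluster_map: dict[str, tuple[str, ...]] = {}
    for members in groups.values():
        labels = tuple(signal.labels[i] for i in members)
        if len(members) == 1:
            i = members[0]
            records.append((labels[0], float(signal.y[i]), float(signal.eps[i])))
            continue
        y_rep, eps_rep = cluster_stats_median_mad([signal.y[i] for i in members])
        merged_label = "+".join(sorted(labels))
        clusters.append(FrequencyCluster(labels, y_rep, eps_rep))
        cluster_map[merged_label] = labels
        records.append((merged_label, y_rep, eps_rep))

    out = build_signal(records, model)
    prov = dict(out.provenance)
    prov["clusters"] = cluster_map
    # carry over the original removal annotations
    prov["absent"] = tuple(signal.provenance.get("absent", ())) + prov.get("absent", ())
    prov["ubiquitous"] = tuple(signal.provenance.get("ubiquitous", ())) + prov.get(
        "ubiquitous", ()
    )
    out = AggregateSignal(out.labels, out.y, out.eps, provenance=prov)
    return out, clusters


def binomial_stats(rc: ReadCount) -> tuple[float, float]:
    """Frequency and error from read counts under the normal approximation
    of the binomial proportion: ``y = m/n``, ``eps = sqrt(y (1-y) / n)``."""
    if rc.n < 1:
        raise InputError(f"read count n must be >= 1 for {rc.label!r}")
    y = rc.m / rc.n
    eps = float(np.sqrt(y * (1.0 - y) / rc.n))
    return y, eps


def _parse_region(region: str) -> tuple[str, int | None, int | None]:
    """Parse ``chrom`` or ``chrom:start-end`` (1-based inclusive)."""
    if ":" not in region:
        if not region:
            raise InputError("empty region string")
        return region, None, None
    chrom, _, span = region.partition(":")
    try:
        start_s, _, end_s = span.partition("-")
        return chrom, int(start_s), int(end_s)
    except ValueError:
        raise InputError(f"malformed region {region!r}; expected chrom[:start-end]") from None


def filter_variants(
    records: Iterable[ReadCount],
    min_coverage: int = 0,
    region: str | None = None,
    presence_in: Callable[[ReadCount], bool] | None = None,
) -> list[ReadCount]:
    """Keep records with coverage strictly above ``min_coverage``, inside
    ``region`` (``chrom`` or ``chrom:start-end``) if given, and satisfying
    the optional presence rule.  Input order is preserved."""
    if region is not None:
        chrom, start, end = _parse_region(region)
    out: list[ReadCount] = []
    for rec in records:
        if rec.n <= min_coverage:
            continue
        if region is not None:
            if rec.chrom != chrom:
                continue
            if start is not None and (rec.pos is None or not start <= rec.pos <= end):
                continue
        if presence_in is not None and not presence_in(rec):
            continue
        out.append(rec)
    return out
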