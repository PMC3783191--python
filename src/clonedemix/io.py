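"""Readers and writers: frequency/genotype/constraint tables, VCF read
counts, and solution exports (JSON, DOT, Newick)."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import InputError
from .model import ROOT, AggregateSignal, CloneTree, Solution
from .nonbinary import MultiAllelicSite
from .preprocess import ReadCount, binomial_stats


@dataclass(frozen=True)
class FrequencyRecord:
    label: str
    y: float
    eps: float = 0.0
    sample: str | None = None

    def as_tuple(self) -> tuple[str, float, float]:
        return (self.label, self.y, self.eps)


def read_frequency_table(path: str | Path) -> list[FrequencyRecord]:
    """Read a TSV with header columns ``id``, ``freq`` and optional
    ``err`` / ``sample``; errors name the offending line."""
    path = Path(path)
    records: list[FrequencyRecord] = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise InputError(f"{path}: empty file, expected a header line")
        missing = {"id", "freq"} - set(reader.fieldnames)
        if missing:
            raise InputError(
                f"{path}: missing required column(s) {sorted(missing)}; "
                f"found {reader.fieldnames}"
            )
        for line_no, row in enumerate(reader, start=2):
            label = (row.get("id") or "").strip()
            if not label:
                raise InputError(f"{path}, line {line_no}: empty id")
            try:
                y = float(row["freq"])
            except (TypeError, ValueError):
                raise InputError(
                    f"{path}, line {line_no}: non-numeric freq {row.get('freq')!r}"
                ) from None
            if not 0.0 <= y <= 1.0:
                raise InputError(f"{path}, line {line_no}: freq {y} outside [0, 1]")
            err_raw = (row.get("err") or "").strip()
            try:
                eps = float(err_raw) if err_raw else 0.0
            except ValueError:
                raise InputError(
                    f"{path}, line {line_no}: non-numeric err {err_raw!r}"
                ) from None
            if eps < 0:
                raise InputError(f"{path}, line {line_no}: negative err {eps}")
            sample = (row.get("sample") or "").strip() or None
            records.append(FrequencyRecord(label, y, eps, sample))
    return records


def read_genotype_table(path: str | Path) -> tuple[list[str], np.ndarray, np.ndarray | None]:
    """Genotype TSV: first column = aberration id, remaining columns =
    subclones (0/1 entries).  An optional final row labelled ``weight``
    gives mixing weights.  Returns (labels, matrix, weights-or-None)."""
    path = Path(path)
    labels: list[str] = []
    rows: list[list[int]] = []
    weights: np.ndarray | None = None
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise InputError(f"{path}: empty genotype file")
        width = len(header) - 1
        for line_no, row in enumerate(reader, start=2):
            if not row or not row[0].strip():
                continue
            if len(row) - 1 != width:
                raise InputError(
                    f"{path}, line {line_no}: expected {width} genotype columns, "
                    f"got {len(row) - 1}"
                )
            if row[0].strip().lower() == "weight":
                weights = np.array([float(v) for v in row[1:]])
                continue
            try:
                vals = [int(v) for v in row[1:]]
            except ValueError:
                raise InputError(
                    f"{path}, line {line_no}: genotype entries must be 0/1"
                ) from None
            if any(v not in (0, 1) for v in vals):
                raise InputError(f"{path}, line {line_no}: genotype entries must be 0/1")
            labels.append(row[0].strip())
            rows.append(vals)
    if not rows:
        raise InputError(f"{path}: no genotype rows")
    return labels, np.array(rows, dtype=np.int8), weights


def read_constraints_table(path: str | Path) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Constraint TSV: rows ``type<TAB>a<TAB>b`` with type ``ancestor``
    (a must be an ancestor of b) or ``exclusive`` (separate branches)."""
    path = Path(path)
    anc: list[tuple[str, str]] = []
    excl: list[tuple[str, str]] = []
    with path.open(newline="", encoding="utf-8") as handle:
        for line_no, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or row[0].startswith("#") or not row[0].strip():
                continue
            if len(row) != 3:
                raise InputError(
                    f"{path}, line {line_no}: expected 'type\\ta\\tb', got {row}"
                )
            kind, a, b = (v.strip() for v in row)
            if kind == "ancestor":
                anc.append((a, b))
            elif kind == "exclusive":
                excl.append((a, b))
            else:
                raise InputError(
                    f"{path}, line {line_no}: unknown constraint type {kind!r}"
                )
    return anc, excl


def read_vcf_counts(
    path: str | Path, sample: str
) -> tuple[list[ReadCount], list[MultiAllelicSite], int]:
    """Extract per-variant read counts for one sample from a VCF.

    Biallelic SNV records become :class:`ReadCount`; multiallelic records
    become :class:`MultiAllelicSite` with binomial frequencies per allele.
    Records lacking depth information are skipped; the skip count is
    returned.  Labels are ``chrom:pos:ref>alt`` with 1-based positions.
    """
    from cyvcf2 import VCF  # deferred: heavy import

    vcf = VCF(str(path))
    if sample not in vcf.samples:
        raise InputError(
            f"sample {sample!r} not in VCF; available samples: {vcf.samples}"
        )
    s_idx = vcf.samples.index(sample)
    counts: list[ReadCount] = []
    sites: list[MultiAllelicSite] = []
    skipped = 0
    for variant in vcf:
        ad = variant.format("AD")
        depths = None
        alt_depths = None
        if ad is not None:
            row = ad[s_idx]
            if len(row) >= 2 and row[0] >= 0:
                depths = int(sum(v for v in row if v >= 0))
                alt_depths = [int(v) for v in row[1:]]
        else:
            ro, ao = variant.format("RO"), variant.format("AO")
            if ro is not None and ao is not None:
                ref_d = int(ro[s_idx][0])
                alt_depths = [int(v) for v in np.atleast_1d(ao[s_idx])]
                depths = ref_d + sum(alt_depths)
        if depths is None or alt_depths is None or depths <= 0:
            skipped += 1
            continue
        chrom, pos, ref = variant.CHROM, variant.POS, variant.REF
        if len(variant.ALT) == 1:
            alt = variant.ALT[0]
            counts.append(
                ReadCount(
                    n=depths,
                    m=alt_depths[0],
                    label=f"{chrom}:{pos}:{ref}>{alt}",
                    chrom=chrom,
                    pos=pos,
                )
            )
        else:
            derived = []
            for alt, m in zip(variant.ALT, alt_depths):
                y, eps = binomial_stats(ReadCount(n=depths, m=m, label=alt))
                derived.append((alt, y, eps))
            sites.append(
                MultiAllelicSite(
                    position=f"{chrom}:{pos}", ref_allele=ref, derived=tuple(derived)
                )
            )
    return counts, sites, skipped


# ---------------------------------------------------------------------------
# Solution export / import
# ---------------------------------------------------------------------------

def signal_to_dict(signal: AggregateSignal) -> dict:
    return {
        "labels": list(signal.labels),
        "y": [float(v) for v in signal.y],
        "eps": [float(v) for v in signal.eps],
        "provenance": _jsonable(signal.provenance),
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    return obj


def signal_from_dict(d: dict) -> AggregateSignal:
    return AggregateSignal(
        tuple(d["labels"]),
        np.array(d["y"], dtype=float),
        np.array(d["eps"], dtype=float),
        provenance=d.get("provenance", {}),
    )


def solution_to_dict(sol: Solution) -> dict:
    return {
        "parent": [None if p == ROOT else p for p in sol.tree.parent],
        "x": [float(v) for v in sol.x],
        "P": sol.P,
        "depth": sol.depth,
        "fit_residual": sol.fit_residual,
        "method": sol.method,
    }


def solution_from_dict(d: dict) -> Solution:
    parent = [ROOT if p is None else int(p) for p in d["parent"]]
    return Solution(
        tree=CloneTree(parent),
        x=np.array(d["x"], dtype=float),
        P=int(d["P"]),
        depth=int(d["depth"]),
        fit_residual=float(d["fit_residual"]),
        method=d.get("method", "exact"),
    )


def newick(solution: Solution, signal: AggregateSignal | None = None) -> str:
    """Newick string for one solution.

    Dialect: every node (internal ones included) is named ``C<k>`` with
    ``k`` the 1-based clone index; a bracketed comment carries the
    aberration label and fitted frequency, e.g.
    ``((C3[&label=a3,x=0.4])C2[&label=a2,x=0.2])C1[&label=dummy,x=0.4];``.
    Stripping comments leaves the bare topology.
    """
    kids = solution.tree.children()

    def render(j: int) -> str:
        name = f"C{j + 1}"
        if signal is not None:
            name += f"[&label={signal.labels[j]},x={solution.x[j]:.6g}]"
        else:
            name += f"[&x={solution.x[j]:.6g}]"
        if kids[j]:
            return "(" + ",".join(render(c) for c in kids[j]) + ")" + name
        return name

    return render(0) + ";"


def dot(solutions: Sequence[Solution], signal: AggregateSignal) -> str:
    """GraphViz DOT rendering, one digraph per solution; nodes show the
    newly acquired aberration and the fitted frequency, unpopulated
    clones drawn dashed (hollow)."""
    chunks = []
    for s_idx, sol in enumerate(solutions):
        lines = [f"digraph solution{s_idx} {{", "  node [shape=box];"]
        for j in range(sol.tree.n):
            label = signal.labels[j]
            style = ' style="dashed"' if sol.x[j] <= 0 else ' style="solid"'
            lines.append(
                f'  n{j} [label="{label}\\nx={sol.x[j]:.4g}"{style}];'
            )
        for j in range(1, sol.tree.n):
            lines.append(f"  n{sol.tree.parent[j]} -> n{j};")
        lines.append("}")
        chunks.append("\n".join(lines))
    return "\n".join(chunks) + "\n"


def write_solutions(
    solutions: Sequence[Solution],
    signal: AggregateSignal,
    prefix: str | Path,
    formats: Iterable[str] = ("json", "dot", "newick"),
    meta: dict | None = None,
) -> list[Path]:
    """Write the requested export formats next to ``prefix``; returns the
    written paths."""
    if not solutions:
        raise InputError("no solutions to write")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    formats = set(formats)
    if "json" in formats:
        payload = {
            "signal": signal_to_dict(signal),
            "solutions": [solution_to_dict(s) for s in solutions],
        }
        if meta:
            payload["meta"] = _jsonable(meta)
        p = prefix.with_suffix(".json")
        p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(p)
    if "dot" in formats:
        p = prefix.with_suffix(".dot")
        p.write_text(dot(solutions, signal))
        written.append(p)
    if "newick" in formats:
        p = prefix.with_suffix(".nwk")
        p.write_text("\n".join(newick(s, signal) for s in solutions) + "\n")
        written.append(p)
    return written


def read_solutions(path: str | Path) -> tuple[AggregateSignal, list[Solution]]:
    """Round-trip loader for the JSON export."""
    payload = json.loads(Path(path).read_text())
    signal = signal_from_dict(payload["signal"])
    return signal, [solution_from_dict(d) for d in payload["solutions"]]
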