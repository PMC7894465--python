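"""Readers and writers for every external artifact of the pipeline.

Dialects
--------
probe table (TSV)
    Header ``probeset_id  pair_index  pm:<s1>  mm:<s1>  pm:<s2> ...``;
    one row per probe pair; intensities are positive reals.  Sample order
    is the column order.
design file
    ``key = value`` lines; keys of the form ``role:<name>`` bind one of
    the four screen roles to a group label, any other key assigns a
    sample to a group.  Blank lines and ``#`` comments are ignored.
gene map (TSV)
    ``probeset_id <TAB> symbol``; probe sets may be absent (unannotated).
gene list
    One symbol per line; blank lines and ``#`` comments ignored.
screen result
    One sorted ID-per-line text file per stage set plus ``summary.json``
    with all stage cardinalities and the final gene list, and a
    ``stage_counts.tsv`` table.  Output is deterministic, so repeated
    writes are byte-identical.

Gene symbols are matched case-sensitively after trimming whitespace
(mouse symbol capitalization is meaningful).  Floats are written in
shortest round-trip form, so write -> read -> write is byte-stable.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Dict, List, Union

import numpy as np
import pandas as pd

from .containers import (
    ROLES,
    AnnotationSet,
    CallMatrix,
    ExpressionMatrix,
    GeneMap,
    GroupDesign,
    ProbeLevelDataset,
)
from .screen import ABSENT_ROLES, PRESENT_ROLES, UP_PAIRS, ScreenResult

__all__ = [
    "FormatError",
    "read_probe_table",
    "write_probe_table",
    "read_design",
    "write_design",
    "read_gene_map",
    "write_gene_map",
    "read_gene_list",
    "write_gene_list",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_call_matrix",
    "write_call_matrix",
    "write_screen_result",
]

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A file violates its documented dialect."""


def read_probe_table(path: PathLike) -> ProbeLevelDataset:
    """Read a probe-level PM/MM table (dialect above)."""
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", dtype={"probeset_id": str}, float_precision="round_trip"
    )
    cols = list(df.columns)
    if cols[:2] != ["probeset_id", "pair_index"]:
        raise FormatError(
            f"{path}: first columns must be probeset_id, pair_index, got {cols[:2]}"
        )
    pm_samples = [c[3:] for c in cols[2:] if c.startswith("pm:")]
    mm_samples = [c[3:] for c in cols[2:] if c.startswith("mm:")]
    other = [c for c in cols[2:] if not (c.startswith("pm:") or c.startswith("mm:"))]
    if other:
        raise FormatError(f"{path}: unrecognized columns {other}")
    if set(pm_samples) != set(mm_samples):
        raise FormatError(
            f"{path}: pm/mm sample sets differ: "
            f"{sorted(set(pm_samples) ^ set(mm_samples))}"
        )
    samples = pm_samples  # column order of the pm: columns
    keys = list(zip(df["probeset_id"], df["pair_index"]))
    if len(set(keys)) != len(keys):
        seen = set()
        for i, k in enumerate(keys):
            if k in seen:
                raise FormatError(
                    f"{path}: duplicate probe pair {k} at data row {i + 1}"
                )
            seen.add(k)
    pm = np.empty((len(df), len(samples)))
    mm = np.empty((len(df), len(samples)))
    for j, s in enumerate(samples):
        for kind, out in (("pm", pm), ("mm", mm)):
            col = df[f"{kind}:{s}"]
            vals = pd.to_numeric(col, errors="coerce").to_numpy(dtype=np.float64)
            bad = ~np.isfinite(vals) | (vals <= 0)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"{path}: non-positive or non-numeric intensity "
                    f"{col.iloc[i]!r} at data row {i + 1}, column {kind}:{s}"
                )
            out[:, j] = vals
    try:
        return ProbeLevelDataset(
            samples=samples,
            probeset_ids=df["probeset_id"].to_numpy(dtype=object),
            pair_index=df["pair_index"].to_numpy(),
            pm=pm,
            mm=mm,
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips to the same float."""
    return repr(float(x))


def write_probe_table(dataset: ProbeLevelDataset, path: PathLike) -> None:
    """Write a probe-level dataset in the probe-table dialect."""
    path = Path(path)
    header = ["probeset_id", "pair_index"]
    for s in dataset.samples:
        header += [f"pm:{s}", f"mm:{s}"]
    lines = ["\t".join(header)]
    for i in range(dataset.n_records):
        row = [str(dataset.probeset_ids[i]), str(int(dataset.pair_index[i]))]
        for j in range(dataset.n_samples):
            row.append(_fmt(dataset.pm[i, j]))
            row.append(_fmt(dataset.mm[i, j]))
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def _parse_kv_lines(path: Path) -> List[tuple]:
    pairs = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        pairs.append((lineno, key.strip(), value.strip()))
    return pairs


def read_design(path: PathLike) -> GroupDesign:
    """Read a design file (``role:<name> = group`` and ``sample = group``)."""
    path = Path(path)
    roles: Dict[str, str] = {}
    assignments: Dict[str, str] = {}
    for lineno, key, value in _parse_kv_lines(path):
        if not key or not value:
            raise FormatError(f"{path}:{lineno}: empty key or value")
        if key.startswith("role:"):
            role = key[5:]
            if role not in ROLES:
                raise FormatError(
                    f"{path}:{lineno}: unknown role {role!r}; expected one of {ROLES}"
                )
            if role in roles:
                raise FormatError(f"{path}:{lineno}: role {role!r} defined twice")
            roles[role] = value
        else:
            if key in assignments:
                raise FormatError(f"{path}:{lineno}: sample {key!r} assigned twice")
            assignments[key] = value
    try:
        return GroupDesign(assignments=assignments, roles=roles)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_design(design: GroupDesign, path: PathLike) -> None:
    path = Path(path)
    lines = [f"role:{role} = {design.roles[role]}" for role in ROLES]
    lines += [f"{s} = {g}" for s, g in design.assignments.items()]
    path.write_text("\n".join(lines) + "\n")


def read_gene_map(path: PathLike) -> GeneMap:
    """Read a probe-set -> gene-symbol TSV (no header)."""
    path = Path(path)
    entries: Dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected 'probeset<TAB>symbol'")
        ps, sym = parts[0].strip(), parts[1].strip()
        if ps in entries:
            raise FormatError(f"{path}:{lineno}: probe set {ps!r} mapped twice")
        if sym:  # empty symbol = unannotated, simply omitted
            entries[ps] = sym
    return GeneMap(entries=entries)


def write_gene_map(gene_map: GeneMap, path: PathLike) -> None:
    path = Path(path)
    lines = [f"{ps}\t{sym}" for ps, sym in sorted(gene_map.entries.items())]
    path.write_text("\n".join(lines) + "\n" if lines else "")


def read_gene_list(path: PathLike, class_id: str = "unspecified") -> AnnotationSet:
    """Read a one-symbol-per-line gene list into an annotation set.

    Symbols are trimmed and matched case-sensitively.  An empty resulting
    set triggers a warning (a screen using it will return no genes) but
    is not an error.
    """
    path = Path(path)
    genes = set()
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        genes.add(line)
    if not genes:
        warnings.warn(
            f"{path}: gene list is empty; the screen will output no genes",
            stacklevel=2,
        )
    return AnnotationSet(class_id=class_id, genes=frozenset(genes))


def write_gene_list(annotation: AnnotationSet, path: PathLike) -> None:
    path = Path(path)
    lines = sorted(annotation.genes)
    path.write_text("\n".join(lines) + "\n" if lines else "")


def write_expression_matrix(expr: ExpressionMatrix, path: PathLike) -> None:
    _write_matrix(expr.values, path)


def read_expression_matrix(path: PathLike) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return ExpressionMatrix(values=df)


def write_call_matrix(calls: CallMatrix, path: PathLike, pvalue_path: PathLike = None) -> None:
    """Write calls as single characters; optionally p-values alongside."""
    _write_matrix(calls.calls, path)
    if pvalue_path is not None:
        _write_matrix(calls.pvalues, pvalue_path)


def read_call_matrix(path: PathLike, pvalue_path: PathLike) -> CallMatrix:
    calls = pd.read_csv(path, sep="\t", index_col=0)
    pvals = pd.read_csv(
        pvalue_path, sep="\t", index_col=0, float_precision="round_trip"
    )
    return CallMatrix(calls=calls, pvalues=pvals)


def _write_matrix(df: pd.DataFrame, path: PathLike) -> None:
    path = Path(path)
    lines = ["\t".join(["probeset_id"] + [str(c) for c in df.columns])]
    values = df.to_numpy()
    is_float = values.dtype.kind == "f"
    for i, idx in enumerate(df.index):
        cells = [
            _fmt(v) if is_float else str(v) for v in values[i]
        ]
        lines.append("\t".join([str(idx)] + cells))
    path.write_text("\n".join(lines) + "\n")


def _write_id_file(ids, path: Path) -> None:
    ids = sorted(ids)
    path.write_text("\n".join(ids) + "\n" if ids else "")


def write_screen_result(result: ScreenResult, out_dir: PathLike) -> None:
    """Write per-stage ID lists, ``summary.json`` and ``stage_counts.tsv``.

    All outputs are lexicographically sorted, so writing the same result
    twice is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for higher, lower in UP_PAIRS:
        _write_id_file(
            result.up_sets[(higher, lower)], out / f"up_{higher}_gt_{lower}.txt"
        )
    _write_id_file(result.fold_intersection, out / "fold_intersection.txt")
    for role in PRESENT_ROLES:
        _write_id_file(result.present_sets[role], out / f"present_{role}.txt")
    for role in ABSENT_ROLES:
        _write_id_file(result.absent_sets[role], out / f"absent_{role}.txt")
    _write_id_file(result.call_intersection, out / "call_intersection.txt")
    _write_id_file(result.combined, out / "combined.txt")
    (out / "tf_genes.txt").write_text(
        "\n".join(result.tf_genes) + "\n" if result.tf_genes else ""
    )
    counts = result.cardinalities()
    summary = {
        "stage_counts": counts,
        "tf_genes": list(result.tf_genes),
        "n_unannotated_dropped": result.n_unannotated_dropped,
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    table = ["stage\tcount"] + [f"{k}\t{v}" for k, v in counts.items()]
    (out / "stage_counts.tsv").write_text("\n".join(table) + "\n")
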