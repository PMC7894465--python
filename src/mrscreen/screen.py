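"""Four-way comparative screen for candidate master regulators.

Candidates must satisfy two independent probe-set-level filters and one
gene-level filter:

* fold change: up-regulated (group-mean log2 difference above a
  threshold, default 2, i.e. four-fold) in target and target-stem
  relative to both source and source-origin — four up-sets, intersected;
* detection: reliably Present in target and target-stem and Absent in
  source and source-origin, aggregated across biological replicates —
  four call sets, intersected;
* annotation: the surviving probe sets are collapsed to gene symbols (a
  gene passes if any of its probe sets passes) and intersected with a
  transcription-factor class list.

Unannotated probe sets are only dropped at the collapse stage, so the
probe-set-level stage counts remain comparable across annotation
versions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Tuple

import pandas as pd

from .containers import (
    AnnotationSet,
    CallMatrix,
    ExpressionMatrix,
    GeneMap,
    GroupDesign,
)

__all__ = [
    "ScreenConfig",
    "ScreenResult",
    "UP_PAIRS",
    "group_mean",
    "up_set",
    "aggregate_calls",
    "run_screen",
]

#: The four (higher, lower) role comparisons of the fold-change stage.
UP_PAIRS: Tuple[Tuple[str, str], ...] = (
    ("target", "source_origin"),
    ("target_stem", "source_origin"),
    ("target", "source"),
    ("target_stem", "source"),
)

PRESENT_ROLES = ("target", "target_stem")
ABSENT_ROLES = ("source", "source_origin")


@dataclass
class ScreenConfig:
    """Tunable knobs of the screen.

    ``fold_threshold`` is the log2 group-mean difference cutoff (2.0 =
    four-fold).  ``strict_inequality`` selects '>' (default) versus '>='
    at the threshold.  ``call_aggregation`` is 'all' (every replicate must
    carry the wanted call) or 'majority' (more than half must).  The
    ``include_marginal_*`` flags let Marginal count as Present or Absent
    during aggregation.
    """

    fold_threshold: float = 2.0
    call_aggregation: str = "all"
    include_marginal_as_present: bool = False
    include_marginal_as_absent: bool = False
    strict_inequality: bool = True

    def __post_init__(self) -> None:
        if not self.fold_threshold > 0:
            raise ValueError("fold_threshold must be > 0")
        if self.call_aggregation not in ("all", "majority"):
            raise ValueError("call_aggregation must be 'all' or 'majority'")


@dataclass
class ScreenResult:
    """Per-stage probe-set sets and the final TF-filtered gene list."""

    up_sets: Dict[Tuple[str, str], FrozenSet[str]]
    fold_intersection: FrozenSet[str]
    present_sets: Dict[str, FrozenSet[str]]
    absent_sets: Dict[str, FrozenSet[str]]
    call_intersection: FrozenSet[str]
    combined: FrozenSet[str]
    tf_genes: List[str]
    n_unannotated_dropped: int = 0

    def cardinalities(self) -> Dict[str, int]:
        """Stage name -> set size, in the pipeline's stage order."""
        out: Dict[str, int] = {}
        for higher, lower in UP_PAIRS:
            out[f"up_{higher}_gt_{lower}"] = len(self.up_sets[(higher, lower)])
        out["fold_intersection"] = len(self.fold_intersection)
        for role in PRESENT_ROLES:
            out[f"present_{role}"] = len(self.present_sets[role])
        for role in ABSENT_ROLES:
            out[f"absent_{role}"] = len(self.absent_sets[role])
        out["call_intersection"] = len(self.call_intersection)
        out["combined"] = len(self.combined)
        out["tf_genes"] = len(self.tf_genes)
        return out


def group_mean(
    expr: ExpressionMatrix, design: GroupDesign, group: str
) -> pd.Series:
    """Per-probe-set arithmetic mean of log2 expression over a group."""
    samples = design.samples_in_group(group)
    if not samples:
        raise ValueError(f"unknown or empty group {group!r}")
    missing = sorted(set(samples) - set(expr.samples))
    if missing:
        raise ValueError(f"group {group!r} samples not in matrix: {missing}")
    return expr.values[samples].mean(axis=1)


def up_set(
    expr: ExpressionMatrix,
    design: GroupDesign,
    higher: str,
    lower: str,
    threshold: float,
    *,
    strict: bool = True,
) -> FrozenSet[str]:
    """Probe sets whose mean log2 expression in ``higher`` exceeds
    ``lower`` by more than ``threshold`` (or at least, if ``strict`` is
    False).  ``higher``/``lower`` are role names."""
    diff = group_mean(expr, design, design.roles[higher]) - group_mean(
        expr, design, design.roles[lower]
    )
    mask = diff > threshold if strict else diff >= threshold
    return frozenset(diff.index[mask])


def aggregate_calls(
    calls: CallMatrix,
    design: GroupDesign,
    group: str,
    wanted: str,
    mode: str = "all",
    *,
    include_marginal: bool = False,
) -> FrozenSet[str]:
    """Probe sets carrying the wanted call across a group's replicates.

    ``mode='all'``: every replicate must have the wanted call;
    ``mode='majority'``: more than half must.  Marginal counts as the
    wanted call only when ``include_marginal`` is set.
    """
    if wanted not in ("P", "A"):
        raise ValueError("wanted must be 'P' or 'A'")
    if mode not in ("all", "majority"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    samples = design.samples_in_group(group)
    if not samples:
        raise ValueError(f"unknown or empty group {group!r}")
    sub = calls.calls[samples]
    hit = sub == wanted
    if include_marginal:
        hit = hit | (sub == "M")
    counts = hit.sum(axis=1)
    if mode == "all":
        mask = counts == len(samples)
    else:
        mask = counts > len(samples) / 2.0
    return frozenset(sub.index[mask])


def run_screen(
    expr: ExpressionMatrix,
    calls: CallMatrix,
    design: GroupDesign,
    config: ScreenConfig,
    gene_map: GeneMap,
    tf_set: AnnotationSet,
) -> ScreenResult:
    """Execute the full candidate-extraction logic.

    Computes the four up-sets and their intersection, the four replicate-
    aggregated call sets and their intersection, the combined overlap, and
    the sorted, deduplicated transcription-factor gene list.
    """
    if set(expr.probesets) != set(calls.probesets):
        raise ValueError("expression and call matrices differ in probe sets")
    design.check_samples(expr.samples)
    design.check_samples(calls.samples)

    up_sets = {
        (hi, lo): up_set(
            expr,
            design,
            hi,
            lo,
            config.fold_threshold,
            strict=config.strict_inequality,
        )
        for hi, lo in UP_PAIRS
    }
    fold_intersection = frozenset.intersection(*up_sets.values())

    present_sets = {
        role: aggregate_calls(
            calls,
            design,
            design.roles[role],
            "P",
            config.call_aggregation,
            include_marginal=config.include_marginal_as_present,
        )
        for role in PRESENT_ROLES
    }
    absent_sets = {
        role: aggregate_calls(
            calls,
            design,
            design.roles[role],
            "A",
            config.call_aggregation,
            include_marginal=config.include_marginal_as_absent,
        )
        for role in ABSENT_ROLES
    }
    call_intersection = frozenset.intersection(
        *present_sets.values(), *absent_sets.values()
    )

    combined = fold_intersection & call_intersection
    annotated = {ps: gene_map.entries[ps] for ps in combined if ps in gene_map.entries}
    n_dropped = len(combined) - len(annotated)
    genes = set(annotated.values())
    tf_genes = sorted(genes & tf_set.genes)
    return ScreenResult(
        up_sets=up_sets,
        fold_intersection=fold_intersection,
        present_sets=present_sets,
        absent_sets=absent_sets,
        call_intersection=call_intersection,
        combined=combined,
        tf_genes=tf_genes,
        n_unannotated_dropped=n_dropped,
    )
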