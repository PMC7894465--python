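"""In-memory containers shared across the pipeline.

The raw unit of data is a probe *pair*: a perfect-match (PM) oligo and its
mismatch (MM) partner carrying a central base substitution.  Eleven or so
pairs interrogate one transcript and together form a probe *set*.  Every
container here is probe-set- or sample-indexed and validated on
construction, so downstream algorithms can assume the invariants hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pandas as pd

#: The four comparison roles of the screen, in canonical order.  ``source``
#: is the population to be reprogrammed (DFAT cells in the motivating
#: study), ``source_origin`` the cell type it derives from (mature
#: adipocytes), ``target`` the desired fate (hepatocytes) and
#: ``target_stem`` the corresponding stem/progenitor population (resident
#: liver stem cells).
ROLES = ("source", "source_origin", "target", "target_stem")

CALL_PRESENT = "P"
CALL_MARGINAL = "M"
CALL_ABSENT = "A"
CALLS = (CALL_PRESENT, CALL_MARGINAL, CALL_ABSENT)


@dataclass
class ProbeLevelDataset:
    """Per-sample PM/MM intensities for probe pairs grouped into probe sets.

    Parameters
    ----------
    samples
        Ordered sample identifiers; defines the column order of ``pm``/``mm``.
    probeset_ids
        Probe-set identifier of each record (row).
    pair_index
        Index of the probe pair within its probe set (``>= 0``).
    pm, mm
        ``(n_records, n_samples)`` arrays of strictly positive intensities.
    """

    samples: List[str]
    probeset_ids: np.ndarray
    pair_index: np.ndarray
    pm: np.ndarray
    mm: np.ndarray
    _blocks: Dict[str, np.ndarray] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.probeset_ids = np.asarray(self.probeset_ids, dtype=object)
        self.pair_index = np.asarray(self.pair_index, dtype=np.int64)
        self.pm = np.asarray(self.pm, dtype=np.float64)
        self.mm = np.asarray(self.mm, dtype=np.float64)
        n = self.probeset_ids.shape[0]
        s = len(self.samples)
        if len(set(self.samples)) != s:
            raise ValueError("duplicate sample identifiers")
        for name, arr in (("pm", self.pm), ("mm", self.mm)):
            if arr.shape != (n, s):
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {(n, s)}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite intensities")
            if not np.all(arr > 0):
                raise ValueError(f"{name} contains non-positive intensities")
        if self.pair_index.shape != (n,):
            raise ValueError("pair_index length mismatch")
        if np.any(self.pair_index < 0):
            raise ValueError("negative pair_index")
        keys = list(zip(self.probeset_ids, self.pair_index))
        if len(set(keys)) != n:
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate probe pair {dup}")

    @property
    def n_records(self) -> int:
        return self.probeset_ids.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def probesets(self) -> List[str]:
        """Unique probe-set identifiers, lexicographically sorted."""
        return sorted(self.blocks())

    def blocks(self) -> Dict[str, np.ndarray]:
        """Map probe-set id -> row indices of its probe pairs (cached)."""
        if self._blocks is None:
            codes, uniques = pd.factorize(self.probeset_ids, sort=False)
            order = np.argsort(codes, kind="stable")
            bounds = np.searchsorted(codes[order], np.arange(len(uniques)))
            bounds = np.append(bounds, len(codes))
            self._blocks = {
                str(uniques[i]): order[bounds[i] : bounds[i + 1]]
                for i in range(len(uniques))
            }
        return self._blocks


@dataclass
class GroupDesign:
    """Sample -> group assignment plus the four screen roles.

    ``roles`` maps each of :data:`ROLES` to a group label; the four labels
    must be distinct and every role's group must contain at least one
    assigned sample.
    """

    assignments: Dict[str, str]
    roles: Dict[str, str]

    def __post_init__(self) -> None:
        if set(self.roles) != set(ROLES):
            missing = set(ROLES) - set(self.roles)
            extra = set(self.roles) - set(ROLES)
            raise ValueError(
                f"roles must be exactly {ROLES}; missing={sorted(missing)} "
                f"unknown={sorted(extra)}"
            )
        if len(set(self.roles.values())) != len(ROLES):
            raise ValueError("the four roles must map to distinct groups")
        for role, group in self.roles.items():
            if not self.samples_in_group(group):
                raise ValueError(f"role {role!r} group {group!r} has no samples")

    def samples_in_group(self, group: str) -> List[str]:
        return [s for s, g in self.assignments.items() if g == group]

    def samples_for_role(self, role: str) -> List[str]:
        if role not in self.roles:
            raise KeyError(f"unknown role {role!r}")
        return self.samples_in_group(self.roles[role])

    def check_samples(self, samples: List[str]) -> None:
        """Verify every assigned sample appears in ``samples``."""
        missing = sorted(set(self.assignments) - set(samples))
        if missing:
            raise ValueError(f"design references unknown samples: {missing}")


@dataclass
class GeneMap:
    """Probe-set id -> gene symbol; unannotated probe sets are simply absent.

    One gene symbol may own several probe sets (Hnf4a does on the Mouse
    430 2.0 array), which is why the screen collapses probe sets to genes
    only at its final stage.
    """

    entries: Dict[str, str]

    def __post_init__(self) -> None:
        for ps, sym in self.entries.items():
            if not isinstance(sym, str) or not sym.strip():
                raise ValueError(f"empty gene symbol for probe set {ps!r}")

    def gene_for(self, probeset_id: str):
        return self.entries.get(probeset_id)


@dataclass
class AnnotationSet:
    """A named gene class, e.g. PANTHER 'Transcription factor' (PC00218)."""

    class_id: str
    genes: frozenset

    def __post_init__(self) -> None:
        genes = frozenset(self.genes)
        for g in genes:
            if not isinstance(g, str) or not g.strip():
                raise ValueError("gene symbols must be non-empty strings")
        self.genes = genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ExpressionMatrix:
    """Probe set x sample matrix of log2-scale summarized expression."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("expression values must be finite")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicate probe sets or samples")

    @property
    def probesets(self) -> List[str]:
        return list(self.values.index)

    @property
    def samples(self) -> List[str]:
        return list(self.values.columns)


@dataclass
class CallMatrix:
    """Probe set x sample detection calls with underlying p-values.

    A cell is Present when its detection p-value is below ``alpha1``,
    Absent when above ``alpha2`` and Marginal in between (boundaries
    inclusive for Marginal).
    """

    calls: pd.DataFrame
    pvalues: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.calls.index.equals(self.pvalues.index) or not self.calls.columns.equals(
            self.pvalues.columns
        ):
            raise ValueError("calls and pvalues must share index and columns")
        vals = self.calls.to_numpy()
        if not np.isin(vals, CALLS).all():
            raise ValueError("calls must be one of P, M, A")
        p = self.pvalues.to_numpy()
        if not (np.all(p >= 0) and np.all(p <= 1)):
            raise ValueError("p-values must lie in [0, 1]")

    @property
    def probesets(self) -> List[str]:
        return list(self.calls.index)

    @property
    def samples(self) -> List[str]:
        return list(self.calls.columns)
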