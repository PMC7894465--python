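"""Shared fixtures: an enumerable toy screen and a small simulated study."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from mrscreen import (
    AnnotationSet,
    CallMatrix,
    ExpressionMatrix,
    GeneMap,
    GroupDesign,
    ROLES,
    SimConfig,
    detection_calls,
    rma,
    simulate_dataset,
)

GROUPS = {"source": "DFAT", "source_origin": "AC", "target": "HC", "target_stem": "RLSC"}

OFF_LEVEL = 2.0
P_PVAL, M_PVAL, A_PVAL = 0.01, 0.05, 0.9


def _toy_samples():
    return [f"{GROUPS[r]}{i}" for r in ROLES for i in (1, 2, 3)]


@pytest.fixture(scope="session")
def toy_screen():
    """Hand-enumerable screen input covering every 2^4 on/off pattern.

    Two probe sets per pattern with different effect sizes (4.0 and 2.5
    log2), plus special probe sets exercising replicate aggregation
    (mixed P/M/A calls), annotation dropout and multi-probe-set gene
    collapse.  Ground truth is fully enumerable from ``meta``.
    """
    samples = _toy_samples()
    role_of = {s: r for r in ROLES for s in (f"{GROUPS[r]}{i}" for i in (1, 2, 3))}
    target = (False, False, True, True)

    meta = {}  # ps -> dict(pattern, effect, calls override)
    for pat in product((False, True), repeat=4):
        code = "".join("1" if b else "0" for b in pat)
        for tag, effect in (("a", 4.0), ("b", 2.5)):
            meta[f"tp{code}{tag}"] = {
                "pattern": pat, "effect": effect, "gene": f"G{code}{tag}",
                "call_override": {},
            }
    # mixed calls: excluded under 'all', included under 'majority'
    meta["mx1"] = {"pattern": target, "effect": 4.0, "gene": "GeneMx1",
                   "call_override": {"HC3": "M"}}
    meta["mx2"] = {"pattern": target, "effect": 4.0, "gene": "GeneMx2",
                   "call_override": {"DFAT3": "P"}}
    # passes both filters but is unannotated -> dropped at TF stage
    meta["unann"] = {"pattern": target, "effect": 4.0, "gene": None,
                     "call_override": {}}
    # two probe sets of one gene (multi-probe-set collapse)
    meta["cg1"] = {"pattern": target, "effect": 4.0, "gene": "GeneH",
                   "call_override": {}}
    meta["cg2"] = {"pattern": target, "effect": 4.0, "gene": "GeneH",
                   "call_override": {}}

    probesets = sorted(meta)
    expr_rows, call_rows, pval_rows = [], [], []
    for ps in probesets:
        info = meta[ps]
        expr_row, call_row, pval_row = [], [], []
        for s in samples:
            on = info["pattern"][ROLES.index(role_of[s])]
            expr_row.append(OFF_LEVEL + (info["effect"] if on else 0.0))
            call = info["call_override"].get(s, "P" if on else "A")
            call_row.append(call)
            pval_row.append({"P": P_PVAL, "M": M_PVAL, "A": A_PVAL}[call])
        expr_rows.append(expr_row)
        call_rows.append(call_row)
        pval_rows.append(pval_row)

    idx = pd.Index(probesets)
    expr = ExpressionMatrix(pd.DataFrame(expr_rows, index=idx, columns=samples))
    calls = CallMatrix(
        calls=pd.DataFrame(call_rows, index=idx, columns=samples),
        pvalues=pd.DataFrame(pval_rows, index=idx, columns=samples),
    )
    design = GroupDesign(
        assignments={s: s.rstrip("123") for s in samples},
        roles=dict(GROUPS),
    )
    gene_map = GeneMap(
        entries={ps: m["gene"] for ps, m in meta.items() if m["gene"]}
    )
    tf = AnnotationSet(
        class_id="TF",
        genes=frozenset(
            {"G0011a", "GeneMx1", "GeneMx2", "GeneH", "G1111a"}
        ),
    )
    return {
        "expr": expr, "calls": calls, "design": design,
        "gene_map": gene_map, "tf": tf, "meta": meta,
        "role_of": role_of, "samples": samples,
    }


@pytest.fixture(scope="session")
def small_sim():
    """A small but structurally complete simulated study."""
    cfg = SimConfig(n_genes=240, n_confounders_per_pattern=5, seed=11)
    return cfg, simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    """RMA + detection calls of the small simulated study."""
    cfg, (ds, design, gmap, tf, truth) = small_sim
    return {
        "cfg": cfg, "dataset": ds, "design": design, "gene_map": gmap,
        "tf": tf, "truth": truth, "expr": rma(ds),
        "calls": detection_calls(ds),
    }
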