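"""Screen set logic against brute-force computation from definitions."""

import numpy as np
import pandas as pd
import pytest

from mrscreen import (
    AnnotationSet,
    CallMatrix,
    ExpressionMatrix,
    GeneMap,
    ROLES,
    ScreenConfig,
    aggregate_calls,
    group_mean,
    run_screen,
    up_set,
)
from mrscreen.screen import ABSENT_ROLES, PRESENT_ROLES, UP_PAIRS


def brute_force_stages(toy, config):
    """Recompute every stage set directly from the definitions."""
    expr = toy["expr"].values
    calls = toy["calls"].calls
    design = toy["design"]
    out = {"up": {}, "present": {}, "absent": {}}

    def mean(ps, role):
        cols = design.samples_for_role(role)
        return sum(expr.loc[ps, c] for c in cols) / len(cols)

    for hi, lo in UP_PAIRS:
        sel = set()
        for ps in expr.index:
            diff = mean(ps, hi) - mean(ps, lo)
            if (diff > config.fold_threshold if config.strict_inequality
                    else diff >= config.fold_threshold):
                sel.add(ps)
        out["up"][(hi, lo)] = sel
    out["fold"] = set.intersection(*out["up"].values())

    def agg(role, wanted):
        cols = design.samples_for_role(role)
        sel = set()
        for ps in calls.index:
            hits = sum(calls.loc[ps, c] == wanted for c in cols)
            if config.call_aggregation == "all":
                ok = hits == len(cols)
            else:
                ok = hits > len(cols) / 2
            if ok:
                sel.add(ps)
        return sel

    for role in PRESENT_ROLES:
        out["present"][role] = agg(role, "P")
    for role in ABSENT_ROLES:
        out["absent"][role] = agg(role, "A")
    out["call"] = set.intersection(
        *out["present"].values(), *out["absent"].values()
    )
    out["combined"] = out["fold"] & out["call"]
    gmap = toy["gene_map"].entries
    genes = {gmap[ps] for ps in out["combined"] if ps in gmap}
    out["tf_genes"] = sorted(genes & toy["tf"].genes)
    return out


def test_group_mean_basics(toy_screen):
    expr, design = toy_screen["expr"], toy_screen["design"]
    m = group_mean(expr, design, "HC")
    hc = [s for s in toy_screen["samples"] if s.startswith("HC")]
    np.testing.assert_allclose(m, expr.values[hc].mean(axis=1))
    with pytest.raises(ValueError, match="unknown or empty group"):
        group_mean(expr, design, "nope")


def test_up_set_hand_example():
    samples = ["d1", "a1", "h1", "r1"]
    df = pd.DataFrame(
        [[2.0, 2.0, 5.0, 5.0], [2.0, 2.0, 3.5, 3.5]],
        index=["ps1", "ps2"], columns=samples,
    )
    expr = ExpressionMatrix(df)
    from mrscreen import GroupDesign

    design = GroupDesign(
        assignments={"d1": "D", "a1": "A", "h1": "H", "r1": "R"},
        roles={"source": "D", "source_origin": "A", "target": "H",
               "target_stem": "R"},
    )
    assert up_set(expr, design, "target", "source", 2.0) == {"ps1"}
    assert up_set(expr, design, "target", "source", 2.0, strict=False) == {"ps1"}
    # equal means everywhere -> empty
    flat = ExpressionMatrix(pd.DataFrame(np.full((2, 4), 3.0),
                                         index=["ps1", "ps2"], columns=samples))
    assert up_set(flat, design, "target", "source", 2.0) == frozenset()


def test_aggregate_calls_modes(toy_screen):
    calls, design = toy_screen["calls"], toy_screen["design"]
    # mx1 has HC calls (P, P, M)
    all_p = aggregate_calls(calls, design, "HC", "P", "all")
    maj_p = aggregate_calls(calls, design, "HC", "P", "majority")
    assert "mx1" not in all_p and "mx1" in maj_p
    # marginal can be counted as present on request
    inc = aggregate_calls(calls, design, "HC", "P", "all", include_marginal=True)
    assert "mx1" in inc
    # unanimous absences are included under both modes
    all_a = aggregate_calls(calls, design, "AC", "A", "all")
    maj_a = aggregate_calls(calls, design, "AC", "A", "majority")
    assert "tp0011a" in all_a and "tp0011a" in maj_a
    with pytest.raises(ValueError, match="unknown aggregation"):
        aggregate_calls(calls, design, "AC", "A", "sometimes")


@pytest.mark.parametrize("aggregation", ["all", "majority"])
@pytest.mark.parametrize("threshold", [1.0, 2.0, 3.0, 4.0])
def test_run_screen_matches_brute_force(toy_screen, aggregation, threshold):
    config = ScreenConfig(fold_threshold=threshold, call_aggregation=aggregation)
    res = run_screen(
        toy_screen["expr"], toy_screen["calls"], toy_screen["design"],
        config, toy_screen["gene_map"], toy_screen["tf"],
    )
    ref = brute_force_stages(toy_screen, config)
    for pair in UP_PAIRS:
        assert res.up_sets[pair] == ref["up"][pair]
    assert res.fold_intersection == ref["fold"]
    for role in PRESENT_ROLES:
        assert res.present_sets[role] == ref["present"][role]
    for role in ABSENT_ROLES:
        assert res.absent_sets[role] == ref["absent"][role]
    assert res.call_intersection == ref["call"]
    assert res.combined == ref["combined"]
    assert res.tf_genes == ref["tf_genes"]
    assert res.combined == res.fold_intersection & res.call_intersection
    counts = res.cardinalities()
    assert counts["combined"] == len(ref["combined"])


def test_default_screen_known_outcome(toy_screen):
    res = run_screen(
        toy_screen["expr"], toy_screen["calls"], toy_screen["design"],
        ScreenConfig(), toy_screen["gene_map"], toy_screen["tf"],
    )
    # mixed-call probe sets are excluded under 'all'; the unannotated one
    # survives to 'combined' but is dropped at the gene stage
    assert res.combined == {"tp0011a", "tp0011b", "unann", "cg1", "cg2"}
    assert res.n_unannotated_dropped == 1
    # GeneH owns two passing probe sets but appears once; G0011b is not a TF
    assert res.tf_genes == ["G0011a", "GeneH"]


def test_screen_monotone_in_threshold_and_aggregation(toy_screen):
    prev = None
    for thr in (1.0, 2.0, 3.0, 4.0):
        res = run_screen(
            toy_screen["expr"], toy_screen["calls"], toy_screen["design"],
            ScreenConfig(fold_threshold=thr), toy_screen["gene_map"],
            toy_screen["tf"],
        )
        if prev is not None:
            for pair in UP_PAIRS:
                assert res.up_sets[pair] <= prev.up_sets[pair]
            assert res.fold_intersection <= prev.fold_intersection
            assert res.combined <= prev.combined
            assert set(res.tf_genes) <= set(prev.tf_genes)
        prev = res
    maj = run_screen(
        toy_screen["expr"], toy_screen["calls"], toy_screen["design"],
        ScreenConfig(call_aggregation="majority"), toy_screen["gene_map"],
        toy_screen["tf"],
    )
    strict = run_screen(
        toy_screen["expr"], toy_screen["calls"], toy_screen["design"],
        ScreenConfig(call_aggregation="all"), toy_screen["gene_map"],
        toy_screen["tf"],
    )
    assert strict.call_intersection <= maj.call_intersection


def test_screen_invariant_to_input_order(toy_screen):
    expr, calls = toy_screen["expr"], toy_screen["calls"]
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(expr.probesets))
    cperm = rng.permutation(len(expr.samples))
    expr2 = ExpressionMatrix(expr.values.iloc[perm, cperm])
    calls2 = CallMatrix(
        calls=calls.calls.iloc[perm, cperm], pvalues=calls.pvalues.iloc[perm, cperm]
    )
    a = run_screen(expr, calls, toy_screen["design"], ScreenConfig(),
                   toy_screen["gene_map"], toy_screen["tf"])
    b = run_screen(expr2, calls2, toy_screen["design"], ScreenConfig(),
                   toy_screen["gene_map"], toy_screen["tf"])
    assert a.combined == b.combined and a.tf_genes == b.tf_genes


def test_screen_empty_tf_set(toy_screen):
    tf_empty = AnnotationSet(class_id="TF", genes=frozenset())
    res = run_screen(
        toy_screen["expr"], toy_screen["calls"], toy_screen["design"],
        ScreenConfig(), toy_screen["gene_map"], tf_empty,
    )
    ref = run_screen(
        toy_screen["expr"], toy_screen["calls"], toy_screen["design"],
        ScreenConfig(), toy_screen["gene_map"], toy_screen["tf"],
    )
    assert res.tf_genes == []
    assert res.combined == ref.combined


def test_run_screen_rejects_probe_set_mismatch(toy_screen):
    calls = toy_screen["calls"]
    trimmed = CallMatrix(calls=calls.calls.iloc[1:], pvalues=calls.pvalues.iloc[1:])
    with pytest.raises(ValueError, match="differ in probe sets"):
        run_screen(toy_screen["expr"], trimmed, toy_screen["design"],
                   ScreenConfig(), toy_screen["gene_map"], toy_screen["tf"])


def test_multi_probe_set_gene_collapse_minimal():
    """Six probe sets, two pass, both map to one gene: list is [GeneA]."""
    samples = ["d1", "a1", "h1", "r1"]
    from mrscreen import GroupDesign

    design = GroupDesign(
        assignments={"d1": "D", "a1": "A", "h1": "H", "r1": "R"},
        roles={"source": "D", "source_origin": "A", "target": "H",
               "target_stem": "R"},
    )
    ps = [f"ps{i}" for i in range(1, 7)]
    expr_vals = np.full((6, 4), 2.0)
    expr_vals[0, 2:] = 7.0  # ps1 up in target+stem
    expr_vals[1, 2:] = 7.0  # ps2 up in target+stem
    expr_vals[2, :] = 7.0   # ps3 high everywhere (fails fold change)
    expr_vals[3, 2] = 7.0   # ps4 up in target only
    calls_vals = np.where(expr_vals > 2.0, "P", "A").astype(object)
    calls_vals[4, :] = "P"  # ps5 present everywhere (fails absence)
    pvals = np.where(calls_vals == "P", 0.01, 0.9)
    expr = ExpressionMatrix(pd.DataFrame(expr_vals, index=ps, columns=samples))
    calls = CallMatrix(
        calls=pd.DataFrame(calls_vals, index=ps, columns=samples),
        pvalues=pd.DataFrame(pvals, index=ps, columns=samples),
    )
    gmap = GeneMap(entries={"ps1": "GeneA", "ps2": "GeneA", "ps3": "GeneB",
                            "ps4": "GeneC", "ps5": "GeneD", "ps6": "GeneE"})
    tf = AnnotationSet(class_id="TF", genes=frozenset({"GeneA"}))
    res = run_screen(expr, calls, design, ScreenConfig(), gmap, tf)
    assert res.combined == {"ps1", "ps2"}
    assert res.tf_genes == ["GeneA"]
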