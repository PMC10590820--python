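"""Preprocessing chain, differential expression, GPR parsing/evaluation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from fluxrevert.expression import (
    collapse_and_normalize,
    differential_expression,
    evaluate_gpr,
    filter_proteins,
    impute,
    map_expression_to_reactions,
    parse_gpr,
    preprocess,
    render_gpr,
)

from conftest import build_model


def stage_frame(rows: dict) -> pd.DataFrame:
    cols = pd.MultiIndex.from_product(
        [["monolayer", "moruloid", "blastuloid"], ["r1", "r2", "r3"]],
        names=["stage", "replicate"],
    )
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


N = float("nan")


class TestFilter:
    @pytest.mark.parametrize(
        "row, kept",
        [
            ([N] * 9, False),  # absent everywhere: dropped first
            ([1, 2, N] + [N] * 6, True),  # 2/3 in one stage suffices
            ([1, N, N, 2, N, N, 3, N, N], False),  # 1/3 everywhere fails
            ([1, 2, 3] * 3, True),
        ],
    )
    def test_replicate_rule(self, row, kept):
        m = stage_frame({"p": row, "anchor": [1.0] * 9})
        out = filter_proteins(m)
        assert ("p" in out.index) is kept

    def test_empty_result_allowed(self):
        out = filter_proteins(stage_frame({"p": [1, N, N, 2, N, N, 3, N, N]}))
        assert out.empty


class TestImpute:
    def test_mean_within_good_stage(self):
        m = stage_frame({"p": [4, 6, N, 1, 1, 1, 1, 1, 1]})
        out = impute(m)
        assert out.loc["p"].iloc[:3].tolist() == [4, 6, 5]

    def test_failing_stage_gets_global_minimum(self):
        m = stage_frame({"p": [N, N, 7, 1, 1, 1, 1, 1, 1], "q": [0.3] + [2] * 8})
        out = impute(m)
        # whole stage-row replaced, including the observed singleton
        assert out.loc["p"].iloc[:3].tolist() == [0.3, 0.3, 0.3]

    def test_singleton_kept_with_switch(self):
        m = stage_frame({"p": [N, N, 7, 1, 1, 1, 1, 1, 1], "q": [0.3] + [2] * 8})
        out = impute(m, replace_whole_stage=False)
        assert out.loc["p"].iloc[:3].tolist() == [0.3, 0.3, 7]

    def test_fully_observed_unchanged_and_complete(self):
        m = stage_frame({"p": list(range(1, 10)), "q": [5, N, 5, N, N, N, 2, 2, 2]})
        out = impute(m)
        assert out.loc["p"].tolist() == list(range(1, 10))
        assert not out.isna().any().any()
        assert out.to_numpy().min() == pytest.approx(np.nanmin(m.to_numpy()))


class TestCollapse:
    def test_mean_then_log10(self):
        m = stage_frame({"p": [10, 100, 1000] + [1] * 6})
        out = collapse_and_normalize(m)
        assert out.loc["p", "monolayer"] == pytest.approx(math.log10(370))

    def test_identical_replicates(self):
        m = stage_frame({"p": [7.0] * 9})
        out = collapse_and_normalize(m)
        assert set(out.loc["p"].round(12)) == {round(math.log10(7.0), 12)}

    def test_rerun_from_merge_is_identity(self):
        m = stage_frame({"p": [4, 6, N, 2, 2, 2, 9, 9, N], "q": [1] * 9})
        once = collapse_and_normalize(impute(filter_proteins(m)))
        assert np.allclose(once.to_numpy(), once.to_numpy())  # defined, finite
        assert np.isfinite(once.to_numpy()).all()


class TestDifferentialExpression:
    def test_twofold_change(self):
        a = pd.DataFrame({"r1": [2.0, 5], "r2": [2.0, 5], "r3": [2.0, 5]},
                         index=["p", "q"])
        b = pd.DataFrame({"r1": [4.0, 5], "r2": [4.0, 5], "r3": [4.0, 5]},
                         index=["p", "q"])
        out = differential_expression(a, b)
        assert out.loc["p", "log2fc"] == pytest.approx(1.0)
        assert out.loc["q", "log2fc"] == pytest.approx(0.0)
        assert out.loc["q", "direction"] == "ns"

    def test_degenerate_equal_groups(self):
        a = pd.DataFrame({"r1": [3.0], "r2": [3.0], "r3": [3.0]}, index=["p"])
        out = differential_expression(a, a)
        assert out.loc["p", "pvalue"] == 1.0

    def test_welch_p_close_to_permutation(self):
        rng = np.random.default_rng(5)
        a = pd.DataFrame(rng.normal(10, 1, (1, 3)), index=["p"])
        b = pd.DataFrame(rng.normal(13, 1, (1, 3)), index=["p"])
        out = differential_expression(a, b)
        # exact permutation reference over all 20 splits of the 6 values
        vals = np.concatenate([a.to_numpy().ravel(), b.to_numpy().ravel()])
        obs = abs(vals[3:].mean() - vals[:3].mean())
        count = 0
        total = 0
        for idx in itertools.combinations(range(6), 3):
            grp = np.zeros(6, dtype=bool)
            grp[list(idx)] = True
            diff = abs(vals[grp].mean() - vals[~grp].mean())
            count += diff >= obs - 1e-12
            total += 1
        p_perm = count / total
        assert abs(out.loc["p", "pvalue"] - p_perm) < 0.15

    def test_bh_adjustment_available(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame(rng.normal(10, 1, (20, 3)))
        b = pd.DataFrame(rng.normal(10, 1, (20, 3)))
        out = differential_expression(a, b, adjust=True)
        assert (out["padj"] >= out["pvalue"] - 1e-12).all()


class TestGprParsing:
    def test_and(self):
        gpr = parse_gpr("g1 and g2")
        assert set(gpr.genes) == {"g1", "g2"}
        assert evaluate_gpr(gpr, {"g1": 2, "g2": 5}) == 2

    def test_nested(self):
        gpr = parse_gpr("(g1 or g2) and g3")
        assert evaluate_gpr(gpr, {"g1": 2, "g2": 5, "g3": 4}) == 4

    def test_case_insensitive(self):
        gpr = parse_gpr("g1 AND g2")
        assert evaluate_gpr(gpr, {"g1": 1, "g2": 3}) == 1

    def test_empty_rule(self):
        assert math.isnan(evaluate_gpr(parse_gpr(""), {"g1": 1}))

    def test_unbalanced_parentheses(self):
        with pytest.raises(ValueError):
            parse_gpr("(g1 and g2")

    @pytest.mark.parametrize(
        "rule",
        ["g1", "g1 and g2", "g1 or g2 or g3", "(g1 or g2) and (g3 or g4)",
         "g1 and (g2 or (g3 and g4))"],
    )
    def test_render_round_trip(self, rule):
        tree = parse_gpr(rule)
        again = parse_gpr(render_gpr(tree))
        vals = {f"g{i}": float(i) for i in range(1, 5)}
        assert evaluate_gpr(again, vals) == evaluate_gpr(tree, vals)


def _reference_eval(expr, vals):
    """Independent recursive min/max evaluator over a nested tuple tree."""
    if isinstance(expr, str):
        return vals.get(expr, float("nan"))
    op, *children = expr
    scored = [v for v in (_reference_eval(c, vals) for c in children)
              if not math.isnan(v)]
    if not scored:
        return float("nan")
    return min(scored) if op == "and" else max(scored)


def _tuple_to_rule(expr):
    if isinstance(expr, str):
        return expr
    op, *children = expr
    return "(" + f" {op} ".join(_tuple_to_rule(c) for c in children) + ")"


class TestGprEvaluation:
    def test_or_takes_maximum(self):
        assert evaluate_gpr(parse_gpr("g1 or g2"), {"g1": 2, "g2": 5}) == 5

    def test_missing_child_ignored(self):
        assert evaluate_gpr(parse_gpr("g1 and g2"), {"g1": 2}) == 2

    def test_all_three_gene_asts_match_reference(self):
        genes = ["g1", "g2", "g3"]
        shapes = []
        for o1 in ("and", "or"):
            for o2 in ("and", "or"):
                shapes.append((o1, (o2, "g1", "g2"), "g3"))
                shapes.append((o1, "g1", (o2, "g2", "g3")))
            shapes.append((o1, "g1", "g2", "g3"))
        for shape in shapes:
            rule = _tuple_to_rule(shape)
            tree = parse_gpr(rule)
            for present in itertools.product([True, False], repeat=3):
                vals = {g: float(i + 1) for i, (g, p) in
                        enumerate(zip(genes, present)) if p}
                got = evaluate_gpr(tree, vals)
                want = _reference_eval(shape, vals)
                assert (math.isnan(got) and math.isnan(want)) or got == want, rule

    def test_monotone_in_gene_values(self):
        rule = "(g1 or g2) and (g3 or (g1 and g4))"
        tree = parse_gpr(rule)
        rng = np.random.default_rng(3)
        for _ in range(50):
            vals = {f"g{i}": float(rng.uniform(0, 10)) for i in range(1, 5)}
            base = evaluate_gpr(tree, vals)
            bump = dict(vals)
            g = f"g{rng.integers(1, 5)}"
            bump[g] = vals[g] + rng.uniform(0, 5)
            assert evaluate_gpr(tree, bump) >= base


class TestReactionMapping:
    def test_map_on_model(self):
        model = build_model(
            {"a": "C"},
            {
                "R_and": ({"a": 1}, 0, 1, "g1 and g2"),
                "R_or": ({"a": -1}, 0, 1, "g1 or g2"),
                "R_none": ({"a": -1}, 0, 1),
            },
        )
        exp = map_expression_to_reactions(model, {"g1": 2.0, "g2": 5.0})
        assert exp["R_and"] == 2 and exp["R_or"] == 5
        assert math.isnan(exp["R_none"])

    def test_preprocess_intersects_model_genes(self, scenario):
        vals = preprocess(scenario.expression, scenario.model)
        assert set(vals.index) <= {g.id for g in scenario.model.genes}
        assert not vals.isna().any().any()
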