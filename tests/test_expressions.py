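"""Predicate mini-language: parsing, three-valued evaluation, oracle equivalence."""

import random

import pandas as pd
import pytest

from cohortviz.errors import EvaluationError, ExpressionError
from cohortviz.expressions import (BoolOp, Col, Compare, InList, IsMissing,
                                   Lit, Not, evaluate, parse_expression,
                                   subset_mask)
from tests.conftest import make_table


class TestParsing:
    def test_comparison_node(self):
        pred = parse_expression("cd4_v_cmp < 200")
        assert pred.ast == Compare("<", Col("cd4_v_cmp"), Lit(200.0))
        assert pred.referenced_columns == {"cd4_v_cmp"}

    def test_conjunction_with_membership_and_missing(self):
        pred = parse_expression("aids_cl_y in (0,1) and not missing(aids_cl_y)")
        assert isinstance(pred.ast, BoolOp) and pred.ast.op == "and"
        first, second = pred.ast.items
        assert first == InList(Col("aids_cl_y"), (0.0, 1.0))
        assert second == Not(IsMissing("aids_cl_y"))

    def test_table_prefix_stripped(self):
        pred = parse_expression("basic_cd4$cd4_v_cmp < 200")
        assert pred.ast == Compare("<", Col("cd4_v_cmp"), Lit(200.0))

    def test_r_style_operator_aliases(self):
        a = parse_expression("cd4_v > 0 & ! missing(cd4_v)")
        b = parse_expression("cd4_v > 0 and not missing(cd4_v)")
        assert a.ast == b.ast

    def test_truncated_expression_position(self):
        with pytest.raises(ExpressionError) as err:
            parse_expression("cd4_v <")
        assert err.value.position == 7

    @pytest.mark.parametrize("bad", ["", "f(x)", "a = 1", "a + 1 > 2", "a >< b"])
    def test_disallowed_constructs_rejected(self, bad):
        with pytest.raises(ExpressionError):
            parse_expression(bad)


class TestEvaluation:
    def test_missing_propagates_then_subset_treats_as_false(self):
        table = make_table(["cd4_v"], [["50"], [None], ["0"]])
        pred = parse_expression("cd4_v > 0 and not missing(cd4_v)")
        assert list(subset_mask(pred, table)) == [True, False, False]

    def test_comparison_with_missing_is_missing(self):
        table = make_table(["x"], [["5"], [None]])
        out = evaluate(parse_expression("x > 1"), table)
        assert bool(out[0]) and out[1] is pd.NA

    def test_tautology(self):
        table = make_table(["x"], [["a"], ["b"], ["c"]])
        assert list(evaluate(parse_expression("1 == 1"), table)) == [True] * 3

    def test_unknown_column_named_before_evaluation(self):
        table = make_table(["x"], [["1"]])
        with pytest.raises(EvaluationError, match="xyz"):
            evaluate(parse_expression("xyz > 0"), table)

    def test_date_comparison_against_iso_literal(self):
        import datetime as dt
        table = make_table(["d"], [[dt.date(2011, 5, 1)], [dt.date(2009, 1, 1)], [None]])
        out = evaluate(parse_expression("d >= '2010-01-01'"), table)
        assert bool(out[0]) and not bool(out[1]) and out[2] is pd.NA

    def test_text_membership(self):
        table = make_table(["site"], [["peru"], ["chile"], [None]])
        out = evaluate(parse_expression("site in ('peru', 'brazil')"), table)
        assert bool(out[0]) and not bool(out[1]) and out[2] is pd.NA


@pytest.mark.parametrize("text", [
    "cd4_v_cmp < 200",
    "aids_cl_y in (0,1) and not missing(aids_cl_y)",
    "a > 1 or b <= 2 and not c == 3",
    "not (a > 1 or missing(b))",
    "site in ('a', 'b') and x != 0",
])
def test_parse_unparse_parse_idempotent(text):
    pred = parse_expression(text)
    again = parse_expression(pred.unparse())
    assert again.ast == pred.ast
    assert parse_expression(again.unparse()).ast == again.ast


# ---------------------------------------------------------------------------
# Oracle equivalence: an independent, deliberately naive interpreter


def _oracle_eval(node, row):
    """Straight-line re-implementation of the three-valued semantics."""
    if isinstance(node, IsMissing):
        return row[node.column] is None
    if isinstance(node, Not):
        v = _oracle_eval(node.item, row)
        return None if v is None else (not v)
    if isinstance(node, BoolOp):
        vals = [_oracle_eval(i, row) for i in node.items]
        if node.op == "and":
            result = True
            for v in vals:
                if v is False:
                    return False
                if v is None:
                    result = None
            return result
        result = False
        for v in vals:
            if v is True:
                return True
            if v is None:
                result = None
        return result
    if isinstance(node, Compare):
        lhs = row[node.left.name] if isinstance(node.left, Col) else node.left.value
        rhs = row[node.right.name] if isinstance(node.right, Col) else node.right.value
        if lhs is None or rhs is None:
            return None
        ops = {"==": "__eq__", "!=": "__ne__", "<": "__lt__",
               "<=": "__le__", ">": "__gt__", ">=": "__ge__"}
        return getattr(float(lhs), ops[node.op])(float(rhs))
    if isinstance(node, InList):
        v = row[node.operand.name] if isinstance(node.operand, Col) else node.operand.value
        if v is None:
            return None
        return float(v) in [float(x) for x in node.values]
    raise AssertionError(node)


def _random_expression(rng, cols, depth=0):
    choice = rng.random()
    if depth >= 3 or choice < 0.45:
        col = rng.choice(cols)
        kind = rng.random()
        if kind < 0.5:
            op = rng.choice(["==", "!=", "<", "<=", ">", ">="])
            return f"{col} {op} {rng.randint(-2, 5)}"
        if kind < 0.75:
            vals = ",".join(str(rng.randint(-2, 5)) for _ in range(rng.randint(1, 3)))
            return f"{col} in ({vals})"
        return f"missing({col})"
    left = _random_expression(rng, cols, depth + 1)
    right = _random_expression(rng, cols, depth + 1)
    if choice < 0.65:
        return f"({left}) and ({right})"
    if choice < 0.85:
        return f"({left}) or ({right})"
    return f"not ({left})"


def test_evaluation_matches_brute_force_interpreter():
    rng = random.Random(42)
    cols = ["a", "b", "c"]
    for _ in range(150):
        n = rng.randint(1, 8)
        rows = [[None if rng.random() < 0.25 else str(rng.randint(-2, 5))
                 for _ in cols] for _ in range(n)]
        table = make_table(cols, rows)
        pred = parse_expression(_random_expression(rng, cols))
        got = evaluate(pred, table)
        for i in range(n):
            row = {c: (None if rows[i][j] is None else float(rows[i][j]))
                   for j, c in enumerate(cols)}
            expected = _oracle_eval(pred.ast, row)
            actual = None if got[i] is pd.NA else bool(got[i])
            assert actual == expected, (pred.text, rows[i])
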