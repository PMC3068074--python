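"""Guideline graph loading, three-valued predicate evaluation, rendering."""

import pytest
from hypothesis import given, strategies as st

from psakit import GraphError, default_guideline, evaluate, load_guideline, render_trace
from psakit.guideline import FactType, NodeKind, Predicate


def _write_graph(tmp_path, body):
    p = tmp_path / "g.yaml"
    p.write_text(body, encoding="utf-8")
    return p


class TestLoadGuideline:
    def test_two_node_linear_graph(self, tmp_path):
        g = load_guideline(
            _write_graph(
                tmp_path,
                """
entry: a
facts: {x: number}
nodes:
  - {id: a, label: A, predicate: true}
  - {id: b, label: B, predicate: x > 0}
edges:
  - {from: a, to: b}
""",
            )
        )
        assert len(g.edges) == 1 and g.entry == "a"

    def test_dangling_edge_rejected(self, tmp_path):
        with pytest.raises(GraphError, match="unknown node 'ghost'"):
            load_guideline(
                _write_graph(
                    tmp_path,
                    """
entry: a
facts: {}
nodes: [{id: a, label: A}]
edges: [{from: a, to: ghost}]
""",
                )
            )

    def test_cycle_reported_with_its_nodes(self, tmp_path):
        with pytest.raises(GraphError, match="cycle"):
            load_guideline(
                _write_graph(
                    tmp_path,
                    """
entry: a
facts: {}
nodes: [{id: a, label: A}, {id: b, label: B}]
edges: [{from: a, to: b}, {from: b, to: a}]
""",
                )
            )

    def test_unknown_fact_name_is_schema_error(self, tmp_path):
        with pytest.raises(GraphError, match="unknown fact name 'psa'"):
            load_guideline(
                _write_graph(
                    tmp_path,
                    """
entry: a
facts: {weight: number}
nodes: [{id: a, label: A, predicate: psa > 4}]
edges: []
""",
                )
            )

    def test_packaged_graph_has_decision_structure(self):
        g = default_guideline()
        decisions = [n for n in g.nodes if n.kind is NodeKind.DECISION]
        assert len(decisions) >= 3
        assert g.entry in {n.id for n in g.nodes}


class TestPredicateLogic:
    SCHEMA = {"psa": FactType.NUMBER, "stage": FactType.CATEGORY, "sympt": FactType.BOOLEAN}

    @pytest.mark.parametrize(
        "text, facts, expected",
        [
            ("psa > 20", {"psa": 82.35}, True),
            ("psa > 20", {"psa": 5}, False),
            ("psa > 20", {}, None),  # unknown fact -> unknown truth
            ("psa > 20 or sympt", {"psa": 30}, True),  # True or unknown = True
            ("psa > 20 and sympt", {"psa": 30}, None),  # True and unknown = unknown
            ("psa > 20 and sympt", {"psa": 5}, False),  # False short-circuits unknown
            ("not sympt", {"sympt": False}, True),
            ("not sympt", {}, None),
            ('stage in ("T1c", "T2a")', {"stage": "T2a"}, True),
            ('stage in ("T1c", "T2a")', {"stage": "T2c"}, False),
            ("0 < psa <= 10", {"psa": 10}, True),  # chained comparison
            ("0 < psa <= 10", {"psa": 12}, False),
        ],
    )
    def test_kleene_evaluation(self, text, facts, expected):
        assert Predicate.compile(text, self.SCHEMA)(facts) is expected

    @pytest.mark.parametrize(
        "bad", ["__import__('os')", "psa + 1 > 2", "f(psa)", "psa if sympt else 0", "[x for x in y]"]
    )
    def test_non_whitelisted_expressions_rejected(self, bad):
        with pytest.raises(GraphError):
            Predicate.compile(bad, self.SCHEMA)

    def test_category_number_comparison_is_type_error(self):
        pred = Predicate.compile("stage > 3", self.SCHEMA)
        with pytest.raises(GraphError, match="type mismatch"):
            pred({"stage": "T2a"})


class TestEvaluate:
    def test_branch_selected_by_facts(self, toy_graph_file):
        g = load_guideline(toy_graph_file)
        assert evaluate(g, {"psa": 82.35}).highlighted == ("entry", "therapyA")
        assert evaluate(g, {"psa": 5}).highlighted == ("entry", "therapyB")

    def test_empty_facts_highlight_entry_only(self, toy_graph_file):
        g = load_guideline(toy_graph_file)
        trace = evaluate(g, {})
        assert trace.highlighted == ("entry",)
        assert set(trace.unmet) == {"therapyA", "therapyB"}

    def test_undeclared_fact_rejected(self, toy_graph_file):
        g = load_guideline(toy_graph_file)
        with pytest.raises(GraphError, match="not declared"):
            evaluate(g, {"age": 70})

    def test_deterministic(self, toy_graph_file):
        g = load_guideline(toy_graph_file)
        traces = {evaluate(g, {"psa": 25}) for _ in range(5)}
        assert len(traces) == 1

    def test_adding_facts_only_extends_highlight(self):
        g = default_guideline()
        partial = {"psa": 82.35, "t_category": "T2c", "gleason_sum": 7}
        full = {**partial, "life_expectancy_years": 15.0,
                "lymph_node_involvement_pct": 38.0, "symptomatic": False}
        assert set(evaluate(g, partial).highlighted) <= set(evaluate(g, full).highlighted)

    def test_high_risk_path_on_worked_facts(self):
        # PSA 82.35, stage T2c, Gleason 4+3, LE 15 y, nodal involvement 38%
        g = default_guideline()
        trace = evaluate(
            g,
            {
                "psa": 82.35,
                "t_category": "T2c",
                "gleason_sum": 7,
                "life_expectancy_years": 15.0,
                "lymph_node_involvement_pct": 38.0,
                "symptomatic": False,
            },
        )
        assert set(trace.highlighted) == {"evaluation", "high_risk", "radiotherapy", "hormonal", "followup"}


@st.composite
def _dag_and_facts(draw):
    """Small random DAG (edges only forward) with threshold predicates."""
    n = draw(st.integers(min_value=2, max_value=6))
    thresholds = [draw(st.integers(min_value=0, max_value=10)) for _ in range(n)]
    edges = []
    for j in range(1, n):
        parents = draw(
            st.lists(st.integers(min_value=0, max_value=j - 1), min_size=1, max_size=2, unique=True)
        )
        edges.extend((p, j) for p in parents)
    psa = draw(st.one_of(st.none(), st.integers(min_value=0, max_value=10)))
    return n, thresholds, edges, psa


class TestPathConnectivity:
    @given(case=_dag_and_facts())
    def test_highlighted_region_is_entry_connected(self, case, tmp_path_factory):
        n, thresholds, edges, psa = case
        body = ["entry: n0", "facts: {psa: number}", "nodes:"]
        body.append("  - {id: n0, label: n0, predicate: true}")
        for j in range(1, n):
            body.append(f"  - {{id: n{j}, label: n{j}, predicate: psa >= {thresholds[j]}}}")
        body.append("edges:")
        body.extend(f"  - {{from: n{a}, to: n{b}}}" for a, b in edges)
        p = tmp_path_factory.mktemp("dag") / "g.yaml"
        p.write_text("\n".join(body) + "\n", encoding="utf-8")
        g = load_guideline(p)
        trace = evaluate(g, {} if psa is None else {"psa": psa})
        hi = set(trace.highlighted)
        assert set(trace.highlighted) <= set(trace.visited)
        parents = {f"n{b}": set() for _, b in edges}
        for a, b in edges:
            parents[f"n{b}"].add(f"n{a}")
        for nid in hi - {"n0"}:
            assert parents[nid] & hi, f"{nid} highlighted without a highlighted parent"


class TestRenderTrace:
    def test_text_lists_highlighted_path(self, toy_graph_file):
        g = load_guideline(toy_graph_file)
        out = render_trace(g, evaluate(g, {"psa": 30}), "text")
        assert "Therapy A" in out and "Therapy B" not in out

    def test_dot_styles_exactly_highlighted_nodes(self, toy_graph_file):
        g = load_guideline(toy_graph_file)
        trace = evaluate(g, {"psa": 30})
        dot = render_trace(g, trace, "dot")
        assert dot.count("fillcolor") == len(trace.highlighted)
        assert dot.startswith("digraph")

    def test_mismatched_trace_rejected(self, toy_graph_file):
        from psakit import EvaluationTrace

        g = load_guideline(toy_graph_file)
        rogue = EvaluationTrace(highlighted=("zzz",), visited=("zzz",), unmet=())
        with pytest.raises(GraphError, match="absent from the graph"):
            render_trace(g, rogue, "text")
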