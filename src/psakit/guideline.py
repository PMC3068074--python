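"""Treatment-guideline decision graphs.

A guideline is a directed acyclic graph whose nodes carry boolean
predicates over named clinical facts (PSA, stage category, Gleason sum,
life expectancy, ...).  Given a patient's facts, :func:`evaluate` walks the
graph from its entry node and highlights every node reachable through
satisfied predicates — the programmatic equivalent of lighting up the
applicable therapeutic path on a guideline flowchart while the clinician
enters data.

Guideline *content* is data, not code: graphs are authored in a small YAML
schema (see ``data/guideline_prostate.yaml`` for the shipped demo) and the
predicate language is deliberately restricted — comparisons, membership
tests over category literals, and/or/not — no arbitrary code execution.

Missing facts use three-valued (Kleene) logic: a predicate that cannot be
decided evaluates to *unknown*, which never highlights but is recorded, so
partially entered records yield partial, monotonically growing highlights.
"""

from __future__ import annotations

import ast
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import networkx as nx
import yaml

from .errors import GraphError

__all__ = [
    "FactType",
    "Predicate",
    "GuidelineNode",
    "GuidelineEdge",
    "GuidelineGraph",
    "EvaluationTrace",
    "load_guideline",
    "default_guideline",
    "evaluate",
    "render_trace",
]


class FactType(str, Enum):
    NUMBER = "number"
    CATEGORY = "category"
    BOOLEAN = "boolean"


class NodeKind(str, Enum):
    DECISION = "decision"
    THERAPY = "therapy"
    TERMINAL = "terminal"


# --- predicate language ----------------------------------------------------

_ALLOWED_CMP = (ast.Lt, ast.LtE, ast.Gt, ast.GtE, ast.Eq, ast.NotEq, ast.In, ast.NotIn)


def _and3(values):  # Kleene conjunction
    if any(v is False for v in values):
        return False
    if any(v is None for v in values):
        return None
    return True


def _or3(values):  # Kleene disjunction
    if any(v is True for v in values):
        return True
    if any(v is None for v in values):
        return None
    return False


def _not3(v):
    return None if v is None else (not v)


@dataclass(frozen=True)
class Predicate:
    """A compiled boolean expression over declared fact names.

    Built from a restricted Python-expression syntax (parsed with ``ast``,
    never executed as code).  Calling it with a fact mapping returns
    ``True``, ``False`` or ``None`` (unknown: some referenced fact absent).
    """

    text: str
    _tree: ast.expr = field(repr=False, compare=False)
    _schema: Mapping[str, FactType] = field(repr=False, compare=False)

    @classmethod
    def compile(cls, text: str | bool, schema: Mapping[str, FactType]) -> "Predicate":
        if isinstance(text, bool):  # YAML bare true/false
            text = "True" if text else "False"
        try:
            tree = ast.parse(text, mode="eval").body
        except SyntaxError as e:
            raise GraphError(f"cannot parse predicate {text!r}: {e}") from None
        cls._check(tree, schema, text)
        return cls(text=text, _tree=tree, _schema=dict(schema))

    @staticmethod
    def _check(node: ast.expr, schema: Mapping[str, FactType], src: str) -> None:
        if isinstance(node, ast.BoolOp):
            for v in node.values:
                Predicate._check(v, schema, src)
        elif isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.Not):
            Predicate._check(node.operand, schema, src)
        elif isinstance(node, ast.Compare):
            for op in node.ops:
                if not isinstance(op, _ALLOWED_CMP):
                    raise GraphError(f"operator {type(op).__name__} not allowed in {src!r}")
            for v in [node.left, *node.comparators]:
                Predicate._check(v, schema, src)
        elif isinstance(node, ast.Name):
            if node.id not in schema:
                raise GraphError(f"unknown fact name {node.id!r} in predicate {src!r}")
        elif isinstance(node, ast.Constant):
            if not isinstance(node.value, (int, float, str, bool)):
                raise GraphError(f"literal {node.value!r} not allowed in {src!r}")
        elif isinstance(node, (ast.Tuple, ast.List, ast.Set)):
            for e in node.elts:
                if not isinstance(e, ast.Constant):
                    raise GraphError(f"collections may contain only literals in {src!r}")
        else:
            raise GraphError(f"expression element {type(node).__name__} not allowed in {src!r}")

    def __call__(self, facts: Mapping[str, object]) -> Optional[bool]:
        return self._truth(self._tree, facts)

    # -- evaluation ---------------------------------------------------------

    def _truth(self, node: ast.expr, facts: Mapping) -> Optional[bool]:
        if isinstance(node, ast.BoolOp):
            vals = [self._truth(v, facts) for v in node.values]
            return _and3(vals) if isinstance(node.op, ast.And) else _or3(vals)
        if isinstance(node, ast.UnaryOp):
            return _not3(self._truth(node.operand, facts))
        if isinstance(node, ast.Compare):
            left = self._value(node.left, facts)
            out = []
            for op, comp in zip(node.ops, node.comparators):
                right = self._value(comp, facts)
                out.append(self._compare(op, left, right))
                left = right
            return _and3(out)
        if isinstance(node, ast.Constant) and isinstance(node.value, bool):
            return node.value
        if isinstance(node, ast.Name):  # bare boolean fact
            v = facts.get(node.id)
            if v is None:
                return None
            if not isinstance(v, bool):
                raise GraphError(f"fact {node.id!r} used as boolean but has value {v!r}")
            return v
        raise GraphError(f"predicate {self.text!r} is not boolean-valued")

    def _value(self, node: ast.expr, facts: Mapping):
        if isinstance(node, ast.Constant):
            return node.value
        if isinstance(node, ast.Name):
            return facts.get(node.id)  # None = unknown
        if isinstance(node, (ast.Tuple, ast.List, ast.Set)):
            return [e.value for e in node.elts]  # type: ignore[union-attr]
        raise GraphError(f"unsupported operand in predicate {self.text!r}")

    def _compare(self, op: ast.cmpop, a, b) -> Optional[bool]:
        if a is None or b is None:
            return None
        try:
            if isinstance(op, ast.In):
                return a in b
            if isinstance(op, ast.NotIn):
                return a not in b
            if isinstance(a, str) != isinstance(b, str):
                raise TypeError("category/number mismatch")
            if isinstance(op, ast.Lt):
                return a < b
            if isinstance(op, ast.LtE):
                return a <= b
            if isinstance(op, ast.Gt):
                return a > b
            if isinstance(op, ast.GtE):
                return a >= b
            if isinstance(op, ast.Eq):
                return a == b
            return a != b  # NotEq
        except TypeError:
            raise GraphError(
                f"type mismatch comparing {a!r} and {b!r} in predicate {self.text!r}"
            ) from None


# --- graph model -----------------------------------------------------------


@dataclass(frozen=True)
class GuidelineNode:
    id: str
    label: str
    kind: NodeKind
    predicate: Predicate


@dataclass(frozen=True)
class GuidelineEdge:
    source: str
    target: str
    predicate: Optional[Predicate] = None  # absent = unconditional


@dataclass(frozen=True)
class GuidelineGraph:
    """Validated decision DAG with a single designated entry node."""

    nodes: tuple[GuidelineNode, ...]
    edges: tuple[GuidelineEdge, ...]
    entry: str
    fact_schema: dict[str, FactType]

    def node(self, node_id: str) -> GuidelineNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise GraphError(f"no node with id {node_id!r}")

    def successors(self, node_id: str) -> list[GuidelineEdge]:
        return [e for e in self.edges if e.source == node_id]


@dataclass(frozen=True)
class EvaluationTrace:
    """Result of walking a guideline with a fact set.

    ``highlighted`` is the satisfied, entry-connected region in discovery
    order; ``visited`` is every node whose predicate was evaluated;
    ``unmet`` the visited nodes that failed or were undecidable.
    """

    highlighted: tuple[str, ...]
    visited: tuple[str, ...]
    unmet: tuple[str, ...]


def load_guideline(source: str | Path) -> GuidelineGraph:
    """Load and validate a guideline graph from its YAML schema file.

    Checks performed at load time: unique node ids, edges reference
    existing ids, acyclicity (a cycle is reported listing its nodes), a
    single existing entry node, and every predicate referencing only
    declared fact names.
    """
    p = Path(source)
    try:
        doc = yaml.safe_load(p.read_text(encoding="utf-8"))
    except yaml.YAMLError as e:
        raise GraphError(f"{p}: invalid YAML: {e}") from None
    if not isinstance(doc, dict):
        raise GraphError(f"{p}: guideline document must be a mapping")
    for key in ("entry", "facts", "nodes", "edges"):
        if key not in doc:
            raise GraphError(f"{p}: missing required section {key!r}")

    try:
        schema = {str(k): FactType(v) for k, v in doc["facts"].items()}
    except ValueError as e:
        raise GraphError(f"{p}: bad fact schema: {e}") from None

    nodes: list[GuidelineNode] = []
    seen: set[str] = set()
    for item in doc["nodes"]:
        nid = str(item["id"])
        if nid in seen:
            raise GraphError(f"{p}: duplicate node id {nid!r}")
        seen.add(nid)
        nodes.append(
            GuidelineNode(
                id=nid,
                label=str(item.get("label", nid)),
                kind=NodeKind(item.get("kind", "decision")),
                predicate=Predicate.compile(item.get("predicate", True), schema),
            )
        )

    edges: list[GuidelineEdge] = []
    for item in doc["edges"]:
        src, dst = str(item["from"]), str(item["to"])
        for end in (src, dst):
            if end not in seen:
                raise GraphError(f"{p}: edge {src!r} -> {dst!r} references unknown node {end!r}")
        pred = item.get("predicate")
        edges.append(
            GuidelineEdge(
                source=src,
                target=dst,
                predicate=Predicate.compile(pred, schema) if pred is not None else None,
            )
        )

    entry = str(doc["entry"])
    if entry not in seen:
        raise GraphError(f"{p}: entry node {entry!r} does not exist")

    g = nx.DiGraph([(e.source, e.target) for e in edges])
    g.add_nodes_from(seen)
    if not nx.is_directed_acyclic_graph(g):
        cycle = [u for u, _ in nx.find_cycle(g)]
        raise GraphError(f"{p}: guideline graph contains a cycle: {' -> '.join(cycle + cycle[:1])}")

    return GuidelineGraph(nodes=tuple(nodes), edges=tuple(edges), entry=entry, fact_schema=schema)


def default_guideline() -> GuidelineGraph:
    """The packaged demo prostate-cancer graph (illustrative content)."""
    with resources.as_file(
        resources.files("psakit.data").joinpath("guideline_prostate.yaml")
    ) as p:
        return load_guideline(p)


def validate_facts(graph: GuidelineGraph, facts: Mapping[str, object]) -> dict[str, object]:
    """Type-check a fact mapping against the graph's declared schema."""
    out: dict[str, object] = {}
    for name, value in facts.items():
        if name not in graph.fact_schema:
            raise GraphError(f"fact {name!r} is not declared in the graph's schema")
        ftype = graph.fact_schema[name]
        if ftype is FactType.NUMBER and (isinstance(value, bool) or not isinstance(value, (int, float))):
            raise GraphError(f"fact {name!r} must be a number, got {value!r}")
        if ftype is FactType.BOOLEAN and not isinstance(value, bool):
            raise GraphError(f"fact {name!r} must be a boolean, got {value!r}")
        if ftype is FactType.CATEGORY and not isinstance(value, str):
            raise GraphError(f"fact {name!r} must be a category string, got {value!r}")
        out[name] = value
    return out


def evaluate(graph: GuidelineGraph, facts: Mapping[str, object]) -> EvaluationTrace:
    """Walk the graph breadth-first and highlight the satisfied region.

    A node is highlighted iff it is reachable from the entry through
    highlighted nodes via edges whose (optional) predicates hold, and its
    own predicate holds.  Unknown predicate values (missing facts) stop
    highlighting but are recorded in ``unmet``; supplying more facts can
    only extend the highlight.
    """
    facts = validate_facts(graph, facts)
    highlighted: list[str] = []
    visited: list[str] = []
    in_high: set[str] = set()
    in_visited: set[str] = set()

    def node_ok(nid: str) -> Optional[bool]:
        if nid not in in_visited:
            in_visited.add(nid)
            visited.append(nid)
        return graph.node(nid).predicate(facts)

    if node_ok(graph.entry) is True:
        highlighted.append(graph.entry)
        in_high.add(graph.entry)
        queue = deque([graph.entry])
        while queue:
            u = queue.popleft()
            for edge in graph.successors(u):
                edge_ok = True if edge.predicate is None else edge.predicate(facts)
                ok = _and3([edge_ok, node_ok(edge.target)])
                if ok is True and edge.target not in in_high:
                    highlighted.append(edge.target)
                    in_high.add(edge.target)
                    queue.append(edge.target)

    unmet = tuple(v for v in visited if v not in in_high)
    return EvaluationTrace(highlighted=tuple(highlighted), visited=tuple(visited), unmet=unmet)


def render_trace(graph: GuidelineGraph, trace: EvaluationTrace, format: str = "text") -> str:
    """Render an evaluation trace as plain text or Graphviz dot.

    Text lists the highlighted nodes in discovery order (with kind and
    label); dot emits the whole graph with highlighted nodes filled.
    """
    known = {n.id for n in graph.nodes}
    stray = [nid for nid in (*trace.highlighted, *trace.visited) if nid not in known]
    if stray:
        raise GraphError(f"trace references nodes absent from the graph: {stray}")

    if format == "text":
        if not trace.highlighted:
            return "(no step satisfied)"
        lines = []
        for i, nid in enumerate(trace.highlighted):
            n = graph.node(nid)
            lines.append(f"{'  ' * min(i, 1)}{'-> ' if i else ''}[{n.kind.value}] {n.label}")
        return "\n".join(lines)

    if format == "dot":
        hi = set(trace.highlighted)
        out = ["digraph guideline {", "  rankdir=TB;", '  node [shape=box, fontname="sans-serif"];']
        for n in graph.nodes:
            style = ' style=filled fillcolor="pink"' if n.id in hi else ""
            out.append(f'  "{n.id}" [label="{n.label}"{style}];')
        for e in graph.edges:
            out.append(f'  "{e.source}" -> "{e.target}";')
        out.append("}")
        return "\n".join(out)

    raise GraphError(f"unknown rendering format {format!r} (use 'text' or 'dot')")
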