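"""Signed two-layer network models compiled from causal statements.

A model has a *backbone* layer (protein activities, abundances, complexes,
processes, pathologies) connected by signed causal edges, and a *transcript*
layer of ``r()`` (mRNA) nodes attached beneath backbone nodes.  Transcript
nodes carry the expression footprint used to infer backbone activity from a
differential-expression contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .bel import BelTerm, CausalStatement, EvidenceContext, parse_term, render_statement

__all__ = [
    "NetworkNode",
    "CausalEdge",
    "NetworkModel",
    "LintWarning",
    "TrimResult",
    "OrthologizeResult",
    "compile_statements",
    "orthologize",
    "trim_dead_ends",
    "merge_models",
    "RODENT_NAMESPACES",
]

#: Leaf namespaces treated as rodent gene symbols for orthologization.
RODENT_NAMESPACES = frozenset({"MGI", "RGD"})

#: Backbone functions that anchor dead-end trimming (processes and pathologies).
ANCHOR_FUNCTIONS = frozenset({"bp", "path"})


@dataclass(frozen=True)
class NetworkNode:
    """A model node; the id is the canonical term string."""

    id: str
    term: BelTerm

    @property
    def layer(self) -> str:
        """``transcript`` for ``r()`` terms, ``backbone`` otherwise."""
        return "transcript" if self.term.function == "r" else "backbone"


@dataclass
class CausalEdge:
    """A signed causal edge with its supporting evidences.

    ``indirect`` marks synthetic edges added by path contraction during
    subgraph extraction; compiled models only contain direct-curated edges
    (``indirect=False``), where ``direct`` distinguishes
    ``directlyIncreases``-style relations from plain ``increases``.
    """

    source: str
    target: str
    sign: int
    direct: bool
    evidences: list[EvidenceContext] = field(default_factory=list)
    indirect: bool = False

    def __post_init__(self):
        if self.sign not in (+1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign}")

    @property
    def key(self) -> tuple[str, str, int, bool]:
        return (self.source, self.target, self.sign, self.direct)

    @property
    def relation(self) -> str:
        base = "increases" if self.sign > 0 else "decreases"
        return ("directly" + base[0].upper() + base[1:]) if self.direct else base


@dataclass(frozen=True)
class LintWarning:
    node: str
    issue: str
    detail: str


class NetworkModel:
    """A compiled model: unique nodes by canonical id, edges by
    (source, target, sign, direct)."""

    def __init__(self, name: str, metadata: dict | None = None):
        self.name = name
        self.metadata: dict = dict(metadata or {})
        self.nodes: dict[str, NetworkNode] = {}
        self.edges: dict[tuple[str, str, int, bool], CausalEdge] = {}

    # -- construction -------------------------------------------------------

    def add_term(self, term: BelTerm) -> NetworkNode:
        node = NetworkNode(term.canonical, term)
        existing = self.nodes.setdefault(node.id, node)
        return existing

    def add_edge(self, source: BelTerm | str, target: BelTerm | str, sign: int,
                 direct: bool = False, evidences: list[EvidenceContext] | None = None,
                 indirect: bool = False) -> CausalEdge:
        if isinstance(source, BelTerm):
            source = self.add_term(source).id
        if isinstance(target, BelTerm):
            target = self.add_term(target).id
        if source not in self.nodes or target not in self.nodes:
            raise KeyError("edge endpoints must be existing nodes or BelTerms")
        key = (source, target, sign, direct)
        edge = self.edges.get(key)
        if edge is None:
            edge = CausalEdge(source, target, sign, direct, [], indirect)
            self.edges[key] = edge
        for ev in evidences or []:
            if ev.key() not in {e.key() for e in edge.evidences}:
                edge.evidences.append(ev)
        return edge

    # -- views ---------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def backbone_nodes(self) -> list[NetworkNode]:
        return [n for n in self.nodes.values() if n.layer == "backbone"]

    def transcript_nodes(self) -> list[NetworkNode]:
        return [n for n in self.nodes.values() if n.layer == "transcript"]

    def out_edges(self, node_id: str) -> list[CausalEdge]:
        return [e for e in self.edges.values() if e.source == node_id]

    def in_edges(self, node_id: str) -> list[CausalEdge]:
        return [e for e in self.edges.values() if e.target == node_id]

    def ambivalent_pairs(self) -> set[tuple[str, str]]:
        """(source, target) pairs connected by both a +1 and a -1 edge."""
        signs: dict[tuple[str, str], set[int]] = {}
        for e in self.edges.values():
            signs.setdefault((e.source, e.target), set()).add(e.sign)
        return {pair for pair, s in signs.items() if len(s) == 2}

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph(name=self.name)
        for n in self.nodes.values():
            g.add_node(n.id, function=n.term.function, layer=n.layer)
        for e in self.edges.values():
            g.add_edge(e.source, e.target, sign=e.sign, direct=e.direct,
                       indirect=e.indirect, evidence_count=len(e.evidences))
        return g

    def copy(self, name: str | None = None) -> "NetworkModel":
        out = NetworkModel(name or self.name, self.metadata)
        for n in self.nodes.values():
            out.nodes[n.id] = n
        for e in self.edges.values():
            out.edges[e.key] = CausalEdge(e.source, e.target, e.sign, e.direct,
                                          list(e.evidences), e.indirect)
        return out

    def structurally_equal(self, other: "NetworkModel") -> bool:
        return (set(self.nodes) == set(other.nodes)
                and set(self.edges) == set(other.edges))

    def validate(self):
        """Raise if any structural invariant is violated."""
        for e in self.edges.values():
            if e.source not in self.nodes or e.target not in self.nodes:
                raise ValueError(f"dangling edge endpoint in {e.key}")
            if e.key != (e.source, e.target, e.sign, e.direct):
                raise ValueError("edge key mismatch")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<NetworkModel {self.name!r}: {self.n_nodes} nodes, {self.n_edges} edges>"


# ---------------------------------------------------------------------------
# compilation

def compile_statements(stmts: list[CausalStatement], name: str) -> NetworkModel:
    """Compile parsed statements into a model.

    One node per distinct canonical term; duplicate statements (same source,
    target, sign, directness) merge into one edge whose evidences are the
    union of the supporting contexts.  Violations of the scripting
    convention "a gene product acting as a source is scripted as a protein
    activity" are recorded as lint warnings in ``metadata['lint']`` — they
    never block compilation.  Self-loop edges are kept and flagged in
    ``metadata['self_loops']``.
    """
    model = NetworkModel(name, metadata={"statements": len(stmts)})
    lint: list[LintWarning] = []
    self_loops: list[str] = []
    for stmt in stmts:
        model.add_edge(stmt.subject, stmt.object, stmt.sign, stmt.direct,
                       evidences=[stmt.evidence])
        subj = stmt.subject
        # gene products (p/g abundances) as causal sources should be wrapped
        # in act(); microRNAs (m) and cellular structures are exempt
        if subj.is_leaf and subj.function in {"p", "g"}:
            lint.append(LintWarning(
                subj.canonical, "abundance-as-source",
                f"source of '{render_statement(stmt)}' is a bare {subj.function}() "
                "abundance; convention scripts gene-product sources as act()"))
        if stmt.self_loop:
            self_loops.append(subj.canonical)
    model.metadata["lint"] = [w.__dict__ for w in lint]
    model.metadata["self_loops"] = sorted(set(self_loops))
    return model


# ---------------------------------------------------------------------------
# orthologization

@dataclass
class OrthologizeResult:
    model: NetworkModel
    unmapped: list[str]


def _map_term(term: BelTerm, symbol_map: dict[str, str], unmapped: set[str]) -> BelTerm:
    if term.is_leaf:
        if term.namespace in RODENT_NAMESPACES:
            mapped = symbol_map.get(term.name)
            if mapped is None:
                unmapped.add(f"{term.namespace}:{term.name}")
                return term
            return BelTerm(term.function, namespace="HGNC", name=mapped)
        return term
    return BelTerm(term.function,
                   args=tuple(_map_term(a, symbol_map, unmapped) for a in term.args))


def orthologize(model: NetworkModel, symbol_map: dict[str, str]) -> OrthologizeResult:
    """Rename rodent-namespace leaf terms (MGI/RGD) to HGNC via ``symbol_map``.

    Nodes whose renamed terms collide with existing HGNC nodes are fused,
    unioning their edges and evidences.  Unmapped rodent symbols are left
    unchanged and listed in the result.
    """
    unmapped: set[str] = set()
    out = NetworkModel(model.name, model.metadata)
    id_map: dict[str, str] = {}
    for node in model.nodes.values():
        new_term = _map_term(node.term, symbol_map, unmapped)
        id_map[node.id] = out.add_term(new_term).id
    for e in model.edges.values():
        out.add_edge(id_map[e.source], id_map[e.target], e.sign, e.direct,
                     evidences=e.evidences, indirect=e.indirect)
    return OrthologizeResult(out, sorted(unmapped))


# ---------------------------------------------------------------------------
# dead-end trimming

@dataclass
class TrimResult:
    model: NetworkModel
    removed: list[tuple[str, str]]  # (node id, reason)
    warning: str | None = None


def trim_dead_ends(model: NetworkModel) -> TrimResult:
    """Remove backbone entities with no directed path to any bp()/path() anchor.

    Anchors are the model's biological-process and pathology nodes.  A
    backbone node survives iff it is an anchor or some directed path (edge
    signs ignored) leads from it to an anchor; a transcript node survives
    iff it remains attached to a surviving backbone node.  The operation is
    idempotent; a model without anchors is returned unchanged with a
    warning.
    """
    anchors = {n.id for n in model.nodes.values() if n.term.function in ANCHOR_FUNCTIONS}
    if not anchors:
        return TrimResult(model.copy(), [], warning="model has no bp()/path() anchors; nothing trimmed")
    g = model.to_networkx()
    reach = set(anchors)
    rev = g.reverse(copy=False)
    for a in anchors:
        reach |= nx.descendants(rev, a)
    keep: set[str] = set()
    for node in model.nodes.values():
        if node.layer == "backbone" and node.id in reach:
            keep.add(node.id)
    for node in model.transcript_nodes():
        attached = any(
            (e.source in keep or e.target in keep)
            for e in model.in_edges(node.id) + model.out_edges(node.id)
        )
        if attached:
            keep.add(node.id)
    removed = []
    out = NetworkModel(model.name, model.metadata)
    for nid in model.nodes:
        if nid in keep:
            out.nodes[nid] = model.nodes[nid]
        else:
            reason = ("transcript detached" if model.nodes[nid].layer == "transcript"
                      else "no path to bp/path anchor")
            removed.append((nid, reason))
    for e in model.edges.values():
        if e.source in keep and e.target in keep:
            out.add_edge(e.source, e.target, e.sign, e.direct,
                         evidences=e.evidences, indirect=e.indirect)
    return TrimResult(out, sorted(removed))


# ---------------------------------------------------------------------------
# merging

def merge_models(models: list[NetworkModel], name: str) -> NetworkModel:
    """Union models by canonical node id and (source, target, sign, direct)
    edge key, with evidence union; commutative and associative up to set
    equality."""
    if not models:
        raise ValueError("merge_models requires at least one model")
    out = NetworkModel(name, metadata={"merged_from": [m.name for m in models]})
    for m in models:
        for node in m.nodes.values():
            out.nodes.setdefault(node.id, node)
        for e in m.edges.values():
            out.add_edge(e.source, e.target, e.sign, e.direct,
                         evidences=e.evidences, indirect=e.indirect)
    return out


# ---------------------------------------------------------------------------
# BEL export (used by the synthetic generator and the CLI round trip)

def to_bel_script(model: NetworkModel) -> str:
    """Serialize a model back to a BEL script, one statement per edge/evidence."""
    lines = [f"# model: {model.name}"]
    for key in sorted(model.edges):
        e = model.edges[key]
        src = model.nodes[e.source].term.canonical
        tgt = model.nodes[e.target].term.canonical
        evs = e.evidences or [EvidenceContext()]
        for ev in evs:
            lines.append("UNSET ALL")
            if ev.citation:
                lines.append(f'SET Citation = "{ev.citation}"')
            if ev.evidence_text:
                lines.append(f'SET Evidence = "{ev.evidence_text}"')
            for k, v in ev.annotations:
                lines.append(f'SET {k} = "{v}"')
            lines.append(f"{src} {e.relation} {tgt}")
    return "\n".join(lines) + "\n"


def report_to_tsv(rows: list[tuple[str, str, str]]) -> str:
    """Render (node id, issue, detail) report rows as TSV text."""
    out = ["node\tissue\tdetail"]
    for node, issue, detail in rows:
        out.append(f"{node}\t{issue}\t{detail}")
    return "\n".join(out) + "\n"
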