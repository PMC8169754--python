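"""Network-exchange formats: JSON Graph (JGF) and Cytoscape SIF.

The JGF dialect mirrors the causal-network database export: a top-level
``graph`` object with ``nodes`` (id + metadata) and ``edges`` (source,
target, relation + metadata).  The reader is permissive — unknown metadata
keys are preserved, and edge relations may be the long-form keywords or
the arrow shorthands.  The writer sorts keys, nodes and edges so that
output is byte-stable for diffing.
"""

from __future__ import annotations

import json
from pathlib import Path

from .bel import ARROWS, RELATIONS, parse_term
from .model import CausalEdge, NetworkModel
from .scoring import ScoreReport

__all__ = ["read_jgf", "write_jgf", "jgf_dumps", "jgf_loads", "write_sif",
           "sif_lines", "node_attributes_tsv"]


class JgfError(ValueError):
    """Malformed JGF document; the message names the offending path."""


_RESERVED_NODE = {"function", "namespace", "layer"}
_RESERVED_EDGE = {"sign", "direct", "indirect", "evidence_count"}


def jgf_dumps(model: NetworkModel) -> str:
    nodes = []
    for nid in sorted(model.nodes):
        n = model.nodes[nid]
        nodes.append({
            "id": n.id,
            "label": n.id,
            "metadata": {
                "function": n.term.function,
                "namespace": n.term.namespace,
                "layer": n.layer,
            },
        })
    edges = []
    for key in sorted(model.edges):
        e = model.edges[key]
        edges.append({
            "source": e.source,
            "target": e.target,
            "relation": e.relation,
            "metadata": {
                "sign": e.sign,
                "direct": e.direct,
                "indirect": e.indirect,
                "evidence_count": len(e.evidences),
            },
        })
    doc = {
        "graph": {
            "label": model.name,
            "metadata": {k: model.metadata[k] for k in sorted(model.metadata)
                         if _json_safe(model.metadata[k])},
            "nodes": nodes,
            "edges": edges,
        }
    }
    return json.dumps(doc, indent=1, sort_keys=True) + "\n"


def _json_safe(value) -> bool:
    try:
        json.dumps(value)
        return True
    except TypeError:
        return False


def write_jgf(model: NetworkModel, file) -> None:
    Path(file).write_text(jgf_dumps(model), encoding="utf-8")


def _edge_sign_direct(edge_obj: dict, path: str) -> tuple[int, bool]:
    meta = edge_obj.get("metadata", {})
    relation = edge_obj.get("relation")
    if relation in ARROWS:
        relation = ARROWS[relation]
    if relation in RELATIONS:
        return RELATIONS[relation]
    if "sign" in meta:
        sign = int(meta["sign"])
        if sign not in (1, -1):
            raise JgfError(f"{path}: sign must be +1/-1")
        return sign, bool(meta.get("direct", False))
    raise JgfError(f"{path}: unknown relation {relation!r}")


def jgf_loads(text: str) -> NetworkModel:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise JgfError(f"invalid JSON: {exc}") from exc
    graph = doc.get("graph")
    if not isinstance(graph, dict):
        raise JgfError("graph: missing top-level 'graph' object")
    model = NetworkModel(graph.get("label", "unnamed"),
                         metadata=dict(graph.get("metadata", {})))
    for i, node_obj in enumerate(graph.get("nodes", [])):
        path = f"graph.nodes[{i}]"
        nid = node_obj.get("id")
        if not nid:
            raise JgfError(f"{path}: missing id")
        try:
            term = parse_term(nid)
        except ValueError as exc:
            raise JgfError(f"{path}: node id is not a BEL term: {exc}") from exc
        node = model.add_term(term)
        extra = {k: v for k, v in node_obj.get("metadata", {}).items()
                 if k not in _RESERVED_NODE}
        if extra:
            model.metadata.setdefault("node_metadata", {})[node.id] = extra
    for i, edge_obj in enumerate(graph.get("edges", [])):
        path = f"graph.edges[{i}]"
        src, tgt = edge_obj.get("source"), edge_obj.get("target")
        for endpoint in (src, tgt):
            if endpoint not in model.nodes:
                raise JgfError(f"{path}: dangling endpoint {endpoint!r}")
        sign, direct = _edge_sign_direct(edge_obj, path)
        meta = edge_obj.get("metadata", {})
        edge = model.add_edge(src, tgt, sign, direct,
                              indirect=bool(meta.get("indirect", False)))
        extra = {k: v for k, v in meta.items() if k not in _RESERVED_EDGE}
        if extra:
            model.metadata.setdefault("edge_metadata", {})[str(edge.key)] = extra
    model.validate()
    return model


def read_jgf(file) -> NetworkModel:
    return jgf_loads(Path(file).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# SIF + node attributes (Cytoscape import convention)

def sif_lines(model: NetworkModel) -> list[str]:
    """One ``source<TAB>relation<TAB>target`` line per edge.

    The relation is ``increases``/``decreases`` (directness collapsed),
    prefixed with ``indirect_`` for contracted edges.
    """
    lines = []
    for key in sorted(model.edges):
        e = model.edges[key]
        rel = "increases" if e.sign > 0 else "decreases"
        if e.indirect:
            rel = "indirect_" + rel
        lines.append(f"{e.source}\t{rel}\t{e.target}")
    return lines


def node_attributes_tsv(model: NetworkModel, scores: ScoreReport | None = None,
                        categories: dict[str, str] | None = None) -> str:
    """Node-attribute table for Cytoscape styling; unscored nodes keep
    empty score fields."""
    by_node = scores.by_node() if scores is not None else {}
    categories = categories or {}
    lines = ["node\tfunction\tlayer\tstrength\tp_adj\tdirection\tcategory"]
    for nid in sorted(model.nodes):
        n = model.nodes[nid]
        r = by_node.get(nid)
        strength = f"{r.strength:.10g}" if r else ""
        p_adj = f"{r.p_adj:.10g}" if r else ""
        direction = r.direction if r else ""
        lines.append(f"{nid}\t{n.term.function}\t{n.layer}\t{strength}\t"
                     f"{p_adj}\t{direction}\t{categories.get(nid, '')}")
    return "\n".join(lines) + "\n"


def write_sif(model: NetworkModel, file, scores: ScoreReport | None = None,
              categories: dict[str, str] | None = None) -> None:
    """Write the SIF file and a companion ``<file>.attrs.tsv`` table."""
    path = Path(file)
    path.write_text("\n".join(sif_lines(model)) + "\n", encoding="utf-8")
    attrs = path.with_suffix(path.suffix + ".attrs.tsv")
    attrs.write_text(node_attributes_tsv(model, scores, categories), encoding="utf-8")
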