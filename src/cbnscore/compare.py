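"""Two-contrast comparison: significance categories and divergent-regulation
subgraphs.

Given scored results from two disease contrasts (e.g. Crohn's disease and
ulcerative colitis, each versus healthy control), every node is put into a
figure-legend category — significant in *both*, in the *first only*, in the
*second only*, or in *none* — and flagged *divergent* when the two
contrasts disagree: significant in both with opposite Strength signs, or
significant in exactly one.  The minimal divergent network is the subgraph
induced on the divergent nodes, optionally re-connected through short
directed paths over unselected backbone nodes ("path contraction").
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import NetworkModel
from .scoring import ScoreResult

__all__ = ["DivergenceRecord", "SubgraphOptions", "classify_divergence",
           "extract_subgraph", "divergence_to_tsv"]


@dataclass(frozen=True)
class DivergenceRecord:
    node: str
    category: str  # both / first_only / second_only / none
    direction_first: str
    direction_second: str
    divergent: bool


@dataclass
class SubgraphOptions:
    contract_paths: bool = False
    max_path_len: int = 3

    def __post_init__(self):
        if self.max_path_len < 1:
            raise ValueError("max_path_len must be >= 1")


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def classify_divergence(res_a: list[ScoreResult], res_b: list[ScoreResult],
                        alpha: float = 0.05,
                        opposite_only: bool = False) -> list[DivergenceRecord]:
    """Categorize nodes by per-contrast significance and flag divergence.

    Nodes scored in only one result are treated as non-significant in the
    other.  ``divergent`` is true for both-significant nodes with opposite
    Strength signs and for nodes significant in exactly one contrast; with
    ``opposite_only`` the single-contrast categories are not counted as
    divergent.  Duplicate node ids within one result raise.
    """
    maps = []
    for label, res in (("first", res_a), ("second", res_b)):
        m = {r.node: r for r in res}
        if len(m) != len(res):
            raise ValueError(f"duplicate node ids in {label} result")
        maps.append(m)
    map_a, map_b = maps
    records = []
    for nid in sorted(set(map_a) | set(map_b)):
        ra, rb = map_a.get(nid), map_b.get(nid)
        sig_a = ra is not None and ra.p_adj < alpha
        sig_b = rb is not None and rb.p_adj < alpha
        if sig_a and sig_b:
            category = "both"
            divergent = _sign(ra.strength) != _sign(rb.strength)
        elif sig_a:
            category, divergent = "first_only", not opposite_only
        elif sig_b:
            category, divergent = "second_only", not opposite_only
        else:
            category, divergent = "none", False
        records.append(DivergenceRecord(
            nid, category,
            ra.direction if ra is not None else "null",
            rb.direction if rb is not None else "null",
            divergent))
    return records


def _sign_products(model: NetworkModel, selected: set[str], source: str,
                   target: str, max_len: int) -> set[int]:
    """Net signs of all directed simple paths source -> target of <= max_len
    edges whose intermediate nodes are unselected backbone nodes."""
    out_signs: dict[str, dict[str, set[int]]] = {}
    for e in model.edges.values():
        out_signs.setdefault(e.source, {}).setdefault(e.target, set()).add(e.sign)
    products: set[int] = set()

    def dfs(node: str, sign: int, depth: int, visited: frozenset[str]):
        for nxt, signs in out_signs.get(node, {}).items():
            for s in signs:
                if nxt == target:
                    if depth >= 1:  # at least one unselected intermediate
                        products.add(sign * s)
                elif (depth + 1 < max_len and nxt not in visited
                      and nxt not in selected
                      and model.nodes[nxt].layer == "backbone"):
                    dfs(nxt, sign * s, depth + 1, visited | {nxt})

    dfs(source, 1, 0, frozenset({source}))
    return products


def extract_subgraph(model: NetworkModel, node_ids: list[str],
                     options: SubgraphOptions | None = None) -> NetworkModel:
    """Induced subgraph on ``node_ids``, optionally with path contraction.

    With ``contract_paths`` enabled, selected pairs joined by a directed
    path of at most ``max_path_len`` edges through unselected backbone
    nodes gain an ``indirect`` edge whose sign is the product of the path
    signs; pairs whose qualifying paths disagree on the net sign get no
    edge and are reported in ``metadata['ambiguous_indirect']``.
    """
    options = options or SubgraphOptions()
    unknown = sorted(set(node_ids) - set(model.nodes))
    if unknown:
        raise KeyError(f"unknown node ids: {', '.join(unknown)}")
    selected = set(node_ids)
    out = NetworkModel(f"{model.name}-subgraph", metadata={"parent": model.name})
    for nid in sorted(selected):
        out.nodes[nid] = model.nodes[nid]
    for e in model.edges.values():
        if e.source in selected and e.target in selected:
            out.add_edge(e.source, e.target, e.sign, e.direct,
                         evidences=e.evidences, indirect=e.indirect)
    if options.contract_paths:
        ambiguous = []
        for src in sorted(selected):
            for tgt in sorted(selected):
                if src == tgt:
                    continue
                signs = _sign_products(model, selected, src, tgt, options.max_path_len)
                if len(signs) == 1:
                    sign = next(iter(signs))
                    already = any(e.source == src and e.target == tgt and e.sign == sign
                                  for e in out.edges.values())
                    if not already:  # an induced edge of the same sign supersedes
                        out.add_edge(src, tgt, sign, direct=False, indirect=True)
                elif len(signs) > 1:
                    ambiguous.append((src, tgt))
        out.metadata["ambiguous_indirect"] = sorted(ambiguous)
    return out


def divergence_to_tsv(records: list[DivergenceRecord]) -> str:
    lines = ["node\tcategory\tdirection_first\tdirection_second\tdivergent"]
    for r in records:
        lines.append(f"{r.node}\t{r.category}\t{r.direction_first}\t"
                     f"{r.direction_second}\t{int(r.divergent)}")
    return "\n".join(lines) + "\n"
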