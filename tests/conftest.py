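"""Shared fixtures, hypothesis strategies and independent oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import strategies as st

from cbnscore.bel import ACT_INNER, EvidenceContext, leaf, parse_term, wrap
from cbnscore.model import NetworkModel

# ---------------------------------------------------------------------------
# model builders

EV = EvidenceContext(citation="PMID:1", evidence_text="test evidence")


def model_from_edges(edges, name="test"):
    """Build a model from (source_bel, target_bel, sign[, direct]) tuples."""
    model = NetworkModel(name)
    for edge in edges:
        src, tgt, sign = edge[:3]
        direct = edge[3] if len(edge) > 3 else False
        model.add_edge(parse_term(src), parse_term(tgt), sign, direct,
                       evidences=[EV])
    return model


@pytest.fixture
def small_model():
    """Backbone chain with a bp() anchor and a 3-gene transcript layer."""
    return model_from_edges([
        ("act(p(HGNC:AAA))", "act(p(HGNC:BBB))", +1),
        ("act(p(HGNC:BBB))", 'bp(GOBP:"cell proliferation")', -1),
        ("act(p(HGNC:AAA))", "r(HGNC:G1)", +1),
        ("act(p(HGNC:AAA))", "r(HGNC:G2)", +1),
        ("act(p(HGNC:AAA))", "r(HGNC:G3)", -1),
    ])


# ---------------------------------------------------------------------------
# hypothesis strategies for BEL terms

NAMESPACES = ["HGNC", "GOBP", "GOCC", "MESHD", "SFAM", "PMIBP", "MGI"]
LEAF_FUNCTIONS = ["p", "r", "g", "m", "bp", "path", "complex"]
NAME_ALPHABET = "ABCxyz019_- .κβ\"\\/:(),"

names = st.text(alphabet=NAME_ALPHABET, min_size=1, max_size=12)
leaf_terms = st.builds(leaf, st.sampled_from(LEAF_FUNCTIONS),
                       st.sampled_from(NAMESPACES), names)


def _extend(children):
    act_terms = st.builds(
        lambda a: wrap("act", a),
        children.filter(lambda t: t.function in ACT_INNER))
    complexes = st.builds(
        lambda args: wrap("complex", *args),
        st.lists(children, min_size=1, max_size=3))
    composites = st.builds(
        lambda args: wrap("composite", *args),
        st.lists(children, min_size=1, max_size=3))
    return st.one_of(act_terms, complexes, composites)


bel_terms = st.recursive(leaf_terms, _extend, max_leaves=6)


# ---------------------------------------------------------------------------
# independent oracles

TOL = 1e-12


def perm_pvalue_oracle(universe, signs, s_obs):
    """Brute force over all ordered draws without replacement: the fraction
    of draws whose |signed mean| is at least |s_obs|."""
    n = len(signs)
    hits = total = 0
    for draw in itertools.permutations(universe, n):
        s = sum(s * v for s, v in zip(signs, draw)) / n
        total += 1
        hits += abs(s) >= abs(s_obs) - TOL
    return hits / total


def trim_oracle_keep(node_ids, edges, anchors):
    """Per-node forward DFS: which nodes can reach an anchor (or are one)."""
    adj = {}
    for src, tgt in edges:
        adj.setdefault(src, set()).add(tgt)
    keep = set()
    for start in node_ids:
        stack, seen = [start], {start}
        while stack:
            node = stack.pop()
            if node in anchors:
                keep.add(start)
                break
            for nxt in adj.get(node, ()):
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
    return keep | set(anchors)


def random_backbone_model(rng: np.random.Generator, n_nodes=20, n_edges=30,
                          n_anchors=2, name="random"):
    """Random signed backbone graph over act(p(HGNC:Nxx)) nodes with bp anchors."""
    ids = [f"act(p(HGNC:N{i:02d}))" for i in range(n_nodes)]
    anchor_ids = [f'bp(GOBP:"process {a}")' for a in range(n_anchors)]
    model = NetworkModel(name)
    for nid in ids + anchor_ids:
        model.add_term(parse_term(nid))
    edges = []
    pool = ids + anchor_ids
    for _ in range(n_edges):
        src = ids[rng.integers(0, n_nodes)]
        tgt = pool[rng.integers(0, len(pool))]
        if src == tgt:
            continue
        sign = 1 if rng.random() < 0.5 else -1
        model.add_edge(src, tgt, sign, evidences=[EV])
        edges.append((src, tgt, sign))
    return model, ids, anchor_ids, edges
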