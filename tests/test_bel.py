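"""BEL parsing, rendering, script semantics, compilation and model surgery."""

import random

import pytest
from hypothesis import given, settings

from cbnscore.bel import (BelSyntaxError, leaf, parse_bel_script, parse_statement,
                          parse_term, render_term, wrap)
from cbnscore.model import (compile_statements, merge_models, orthologize,
                            trim_dead_ends)
from conftest import EV, bel_terms, model_from_edges, random_backbone_model, trim_oracle_keep
import numpy as np


class TestTermParsing:
    @pytest.mark.parametrize("text, function, namespace, name", [
        ("p(HGNC:OCLN)", "p", "HGNC", "OCLN"),
        ('bp(PMIBP:"tight junction disruption")', "bp", "PMIBP", "tight junction disruption"),
        ("path(MESHD:Inflammation)", "path", "MESHD", "Inflammation"),
        ('complex(GOCC:"NF-kappaB complex")', "complex", "GOCC", "NF-kappaB complex"),
    ])
    def test_leaf_terms(self, text, function, namespace, name):
        term = parse_term(text)
        assert term.is_leaf
        assert (term.function, term.namespace, term.name) == (function, namespace, name)

    def test_activity_wrapper(self):
        term = parse_term('act(p(SFAM:"TNFRSF Family"))')
        assert not term.is_leaf
        assert term.function == "act"
        inner = term.args[0]
        assert (inner.function, inner.namespace, inner.name) == ("p", "SFAM", "TNFRSF Family")

    def test_whitespace_between_tokens_ignored(self):
        assert parse_term(' act( p( HGNC : MYLK ) ) ') == parse_term("act(p(HGNC:MYLK))")

    @pytest.mark.parametrize("bad", [
        "p(HGNC:OCLN",               # unbalanced parens
        "tloc(p(HGNC:OCLN))",        # unsupported BEL construct
        "p(OCLN)",                   # missing namespace on leaf
        "act(bp(GOBP:x))",           # act over a process
        "p(HGNC:A) p(HGNC:B)",       # trailing text
    ])
    def test_syntax_errors(self, bad):
        with pytest.raises(BelSyntaxError):
            parse_term(bad)

    def test_quoting_rule(self):
        assert render_term(leaf("bp", "GOBP", "cell proliferation")) == \
            'bp(GOBP:"cell proliferation")'
        assert render_term(leaf("path", "MESHD", "Inflammation")) == \
            "path(MESHD:Inflammation)"
        assert render_term(wrap("act", leaf("p", "HGNC", "MYLK"))) == "act(p(HGNC:MYLK))"

    @settings(derandomize=True, max_examples=300)
    @given(bel_terms)
    def test_parse_render_round_trip(self, term):
        assert parse_term(render_term(term)) == term


class TestStatements:
    def test_arrow_shorthand_normalized(self):
        s = parse_statement("act(p(HGNC:STAT5B)) -| act(p(HGNC:PPARG))")
        assert s.relation == "decreases"
        assert s.sign == -1 and not s.direct

    def test_long_form_relation(self):
        s = parse_statement('act(p(HGNC:NOD2)) increases complex(GOCC:"NF-kappaB complex")')
        assert s.relation == "increases" and s.sign == +1

    @pytest.mark.parametrize("arrow, relation, direct", [
        ("->", "increases", False), ("-|", "decreases", False),
        ("=>", "directlyIncreases", True), ("=|", "directlyDecreases", True),
    ])
    def test_all_arrows(self, arrow, relation, direct):
        s = parse_statement(f"p(HGNC:A) {arrow} p(HGNC:B)")
        assert s.relation == relation and s.direct == direct

    def test_unknown_relation_rejected(self):
        with pytest.raises(BelSyntaxError):
            parse_statement('p(HGNC:TNF) ~ bp(GOBP:"wound healing")')

    def test_self_loop_flagged(self):
        s = parse_statement("act(p(HGNC:A)) -> act(p(HGNC:A))")
        assert s.self_loop


class TestScriptParsing:
    SCRIPT = '\n'.join([
        '# a comment',
        'SET Species = "9606"',
        'SET Citation = "PMID:123"',
        'SET Evidence = "TNF disrupts tight junctions"',
        'act(p(HGNC:TNF)) increases bp(PMIBP:"tight junction disruption")',
        'UNSET Species',
        'act(p(HGNC:MYLK)) -| p(HGNC:OCLN)',
    ])

    def test_annotation_state_tracks_lines(self):
        stmts = parse_bel_script(self.SCRIPT)
        assert len(stmts) == 2
        first, second = stmts
        assert first.evidence.annotation_dict() == {"Species": "9606"}
        assert first.evidence.citation == "PMID:123"
        assert first.evidence.evidence_text == "TNF disrupts tight junctions"
        assert second.evidence.annotation_dict() == {}
        assert second.evidence.citation == "PMID:123"

    def test_unknown_set_keys_become_annotations(self):
        stmts = parse_bel_script('SET CellLine = "Caco-2"\np(HGNC:A) -> p(HGNC:B)')
        assert stmts[0].evidence.annotation_dict() == {"CellLine": "Caco-2"}

    def test_empty_script(self):
        assert parse_bel_script("") == []
        assert parse_bel_script("# only a comment\n\n") == []

    def test_error_carries_line_number(self):
        with pytest.raises(BelSyntaxError, match="line 3"):
            parse_bel_script("p(HGNC:A) -> p(HGNC:B)\n\np(HGNC:A) ~ p(HGNC:B)")


class TestCompilation:
    def test_chain_counts(self):
        stmts = [parse_statement(s) for s in [
            "act(p(HGNC:A)) -> act(p(HGNC:B))",
            "act(p(HGNC:B)) -> act(p(HGNC:C))",
        ]]
        model = compile_statements(stmts, "chain")
        assert model.n_nodes == 3 and model.n_edges == 2

    def test_duplicate_statement_merges_evidences(self):
        script = ('SET Citation = "PMID:1"\nact(p(HGNC:A)) -> act(p(HGNC:B))\n'
                  'SET Citation = "PMID:2"\nact(p(HGNC:A)) -> act(p(HGNC:B))\n')
        model = compile_statements(parse_bel_script(script), "dup")
        assert model.n_edges == 1
        edge = next(iter(model.edges.values()))
        assert len(edge.evidences) == 2

    def test_abundance_as_source_lints(self):
        model = compile_statements(
            [parse_statement('p(HGNC:TNF) -> bp(GOBP:"wound healing")')], "lint")
        assert model.n_edges == 1
        assert [w["issue"] for w in model.metadata["lint"]] == ["abundance-as-source"]

    def test_order_invariance(self):
        lines = [f"act(p(HGNC:N{i})) -> act(p(HGNC:N{(i * 3) % 7}))" for i in range(1, 7)]
        stmts = [parse_statement(s) for s in lines]
        shuffled = stmts[:]
        random.Random(0).shuffle(shuffled)
        assert compile_statements(stmts, "a").structurally_equal(
            compile_statements(shuffled, "b"))

    def test_opposite_signs_kept_as_two_edges(self):
        stmts = [parse_statement("act(p(HGNC:A)) -> r(HGNC:G1)"),
                 parse_statement("act(p(HGNC:A)) -| r(HGNC:G1)")]
        model = compile_statements(stmts, "amb")
        assert model.n_edges == 2
        assert model.ambivalent_pairs() == {("act(p(HGNC:A))", "r(HGNC:G1)")}


class TestOrthologize:
    def test_rodent_symbol_mapped(self):
        model = model_from_edges([("p(MGI:Tnf)", 'bp(GOBP:"wound healing")', +1)])
        result = orthologize(model, {"Tnf": "TNF"})
        assert "p(HGNC:TNF)" in result.model.nodes
        assert "p(MGI:Tnf)" not in result.model.nodes
        assert result.unmapped == []

    def test_identity_on_all_hgnc_model(self, small_model):
        result = orthologize(small_model, {"Tnf": "TNF"})
        assert result.model.structurally_equal(small_model)

    def test_fusion_unions_edges(self):
        model = model_from_edges([
            ("p(MGI:Tnf)", "act(p(HGNC:X))", +1),
            ("p(HGNC:TNF)", "act(p(HGNC:Y))", -1),
        ])
        result = orthologize(model, {"Tnf": "TNF"})
        assert result.model.n_nodes == 3
        assert len(result.model.out_edges("p(HGNC:TNF)")) == 2

    def test_unmapped_reported_and_kept(self):
        model = model_from_edges([("p(RGD:Il6)", "act(p(HGNC:X))", +1)])
        result = orthologize(model, {})
        assert "p(RGD:Il6)" in result.model.nodes
        assert result.unmapped == ["RGD:Il6"]


class TestTrim:
    def test_isolated_branch_removed(self):
        model = model_from_edges([
            ("act(p(HGNC:A))", "act(p(HGNC:B))", +1),
            ("act(p(HGNC:B))", "bp(GOBP:X)", +1),
            ("act(p(HGNC:C))", "act(p(HGNC:D))", +1),
        ])
        result = trim_dead_ends(model)
        assert set(result.model.nodes) == {"act(p(HGNC:A))", "act(p(HGNC:B))", "bp(GOBP:X)"}
        assert {nid for nid, _ in result.removed} == {"act(p(HGNC:C))", "act(p(HGNC:D))"}

    def test_identity_when_all_reach_anchor(self, small_model):
        result = trim_dead_ends(small_model)
        assert result.model.structurally_equal(small_model)
        assert result.removed == []

    def test_cascading_dead_ends(self):
        # C -> D where D is the only outlet; both fall in one pass
        model = model_from_edges([
            ("act(p(HGNC:A))", "bp(GOBP:X)", +1),
            ("act(p(HGNC:C))", "act(p(HGNC:D))", +1),
            ("act(p(HGNC:D))", "act(p(HGNC:E))", -1),
        ])
        result = trim_dead_ends(model)
        assert set(result.model.nodes) == {"act(p(HGNC:A))", "bp(GOBP:X)"}

    def test_no_anchor_returns_unchanged_with_warning(self):
        model = model_from_edges([("act(p(HGNC:A))", "act(p(HGNC:B))", +1)])
        result = trim_dead_ends(model)
        assert result.model.structurally_equal(model)
        assert result.warning is not None

    def test_idempotent_and_shrinking(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            model, *_ = random_backbone_model(rng)
            once = trim_dead_ends(model)
            twice = trim_dead_ends(once.model)
            assert twice.model.structurally_equal(once.model)
            assert set(once.model.nodes) <= set(model.nodes)

    def test_matches_reachability_oracle_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            model, ids, anchor_ids, edges = random_backbone_model(rng)
            keep = trim_oracle_keep(ids, [(s, t) for s, t, _ in edges], set(anchor_ids))
            result = trim_dead_ends(model)
            assert set(result.model.nodes) == keep

    def test_transcripts_follow_their_backbone(self):
        model = model_from_edges([
            ("act(p(HGNC:A))", "bp(GOBP:X)", +1),
            ("act(p(HGNC:A))", "r(HGNC:G1)", +1),
            ("act(p(HGNC:C))", "r(HGNC:G2)", +1),
        ])
        result = trim_dead_ends(model)
        assert "r(HGNC:G1)" in result.model.nodes
        assert "r(HGNC:G2)" not in result.model.nodes


class TestMerge:
    def test_self_merge_idempotent(self, small_model):
        merged = merge_models([small_model, small_model], "m")
        assert merged.structurally_equal(small_model)

    def test_commutative(self, small_model):
        other = model_from_edges([("act(p(HGNC:ZZZ))", "bp(GOBP:Y)", +1)])
        ab = merge_models([small_model, other], "ab")
        ba = merge_models([other, small_model], "ba")
        assert ab.structurally_equal(ba)

    def test_disjoint_and_shared_counts(self):
        m1 = model_from_edges([("act(p(HGNC:A))", "act(p(HGNC:B))", +1)])
        m2 = model_from_edges([("act(p(HGNC:C))", "act(p(HGNC:D))", +1)])
        m3 = model_from_edges([("act(p(HGNC:B))", "act(p(HGNC:E))", +1)])
        assert merge_models([m1, m2], "x").n_nodes == 4
        assert merge_models([m1, m3], "y").n_nodes == 3

    def test_evidence_union_not_duplicated(self, small_model):
        merged = merge_models([small_model, small_model], "m")
        for edge in merged.edges.values():
            assert len(edge.evidences) == 1
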