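"""Parsing and rendering of a BEL 1.0 subset.

The subset covers the vocabulary used by causal biological network (CBN)
models: nine entity functions (``p``, ``act``, ``r``, ``g``, ``m``, ``bp``,
``path``, ``complex``, ``composite``) and the four causal relations
(``increases``, ``decreases``, ``directlyIncreases``, ``directlyDecreases``,
plus their arrow shorthands ``->``, ``-|``, ``=>``, ``=|``).  Other BEL 1.0
constructs (translocation, degradation, hasComponent, ...) are rejected with
an explicit error.

A script file consists of statement lines interleaved with annotation
state commands::

    SET Species = "9606"
    SET Citation = "PMID:12345"
    SET Evidence = "TNF disrupts tight junctions"
    act(p(HGNC:TNF)) increases bp(PMIBP:"tight junction disruption")
    UNSET Species

Comment lines start with ``#``.  Each parsed statement carries the
annotation state active at its line.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "FUNCTIONS",
    "RELATIONS",
    "BelSyntaxError",
    "BelTerm",
    "EvidenceContext",
    "CausalStatement",
    "leaf",
    "wrap",
    "parse_term",
    "render_term",
    "parse_statement",
    "parse_bel_script",
]

#: Entity functions supported by the subset.
FUNCTIONS = frozenset({"p", "act", "r", "g", "m", "bp", "path", "complex", "composite"})

#: Functions that ``act()`` may wrap (activity of a protein, complex, gene or microRNA).
ACT_INNER = frozenset({"p", "complex", "g", "m"})

#: Causal relation keywords mapped to (sign, direct).
RELATIONS = {
    "increases": (+1, False),
    "decreases": (-1, False),
    "directlyIncreases": (+1, True),
    "directlyDecreases": (-1, True),
}

#: Arrow shorthands mapped to long-form relation keywords.
ARROWS = {"->": "increases", "-|": "decreases", "=>": "directlyIncreases", "=|": "directlyDecreases"}

_UNQUOTED_NAME = re.compile(r"[A-Za-z0-9_-]+\Z")
_NAMESPACE = re.compile(r"[A-Za-z0-9_]+\Z")


class BelSyntaxError(ValueError):
    """Raised on malformed BEL input; carries the character (and line) position."""

    def __init__(self, message: str, pos: int | None = None, line: int | None = None):
        loc = ""
        if line is not None:
            loc += f" at line {line}"
        if pos is not None:
            loc += f" at position {pos}"
        super().__init__(message + loc)
        self.pos = pos
        self.line = line


@dataclass(frozen=True)
class BelTerm:
    """A BEL entity term: either a namespaced leaf or a wrapper with arguments.

    A leaf term has a ``namespace`` and ``name`` and no ``args``; a wrapper
    term (e.g. ``act(...)``, ``complex(a, b)``) has one or more ``args`` and
    no namespace/name.
    """

    function: str
    namespace: str | None = None
    name: str | None = None
    args: tuple["BelTerm", ...] = ()

    def __post_init__(self):
        if self.function not in FUNCTIONS:
            raise BelSyntaxError(f"unknown BEL function {self.function!r}")
        if self.args and (self.namespace is not None or self.name is not None):
            raise BelSyntaxError("term cannot have both a namespace:name and arguments")
        if not self.args:
            if self.namespace is None or self.name is None:
                raise BelSyntaxError(f"leaf term {self.function}() requires namespace:name")
            if not _NAMESPACE.match(self.namespace):
                raise BelSyntaxError(f"invalid namespace {self.namespace!r}")
            if self.name == "":
                raise BelSyntaxError("empty term name")
        if self.function == "act":
            if len(self.args) != 1 or self.args[0].function not in ACT_INNER:
                raise BelSyntaxError("act() takes exactly one p/complex/g/m argument")

    @property
    def is_leaf(self) -> bool:
        return not self.args

    @property
    def canonical(self) -> str:
        """Single-line text rendering; injective on term structure."""
        return render_term(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical


def leaf(function: str, namespace: str, name: str) -> BelTerm:
    """Build a leaf term such as ``p(HGNC:OCLN)``."""
    return BelTerm(function, namespace=namespace, name=name)


def wrap(function: str, *args: BelTerm) -> BelTerm:
    """Build a wrapper term such as ``act(p(HGNC:MYLK))``."""
    return BelTerm(function, args=tuple(args))


@dataclass(frozen=True)
class EvidenceContext:
    """Provenance of a causal statement: citation, evidence sentence, annotations."""

    citation: str = ""
    evidence_text: str = ""
    annotations: tuple[tuple[str, str], ...] = ()

    def annotation_dict(self) -> dict[str, str]:
        return dict(self.annotations)

    def key(self) -> tuple:
        """Deduplication key (citation, evidence, sorted annotations)."""
        return (self.citation, self.evidence_text, tuple(sorted(self.annotations)))


@dataclass(frozen=True)
class CausalStatement:
    """Signed causal relation between two BEL terms, with evidence context."""

    subject: BelTerm
    relation: str
    object: BelTerm
    evidence: EvidenceContext = field(default_factory=EvidenceContext)

    def __post_init__(self):
        if self.relation not in RELATIONS:
            raise BelSyntaxError(f"unknown relation {self.relation!r}")

    @property
    def sign(self) -> int:
        return RELATIONS[self.relation][0]

    @property
    def direct(self) -> bool:
        return RELATIONS[self.relation][1]

    @property
    def self_loop(self) -> bool:
        return self.subject.canonical == self.object.canonical


# ---------------------------------------------------------------------------
# rendering

def _render_name(name: str) -> str:
    if _UNQUOTED_NAME.match(name):
        return name
    escaped = name.replace("\\", "\\\\").replace('"', '\\"')
    return f'"{escaped}"'


def render_term(term: BelTerm) -> str:
    """Render a term to its canonical single-line form.

    Names containing characters outside ``[A-Za-z0-9_-]`` are double-quoted
    (with backslash escaping); other names are left bare, so
    ``parse_term(render_term(t)) == t`` for every valid term.
    """
    if term.is_leaf:
        return f"{term.function}({term.namespace}:{_render_name(term.name)})"
    inner = ", ".join(render_term(a) for a in term.args)
    return f"{term.function}({inner})"


# ---------------------------------------------------------------------------
# parsing

class _Cursor:
    def __init__(self, text: str, line: int | None = None):
        self.text = text
        self.pos = 0
        self.line = line

    def error(self, message: str) -> BelSyntaxError:
        return BelSyntaxError(message, pos=self.pos, line=self.line)

    def skip_ws(self):
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def expect(self, ch: str):
        if self.peek() != ch:
            raise self.error(f"expected {ch!r}")
        self.pos += 1

    def ident(self) -> str:
        m = re.compile(r"[A-Za-z0-9_-]+").match(self.text, self.pos)
        if not m:
            raise self.error("expected identifier")
        self.pos = m.end()
        return m.group()

    def quoted(self) -> str:
        assert self.peek() == '"'
        self.pos += 1
        out = []
        while True:
            if self.pos >= len(self.text):
                raise self.error("unterminated quoted string")
            ch = self.text[self.pos]
            if ch == "\\" and self.pos + 1 < len(self.text):
                out.append(self.text[self.pos + 1])
                self.pos += 2
            elif ch == '"':
                self.pos += 1
                return "".join(out)
            else:
                out.append(ch)
                self.pos += 1


def _parse_term_at(cur: _Cursor) -> BelTerm:
    cur.skip_ws()
    func = cur.ident()
    if func not in FUNCTIONS:
        raise cur.error(f"unknown BEL function {func!r}")
    cur.skip_ws()
    cur.expect("(")
    cur.skip_ws()
    # Decide between leaf body (NS:name) and argument list (term, term, ...):
    # an argument starts with a function name followed by '('.
    save = cur.pos
    try:
        first = cur.ident()
    except BelSyntaxError:
        first = None
    cur.skip_ws()
    if first in FUNCTIONS and cur.peek() == "(":
        cur.pos = save
        args = [_parse_term_at(cur)]
        cur.skip_ws()
        while cur.peek() == ",":
            cur.pos += 1
            args.append(_parse_term_at(cur))
            cur.skip_ws()
        cur.expect(")")
        try:
            return BelTerm(func, args=tuple(args))
        except BelSyntaxError as exc:
            raise cur.error(str(exc))
    # leaf body
    if first is None:
        raise cur.error(f"missing namespace in {func}() leaf term")
    namespace = first
    if cur.peek() != ":":
        raise cur.error(f"missing namespace separator ':' in {func}() leaf term")
    cur.pos += 1
    cur.skip_ws()
    if cur.peek() == '"':
        name = cur.quoted()
    else:
        name = cur.ident()
    cur.skip_ws()
    cur.expect(")")
    try:
        return BelTerm(func, namespace=namespace, name=name)
    except BelSyntaxError as exc:
        raise cur.error(str(exc))


def parse_term(text: str, line: int | None = None) -> BelTerm:
    """Parse a single BEL term expression.

    Raises :class:`BelSyntaxError` (with character position) for unbalanced
    parentheses, unknown functions, or a leaf without a namespace.
    """
    cur = _Cursor(text, line=line)
    term = _parse_term_at(cur)
    cur.skip_ws()
    if cur.pos != len(cur.text):
        raise cur.error("unexpected trailing text after term")
    return term


def _parse_relation(cur: _Cursor) -> str:
    cur.skip_ws()
    for arrow, name in ARROWS.items():
        if cur.text.startswith(arrow, cur.pos):
            cur.pos += len(arrow)
            return name
    m = re.compile(r"[A-Za-z]+").match(cur.text, cur.pos)
    word = m.group() if m else cur.text[cur.pos : cur.pos + 10]
    if m and m.group() in RELATIONS:
        cur.pos = m.end()
        return m.group()
    raise cur.error(f"unknown relation {word!r}")


def parse_statement(line: str, lineno: int | None = None,
                    evidence: EvidenceContext | None = None) -> CausalStatement:
    """Parse ``<subject term> <relation> <object term>``.

    The relation may be a long-form keyword or one of the arrow shorthands;
    it is normalized to the long form.  Evidence defaults to an empty
    context (the script parser fills it in).
    """
    cur = _Cursor(line, line=lineno)
    subject = _parse_term_at(cur)
    relation = _parse_relation(cur)
    obj = _parse_term_at(cur)
    cur.skip_ws()
    if cur.pos != len(cur.text):
        raise cur.error("unexpected trailing text after statement")
    return CausalStatement(subject, relation, obj, evidence or EvidenceContext())


_SET_RE = re.compile(r"SET\s+([A-Za-z_][A-Za-z0-9_]*)\s*=\s*(.*)\Z")
_UNSET_RE = re.compile(r"UNSET\s+([A-Za-z_][A-Za-z0-9_]*|ALL)\s*\Z")


def _unquote(value: str) -> str:
    value = value.strip()
    if len(value) >= 2 and value[0] == '"' and value[-1] == '"':
        return value[1:-1].replace('\\"', '"').replace("\\\\", "\\")
    return value


def parse_bel_script(text: str) -> list[CausalStatement]:
    """Parse a multi-line BEL script into statements with annotation state.

    ``SET Citation`` and ``SET Evidence`` populate the corresponding
    evidence fields; any other ``SET`` key becomes a generic annotation
    (e.g. Species, CellLine, Disease).  ``UNSET <key>`` removes one
    annotation, ``UNSET ALL`` clears all.  Statement-level syntax errors
    propagate with their line number.
    """
    citation = ""
    evidence_text = ""
    annotations: dict[str, str] = {}
    statements: list[CausalStatement] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            continue
        m = _SET_RE.match(stripped)
        if m:
            key, value = m.group(1), _unquote(m.group(2))
            if key == "Citation":
                citation = value
            elif key == "Evidence":
                evidence_text = value
            else:
                annotations[key] = value
            continue
        m = _UNSET_RE.match(stripped)
        if m:
            key = m.group(1)
            if key == "ALL":
                citation = ""
                evidence_text = ""
                annotations.clear()
            elif key == "Citation":
                citation = ""
            elif key == "Evidence":
                evidence_text = ""
            else:
                annotations.pop(key, None)
            continue
        ctx = EvidenceContext(
            citation=citation,
            evidence_text=evidence_text,
            annotations=tuple(sorted(annotations.items())),
        )
        statements.append(parse_statement(stripped, lineno=lineno, evidence=ctx))
    return statements


def render_statement(stmt: CausalStatement) -> str:
    """Render a statement line (long-form relation)."""
    return f"{stmt.subject.canonical} {stmt.relation} {stmt.object.canonical}"
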