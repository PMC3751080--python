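"""Gene–protein–reaction (GPR) rules.

A GPR rule is a Boolean expression over gene identifiers stating the genetic
requirement for a reaction to carry flux: ``and`` joins subunits of a complex
(all required), ``or`` joins isozymes (any suffices).  The grammar has no
negation, so deleting more genes can only switch rules from true to false —
the monotonicity that makes deletion screens well defined.

Grammar::

    expr   := term  (OR  term)*
    term   := factor (AND factor)*
    factor := IDENT | "(" expr ")"

Keywords ``and``/``or`` are case-insensitive; ``&``/``|`` are accepted as
synonyms (the MATLAB Toolbox dialect).  Identifiers may contain letters,
digits, dots, underscores and hyphens (covers locus tags such as ``b0008``
or ``STM1234``).  ``and`` binds tighter than ``or``.  An empty or
whitespace-only rule means the reaction is spontaneous and is represented by
``None``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "GprExpression",
    "GprParseError",
    "parse_gpr",
    "evaluate_gpr",
    "genes_of",
    "format_gpr",
    "rules_to_gpr_text",
    "gpr_text_to_rules",
]

GENE = "GENE"
AND = "AND"
OR = "OR"


@dataclass(frozen=True)
class GprExpression:
    """Node of a parsed GPR tree.

    ``kind`` is one of ``GENE`` (leaf; ``gene`` set), ``AND`` or ``OR``
    (``children`` holds >= 2 sub-expressions).  Same-kind operators are
    flattened into a single n-ary node, so ``a and b and c`` and
    ``(a and b) and c`` produce identical trees.
    """

    kind: str
    gene: Optional[str] = None
    children: tuple["GprExpression", ...] = field(default=())

    def __post_init__(self) -> None:
        if self.kind == GENE:
            if not self.gene:
                raise ValueError("GENE node requires a gene id")
        elif self.kind in (AND, OR):
            if len(self.children) < 2:
                raise ValueError(f"{self.kind} node requires >= 2 children")
        else:
            raise ValueError(f"unknown node kind {self.kind!r}")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.kind == GENE:
            return f"Gene({self.gene})"
        return f"{self.kind}({', '.join(map(repr, self.children))})"


class GprParseError(ValueError):
    """Raised for malformed rule text; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def gene_node(gene_id: str) -> GprExpression:
    return GprExpression(GENE, gene=gene_id)


def make_node(kind: str, children: list[GprExpression]) -> GprExpression:
    """Build an AND/OR node, flattening same-kind children (canonical form)."""
    if len(children) == 1:
        return children[0]
    flat: list[GprExpression] = []
    for child in children:
        if child.kind == kind:
            flat.extend(child.children)
        else:
            flat.append(child)
    return GprExpression(kind, children=tuple(flat))


_TOKEN_RE = re.compile(
    r"""
    (?P<WS>\s+)
  | (?P<LPAR>\()
  | (?P<RPAR>\))
  | (?P<AMP>&&?)
  | (?P<PIPE>\|\|?)
  | (?P<IDENT>[A-Za-z0-9._-]+)
    """,
    re.VERBOSE,
)

_KEYWORDS = {"and": AND, "or": OR}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise GprParseError(f"illegal character {text[pos]!r}", pos)
        kind = m.lastgroup
        value = m.group()
        if kind == "IDENT":
            lowered = value.lower()
            if lowered in _KEYWORDS:
                tokens.append((_KEYWORDS[lowered], value, pos))
            else:
                tokens.append(("IDENT", value, pos))
        elif kind == "AMP":
            tokens.append((AND, value, pos))
        elif kind == "PIPE":
            tokens.append((OR, value, pos))
        elif kind in ("LPAR", "RPAR"):
            tokens.append((kind, value, pos))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str, int]], length: int):
        self.tokens = tokens
        self.i = 0
        self.length = length

    def peek(self) -> Optional[tuple[str, str, int]]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def advance(self) -> tuple[str, str, int]:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expr(self) -> GprExpression:
        terms = [self.term()]
        while (tok := self.peek()) is not None and tok[0] == OR:
            self.advance()
            terms.append(self.term())
        return make_node(OR, terms)

    def term(self) -> GprExpression:
        factors = [self.factor()]
        while (tok := self.peek()) is not None and tok[0] == AND:
            self.advance()
            factors.append(self.factor())
        return make_node(AND, factors)

    def factor(self) -> GprExpression:
        tok = self.peek()
        if tok is None:
            raise GprParseError("dangling operator: expected identifier", self.length)
        kind, value, pos = tok
        if kind == "IDENT":
            self.advance()
            return gene_node(value)
        if kind == "LPAR":
            self.advance()
            inner = self.expr()
            closing = self.peek()
            if closing is None or closing[0] != "RPAR":
                raise GprParseError("unbalanced parentheses: missing ')'", pos)
            self.advance()
            return inner
        raise GprParseError(f"unexpected token {value!r}", pos)


def parse_gpr(text: Optional[str]) -> Optional[GprExpression]:
    """Parse rule text into a :class:`GprExpression`; ``None`` for empty text.

    Raises :class:`GprParseError` for unbalanced parentheses, dangling
    operators or illegal characters, with the character position.
    """
    if text is None or not text.strip():
        return None
    tokens = _tokenize(text)
    parser = _Parser(tokens, len(text))
    expr = parser.expr()
    trailing = parser.peek()
    if trailing is not None:
        raise GprParseError(f"unexpected trailing token {trailing[1]!r}", trailing[2])
    return expr


def evaluate_gpr(expr: Optional[GprExpression], deleted_genes: set[str]) -> bool:
    """True iff the genetic requirement is met with ``deleted_genes`` removed.

    Empty rules (spontaneous reactions) are always satisfied.
    """
    if expr is None:
        return True
    if expr.kind == GENE:
        return expr.gene not in deleted_genes
    if expr.kind == AND:
        return all(evaluate_gpr(c, deleted_genes) for c in expr.children)
    return any(evaluate_gpr(c, deleted_genes) for c in expr.children)


def genes_of(expr: Optional[GprExpression]) -> set[str]:
    """The set of distinct gene ids appearing in the rule (empty for ``None``)."""
    if expr is None:
        return set()
    if expr.kind == GENE:
        return {expr.gene}
    out: set[str] = set()
    for child in expr.children:
        out |= genes_of(child)
    return out


def format_gpr(expr: Optional[GprExpression]) -> str:
    """Canonical rule text; ``parse_gpr(format_gpr(e))`` is structurally ``e``."""
    if expr is None:
        return ""
    if expr.kind == GENE:
        return expr.gene
    sep = " and " if expr.kind == AND else " or "
    parts = []
    for child in expr.children:
        text = format_gpr(child)
        if child.kind != GENE:
            text = f"({text})"
        parts.append(text)
    return sep.join(parts)


_INDEX_RE = re.compile(r"x\(\s*(\d+)\s*\)")


def rules_to_gpr_text(rule: str, genes: list[str]) -> str:
    """Translate a Toolbox index-based rule (``x(1) & x(2)``) to gene-id text.

    Indices are 1-based into ``genes``.  Empty rules map to "".
    """
    if not rule or not rule.strip():
        return ""

    def repl(m: re.Match) -> str:
        idx = int(m.group(1))
        if not 1 <= idx <= len(genes):
            raise GprParseError(f"gene index x({idx}) out of range (1..{len(genes)})", m.start())
        return genes[idx - 1]

    translated = _INDEX_RE.sub(repl, rule)
    return format_gpr(parse_gpr(translated))


def gpr_text_to_rules(text: str, genes: list[str]) -> str:
    """Inverse of :func:`rules_to_gpr_text`: gene-id rule to index-based rule."""
    expr = parse_gpr(text)
    if expr is None:
        return ""
    index = {g: i + 1 for i, g in enumerate(genes)}

    def fmt(e: GprExpression) -> str:
        if e.kind == GENE:
            if e.gene not in index:
                raise KeyError(f"gene {e.gene!r} not in model gene list")
            return f"x({index[e.gene]})"
        sep = " & " if e.kind == AND else " | "
        parts = []
        for child in e.children:
            part = fmt(child)
            if child.kind != GENE:
                part = f"({part})"
            parts.append(part)
        return sep.join(parts)

    return fmt(expr)
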