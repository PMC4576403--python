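"""Rule-based leukocyte population queries over cluster level vectors.

A query is a boolean predicate over per-channel ordinal levels (1–4), built
from atoms ``channel comparator level`` with comparators ``=``, ``≤``, ``≥``
(ASCII ``<=``/``>=`` accepted), combined with AND/OR and parentheses — e.g.
the classic scatter gates ``FSC ≤ 2 AND SSC = 1`` (small agranular cells:
lymphocytes) or ``FSC ≥ 1 AND SSC = 4`` (maximally granular cells:
hypergranular granulocytes).  Applying a query to a sample's gating returns
the summed percentage (of total events) of all clusters whose level vector
satisfies the predicate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Union

from .autogate import SampleGating
from .events import CHANNELS

__all__ = [
    "Atom",
    "And",
    "Or",
    "PopulationQuery",
    "QueryParseError",
    "parse_query",
    "apply_query",
    "builtin_queries",
    "BUILTIN_QUERY_TEXT",
]

MIN_LEVEL, MAX_LEVEL = 1, 4

_COMPARATORS = {"=": "=", "≤": "≤", "<=": "≤", "≥": "≥", ">=": "≥"}


class QueryParseError(ValueError):
    """Malformed query expression; the message names the offending token."""


@dataclass(frozen=True)
class Atom:
    channel: str
    comparator: str  # canonical: '=', '≤', '≥'
    level: int

    def evaluate(self, levels: dict[str, int]) -> bool:
        v = levels[self.channel]
        if self.comparator == "=":
            return v == self.level
        if self.comparator == "≤":
            return v <= self.level
        return v >= self.level

    def text(self) -> str:
        return f"{self.channel} {self.comparator} {self.level}"


@dataclass(frozen=True)
class And:
    terms: tuple["Node", ...]

    def evaluate(self, levels: dict[str, int]) -> bool:
        return all(t.evaluate(levels) for t in self.terms)

    def text(self) -> str:
        return " AND ".join(
            f"({t.text()})" if isinstance(t, Or) else t.text() for t in self.terms
        )


@dataclass(frozen=True)
class Or:
    terms: tuple["Node", ...]

    def evaluate(self, levels: dict[str, int]) -> bool:
        return any(t.evaluate(levels) for t in self.terms)

    def text(self) -> str:
        return " OR ".join(
            f"({t.text()})" if isinstance(t, And) else t.text() for t in self.terms
        )


Node = Union[Atom, And, Or]


@dataclass(frozen=True)
class PopulationQuery:
    """A named predicate over channel levels."""

    name: str
    predicate: Node

    def text(self) -> str:
        """Canonical text form; re-parsing it yields an equivalent query."""
        return self.predicate.text()


_TOKEN_RE = re.compile(r"\s*(\(|\)|<=|>=|≤|≥|=|AND\b|OR\b|[A-Za-z][A-Za-z0-9]*|\d+)")


def _tokenize(expression: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(expression):
        m = _TOKEN_RE.match(expression, pos)
        if m is None:
            rest = expression[pos:].strip()
            raise QueryParseError(f"unrecognized token at {rest[:12]!r}")
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser: or_expr := and_expr (OR and_expr)* ..."""

    def __init__(self, tokens: list[str], channels: tuple[str, ...]):
        self.tokens = tokens
        self.pos = 0
        self.channels = channels

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def advance(self) -> str:
        tok = self.peek()
        if tok is None:
            raise QueryParseError("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> Node:
        node = self.or_expr()
        if self.peek() is not None:
            raise QueryParseError(f"unexpected trailing token {self.peek()!r}")
        return node

    def or_expr(self) -> Node:
        terms = [self.and_expr()]
        while self.peek() == "OR":
            self.advance()
            terms.append(self.and_expr())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def and_expr(self) -> Node:
        terms = [self.atom_or_group()]
        while self.peek() == "AND":
            self.advance()
            terms.append(self.atom_or_group())
        return terms[0] if len(terms) == 1 else And(tuple(terms))

    def atom_or_group(self) -> Node:
        tok = self.advance()
        if tok == "(":
            node = self.or_expr()
            if self.advance() != ")":
                raise QueryParseError("missing closing parenthesis")
            return node
        if tok not in self.channels:
            raise QueryParseError(f"unknown channel {tok!r}")
        comp = self.advance()
        if comp not in _COMPARATORS:
            raise QueryParseError(f"expected comparator after {tok}, got {comp!r}")
        level_tok = self.advance()
        if not level_tok.isdigit():
            raise QueryParseError(f"expected level after comparator, got {level_tok!r}")
        level = int(level_tok)
        if not MIN_LEVEL <= level <= MAX_LEVEL:
            raise QueryParseError(
                f"level {level} outside {MIN_LEVEL}..{MAX_LEVEL} in atom for {tok}"
            )
        return Atom(tok, _COMPARATORS[comp], level)


def parse_query(
    expression: str,
    name: str = "",
    channels: tuple[str, ...] = CHANNELS,
) -> PopulationQuery:
    """Parse a query expression into a :class:`PopulationQuery`.

    Raises :class:`QueryParseError` naming the offending token for unknown
    channels, malformed syntax, or levels outside 1..4.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise QueryParseError("empty expression")
    node = _Parser(tokens, channels).parse()
    return PopulationQuery(name=name or expression, predicate=node)


#: Clusters negative on both scatter channels are debris-like.
_DEBRIS_PREDICATE = And((Atom("FSC", "=", 1), Atom("SSC", "=", 1)))


def apply_query(
    gating: SampleGating, query: PopulationQuery, exclude_debris: bool = False
) -> float:
    """Percentage of total events in clusters satisfying the query.

    Sums ``percent_of_total`` over every cluster whose level vector satisfies
    the predicate; 0 if none does.  By default the denominator is the total
    cell population, debris included; with ``exclude_debris`` clusters that
    are negative on both scatter channels (FSC = 1 and SSC = 1) are dropped
    from both numerator and denominator.
    """
    if not exclude_debris:
        return float(
            sum(
                c.percent_of_total
                for c in gating.clusters
                if query.predicate.evaluate(c.levels)
            )
        )
    kept = [c for c in gating.clusters if not _DEBRIS_PREDICATE.evaluate(c.levels)]
    denom = sum(c.percent_of_total for c in kept)
    if denom == 0.0:
        return 0.0
    num = sum(c.percent_of_total for c in kept if query.predicate.evaluate(c.levels))
    return float(100.0 * num / denom)


#: The ten built-in population definitions over the 1-4 level scale.
BUILTIN_QUERY_TEXT: dict[str, str] = {
    "Total lymphocytes": "FSC ≤ 2 AND SSC = 1",
    "CD1c+ lymphocytes": "FSC ≤ 2 AND SSC = 1 AND CD1c ≥ 2",
    "CD5+ lymphocytes": "FSC ≤ 2 AND SSC = 1 AND CD5 ≥ 2",
    "CD19+ lymphocytes": "FSC ≤ 2 AND SSC = 1 AND CD19 ≥ 2",
    "CD21+ lymphocytes": "FSC ≤ 2 AND SSC = 1 AND CD21 ≥ 2",
    "CD23+ lymphocytes": "FSC ≤ 2 AND SSC = 1 AND CD23 ≥ 2",
    "Total monocytes": "FSC ≥ 3 AND SSC ≤ 2",
    "Total granulocytes": "((FSC ≥ 3 AND SSC ≥ 3) OR (FSC ≤ 2 AND SSC ≥ 2))",
    "Hypergranular granulocytes": "FSC ≥ 1 AND SSC = 4",
    "Hypogranular granulocytes": (
        "(FSC ≤ 2 AND SSC = 3) OR (FSC ≤ 2 AND SSC = 2) OR (FSC ≥ 3 AND SSC = 3)"
    ),
}


def builtin_queries() -> list[PopulationQuery]:
    """The ten standard leukocyte population queries."""
    return [parse_query(expr, name=name) for name, expr in BUILTIN_QUERY_TEXT.items()]
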