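"""Boolean rule expressions: syntax trees, parsing, and evaluation.

A rule is a Boolean function over named regulators, written with NOT/AND/OR
and parentheses.  The published rule tables this package targets use the
glyphs ``˄`` (AND), ``˅`` (OR) and ``¬`` (NOT); the parser also accepts the
ASCII spellings ``&``/``AND``, ``|``/``OR``, ``!``/``NOT`` and the unicode
logic symbols ``∧ ∨``.  Operator precedence is NOT > AND > OR, with AND/OR
left-associative and flattened into n-ary nodes.

Printed rule tables are occasionally damaged: a rule may open a parenthesis
that is never closed.  Such expressions have exactly one consistent reading
(close every open group at end of expression), so the parser repairs them
and reports the repair rather than refusing the rule.  Repairs are emitted
as WARNING log records and returned to callers that ask for them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "BooleanExpression",
    "Var",
    "Not",
    "And",
    "Or",
    "RuleParseError",
    "UnknownNameError",
    "parse_rule",
]


class RuleParseError(ValueError):
    """Raised when rule text cannot be read as a Boolean expression."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class UnknownNameError(RuleParseError):
    """Raised when a rule references a name outside the declared vocabulary."""

    def __init__(self, name: str, position: int | None = None, vocabulary=None):
        msg = f"unknown identifier {name!r}"
        if vocabulary:
            msg += f"; declared names are {sorted(vocabulary)}"
        super().__init__(msg, position)
        self.name = name


class BooleanExpression:
    """Base class for rule syntax-tree nodes."""

    __slots__ = ()

    def evaluate(self, valuation: Mapping[str, object]):
        """Evaluate under ``valuation`` (name -> 0/1 scalar or bit array).

        Uses only ``&``, ``|`` and ``^ 1``, so the same tree evaluates
        pointwise over numpy integer arrays of 0/1 bits, which is how the
        exhaustive state-space engine vectorises rules.  The valuation is
        never mutated.
        """
        raise NotImplementedError

    def leaves(self) -> frozenset[str]:
        """Names of all regulators referenced by this expression."""
        raise NotImplementedError

    def __call__(self, valuation: Mapping[str, object]):
        return self.evaluate(valuation)


@dataclass(frozen=True, slots=True)
class Var(BooleanExpression):
    name: str

    def evaluate(self, valuation):
        try:
            return valuation[self.name]
        except KeyError:
            raise KeyError(
                f"valuation does not define regulator {self.name!r}"
            ) from None

    def leaves(self):
        return frozenset((self.name,))

    def __str__(self):
        return self.name


@dataclass(frozen=True, slots=True)
class Not(BooleanExpression):
    child: BooleanExpression

    def evaluate(self, valuation):
        return self.child.evaluate(valuation) ^ 1

    def leaves(self):
        return self.child.leaves()

    def __str__(self):
        return f"!{self.child}" if isinstance(self.child, (Var, Not)) else f"!({self.child})"


def _nary_init(self, children: Sequence[BooleanExpression]):
    children = tuple(children)
    if len(children) < 2:
        raise ValueError(f"{type(self).__name__} requires at least 2 children")
    object.__setattr__(self, "children", children)


@dataclass(frozen=True, init=False, slots=True)
class And(BooleanExpression):
    children: tuple[BooleanExpression, ...]

    __init__ = _nary_init

    def evaluate(self, valuation):
        out = self.children[0].evaluate(valuation)
        for child in self.children[1:]:
            out = out & child.evaluate(valuation)
        return out

    def leaves(self):
        return frozenset().union(*(c.leaves() for c in self.children))

    def __str__(self):
        return " & ".join(
            str(c) if isinstance(c, (Var, Not)) else f"({c})" for c in self.children
        )


@dataclass(frozen=True, init=False, slots=True)
class Or(BooleanExpression):
    children: tuple[BooleanExpression, ...]

    __init__ = _nary_init

    def evaluate(self, valuation):
        out = self.children[0].evaluate(valuation)
        for child in self.children[1:]:
            out = out | child.evaluate(valuation)
        return out

    def leaves(self):
        return frozenset().union(*(c.leaves() for c in self.children))

    def __str__(self):
        parts = []
        for c in self.children:
            parts.append(str(c) if isinstance(c, (Var, Not, And)) else f"({c})")
        return " | ".join(parts)


# ---------------------------------------------------------------------------
# Tokenizer / parser

_NOT_GLYPHS = {"¬", "!", "~"}
_AND_GLYPHS = {"∧", "˄", "&", "^"}
_OR_GLYPHS = {"∨", "˅", "|", "v̌"}
_WORD_OPS = {"AND": "AND", "OR": "OR", "NOT": "NOT"}
_STRUCTURAL = set("()") | _NOT_GLYPHS | _AND_GLYPHS | _OR_GLYPHS


@dataclass(slots=True)
class _Token:
    kind: str  # NAME, AND, OR, NOT, LPAREN, RPAREN, EOF
    text: str
    pos: int


def _tokenize(text: str) -> Iterator[_Token]:
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "(":
            yield _Token("LPAREN", ch, i)
        elif ch == ")":
            yield _Token("RPAREN", ch, i)
        elif ch in _NOT_GLYPHS:
            yield _Token("NOT", ch, i)
        elif ch in _AND_GLYPHS:
            yield _Token("AND", ch, i)
        elif ch in _OR_GLYPHS:
            yield _Token("OR", ch, i)
        else:
            start = i
            while i < n and not text[i].isspace() and text[i] not in _STRUCTURAL:
                i += 1
            word = text[start:i]
            kind = _WORD_OPS.get(word.upper()) if word.upper() in _WORD_OPS else None
            yield _Token(kind or "NAME", word, start)
            continue
        i += 1
    yield _Token("EOF", "", n)


class _Parser:
    """Recursive-descent parser with end-of-expression parenthesis repair."""

    def __init__(self, text: str, vocabulary, aliases: Mapping[str, str] | None):
        self.text = text
        self.vocabulary = frozenset(vocabulary) if vocabulary is not None else None
        self.aliases = dict(aliases or {})
        self.tokens = list(_tokenize(text))
        self.i = 0
        self.repairs: list[str] = []

    @property
    def tok(self) -> _Token:
        return self.tokens[self.i]

    def advance(self) -> _Token:
        t = self.tok
        if t.kind != "EOF":
            self.i += 1
        return t

    def parse(self) -> BooleanExpression:
        expr = self.parse_or(depth=0)
        if self.tok.kind != "EOF":
            raise RuleParseError(
                f"unexpected {self.tok.text!r} after end of expression", self.tok.pos
            )
        return expr

    def parse_or(self, depth: int) -> BooleanExpression:
        terms = [self.parse_and(depth)]
        while self.tok.kind == "OR":
            self.advance()
            terms.append(self.parse_and(depth))
        return terms[0] if len(terms) == 1 else Or(terms)

    def parse_and(self, depth: int) -> BooleanExpression:
        factors = [self.parse_not(depth)]
        while self.tok.kind == "AND":
            self.advance()
            factors.append(self.parse_not(depth))
        return factors[0] if len(factors) == 1 else And(factors)

    def parse_not(self, depth: int) -> BooleanExpression:
        if self.tok.kind == "NOT":
            self.advance()
            return Not(self.parse_not(depth))
        return self.parse_atom(depth)

    def parse_atom(self, depth: int) -> BooleanExpression:
        t = self.tok
        if t.kind == "LPAREN":
            self.advance()
            inner = self.parse_or(depth + 1)
            if self.tok.kind == "RPAREN":
                self.advance()
            elif self.tok.kind == "EOF":
                # Damaged rule text: the group was never closed.  Closing at
                # end-of-expression is the only consistent reading.
                msg = (
                    f"auto-closed unbalanced '(' opened at position {t.pos} "
                    f"in rule {self.text!r}"
                )
                self.repairs.append(msg)
                logger.warning(msg)
            else:  # pragma: no cover - defensive; parse_or consumes until ) or EOF
                raise RuleParseError(
                    f"expected ')' but found {self.tok.text!r}", self.tok.pos
                )
            return inner
        if t.kind == "NAME":
            self.advance()
            name = self.aliases.get(t.text, t.text)
            if self.vocabulary is not None and name not in self.vocabulary:
                raise UnknownNameError(t.text, t.pos, self.vocabulary)
            return Var(name)
        if t.kind == "EOF":
            raise RuleParseError("unexpected end of expression", t.pos)
        raise RuleParseError(f"unexpected token {t.text!r}", t.pos)


def parse_rule(
    text: str,
    vocabulary=None,
    *,
    aliases: Mapping[str, str] | None = None,
    on_repair: Callable[[str], None] | None = None,
) -> BooleanExpression:
    """Parse rule ``text`` into a :class:`BooleanExpression`.

    Parameters
    ----------
    text:
        The rule, e.g. ``"A ∧ ¬B"`` or ``"A & !(B | C)"``.
    vocabulary:
        Optional set of legal regulator names.  Any leaf outside it (after
        alias substitution) raises :class:`UnknownNameError`.
    aliases:
        Optional token -> canonical-name substitutions, applied to every
        identifier before the vocabulary check (used to normalise OCR-style
        typos such as ``FOX01`` for ``FOXO1``).
    on_repair:
        Callback invoked with a message for every unbalanced-parenthesis
        repair; repairs are always also logged at WARNING level.
    """
    if not text or not text.strip():
        raise RuleParseError("empty rule text", 0)
    parser = _Parser(text, vocabulary, aliases)
    expr = parser.parse()
    if on_repair is not None:
        for msg in parser.repairs:
            on_repair(msg)
    return expr
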