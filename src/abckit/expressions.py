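"""Minimal arithmetic expression language for derived parameters.

Derived parameters (e.g. a population size rescaled for a second marker
type) are declared as formulas over prior-parameter names.  The grammar is
deliberately tiny — arithmetic, power, ``log10``/``pow10`` — with no
conditionals, so a rule can rescale or combine parameters but never branch:

    expr   := term (("+" | "-") term)*
    term   := factor (("*" | "/") factor)*
    factor := "-" factor | primary (("^" | "**") factor)?   # power right-assoc
    primary:= NUMBER | NAME | NAME "(" expr ")" | "(" expr ")"
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from .exceptions import ConfigError

_TOKEN_RE = re.compile(r"""
    \s*(?:
      (?P<number>(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)
    | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
    | (?P<op>\*\*|[-+*/^()])
    )""", re.VERBOSE)

_FUNCTIONS = {
    "log10": math.log10,
    "pow10": lambda x: 10.0 ** x,
}


def _tokenize(text: str):
    pos, tokens = 0, []
    while pos < len(text):
        match = _TOKEN_RE.match(text, pos)
        if match is None or match.end() == pos:
            rest = text[pos:].strip()
            if not rest:
                break
            raise ConfigError(f"expression {text!r}: cannot tokenize at {rest!r}")
        pos = match.end()
        kind = match.lastgroup
        tokens.append((kind, match.group(kind)))
    tokens.append(("end", ""))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos]

    def advance(self):
        token = self.tokens[self.pos]
        self.pos += 1
        return token

    def expect_op(self, op: str):
        kind, value = self.advance()
        if kind != "op" or value != op:
            raise ConfigError(f"expression {self.text!r}: expected {op!r}, found {value!r}")

    def parse(self):
        node = self.expr()
        if self.peek()[0] != "end":
            raise ConfigError(
                f"expression {self.text!r}: trailing input {self.peek()[1]!r}")
        return node

    def expr(self):
        node = self.term()
        while self.peek() == ("op", "+") or self.peek() == ("op", "-"):
            op = self.advance()[1]
            node = (op, node, self.term())
        return node

    def term(self):
        node = self.factor()
        while self.peek() == ("op", "*") or self.peek() == ("op", "/"):
            op = self.advance()[1]
            node = (op, node, self.factor())
        return node

    def factor(self):
        # unary minus binds looser than power: -x^2 == -(x^2)
        if self.peek() == ("op", "-"):
            self.advance()
            return ("neg", self.factor())
        node = self.primary()
        if self.peek() in (("op", "^"), ("op", "**")):
            self.advance()
            node = ("^", node, self.factor())
        return node

    def primary(self):
        kind, value = self.advance()
        if kind == "number":
            return ("num", float(value))
        if kind == "name":
            if self.peek() == ("op", "("):
                if value not in _FUNCTIONS:
                    raise ConfigError(f"expression {self.text!r}: unknown function {value!r}")
                self.advance()
                arg = self.expr()
                self.expect_op(")")
                return ("call", value, arg)
            return ("var", value)
        if (kind, value) == ("op", "("):
            node = self.expr()
            self.expect_op(")")
            return node
        raise ConfigError(f"expression {self.text!r}: unexpected token {value!r}")


def _names_of(node, out: set):
    tag = node[0]
    if tag == "var":
        out.add(node[1])
    elif tag == "call":
        _names_of(node[2], out)
    elif tag in {"+", "-", "*", "/", "^"}:
        _names_of(node[1], out)
        _names_of(node[2], out)
    elif tag == "neg":
        _names_of(node[1], out)


def _eval(node, env: dict):
    tag = node[0]
    if tag == "num":
        return node[1]
    if tag == "var":
        try:
            return float(env[node[1]])
        except KeyError:
            raise ConfigError(f"expression references unknown name {node[1]!r}") from None
    if tag == "neg":
        return -_eval(node[1], env)
    if tag == "call":
        return _FUNCTIONS[node[1]](_eval(node[2], env))
    left, right = _eval(node[1], env), _eval(node[2], env)
    if tag == "+":
        return left + right
    if tag == "-":
        return left - right
    if tag == "*":
        return left * right
    if tag == "/":
        return left / right
    return left ** right


@dataclass(frozen=True)
class Expression:
    """A parsed arithmetic expression over named parameters."""

    text: str
    _ast: tuple = field(repr=False, compare=False, default=None)

    @classmethod
    def parse(cls, text: str) -> "Expression":
        return cls(text=text, _ast=_Parser(text).parse())

    @property
    def names(self) -> frozenset:
        out: set = set()
        _names_of(self._ast, out)
        return frozenset(out)

    def evaluate(self, env: dict) -> float:
        """Evaluate with ``env`` mapping names to values.

        Raises :class:`ConfigError` for an unknown name.  Non-finiteness is
        the caller's concern (a rule knows its own name for the diagnostic).
        """
        try:
            return _eval(self._ast, env)
        except ZeroDivisionError:
            return math.inf
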