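"""Filter-expression grammar for record selection (bcftools -i style).

Supported grammar::

    expr   := and_expr ( "|" and_expr )*
    and_expr := primary ( "&" primary )*
    primary  := "(" expr ")" | comparison
    comparison := field op number | number op field
    field  := "INFO/" KEY | "FORMAT/" KEY | "FMT/" KEY
    op     := < | <= | > | >= | == | !=

FORMAT terms evaluate per call; INFO terms per record.  Missing values
compare false in every comparison.  When an expression contains FORMAT
terms its value is a (variants, samples) matrix; a *record* passes if any
sample satisfies the whole per-call conjunction (bcftools' site-level
``-i`` semantics).  Fields with a trailing dimension are reduced with
"any element satisfies" before combination.
"""

from __future__ import annotations

import re

import numpy as np

from .model import FLOAT_FILL_BITS, FLOAT_MISSING_BITS, float_bits


class ExpressionError(ValueError):
    def __init__(self, message, position=None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


_TOKEN_RE = re.compile(
    r"\s*(?:"
    r"(?P<field>(?:INFO|FORMAT|FMT)/[A-Za-z_][A-Za-z0-9_.]*)"
    r"|(?P<number>-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)"
    r"|(?P<op><=|>=|==|!=|<|>)"
    r"|(?P<and>&&?)"
    r"|(?P<or>\|\|?)"
    r"|(?P<lparen>\()"
    r"|(?P<rparen>\))"
    r")"
)


def tokenize(text: str):
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == m.start():
            if text[pos:].strip() == "":
                break
            raise ExpressionError(
                f"unsupported syntax {text[pos:pos + 10]!r}", position=pos
            )
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    return tokens


class _Comparison:
    def __init__(self, field, op, value):
        self.field = field  # ("INFO"|"FORMAT", key)
        self.op = op
        self.value = value

    def fields(self):
        return {self.field}

    def evaluate(self, resolver):
        data, valid = resolver(self.field)
        with np.errstate(invalid="ignore"):
            if self.op == "<":
                ok = data < self.value
            elif self.op == "<=":
                ok = data <= self.value
            elif self.op == ">":
                ok = data > self.value
            elif self.op == ">=":
                ok = data >= self.value
            elif self.op == "==":
                ok = data == self.value
            else:
                ok = data != self.value
        ok = np.asarray(ok) & valid  # missing compares false
        if ok.ndim > (2 if self.field[0] == "FORMAT" else 1):
            ok = ok.any(axis=-1)
        return ok


class _Binary:
    def __init__(self, op, left, right):
        self.op = op
        self.left = left
        self.right = right

    def fields(self):
        return self.left.fields() | self.right.fields()

    def evaluate(self, resolver):
        a = self.left.evaluate(resolver)
        b = self.right.evaluate(resolver)
        if a.ndim != b.ndim:  # broadcast INFO (n,) against FORMAT (n, s)
            if a.ndim < b.ndim:
                a = a[:, None]
            else:
                b = b[:, None]
        return (a & b) if self.op == "&" else (a | b)


class _Parser:
    def __init__(self, tokens, text):
        self.tokens = tokens
        self.text = text
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None, len(self.text))

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def parse(self):
        node = self.parse_or()
        kind, val, pos = self.peek()
        if kind is not None:
            raise ExpressionError(f"unexpected token {val!r}", position=pos)
        return node

    def parse_or(self):
        node = self.parse_and()
        while self.peek()[0] == "or":
            self.next()
            node = _Binary("|", node, self.parse_and())
        return node

    def parse_and(self):
        node = self.parse_primary()
        while self.peek()[0] == "and":
            self.next()
            node = _Binary("&", node, self.parse_primary())
        return node

    def parse_primary(self):
        kind, val, pos = self.peek()
        if kind == "lparen":
            self.next()
            node = self.parse_or()
            k, v, p = self.next()
            if k != "rparen":
                raise ExpressionError("expected ')'", position=p)
            return node
        if kind == "field":
            self.next()
            okind, op, opos = self.next()
            if okind != "op":
                raise ExpressionError("expected comparison operator", position=opos)
            nkind, num, npos = self.next()
            if nkind != "number":
                raise ExpressionError("expected numeric literal", position=npos)
            return _Comparison(self._field(val), op, float(num))
        if kind == "number":
            num = val
            self.next()
            okind, op, opos = self.next()
            if okind != "op":
                raise ExpressionError("expected comparison operator", position=opos)
            fkind, fval, fpos = self.next()
            if fkind != "field":
                raise ExpressionError("expected INFO/ or FORMAT/ field", position=fpos)
            return _Comparison(self._field(fval), _flip(op), float(num))
        raise ExpressionError("expected a comparison or '('", position=pos)

    @staticmethod
    def _field(text):
        prefix, key = text.split("/", 1)
        return ("FORMAT" if prefix in ("FORMAT", "FMT") else "INFO", key)


def _flip(op):
    return {"<": ">", ">": "<", "<=": ">=", ">=": "<=", "==": "==", "!=": "!="}[op]


def parse_expression(text: str):
    """Parse a filter expression; raises ExpressionError with a position."""
    tokens = tokenize(text)
    if not tokens:
        raise ExpressionError("empty expression", position=0)
    return _Parser(tokens, text).parse()


def valid_mask(values: np.ndarray) -> np.ndarray:
    """True where a stored value is genuine (neither missing nor fill)."""
    values = np.asarray(values)
    if values.dtype == np.float32 or values.dtype == np.float64:
        bits = float_bits(values.astype(np.float32))
        return (bits != FLOAT_MISSING_BITS) & (bits != FLOAT_FILL_BITS) & ~np.isnan(
            values
        )
    if values.dtype == bool:
        return np.ones(values.shape, dtype=bool)
    # integers: -1 missing, -2 fill (genuine negatives are rejected at
    # conversion, so anything below -1 .. -1 itself is a sentinel)
    return values > -1


def evaluate(node, resolve_array):
    """Evaluate a parsed expression into a per-record boolean mask.

    ``resolve_array(("INFO"|"FORMAT", key))`` must return the numpy array
    for the field over the records under consideration: (n, ...) for INFO,
    (n, samples, ...) for FORMAT.
    """

    def resolver(field):
        data = np.asarray(resolve_array(field))
        if data.dtype.kind in "OTU":
            raise ExpressionError(
                f"{field[0]}/{field[1]} is a string field; only numeric "
                "comparisons are supported"
            )
        valid = valid_mask(data)
        if data.dtype == bool:
            data = data.astype(np.int8)
        # integers: keep sentinel entries from comparing true via `valid`
        return data, valid

    result = node.evaluate(resolver)
    if result.ndim == 2:
        result = result.any(axis=1)
    return result


def evaluate_per_call(node, resolve_array):
    """Evaluate to a (variants, samples) per-call mask (bcftools -I style).

    INFO-only expressions broadcast across samples; the caller supplies the
    sample count via a FORMAT field or post-broadcasts the (n,) result.
    """

    def resolver(field):
        data = np.asarray(resolve_array(field))
        valid = valid_mask(data)
        if data.dtype == bool:
            data = data.astype(np.int8)
        return data, valid

    return node.evaluate(resolver)
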