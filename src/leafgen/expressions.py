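"""Tiny arithmetic/boolean expression language for parametric production rules.

Rule parameters and conditions are plain infix expressions over the rule's
formal parameters, e.g. ``x*2``, ``x > 0``, ``pow(l, 0.5) + sin(a)``.
Expressions are parsed once (via the Python ``ast`` module, restricted to a
closed whitelist of node types) and evaluated many times during derivation.

Supported: ``+ - * /``, unary ``-``, parentheses, comparisons
(``< <= > >= == !=``), and the functions ``sin``, ``cos``, ``pow``
(angles in degrees).
"""

from __future__ import annotations

import ast
import math
from typing import Mapping

__all__ = ["Expression", "ExpressionError"]


class ExpressionError(ValueError):
    """Raised for an expression outside the supported language."""


_FUNCTIONS = {
    "sin": lambda x: math.sin(math.radians(x)),
    "cos": lambda x: math.cos(math.radians(x)),
    "pow": math.pow,
}

_BINOPS = {
    ast.Add: lambda a, b: a + b,
    ast.Sub: lambda a, b: a - b,
    ast.Mult: lambda a, b: a * b,
    ast.Div: lambda a, b: a / b,
}

_CMPOPS = {
    ast.Lt: lambda a, b: a < b,
    ast.LtE: lambda a, b: a <= b,
    ast.Gt: lambda a, b: a > b,
    ast.GtE: lambda a, b: a >= b,
    ast.Eq: lambda a, b: a == b,
    ast.NotEq: lambda a, b: a != b,
}


class Expression:
    """A compiled expression over named formal parameters."""

    def __init__(self, source: str):
        self.source = source.strip()
        if not self.source:
            raise ExpressionError("empty expression")
        try:
            tree = ast.parse(self.source, mode="eval")
        except SyntaxError as exc:
            raise ExpressionError(f"bad expression {source!r}: {exc.msg}") from exc
        self._root = tree.body
        self.variables = self._validate(self._root)

    def _validate(self, node: ast.AST) -> frozenset[str]:
        names: set[str] = set()
        for sub in ast.walk(node):
            if isinstance(sub, ast.Name):
                if sub.id not in _FUNCTIONS:
                    names.add(sub.id)
            elif isinstance(sub, ast.Call):
                if not (isinstance(sub.func, ast.Name) and sub.func.id in _FUNCTIONS):
                    raise ExpressionError(f"unsupported function call in {self.source!r}")
                if len(sub.args) != (2 if sub.func.id == "pow" else 1) or sub.keywords:
                    raise ExpressionError(f"wrong arity for {sub.func.id} in {self.source!r}")
            elif isinstance(sub, ast.BinOp):
                if type(sub.op) not in _BINOPS:
                    raise ExpressionError(f"unsupported operator in {self.source!r}")
            elif isinstance(sub, ast.UnaryOp):
                if not isinstance(sub.op, (ast.USub, ast.UAdd)):
                    raise ExpressionError(f"unsupported unary operator in {self.source!r}")
            elif isinstance(sub, ast.Compare):
                for op in sub.ops:
                    if type(op) not in _CMPOPS:
                        raise ExpressionError(f"unsupported comparison in {self.source!r}")
            elif isinstance(sub, ast.Constant):
                if not isinstance(sub.value, (int, float)):
                    raise ExpressionError(f"non-numeric constant in {self.source!r}")
            elif isinstance(
                sub, (ast.Expression, ast.Load, ast.operator, ast.unaryop, ast.cmpop)
            ):
                pass
            else:
                raise ExpressionError(
                    f"unsupported syntax ({type(sub).__name__}) in {self.source!r}"
                )
        return frozenset(names)

    def __call__(self, env: Mapping[str, float] | None = None) -> float:
        env = env or {}
        missing = self.variables - env.keys()
        if missing:
            raise ExpressionError(
                f"undefined parameter(s) {sorted(missing)} in {self.source!r}"
            )
        return self._eval(self._root, env)

    def _eval(self, node: ast.AST, env: Mapping[str, float]) -> float:
        if isinstance(node, ast.Constant):
            return float(node.value)
        if isinstance(node, ast.Name):
            return float(env[node.id])
        if isinstance(node, ast.BinOp):
            return _BINOPS[type(node.op)](self._eval(node.left, env), self._eval(node.right, env))
        if isinstance(node, ast.UnaryOp):
            v = self._eval(node.operand, env)
            return -v if isinstance(node.op, ast.USub) else v
        if isinstance(node, ast.Compare):
            left = self._eval(node.left, env)
            for op, comparator in zip(node.ops, node.comparators):
                right = self._eval(comparator, env)
                if not _CMPOPS[type(op)](left, right):
                    return 0.0
                left = right
            return 1.0
        if isinstance(node, ast.Call):
            fn = _FUNCTIONS[node.func.id]  # type: ignore[union-attr]
            return float(fn(*(self._eval(a, env) for a in node.args)))
        raise ExpressionError(f"unsupported node {type(node).__name__}")

    def __repr__(self) -> str:  # pragma: no cover
        return f"Expression({self.source!r})"
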