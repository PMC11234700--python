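"""Tiny arithmetic expression language for payoffs and branch probabilities.

Expressions are strings over parameter names, numeric literals, ``+ - * /``
and parentheses.  The keyword ``complement`` is *not* part of this language:
it is only legal as the whole probability of one branch of a chance node and
is resolved by the tree layer as 1 minus the sum of the sibling branches.

Expressions are compiled once (after an AST whitelist check) and evaluated
against a plain ``{name: value}`` environment, so no Python builtins or
attribute access can ever be reached from a model configuration file.
"""

from __future__ import annotations

import ast
from functools import lru_cache
from typing import Mapping, Union

from .errors import ExpressionError

#: branch-probability keyword, resolved by the tree layer
COMPLEMENT = "complement"

Expr = Union[str, float, int]

_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div)
_ALLOWED_UNARY = (ast.UAdd, ast.USub)


def _check_node(node: ast.AST, expr: str) -> None:
    if isinstance(node, ast.Expression):
        _check_node(node.body, expr)
    elif isinstance(node, ast.BinOp):
        if not isinstance(node.op, _ALLOWED_BINOPS):
            raise ExpressionError(f"operator not allowed in expression {expr!r}")
        _check_node(node.left, expr)
        _check_node(node.right, expr)
    elif isinstance(node, ast.UnaryOp):
        if not isinstance(node.op, _ALLOWED_UNARY):
            raise ExpressionError(f"operator not allowed in expression {expr!r}")
        _check_node(node.operand, expr)
    elif isinstance(node, ast.Constant):
        if isinstance(node.value, bool) or not isinstance(node.value, (int, float)):
            raise ExpressionError(f"non-numeric literal in expression {expr!r}")
    elif isinstance(node, ast.Name):
        if node.id == COMPLEMENT:
            raise ExpressionError(
                f"'{COMPLEMENT}' is only allowed as a whole branch probability, "
                f"not inside expression {expr!r}"
            )
    else:
        raise ExpressionError(f"syntax not allowed in expression {expr!r}")


@lru_cache(maxsize=8192)
def _compile(expr: str):
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"cannot parse expression {expr!r}: {exc.msg}") from exc
    _check_node(tree, expr)
    return compile(tree, "<expression>", "eval")


@lru_cache(maxsize=8192)
def parameter_names(expr: str) -> frozenset[str]:
    """Names referenced by ``expr`` (empty for purely numeric expressions)."""
    tree = ast.parse(expr, mode="eval")
    _check_node(tree, expr)
    return frozenset(n.id for n in ast.walk(tree) if isinstance(n, ast.Name))


def evaluate(expr: Expr, env: Mapping[str, float]) -> float:
    """Evaluate an expression (or pass a numeric literal through)."""
    if isinstance(expr, (int, float)):
        return float(expr)
    code = _compile(expr)
    try:
        return float(eval(code, {"__builtins__": {}}, dict(env)))  # noqa: S307 - whitelisted AST
    except NameError as exc:
        raise ExpressionError(f"unknown parameter {exc.name!r} in expression {expr!r}") from exc
    except ZeroDivisionError as exc:
        raise ExpressionError(f"division by zero in expression {expr!r}") from exc
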