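"""Parsing, analysis and evaluation of model expressions.

Expressions use infix syntax with ``**`` for powers, ``%`` for mathematical
modulo, boolean ``and/or/not`` and comparisons, plus a closed set of
functions.  They are parsed once into a restricted Python AST which is then
used for three purposes:

* dimension inference (:func:`dims_of_expression`),
* conversion to/from SymPy for symbolic manipulation,
* compilation to vectorized NumPy evaluation.
"""

from __future__ import annotations

import ast
from fractions import Fraction

import numpy as np
import sympy
from sympy.printing.str import StrPrinter

from .units import (
    DIMENSIONLESS,
    Dimension,
    DimensionError,
    Quantity,
    UNIT_REGISTRY,
    render_dimension,
)

__all__ = [
    "ExpressionError",
    "FUNCTIONS",
    "RESERVED_NAMES",
    "parse_expression",
    "identifiers",
    "dims_of_expression",
    "to_sympy",
    "sympy_to_str",
    "compile_expression",
    "make_function_namespace",
    "is_xi_name",
]


class ExpressionError(ValueError):
    """Malformed or unsupported expression."""


#: closed function set usable in model expressions
FUNCTIONS = frozenset(
    {
        "exp",
        "log",
        "sin",
        "cos",
        "sqrt",
        "abs",
        "floor",
        "clip",
        "int",
        "rand",
        "randn",
        "min",
        "max",
    }
)

#: names a model may not (re)define
RESERVED_NAMES = frozenset(
    {"t", "dt", "i", "j", "N", "N_pre", "N_post", "lastspike", "lastupdate",
     "xi", "e", "pi", "inf", "True", "False"} | FUNCTIONS
)

SECOND = Dimension((0, 0, 1, 0, 0, 0, 0))
XI_DIM = SECOND ** Fraction(-1, 2)  # white-noise process dimension

#: dimensions of the special runtime symbols
RESERVED_DIMS = {
    "t": SECOND,
    "dt": SECOND,
    "lastspike": SECOND,
    "lastupdate": SECOND,
    "i": DIMENSIONLESS,
    "j": DIMENSIONLESS,
    "N": DIMENSIONLESS,
    "N_pre": DIMENSIONLESS,
    "N_post": DIMENSIONLESS,
    "e": DIMENSIONLESS,
    "pi": DIMENSIONLESS,
    "inf": DIMENSIONLESS,
}


def is_xi_name(name: str) -> bool:
    if name == "xi":
        return True
    if name.startswith("xi_"):
        suffix = name[3:]
        return suffix.isdigit()
    return False


_ALLOWED_NODES = (
    ast.Expression,
    ast.BinOp,
    ast.UnaryOp,
    ast.BoolOp,
    ast.Compare,
    ast.Call,
    ast.Name,
    ast.Constant,
    ast.Load,
    ast.Add,
    ast.Sub,
    ast.Mult,
    ast.Div,
    ast.Pow,
    ast.Mod,
    ast.USub,
    ast.UAdd,
    ast.Not,
    ast.And,
    ast.Or,
    ast.Lt,
    ast.LtE,
    ast.Gt,
    ast.GtE,
    ast.Eq,
    ast.NotEq,
)


def parse_expression(text: str, extra_functions=()) -> ast.expr:
    """Parse ``text`` into a validated AST node.

    Only arithmetic, comparisons, boolean logic and the closed function set
    (plus ``extra_functions``, used for the ``f``/``g`` placeholders of
    integration-scheme descriptions) are allowed; anything else (attribute
    access, subscripts, lambdas, control flow) is rejected.
    """
    allowed_functions = FUNCTIONS | set(extra_functions)
    try:
        tree = ast.parse(text.strip(), mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"syntax error in expression {text!r}: {exc.msg}") from None
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise ExpressionError(
                f"unsupported construct {type(node).__name__} in expression {text!r}"
            )
        if isinstance(node, ast.Call):
            if not isinstance(node.func, ast.Name):
                raise ExpressionError(f"unsupported call target in {text!r}")
            if node.func.id not in allowed_functions:
                raise ExpressionError(
                    f"unknown function {node.func.id!r} in expression {text!r}"
                )
            if node.keywords:
                raise ExpressionError("keyword arguments are not supported")
        if isinstance(node, ast.Constant) and not isinstance(
            node.value, (int, float, bool)
        ):
            raise ExpressionError(f"unsupported literal {node.value!r} in {text!r}")
    return tree.body


def identifiers(node: ast.expr) -> set:
    """All variable names read by the expression (function names excluded)."""
    names = set()
    for sub in ast.walk(node):
        if isinstance(sub, ast.Name):
            names.add(sub.id)
        elif isinstance(sub, ast.Call):
            pass
    # function names arrive as Name nodes inside Call.func; remove them
    funcs = {
        sub.func.id
        for sub in ast.walk(node)
        if isinstance(sub, ast.Call) and isinstance(sub.func, ast.Name)
    }
    return names - funcs


# ---------------------------------------------------------------------------
# Dimension inference
# ---------------------------------------------------------------------------

_ARITY = {"exp": 1, "log": 1, "sin": 1, "cos": 1, "sqrt": 1, "abs": 1,
          "floor": 1, "clip": 3, "int": 1, "rand": 0, "randn": 0,
          "min": 2, "max": 2}


def _static_value(node: ast.expr):
    """Evaluate a constant numeric subexpression, or return None."""
    if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
        return node.value
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, (ast.USub, ast.UAdd)):
        val = _static_value(node.operand)
        if val is None:
            return None
        return -val if isinstance(node.op, ast.USub) else val
    if isinstance(node, ast.BinOp):
        left = _static_value(node.left)
        right = _static_value(node.right)
        if left is None or right is None:
            return None
        try:
            if isinstance(node.op, ast.Add):
                return left + right
            if isinstance(node.op, ast.Sub):
                return left - right
            if isinstance(node.op, ast.Mult):
                return left * right
            if isinstance(node.op, ast.Div):
                return left / right
            if isinstance(node.op, ast.Pow):
                return left ** right
        except (ZeroDivisionError, OverflowError):
            return None
    return None


def _lookup_dim(name: str, symbol_dims: dict) -> Dimension:
    if name in symbol_dims:
        dim = symbol_dims[name]
        if isinstance(dim, Quantity):
            return dim.dim
        return dim
    if is_xi_name(name):
        return XI_DIM
    if name in RESERVED_DIMS:
        return RESERVED_DIMS[name]
    if name in UNIT_REGISTRY:
        return UNIT_REGISTRY[name].dim
    raise ExpressionError(f"cannot resolve identifier {name!r}")


def dims_of_expression(node, symbol_dims: dict) -> Dimension:
    """Infer the :class:`Dimension` of an expression.

    ``node`` may be an AST node or a source string.  ``symbol_dims`` maps
    identifier names to Dimensions (or Quantities, whose dimension is used).
    Raises :class:`~eqspike.units.DimensionError` on inconsistency and
    :class:`ExpressionError` on unresolved identifiers.
    """
    if isinstance(node, str):
        node = parse_expression(node)
    return _dims(node, symbol_dims)


def _dims(node: ast.expr, env: dict) -> Dimension:
    if isinstance(node, ast.Constant):
        return DIMENSIONLESS
    if isinstance(node, ast.Name):
        return _lookup_dim(node.id, env)
    if isinstance(node, ast.UnaryOp):
        if isinstance(node.op, ast.Not):
            operand = _dims(node.operand, env)
            if not operand.is_dimensionless:
                raise DimensionError("'not' requires a dimensionless operand")
            return DIMENSIONLESS
        return _dims(node.operand, env)
    if isinstance(node, ast.BinOp):
        left = _dims(node.left, env)
        right = _dims(node.right, env)
        if isinstance(node.op, (ast.Add, ast.Sub, ast.Mod)):
            if left != right:
                raise DimensionError(
                    f"dimension mismatch: {render_dimension(left)} "
                    f"{'+' if isinstance(node.op, ast.Add) else '-' if isinstance(node.op, ast.Sub) else '%'} "
                    f"{render_dimension(right)}"
                )
            return left
        if isinstance(node.op, ast.Mult):
            return left * right
        if isinstance(node.op, ast.Div):
            return left / right
        if isinstance(node.op, ast.Pow):
            if not right.is_dimensionless:
                raise DimensionError("exponent must be dimensionless")
            if left.is_dimensionless:
                return DIMENSIONLESS
            exponent = _static_value(node.right)
            if exponent is None:
                raise DimensionError(
                    "non-constant exponent applied to a dimensioned quantity"
                )
            return left ** exponent
        raise ExpressionError("unsupported binary operator")
    if isinstance(node, ast.BoolOp):
        for value in node.values:
            if not _dims(value, env).is_dimensionless:
                raise DimensionError("boolean operands must be dimensionless")
        return DIMENSIONLESS
    if isinstance(node, ast.Compare):
        dims = [_dims(node.left, env)] + [_dims(c, env) for c in node.comparators]
        if any(d != dims[0] for d in dims):
            raise DimensionError(
                "comparison between quantities of different dimensions"
            )
        return DIMENSIONLESS
    if isinstance(node, ast.Call):
        fname = node.func.id
        if len(node.args) != _ARITY[fname]:
            raise ExpressionError(
                f"{fname}() takes {_ARITY[fname]} argument(s), got {len(node.args)}"
            )
        arg_dims = [_dims(a, env) for a in node.args]
        if fname in ("exp", "log", "sin", "cos"):
            if not arg_dims[0].is_dimensionless:
                raise DimensionError(f"{fname}() requires a dimensionless argument")
            return DIMENSIONLESS
        if fname == "sqrt":
            return arg_dims[0] ** Fraction(1, 2)
        if fname == "abs":
            return arg_dims[0]
        if fname in ("floor", "int"):
            if not arg_dims[0].is_dimensionless:
                raise DimensionError(f"{fname}() requires a dimensionless argument")
            return DIMENSIONLESS
        if fname == "clip":
            if arg_dims[0] != arg_dims[1] or arg_dims[0] != arg_dims[2]:
                raise DimensionError("clip() arguments must share one dimension")
            return arg_dims[0]
        if fname in ("min", "max"):
            if arg_dims[0] != arg_dims[1]:
                raise DimensionError(f"{fname}() arguments must share one dimension")
            return arg_dims[0]
        if fname in ("rand", "randn"):
            return DIMENSIONLESS
    raise ExpressionError(f"cannot infer dimension of {ast.dump(node)}")


# ---------------------------------------------------------------------------
# SymPy bridge
# ---------------------------------------------------------------------------

_SYMPY_FUNCS = {
    "exp": sympy.exp,
    "log": sympy.log,
    "sin": sympy.sin,
    "cos": sympy.cos,
    "sqrt": sympy.sqrt,
    "abs": sympy.Abs,
    "floor": sympy.floor,
}


def to_sympy(node) -> sympy.Expr:
    """Convert an expression (AST node or string) to a SymPy expression.

    All identifiers become plain :class:`sympy.Symbol`; non-analytic
    functions (``clip``, ``int``, ``rand`` ...) become undefined functions so
    that they survive symbolic manipulation untouched.
    """
    if isinstance(node, str):
        node = parse_expression(node)
    return _to_sympy(node)


def _to_sympy(node: ast.expr) -> sympy.Expr:
    if isinstance(node, ast.Constant):
        if isinstance(node.value, bool):
            return sympy.true if node.value else sympy.false
        if isinstance(node.value, int):
            return sympy.Integer(node.value)
        return sympy.Float(node.value)
    if isinstance(node, ast.Name):
        return sympy.Symbol(node.id)
    if isinstance(node, ast.UnaryOp):
        operand = _to_sympy(node.operand)
        if isinstance(node.op, ast.USub):
            return -operand
        if isinstance(node.op, ast.UAdd):
            return operand
        return sympy.Not(operand)
    if isinstance(node, ast.BinOp):
        left, right = _to_sympy(node.left), _to_sympy(node.right)
        if isinstance(node.op, ast.Add):
            return left + right
        if isinstance(node.op, ast.Sub):
            return left - right
        if isinstance(node.op, ast.Mult):
            return left * right
        if isinstance(node.op, ast.Div):
            return left / right
        if isinstance(node.op, ast.Pow):
            return left ** right
        if isinstance(node.op, ast.Mod):
            return sympy.Mod(left, right)
    if isinstance(node, ast.BoolOp):
        values = [_to_sympy(v) for v in node.values]
        return sympy.And(*values) if isinstance(node.op, ast.And) else sympy.Or(*values)
    if isinstance(node, ast.Compare):
        ops = {
            ast.Lt: sympy.Lt,
            ast.LtE: sympy.Le,
            ast.Gt: sympy.Gt,
            ast.GtE: sympy.Ge,
            ast.Eq: sympy.Eq,
            ast.NotEq: sympy.Ne,
        }
        parts = []
        left = _to_sympy(node.left)
        for op, comparator in zip(node.ops, node.comparators):
            right = _to_sympy(comparator)
            parts.append(ops[type(op)](left, right))
            left = right
        return parts[0] if len(parts) == 1 else sympy.And(*parts)
    if isinstance(node, ast.Call):
        fname = node.func.id
        args = [_to_sympy(a) for a in node.args]
        if fname in _SYMPY_FUNCS:
            return _SYMPY_FUNCS[fname](*args)
        return sympy.Function(fname)(*args)
    raise ExpressionError(f"cannot convert {ast.dump(node)} to sympy")


class _ExprPrinter(StrPrinter):
    """Print SymPy back into the model-expression grammar."""

    def _print_Abs(self, expr):
        return f"abs({self._print(expr.args[0])})"

    def _print_Function(self, expr):
        name = expr.func.__name__
        args = ", ".join(self._print(a) for a in expr.args)
        return f"{name}({args})"


_printer = _ExprPrinter()


def sympy_to_str(expr: sympy.Expr) -> str:
    return _printer.doprint(expr)


# ---------------------------------------------------------------------------
# NumPy compilation
# ---------------------------------------------------------------------------

class _VectorBool(ast.NodeTransformer):
    """Rewrite boolean operators and chained comparisons for array semantics."""

    def visit_BoolOp(self, node):
        self.generic_visit(node)
        func = "logical_and" if isinstance(node.op, ast.And) else "logical_or"
        result = node.values[0]
        for value in node.values[1:]:
            result = ast.Call(
                func=ast.Name(id=func, ctx=ast.Load()), args=[result, value], keywords=[]
            )
        return result

    def visit_UnaryOp(self, node):
        self.generic_visit(node)
        if isinstance(node.op, ast.Not):
            return ast.Call(
                func=ast.Name(id="logical_not", ctx=ast.Load()),
                args=[node.operand],
                keywords=[],
            )
        return node

    def visit_Compare(self, node):
        self.generic_visit(node)
        if len(node.ops) == 1:
            return node
        parts = []
        left = node.left
        for op, comparator in zip(node.ops, node.comparators):
            parts.append(ast.Compare(left=left, ops=[op], comparators=[comparator]))
            left = comparator
        result = parts[0]
        for part in parts[1:]:
            result = ast.Call(
                func=ast.Name(id="logical_and", ctx=ast.Load()),
                args=[result, part],
                keywords=[],
            )
        return result


def compile_expression(node):
    """Compile an expression (AST node or string) to a Python code object."""
    if isinstance(node, str):
        node = parse_expression(node)
    import copy

    node = copy.deepcopy(node)
    node = _VectorBool().visit(node)
    tree = ast.Expression(body=node)
    ast.fix_missing_locations(tree)
    return compile(tree, "<eqspike expression>", "eval")


def _as_float(x):
    return np.asarray(x, dtype=float)


def make_function_namespace(n: int, rng) -> dict:
    """Evaluation namespace for one vectorized evaluation over ``n`` instances.

    ``rand()``/``randn()`` draw a fresh vector of length ``n`` on every call
    (per instance, per occurrence); evaluation order inside an expression is
    Python's left-to-right order, so seeded runs are reproducible.
    """
    ns = {
        "exp": np.exp,
        "log": np.log,
        "sin": np.sin,
        "cos": np.cos,
        "sqrt": np.sqrt,
        "abs": np.abs,
        "floor": np.floor,
        "clip": np.clip,
        "int": _as_float,
        "min": np.minimum,
        "max": np.maximum,
        "logical_and": np.logical_and,
        "logical_or": np.logical_or,
        "logical_not": np.logical_not,
        "e": float(np.e),
        "pi": float(np.pi),
        "inf": float(np.inf),
    }
    if rng is not None:
        ns["rand"] = lambda: rng.random(n)
        ns["randn"] = lambda: rng.standard_normal(n)
    else:
        def _needs_rng():
            raise ExpressionError(
                "rand()/randn() used but no random generator was supplied"
            )
        ns["rand"] = ns["randn"] = _needs_rng
    return ns
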