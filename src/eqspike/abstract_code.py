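"""The abstract-code intermediate representation.

Everything executable — integrator updates, resets, synaptic statements,
state assignments — is a sequence of ``variable operator expression``
statements where the operator is one of ``=``, ``+=``, ``-=``, ``*=``,
``/=``.  Statements execute strictly in order; there are no control
structures (conditional effects use ``int(condition)`` multipliers).

Execution is vectorized over instances but defined to be equivalent to a
per-instance loop, with one important contract: when several instances of a
subset alias the same underlying array element (synapses sharing a target
neuron), in-place operators accumulate every contribution, while plain
``=`` follows ascending-index last-write-wins.
"""

from __future__ import annotations

import ast
import re
from dataclasses import dataclass

import numpy as np

from . import expressions as xp
from .units import UNIT_REGISTRY

__all__ = [
    "AbstractStatement",
    "AbstractCodeBlock",
    "ArrayView",
    "ComputedView",
    "parse_statements",
    "execute",
    "evaluate",
    "render_loop_source",
]

OPERATORS = ("=", "+=", "-=", "*=", "/=")

_STMT_RE = re.compile(r"^([A-Za-z_]\w*)\s*(\+=|-=|\*=|/=|=)\s*(.+)$")

_CONTROL_KEYWORDS = re.compile(r"\b(if|else|for|while|def|return|lambda|import)\b")


@dataclass
class AbstractStatement:
    target: str
    op: str
    rhs: str

    def __post_init__(self):
        if self.op not in OPERATORS:
            raise xp.ExpressionError(f"unsupported operator {self.op!r}")
        self.rhs_ast = xp.parse_expression(self.rhs)
        self.code = xp.compile_expression(self.rhs_ast)

    def render(self):
        return f"{self.target} {self.op} {self.rhs}"


class AbstractCodeBlock:
    """An ordered list of statements with dependency sets.

    ``temp_set`` holds candidate temporaries: names first assigned with
    ``=`` before any read.  Whether such a name really is a temporary (vs.
    persistent state being overwritten) is decided at execution time against
    the set of persistent variables.
    """

    def __init__(self, statements):
        self.statements = list(statements)
        read, written, temps = set(), set(), set()
        for stmt in self.statements:
            rhs_names = xp.identifiers(stmt.rhs_ast)
            read |= rhs_names - temps
            if stmt.op != "=":
                if stmt.target not in temps:
                    read.add(stmt.target)
            elif stmt.target not in read and stmt.target not in written:
                temps.add(stmt.target)
            written.add(stmt.target)
        self.read_set = read
        self.write_set = written
        self.temp_set = temps

    def __len__(self):
        return len(self.statements)

    def __iter__(self):
        return iter(self.statements)

    def __add__(self, other):
        return AbstractCodeBlock(self.statements + other.statements)

    def render(self):
        return "\n".join(stmt.render() for stmt in self.statements)

    def __repr__(self):
        return f"AbstractCodeBlock(\n{self.render()}\n)"


def parse_statements(text: str) -> AbstractCodeBlock:
    """Parse statements, one per line or separated by ``;``."""
    statements = []
    for raw in text.replace(";", "\n").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if _CONTROL_KEYWORDS.search(line):
            raise xp.ExpressionError(
                f"control structures are not supported in abstract code: {line!r}"
            )
        match = _STMT_RE.match(line)
        if match is None:
            raise xp.ExpressionError(f"malformed statement {line!r}")
        target, op, rhs = match.groups()
        if target in xp.FUNCTIONS:
            raise xp.ExpressionError(f"cannot assign to function name {target!r}")
        statements.append(AbstractStatement(target, op, rhs))
    return AbstractCodeBlock(statements)


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------

class ArrayView:
    """A persistent array addressed through an (optional) index vector.

    Reads gather the current values; writes scatter back.  In-place
    operators use unbuffered ``ufunc.at`` so duplicate indices accumulate
    exactly as a per-instance loop would.
    """

    _UFUNC = {"+=": np.add, "-=": np.subtract, "*=": np.multiply, "/=": np.divide}

    def __init__(self, array, indices=None):
        self.array = array
        self.indices = indices

    def get(self):
        if self.indices is None:
            return self.array.copy()
        return self.array[self.indices]

    def set(self, op, values):
        if self.indices is None:
            if op == "=":
                self.array[...] = values
            else:
                self._UFUNC[op].at(self.array, slice(None), values)
            return
        if op == "=":
            self.array[self.indices] = values
        else:
            values = np.broadcast_to(values, np.shape(self.indices))
            self._UFUNC[op].at(self.array, self.indices, values)


class ComputedView:
    """Read-only view computed on demand (used for subexpressions)."""

    def __init__(self, getter):
        self._getter = getter

    def get(self):
        return self._getter()

    def set(self, op, values):
        raise xp.ExpressionError("cannot assign to a computed subexpression")


def execute(block, variables, n, namespace=None, rng=None):
    """Execute ``block`` vectorized over ``n`` instances.

    ``variables`` maps names to views (``ArrayView``/``ComputedView``);
    ``namespace`` provides scalar constants (plain floats, base SI).
    Temporaries — names in ``block.temp_set`` that are not persistent
    variables — live only for the duration of this call.
    """
    namespace = namespace or {}
    funcs = xp.make_function_namespace(n, rng)
    temps: dict = {}

    def lookup(name):
        if name in temps:
            return temps[name]
        if name in variables:
            return variables[name].get()
        if name in namespace:
            return namespace[name]
        if name in UNIT_REGISTRY:
            return UNIT_REGISTRY[name].magnitude
        raise xp.ExpressionError(f"unresolved identifier {name!r} in abstract code")

    for stmt in block.statements:
        env = dict(funcs)
        for name in xp.identifiers(stmt.rhs_ast):
            if name not in env:
                env[name] = lookup(name)
        value = eval(stmt.code, {"__builtins__": {}}, env)
        target = stmt.target
        if target in variables:
            variables[target].set(stmt.op, value)
        else:
            if stmt.op == "=":
                temps[target] = np.broadcast_to(np.asarray(value, dtype=float), (n,)).copy()
            else:
                if target not in temps:
                    raise xp.ExpressionError(
                        f"in-place update of undefined temporary {target!r}"
                    )
                current = temps[target]
                if stmt.op == "+=":
                    current += value
                elif stmt.op == "-=":
                    current -= value
                elif stmt.op == "*=":
                    current *= value
                else:
                    current /= value


def evaluate(expr, variables, n, namespace=None, rng=None):
    """Evaluate a single expression vectorized over ``n`` instances.

    ``expr`` may be a source string or a pre-parsed AST node.  Resolution
    order matches :func:`execute`: views, then scalar namespace, then unit
    names.
    """
    if isinstance(expr, str):
        expr = xp.parse_expression(expr)
    namespace = namespace or {}
    env = xp.make_function_namespace(n, rng)
    for name in xp.identifiers(expr):
        if name in env:
            continue
        if name in variables:
            env[name] = variables[name].get()
        elif name in namespace:
            env[name] = namespace[name]
        elif name in UNIT_REGISTRY:
            env[name] = UNIT_REGISTRY[name].magnitude
        else:
            raise xp.ExpressionError(f"unresolved identifier {name!r}")
    return eval(xp.compile_expression(expr), {"__builtins__": {}}, env)


# ---------------------------------------------------------------------------
# Loop-dialect rendering
# ---------------------------------------------------------------------------

def _render_c(node: ast.expr) -> str:
    """Render an expression AST as C-like source with pow() for powers."""
    if isinstance(node, ast.Constant):
        if isinstance(node.value, bool):
            return "true" if node.value else "false"
        return repr(node.value)
    if isinstance(node, ast.Name):
        return node.id
    if isinstance(node, ast.UnaryOp):
        operand = _render_c(node.operand)
        if isinstance(node.op, ast.USub):
            if isinstance(node.operand, (ast.Constant, ast.Name)):
                return f"-{operand}"
            return f"-({operand})"
        if isinstance(node.op, ast.UAdd):
            return operand
        return f"!({operand})"
    if isinstance(node, ast.BinOp):
        left, right = _render_c(node.left), _render_c(node.right)
        if isinstance(node.op, ast.Pow):
            return f"pow({left}, {right})"
        if isinstance(node.op, ast.Mod):
            return f"fmod(fmod({left}, {right}) + {right}, {right})"
        op = {ast.Add: "+", ast.Sub: "-", ast.Mult: "*", ast.Div: "/"}[type(node.op)]
        return f"({left} {op} {right})"
    if isinstance(node, ast.BoolOp):
        op = " && " if isinstance(node.op, ast.And) else " || "
        return "(" + op.join(_render_c(v) for v in node.values) + ")"
    if isinstance(node, ast.Compare):
        parts = []
        left = node.left
        sym = {ast.Lt: "<", ast.LtE: "<=", ast.Gt: ">", ast.GtE: ">=",
               ast.Eq: "==", ast.NotEq: "!="}
        for op, comparator in zip(node.ops, node.comparators):
            parts.append(f"({_render_c(left)} {sym[type(op)]} {_render_c(comparator)})")
            left = comparator
        return " && ".join(parts)
    if isinstance(node, ast.Call):
        args = ", ".join(_render_c(a) for a in node.args)
        return f"{node.func.id}({args})"
    raise xp.ExpressionError(f"cannot render {ast.dump(node)}")


def render_loop_source(block, dialect="vectorized", state_vars=None):
    """Render a block as target-language source text (for inspection only).

    The ``vectorized`` dialect emits whole-array statements framed by array
    reads and copy-back writes; the ``loop`` dialect emits an explicit
    indexed loop with scalar reads before and writes after the statements,
    ``;`` terminators, and ``x**y`` replaced by ``pow(x, y)``.
    """
    if state_vars is None:
        state_vars = sorted(
            (block.read_set | block.write_set) - block.temp_set
        )
    reads = [v for v in state_vars if v in block.read_set | block.write_set]
    writes = [v for v in state_vars if v in block.write_set]

    if dialect == "vectorized":
        lines = [f"{v} = _array_{v}" for v in reads]
        lines += [stmt.render() for stmt in block.statements]
        lines += [f"_array_{v}[:] = {v}" for v in writes]
        return "\n".join(lines) + ("\n" if lines else "")
    if dialect != "loop":
        raise ValueError(f"unknown dialect {dialect!r}")

    body = [f"double {v} = _array_{v}[_idx];" for v in reads]
    declared = set(reads)
    for stmt in block.statements:
        rendered = _render_c(stmt.rhs_ast)
        if stmt.target not in declared:
            body.append(f"double {stmt.target} = {rendered};"
                        if stmt.op == "=" else f"double {stmt.target};")
            declared.add(stmt.target)
            if stmt.op == "=":
                continue
        body.append(f"{stmt.target} {stmt.op} {rendered};")
    body += [f"_array_{v}[_idx] = {v};" for v in writes]
    inner = "\n".join("    " + line for line in body)
    return (
        "for(int _idx=0; _idx<_N; _idx++)\n{\n" + inner + ("\n" if inner else "") + "}\n"
    )
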