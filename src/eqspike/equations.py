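"""Parsing of multi-line model descriptions into structured equations.

A model description is a multi-line string where each line is one of::

    dNAME/dt = EXPR : UNIT [(FLAG)]     # differential equation
    NAME = EXPR : UNIT [(FLAG)]         # named subexpression
    NAME : UNIT                         # parameter

``#`` starts a comment; a line ending inside unbalanced parentheses
continues on the next line.  Recognized flags are ``unless refractory``
(differential equations of neurons), ``event-driven`` (synaptic
differential equations) and ``summed`` (synaptic subexpressions named
``*_post``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import sympy

from . import expressions as xp
from .units import DIMENSIONLESS, Dimension, Quantity, parse_unit, render_dimension

__all__ = [
    "EquationError",
    "EquationEntry",
    "ModelEquations",
    "parse_model",
    "resolve_subexpressions",
    "split_drift_diffusion",
    "check_equation_dimensions",
]

DIFFERENTIAL = "differential"
SUBEXPRESSION = "subexpression"
PARAMETER = "parameter"

_FLAGS = {"unless refractory", "unless-refractory", "event-driven", "summed"}
_CANONICAL_FLAG = {"unless-refractory": "unless refractory"}


class EquationError(ValueError):
    """Grammar or consistency error in a model description."""


@dataclass
class EquationEntry:
    name: str
    kind: str
    rhs: Optional[str]
    unit: Dimension
    unit_str: str
    flags: frozenset = frozenset()
    stochastic_terms: frozenset = frozenset()

    @property
    def rhs_ast(self):
        return xp.parse_expression(self.rhs) if self.rhs is not None else None

    def render(self) -> str:
        flag = f" ({next(iter(self.flags))})" if self.flags else ""
        if self.kind == DIFFERENTIAL:
            return f"d{self.name}/dt = {self.rhs} : {self.unit_str}{flag}"
        if self.kind == SUBEXPRESSION:
            return f"{self.name} = {self.rhs} : {self.unit_str}{flag}"
        return f"{self.name} : {self.unit_str}"


class ModelEquations:
    """An ordered, validated set of equation entries keyed by variable name."""

    def __init__(self, entries):
        self.entries: dict = {}
        for entry in entries:
            if entry.name in self.entries:
                raise EquationError(f"duplicate definition of {entry.name!r}")
            self.entries[entry.name] = entry

    def __iter__(self):
        return iter(self.entries.values())

    def __contains__(self, name):
        return name in self.entries

    def __getitem__(self, name) -> EquationEntry:
        return self.entries[name]

    def __len__(self):
        return len(self.entries)

    def __eq__(self, other):
        if not isinstance(other, ModelEquations):
            return NotImplemented
        return [
            (e.name, e.kind, e.rhs, e.unit, e.flags, e.stochastic_terms)
            for e in self
        ] == [
            (e.name, e.kind, e.rhs, e.unit, e.flags, e.stochastic_terms)
            for e in other
        ]

    def by_kind(self, kind):
        return [e for e in self if e.kind == kind]

    @property
    def differential_names(self):
        return [e.name for e in self if e.kind == DIFFERENTIAL]

    @property
    def state_variable_names(self):
        """Variables with storage: differentials and parameters."""
        return [e.name for e in self if e.kind != SUBEXPRESSION]

    @property
    def stochastic_names(self):
        names = set()
        for entry in self:
            names |= entry.stochastic_terms
        return sorted(names)

    @property
    def is_stochastic(self):
        return bool(self.stochastic_names)

    def render(self) -> str:
        return "\n".join(entry.render() for entry in self)

    def __repr__(self):
        return f"ModelEquations(\n{self.render()}\n)"


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_DIFF_RE = re.compile(r"^d([A-Za-z_]\w*)\s*/\s*dt\s*=\s*(.+)$")
_SUB_RE = re.compile(r"^([A-Za-z_]\w*)\s*=\s*(.+)$")
_PARAM_RE = re.compile(r"^([A-Za-z_]\w*)\s*:\s*(.+)$")
_FLAG_RE = re.compile(r"^(.*?)\s*\(\s*([A-Za-z][A-Za-z -]*?)\s*\)\s*$")


def _logical_lines(text: str):
    """Yield (line_number, joined_line) with comments stripped and
    parenthesized continuations merged."""
    pending = ""
    pending_no = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0]
        if pending:
            pending += " " + line.strip()
        else:
            pending = line.strip()
            pending_no = lineno
        if not pending:
            pending = ""
            continue
        if pending.count("(") > pending.count(")"):
            continue  # line continues
        yield pending_no, pending
        pending = ""
    if pending:
        raise EquationError(f"line {pending_no}: unbalanced parentheses")


def _split_unit_and_flag(rest: str, lineno: int):
    """Split ``EXPR : UNIT (FLAG)`` right-hand side into components."""
    flag = None
    match = _FLAG_RE.match(rest)
    if match and match.group(2).strip() in _FLAGS:
        rest = match.group(1)
        flag = match.group(2).strip()
        flag = _CANONICAL_FLAG.get(flag, flag)
    if ":" not in rest:
        raise EquationError(f"line {lineno}: missing unit annotation (': UNIT')")
    expr, unit = rest.rsplit(":", 1)
    return expr.strip(), unit.strip(), flag


def parse_model(text: str) -> ModelEquations:
    """Parse a multi-line model description string.

    Grammar errors report line numbers; duplicate names, unknown flags,
    reserved names and flags on the wrong entry kind are rejected.
    """
    entries = []
    for lineno, line in _logical_lines(text):
        diff = _DIFF_RE.match(line)
        if diff:
            name, rest = diff.group(1), diff.group(2)
            rhs, unit_str, flag = _split_unit_and_flag(rest, lineno)
            entry = _make_entry(name, DIFFERENTIAL, rhs, unit_str, flag, lineno)
            entries.append(entry)
            continue
        # try parameter first only when there is no '=' sign
        if "=" not in line:
            param = _PARAM_RE.match(line)
            if param:
                name, unit_str = param.group(1), param.group(2).strip()
                match = _FLAG_RE.match(unit_str)
                if match and match.group(2).strip() in _FLAGS:
                    raise EquationError(
                        f"line {lineno}: flags are not allowed on parameters"
                    )
                entries.append(_make_entry(name, PARAMETER, None, unit_str, None, lineno))
                continue
            raise EquationError(f"line {lineno}: cannot parse {line!r}")
        sub = _SUB_RE.match(line)
        if sub:
            name, rest = sub.group(1), sub.group(2)
            rhs, unit_str, flag = _split_unit_and_flag(rest, lineno)
            entries.append(_make_entry(name, SUBEXPRESSION, rhs, unit_str, flag, lineno))
            continue
        raise EquationError(f"line {lineno}: cannot parse {line!r}")
    return ModelEquations(entries)


def _make_entry(name, kind, rhs, unit_str, flag, lineno) -> EquationEntry:
    if name in xp.RESERVED_NAMES or xp.is_xi_name(name):
        raise EquationError(f"line {lineno}: {name!r} is a reserved name")
    if name == "lastspike" or name == "lastupdate":
        raise EquationError(f"line {lineno}: {name!r} is a reserved name")
    try:
        unit = parse_unit(unit_str).dim
    except Exception as exc:
        raise EquationError(f"line {lineno}: {exc}") from None
    flags = frozenset() if flag is None else frozenset({flag})
    stochastic = frozenset()
    if rhs is not None:
        node = _parse_rhs(rhs, lineno)
        stochastic = frozenset(
            n for n in xp.identifiers(node) if xp.is_xi_name(n)
        )
    if flag == "unless refractory" and kind != DIFFERENTIAL:
        raise EquationError(
            f"line {lineno}: 'unless refractory' is only valid on differential equations"
        )
    if flag == "event-driven" and kind != DIFFERENTIAL:
        raise EquationError(
            f"line {lineno}: 'event-driven' is only valid on differential equations"
        )
    if flag == "summed":
        if kind != SUBEXPRESSION:
            raise EquationError(
                f"line {lineno}: 'summed' is only valid on subexpressions"
            )
        if not name.endswith("_post"):
            raise EquationError(
                f"line {lineno}: summed variable {name!r} must end with '_post'"
            )
    if stochastic and kind != DIFFERENTIAL:
        raise EquationError(
            f"line {lineno}: stochastic term in non-differential entry {name!r}"
        )
    return EquationEntry(
        name=name,
        kind=kind,
        rhs=rhs,
        unit=unit,
        unit_str=unit_str,
        flags=flags,
        stochastic_terms=stochastic,
    )


def _parse_rhs(rhs, lineno):
    try:
        return xp.parse_expression(rhs)
    except xp.ExpressionError as exc:
        raise EquationError(f"line {lineno}: {exc}") from None


# ---------------------------------------------------------------------------
# Subexpression resolution
# ---------------------------------------------------------------------------

def _subexpression_order(eqs: ModelEquations, include_summed=False):
    """Topological order of subexpressions; raises on cycles."""
    subs = {
        e.name: e
        for e in eqs.by_kind(SUBEXPRESSION)
        if include_summed or "summed" not in e.flags
    }
    order, state = [], {}

    def visit(name, stack):
        if state.get(name) == "done":
            return
        if state.get(name) == "visiting":
            cycle = " -> ".join(stack[stack.index(name):] + [name])
            raise EquationError(f"cyclic subexpressions: {cycle}")
        state[name] = "visiting"
        for dep in xp.identifiers(subs[name].rhs_ast):
            if dep in subs:
                visit(dep, stack + [name])
        state[name] = "done"
        order.append(name)

    for name in subs:
        visit(name, [])
    return [subs[name] for name in order]


def resolve_subexpressions(eqs: ModelEquations) -> ModelEquations:
    """Substitute (non-summed) subexpression definitions into all other
    right-hand sides, yielding a semantically equivalent model."""
    order = _subexpression_order(eqs)
    resolved: dict = {}
    for entry in order:
        expr = xp.to_sympy(entry.rhs)
        expr = expr.subs({sympy.Symbol(n): resolved[n] for n in resolved})
        resolved[entry.name] = expr

    new_entries = []
    for entry in eqs:
        if entry.rhs is None or entry.name in resolved:
            new_entries.append(entry)
            continue
        node_ids = xp.identifiers(entry.rhs_ast)
        if not (node_ids & set(resolved)):
            new_entries.append(entry)
            continue
        expr = xp.to_sympy(entry.rhs)
        expr = expr.subs({sympy.Symbol(n): resolved[n] for n in resolved})
        new_entries.append(
            EquationEntry(
                name=entry.name,
                kind=entry.kind,
                rhs=xp.sympy_to_str(expr),
                unit=entry.unit,
                unit_str=entry.unit_str,
                flags=entry.flags,
                stochastic_terms=entry.stochastic_terms,
            )
        )
    return ModelEquations(new_entries)


# ---------------------------------------------------------------------------
# Drift/diffusion split
# ---------------------------------------------------------------------------

def split_drift_diffusion(eqs: ModelEquations):
    """Split each differential right-hand side into drift ``f`` and
    per-noise-process diffusion factors ``g``.

    Returns ``(f, g)`` where ``f`` maps variable name to a SymPy drift
    expression and ``g`` maps ``(variable, xi_name)`` to the multiplicative
    factor of that noise process.  Every right-hand side must be affine in
    each noise symbol.
    """
    xi_names = eqs.stochastic_names
    xi_syms = [sympy.Symbol(n) for n in xi_names]
    f, g = {}, {}
    for entry in eqs.by_kind(DIFFERENTIAL):
        expr = sympy.expand(xp.to_sympy(entry.rhs))
        drift = expr
        for xi_name, xi_sym in zip(xi_names, xi_syms):
            coeff = expr.coeff(xi_sym, 1)
            if coeff != 0:
                if coeff.has(*xi_syms):
                    raise EquationError(
                        f"nonlinear noise term in d{entry.name}/dt"
                    )
                g[(entry.name, xi_name)] = coeff
            drift = drift - coeff * xi_sym
        drift = sympy.expand(drift)
        if xi_syms and drift.has(*xi_syms):
            raise EquationError(
                f"unsupported nonlinear occurrence of a noise symbol in d{entry.name}/dt"
            )
        f[entry.name] = drift
    return f, g


# ---------------------------------------------------------------------------
# Dimensional consistency
# ---------------------------------------------------------------------------

def check_equation_dimensions(eqs: ModelEquations, namespace=None, extra_dims=None):
    """Check every equation's unit annotation against its right-hand side.

    For a differential equation ``dx/dt = rhs : U`` the rhs must have
    dimension ``U/second``; for a subexpression ``x = rhs : U`` it must have
    dimension ``U``.  Returns a list of human-readable violation strings
    (empty iff the model is consistent).  Unresolvable identifiers raise.
    """
    symbol_dims = {}
    if namespace:
        for name, value in namespace.items():
            symbol_dims[name] = value.dim if isinstance(value, Quantity) else DIMENSIONLESS
    if extra_dims:
        symbol_dims.update(extra_dims)
    for entry in eqs:
        symbol_dims[entry.name] = entry.unit

    violations = []
    for entry in eqs:
        if entry.rhs is None:
            continue
        actual = xp.dims_of_expression(entry.rhs_ast, symbol_dims)
        if entry.kind == DIFFERENTIAL:
            expected = entry.unit / xp.SECOND
            label = f"{entry.unit_str}/second"
        else:
            expected = entry.unit
            label = entry.unit_str
        if actual != expected:
            violations.append(
                f"{entry.name}: expected {label} "
                f"({render_dimension(expected)}), got {render_dimension(actual)}"
            )
    return violations
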