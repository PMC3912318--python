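"""Textual integration schemes and their symbolic application to models.

An explicit integration method is written as a short sequence of
statements over the symbols ``x`` (the state vector), ``t``, ``dt``, the
drift function ``f(x, t)``, the diffusion factor ``g(x, t)`` and the Wiener
increment ``dW``; the final statement assigns ``x_new``.  Applying a scheme
to a set of model equations expands every statement componentwise over the
state variables, producing abstract code.

Also provided: closed-form event-driven updates for independent linear
synaptic equations (``dA/dt = a*A`` becomes
``A = A*exp(a*(t - lastupdate))`` applied lazily at spike times).
"""

from __future__ import annotations

from dataclasses import dataclass

import sympy

from . import expressions as xp
from .abstract_code import AbstractCodeBlock, AbstractStatement
from .equations import (
    DIFFERENTIAL,
    EquationError,
    ModelEquations,
    split_drift_diffusion,
)

__all__ = [
    "SchemeError",
    "SchemeDescription",
    "parse_scheme",
    "get_scheme",
    "apply_scheme",
    "event_driven_updates",
    "symbolic_state_update",
    "BUILTIN_SCHEMES",
]


class SchemeError(ValueError):
    """Malformed scheme description or unsupported scheme/model pairing."""


_X = sympy.Symbol("x")
_T = sympy.Symbol("t")
_DT = sympy.Symbol("dt")
_DW = sympy.Symbol("dW")
_SCALARS = {"t", "dt"}


@dataclass
class SchemeDescription:
    """Parsed integration method: ordered (name, expression) statements,
    the last of which assigns ``x_new``."""

    statements: list
    is_stochastic: bool
    text: str

    @property
    def temp_names(self):
        return [name for name, _ in self.statements[:-1]]


def parse_scheme(text: str) -> SchemeDescription:
    """Parse a multi-line scheme description.

    Each line is ``NAME = EXPR``; ``x_new`` must be assigned exactly once,
    by the final statement.  Temporaries must be assigned before use;
    ``g``/``dW`` mark the scheme as stochastic.
    """
    statements = []
    known = set(_SCALARS) | {"x", "dW"}
    uses_noise = False
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SchemeError(f"malformed scheme line {line!r}")
        name, _, rhs = line.partition("=")
        name = name.strip()
        if not name.isidentifier():
            raise SchemeError(f"invalid statement target {name!r}")
        if name in ("x", "t", "dt", "dW", "x_prev"):
            raise SchemeError(f"cannot assign to {name!r} in a scheme")
        if name == "y":
            raise SchemeError("temporary name 'y' is reserved")
        if any(name == existing for existing, _ in statements):
            raise SchemeError(f"duplicate assignment to {name!r}")
        node = xp.parse_expression(rhs, extra_functions=("f", "g"))
        for ident in xp.identifiers(node):
            if ident in ("x_new", "x_prev"):
                raise SchemeError(
                    f"{ident!r} may not appear on a right-hand side (explicit "
                    "single-step schemes only)"
                )
            if ident not in known:
                raise SchemeError(f"unknown symbol {ident!r} in scheme")
        expr = xp.to_sympy(node)
        if expr.has(sympy.Function("g")) or expr.has(_DW):
            uses_noise = True
        statements.append((name, expr))
        known.add(name)
    if not statements or statements[-1][0] != "x_new":
        raise SchemeError("the final scheme statement must assign x_new")
    if any(name == "x_new" for name, _ in statements[:-1]):
        raise SchemeError("x_new must be assigned exactly once, last")
    return SchemeDescription(statements=statements, is_stochastic=uses_noise, text=text)


BUILTIN_SCHEMES = {
    "euler": "x_new = x + dt*f(x,t)",
    "midpoint": "k = dt*f(x,t)\nx_new = x + dt*f(x + k/2, t + dt/2)",
    "euler_maruyama": "x_new = x + dt*f(x,t) + g(x,t)*dW",
}


def get_scheme(method) -> SchemeDescription:
    """Resolve a scheme from a name, description text or parsed object."""
    if isinstance(method, SchemeDescription):
        return method
    if method in BUILTIN_SCHEMES:
        return parse_scheme(BUILTIN_SCHEMES[method])
    return parse_scheme(method)


# ---------------------------------------------------------------------------
# Scheme application
# ---------------------------------------------------------------------------

def _dw_name(xi_name: str) -> str:
    return f"_dW_{xi_name}"


class _Expander:
    """Componentwise expansion of one scheme over one model."""

    def __init__(self, scheme, eqs):
        self.scheme = scheme
        self.variables = eqs.differential_names
        self.f, self.g = split_drift_diffusion(eqs)
        self.xi_names = eqs.stochastic_names
        state_syms = [sympy.Symbol(v) for v in self.variables]
        for (var, xi), factor in self.g.items():
            if factor.has(*state_syms):
                raise SchemeError(
                    f"state-dependent (multiplicative) noise factor for "
                    f"d{var}/dt is not supported; only additive noise is"
                )
        if self.xi_names and not scheme.is_stochastic:
            raise SchemeError(
                "stochastic model equations require a stochastic scheme"
            )
        self.temp_names = set(scheme.temp_names)

    def target_for(self, name, var):
        if name == "x_new":
            return f"_y_{var}"
        return f"_{name}_{var}"

    def component(self, expr, var):
        """Map a scheme-space expression to its component for ``var``."""
        if expr.is_Symbol:
            name = expr.name
            if name == "x":
                return sympy.Symbol(var)
            if name in self.temp_names:
                return sympy.Symbol(f"_{name}_{var}")
            if name in _SCALARS:
                return expr
            if name == "dW":
                raise SchemeError("dW may only appear multiplying g(x, t)")
            return expr
        if expr.is_Mul:
            g_calls = [a for a in expr.args
                       if a.func == sympy.Function("g")]
            has_dw = _DW in expr.args
            if g_calls or has_dw:
                if len(g_calls) != 1 or not has_dw:
                    raise SchemeError(
                        "g(x, t) and dW must appear together as a product g(x,t)*dW"
                    )
                rest = [a for a in expr.args if a not in (g_calls[0], _DW)]
                coeff = sympy.Mul(*[self.component(a, var) for a in rest])
                return coeff * self._expand_g(g_calls[0], var)
            return sympy.Mul(*[self.component(a, var) for a in expr.args])
        if expr.func == sympy.Function("f"):
            return self._expand_f(expr, var)
        if expr.func == sympy.Function("g"):
            raise SchemeError("g(x, t) may only appear multiplied by dW")
        if expr.args:
            return expr.func(*[self.component(a, var) for a in expr.args])
        return expr

    def _substitution(self, call, var):
        if len(call.args) != 2:
            raise SchemeError("f()/g() take exactly two arguments (x, t)")
        x_arg, t_arg = call.args
        mapping = {
            sympy.Symbol(u): self.component(x_arg, u) for u in self.variables
        }
        mapping[_T] = self.component(t_arg, var)
        return mapping

    def _expand_f(self, call, var):
        return self.f[var].xreplace(self._substitution(call, var))

    def _expand_g(self, call, var):
        mapping = self._substitution(call, var)
        total = sympy.Integer(0)
        for xi in self.xi_names:
            factor = self.g.get((var, xi))
            if factor is None:
                continue
            total += factor.xreplace(mapping) * sympy.Symbol(_dw_name(xi))
        return total


def apply_scheme(scheme, eqs: ModelEquations) -> AbstractCodeBlock:
    """Combine an integration scheme with model equations into abstract code.

    For each scheme statement, the drift ``f`` (and diffusion ``g``) are
    expanded componentwise over the state variables, ``x_new`` is replaced
    by fresh per-variable names, and per-variable statements are appended;
    copy-back statements follow.  ``dW`` expands to one fresh
    ``randn()*sqrt(dt)`` draw per noise process per step, shared across all
    variables referencing the same process.
    """
    scheme = get_scheme(scheme)
    expander = _Expander(scheme, eqs)
    statements = []
    for xi in expander.xi_names:
        statements.append(
            AbstractStatement(_dw_name(xi), "=", "randn() * sqrt(dt)")
        )
    for name, expr in scheme.statements:
        for var in expander.variables:
            component = expander.component(expr, var)
            statements.append(
                AbstractStatement(
                    expander.target_for(name, var), "=", xp.sympy_to_str(component)
                )
            )
    for var in expander.variables:
        statements.append(AbstractStatement(var, "=", f"_y_{var}"))
    return AbstractCodeBlock(statements)


# ---------------------------------------------------------------------------
# Event-driven closed forms
# ---------------------------------------------------------------------------

def event_driven_updates(eqs: ModelEquations) -> dict:
    """Closed-form spike-time updates for event-driven linear equations.

    Each differential entry flagged ``event-driven`` must have the form
    ``dx/dt = a*x`` with ``a`` a state-independent constant expression; the
    returned mapping gives the update ``x = x*exp(a*(t - lastupdate))`` to
    run before any pre/post statement block (with ``lastupdate = t``
    appended afterwards).
    """
    # 'constant' means independent of any dynamic variable; per-instance
    # parameters such as time constants are fine
    state_syms = [sympy.Symbol(n) for n in eqs.differential_names]
    updates = {}
    for entry in eqs.by_kind(DIFFERENTIAL):
        if "event-driven" not in entry.flags:
            continue
        var = sympy.Symbol(entry.name)
        rhs = xp.to_sympy(entry.rhs)
        a = sympy.diff(rhs, var)
        if a.has(*state_syms) or sympy.simplify(rhs - a * var) != 0:
            raise SchemeError(
                f"event-driven equation d{entry.name}/dt = {entry.rhs} is not "
                "an independent linear equation (dx/dt = a*x)"
            )
        if a == 0:
            updates[entry.name] = entry.name  # dx/dt = 0: no-op update
            continue
        expr = var * sympy.exp(a * (_T - sympy.Symbol("lastupdate")))
        updates[entry.name] = xp.sympy_to_str(expr)
    return updates


# ---------------------------------------------------------------------------
# Symbolic execution helper (used in tests and validation)
# ---------------------------------------------------------------------------

def symbolic_state_update(block: AbstractCodeBlock, var_names) -> dict:
    """Symbolically execute ``block`` and return, per state variable, the
    final value expressed in terms of the initial state symbols."""
    env = {}

    def substitute(expr):
        return expr.xreplace({sympy.Symbol(n): v for n, v in env.items()})

    for stmt in block.statements:
        rhs = substitute(xp.to_sympy(stmt.rhs_ast))
        if stmt.op == "=":
            env[stmt.target] = rhs
        else:
            current = env.get(stmt.target, sympy.Symbol(stmt.target))
            if stmt.op == "+=":
                env[stmt.target] = current + rhs
            elif stmt.op == "-=":
                env[stmt.target] = current - rhs
            elif stmt.op == "*=":
                env[stmt.target] = current * rhs
            else:
                env[stmt.target] = current / rhs
    return {v: env.get(v, sympy.Symbol(v)) for v in var_names}
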