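"""Automatic human-readable / LaTeX documentation of models.

Because models are defined by strings, a formatted description can be
regenerated from the model objects at any time and is therefore always in
sync with what is actually simulated.
"""

from __future__ import annotations

import ast

import numpy as np
import sympy

from . import expressions as xp
from .equations import DIFFERENTIAL, PARAMETER, SUBEXPRESSION, ModelEquations
from .units import Quantity, render_unit

__all__ = [
    "equations_to_latex",
    "equations_to_text",
    "describe_assignment",
    "model_report",
]

_GREEK = {
    "alpha": "α", "beta": "β", "gamma": "γ", "delta": "δ", "epsilon": "ε",
    "eta": "η", "theta": "θ", "kappa": "κ", "lambda": "λ", "mu": "μ",
    "nu": "ν", "rho": "ρ", "sigma": "σ", "tau": "τ", "phi": "φ",
    "chi": "χ", "psi": "ψ", "omega": "ω", "xi": "ξ", "pi": "π",
}

# display scaling for scalar quantities
_PREFIX_STEPS = [
    (1e9, "G"), (1e6, "M"), (1e3, "k"), (1.0, ""),
    (1e-3, "m"), (1e-6, "u"), (1e-9, "n"), (1e-12, "p"),
]


def pretty_name(name: str) -> str:
    """Map identifier spellings like ``tau_m`` to ``τ_m``."""
    head, _, tail = name.partition("_")
    head = _GREEK.get(head, head)
    return f"{head}_{tail}" if tail else head


def _latex_name(name: str) -> str:
    return sympy.latex(sympy.Symbol(name))


def _unit_label(dim) -> str:
    return render_unit(dim)


def equations_to_latex(eqs: ModelEquations) -> list:
    """One LaTeX line per equation entry, with a ``(unit: U)`` annotation."""
    lines = []
    for entry in eqs:
        unit = _unit_label(entry.unit)
        if entry.kind == DIFFERENTIAL:
            lhs = r"\frac{d %s}{d t}" % _latex_name(entry.name)
            rhs = sympy.latex(xp.to_sympy(entry.rhs))
            lines.append(rf"{lhs} = {rhs} \quad \text{{(unit: {unit})}}")
        elif entry.kind == SUBEXPRESSION:
            rhs = sympy.latex(xp.to_sympy(entry.rhs))
            lines.append(
                rf"{_latex_name(entry.name)} = {rhs} \quad \text{{(unit: {unit})}}"
            )
        else:
            lines.append(rf"{_latex_name(entry.name)} \quad \text{{(unit: {unit})}}")
    return lines


def equations_to_text(eqs: ModelEquations) -> list:
    """Plain-text twin of :func:`equations_to_latex`."""
    lines = []
    for entry in eqs:
        unit = _unit_label(entry.unit)
        if entry.kind == DIFFERENTIAL:
            lines.append(f"d{entry.name}/dt = {entry.rhs}  (unit: {unit})")
        elif entry.kind == SUBEXPRESSION:
            lines.append(f"{entry.name} = {entry.rhs}  (unit: {unit})")
        else:
            lines.append(f"{entry.name}  (unit: {unit})")
    return lines


# ---------------------------------------------------------------------------
# Assignment descriptions
# ---------------------------------------------------------------------------

def format_quantity(value: Quantity) -> str:
    """Render a scalar quantity with a sensible SI prefix, e.g. ``20 ms``."""
    if not isinstance(value, Quantity):
        value = Quantity(float(value))
    magnitude = float(value.magnitude)
    if value.dim.is_dimensionless:
        return _trim(magnitude)
    unit = render_unit(value.dim)
    if magnitude == 0:
        return f"0 {unit}"
    for scale, prefix in _PREFIX_STEPS:
        if abs(magnitude) >= scale:
            return f"{_trim(magnitude / scale)} {prefix}{unit}"
    return f"{_trim(magnitude)} {unit}"


def _trim(x: float) -> str:
    text = f"{x:.12g}"
    return text


def _describe_node(node: ast.expr) -> str:
    if isinstance(node, ast.Constant):
        return _trim(float(node.value))
    if isinstance(node, ast.Name):
        return pretty_name(node.id)
    if isinstance(node, ast.UnaryOp):
        inner = _describe_node(node.operand)
        if isinstance(node.op, ast.USub):
            return f"-{inner}"
        return inner
    if isinstance(node, ast.BinOp):
        left = _describe_node(node.left)
        right = _describe_node(node.right)
        if isinstance(node.op, ast.Add):
            return f"{left} + {right}"
        if isinstance(node.op, ast.Sub):
            return f"{left} - {right}"
        if isinstance(node.op, ast.Div):
            return f"{left} / {right}"
        if isinstance(node.op, ast.Pow):
            return f"{left}^{right}"
        # multiplication: NUMBER*unit renders as "20 ms", otherwise a dot
        from .units import UNIT_REGISTRY

        if isinstance(node.right, ast.Name) and node.right.id in UNIT_REGISTRY:
            if isinstance(node.left, ast.Constant):
                return f"{left} {node.right.id}"
            # reassociate (expr * NUMBER) * unit -> expr · NUMBER unit
            if (isinstance(node.left, ast.BinOp)
                    and isinstance(node.left.op, ast.Mult)
                    and isinstance(node.left.right, ast.Constant)):
                head = _describe_node(node.left.left)
                num = _describe_node(node.left.right)
                return f"{head} · {num} {node.right.id}"
        return f"{left} · {right}"
    if isinstance(node, ast.Call):
        fname = node.func.id
        if fname == "randn":
            return "N(0, 1)"
        if fname == "rand":
            return "U(0, 1)"
        args = ", ".join(_describe_node(a) for a in node.args)
        return f"{fname}({args})"
    if isinstance(node, ast.Compare):
        sym = {ast.Lt: "<", ast.LtE: "<=", ast.Gt: ">", ast.GtE: ">=",
               ast.Eq: "=", ast.NotEq: "!="}
        parts = [_describe_node(node.left)]
        for op, comparator in zip(node.ops, node.comparators):
            parts.append(sym[type(op)])
            parts.append(_describe_node(comparator))
        return " ".join(parts)
    return "<expression>"


def describe_assignment(var: str, source) -> str:
    """Human-readable one-liner for a recorded state assignment.

    Scalars render with units (``τ_m = 20 ms``); expression strings render
    with ``randn()`` as the standard-normal symbol and ``rand()`` as the
    uniform symbol; raw arrays fall back to summary statistics and are
    flagged as non-symbolic.
    """
    name = pretty_name(var)
    if isinstance(source, str):
        return f"{name} = {_describe_node(xp.parse_expression(source))}"
    if isinstance(source, Quantity) and np.ndim(source.magnitude) == 0:
        return f"{name} = {format_quantity(source)}"
    if isinstance(source, (int, float)):
        return f"{name} = {format_quantity(Quantity(float(source)))}"
    values = np.asarray(
        source.magnitude if isinstance(source, Quantity) else source, dtype=float
    )
    return (
        f"{name} = <array of {values.size} values; non-symbolic; "
        f"min {_trim(values.min())}, max {_trim(values.max())}, "
        f"mean {_trim(values.mean())}, sd {_trim(values.std())}>"
    )


# ---------------------------------------------------------------------------
# Whole-group reports
# ---------------------------------------------------------------------------

def model_report(group, fmt="text") -> str:
    """A full report for a neuron group or synapse store.

    Contains the rendered equations, the event-related expressions
    (threshold/reset/refractoriness or pre/post statements), every recorded
    state assignment and a table of external constants.  Rendering is pure:
    the same model produces byte-identical output.
    """
    lines = [f"== {group.name} =="]
    renderer = equations_to_latex if fmt == "latex" else equations_to_text
    if len(group.eqs):
        lines.append("equations:")
        lines.extend("  " + line for line in renderer(group.eqs))
    threshold = getattr(group, "threshold", None)
    if threshold:
        lines.append(f"threshold: {threshold}")
    reset = getattr(group, "reset", None)
    if reset is not None and len(reset):
        lines.append("reset: " + "; ".join(s.render() for s in reset.statements))
    refractory = getattr(group, "refractory_condition", None)
    if refractory:
        lines.append(f"refractory: {refractory}")
    for pathway in getattr(group, "pathways", []):
        lines.append(
            f"on {pathway.direction}-synaptic spike: "
            + "; ".join(s.render() for s in pathway.statements)
        )
    if group.assignments:
        lines.append("assignments:")
        for var, source in group.assignments.items():
            lines.append("  " + describe_assignment(var, source))
    if group.namespace:
        lines.append("constants:")
        for name, value in sorted(group.namespace.items()):
            lines.append(f"  {describe_assignment(name, value)}")
    return "\n".join(lines) + "\n"
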