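"""Physical dimensions and quantities.

Every state variable, constant and expression in a model carries a
:class:`Dimension` — a vector of rational exponents over the seven SI base
dimensions.  Values are stored as plain floats in base SI units; unit names
(``mV``, ``nS``, ...) exist only at the parse/render boundary, where they
evaluate to scale factors.

Dimension exponents are :class:`fractions.Fraction` so that ``sqrt`` and
fractional powers such as ``tau**-0.5`` stay exact.
"""

from __future__ import annotations

import ast
from fractions import Fraction
from typing import Union

import numpy as np

__all__ = [
    "Dimension",
    "Quantity",
    "DimensionError",
    "UnitParseError",
    "DIMENSIONLESS",
    "UNIT_REGISTRY",
    "parse_unit",
    "render_dimension",
]


class DimensionError(TypeError):
    """Raised when an operation combines incompatible dimensions."""


class UnitParseError(ValueError):
    """Raised for an unknown or malformed unit token."""


_BASE_NAMES = ("m", "kg", "s", "A", "K", "mol", "cd")


def _as_fraction(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, float):
        f = Fraction(x).limit_denominator(1000)
        if float(f) != x:
            raise DimensionError(f"exponent {x} is not a small rational")
        return f
    raise DimensionError(f"invalid exponent {x!r}")


class Dimension:
    """A point in the lattice of SI base-dimension exponents.

    The exponent order is (length, mass, time, current, temperature,
    amount, luminous intensity).
    """

    __slots__ = ("exponents",)

    def __init__(self, exponents=(0, 0, 0, 0, 0, 0, 0)):
        exps = tuple(_as_fraction(e) for e in exponents)
        if len(exps) != 7:
            raise ValueError("need exactly 7 exponents")
        self.exponents = exps

    @property
    def is_dimensionless(self) -> bool:
        return all(e == 0 for e in self.exponents)

    def __mul__(self, other: "Dimension") -> "Dimension":
        return Dimension(tuple(a + b for a, b in zip(self.exponents, other.exponents)))

    def __truediv__(self, other: "Dimension") -> "Dimension":
        return Dimension(tuple(a - b for a, b in zip(self.exponents, other.exponents)))

    def __pow__(self, exponent) -> "Dimension":
        q = _as_fraction(exponent)
        return Dimension(tuple(e * q for e in self.exponents))

    def sqrt(self) -> "Dimension":
        return self ** Fraction(1, 2)

    def __eq__(self, other) -> bool:
        return isinstance(other, Dimension) and self.exponents == other.exponents

    def __hash__(self):
        return hash(self.exponents)

    def __repr__(self):
        if self.is_dimensionless:
            return "Dimension(1)"
        return f"Dimension({render_dimension(self)!r})"


DIMENSIONLESS = Dimension()

# base dimensions
_LENGTH = Dimension((1, 0, 0, 0, 0, 0, 0))
_MASS = Dimension((0, 1, 0, 0, 0, 0, 0))
_TIME = Dimension((0, 0, 1, 0, 0, 0, 0))
_CURRENT = Dimension((0, 0, 0, 1, 0, 0, 0))


def render_dimension(dim: Dimension) -> str:
    """Render a dimension in terms of SI base symbols, e.g. ``m**2 kg s**-3 A**-1``."""
    if dim.is_dimensionless:
        return "1"
    parts = []
    for name, exp in zip(_BASE_NAMES, dim.exponents):
        if exp == 0:
            continue
        if exp == 1:
            parts.append(name)
        else:
            e = int(exp) if exp.denominator == 1 else float(exp)
            parts.append(f"{name}**{e}")
    return " ".join(parts)


def _coerce(value):
    if isinstance(value, Quantity):
        return value
    return Quantity(value, DIMENSIONLESS)


class Quantity:
    """A magnitude (scalar or array) together with a :class:`Dimension`.

    Addition, subtraction and comparison require equal dimensions;
    multiplication and division combine them.
    """

    __slots__ = ("magnitude", "dim")

    def __init__(self, magnitude, dim: Dimension = DIMENSIONLESS):
        self.magnitude = magnitude
        self.dim = dim

    # -- helpers ---------------------------------------------------------
    def _require_same(self, other: "Quantity", op: str) -> None:
        if self.dim != other.dim:
            raise DimensionError(
                f"cannot {op} quantities with dimensions "
                f"{render_dimension(self.dim)} and {render_dimension(other.dim)}"
            )

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = _coerce(other)
        self._require_same(other, "add")
        return Quantity(self.magnitude + other.magnitude, self.dim)

    __radd__ = __add__

    def __sub__(self, other):
        other = _coerce(other)
        self._require_same(other, "subtract")
        return Quantity(self.magnitude - other.magnitude, self.dim)

    def __rsub__(self, other):
        return _coerce(other).__sub__(self)

    def __mul__(self, other):
        other = _coerce(other)
        return Quantity(self.magnitude * other.magnitude, self.dim * other.dim)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _coerce(other)
        return Quantity(self.magnitude / other.magnitude, self.dim / other.dim)

    def __rtruediv__(self, other):
        return _coerce(other).__truediv__(self)

    def __pow__(self, exponent):
        if isinstance(exponent, Quantity):
            if not exponent.dim.is_dimensionless:
                raise DimensionError("exponent must be dimensionless")
            exponent = exponent.magnitude
        return Quantity(self.magnitude ** exponent, self.dim ** exponent)

    def __neg__(self):
        return Quantity(-self.magnitude, self.dim)

    def __abs__(self):
        return Quantity(abs(self.magnitude), self.dim)

    # -- comparisons -----------------------------------------------------
    def __eq__(self, other):
        other = _coerce(other)
        if self.dim != other.dim:
            return False
        return bool(np.all(self.magnitude == other.magnitude))

    def __hash__(self):
        return hash((float(self.magnitude), self.dim))

    def _cmp(self, other, op):
        other = _coerce(other)
        self._require_same(other, "compare")
        return op(self.magnitude, other.magnitude)

    def __lt__(self, other):
        return self._cmp(other, lambda a, b: a < b)

    def __le__(self, other):
        return self._cmp(other, lambda a, b: a <= b)

    def __gt__(self, other):
        return self._cmp(other, lambda a, b: a > b)

    def __ge__(self, other):
        return self._cmp(other, lambda a, b: a >= b)

    def __float__(self):
        return float(self.magnitude)

    def __repr__(self):
        if self.dim.is_dimensionless:
            return f"Quantity({self.magnitude!r})"
        return f"Quantity({self.magnitude!r}, {render_dimension(self.dim)!r})"


# ---------------------------------------------------------------------------
# Unit registry
# ---------------------------------------------------------------------------

# name -> (scale to base SI, dimension); full names plus short symbols
_BASE_UNITS = {
    "metre": (1.0, _LENGTH),
    "meter": (1.0, _LENGTH),
    "m": (1.0, _LENGTH),
    "second": (1.0, _TIME),
    "s": (1.0, _TIME),
    "gram": (1e-3, _MASS),
    "g": (1e-3, _MASS),
    "kilogram": (1.0, _MASS),
    "kg": (1.0, _MASS),
    "amp": (1.0, _CURRENT),
    "ampere": (1.0, _CURRENT),
    "A": (1.0, _CURRENT),
    "volt": (1.0, _MASS * _LENGTH ** 2 / (_TIME ** 3 * _CURRENT)),
    "V": (1.0, _MASS * _LENGTH ** 2 / (_TIME ** 3 * _CURRENT)),
    "siemens": (1.0, _CURRENT ** 2 * _TIME ** 3 / (_MASS * _LENGTH ** 2)),
    "S": (1.0, _CURRENT ** 2 * _TIME ** 3 / (_MASS * _LENGTH ** 2)),
    "farad": (1.0, _CURRENT ** 2 * _TIME ** 4 / (_MASS * _LENGTH ** 2)),
    "F": (1.0, _CURRENT ** 2 * _TIME ** 4 / (_MASS * _LENGTH ** 2)),
    "ohm": (1.0, _MASS * _LENGTH ** 2 / (_TIME ** 3 * _CURRENT ** 2)),
    "hertz": (1.0, DIMENSIONLESS / _TIME),
    "Hz": (1.0, DIMENSIONLESS / _TIME),
    "coulomb": (1.0, _CURRENT * _TIME),
    "C": (1.0, _CURRENT * _TIME),
}

_PREFIXES = {
    "p": 1e-12,
    "n": 1e-9,
    "u": 1e-6,
    "μ": 1e-6,  # μ
    "m": 1e-3,
    "k": 1e3,
    "M": 1e6,
    "G": 1e9,
}


def _build_registry() -> dict:
    reg = {}
    for name, (scale, dim) in _BASE_UNITS.items():
        reg[name] = Quantity(scale, dim)
    for name, (scale, dim) in _BASE_UNITS.items():
        if name in ("kg", "kilogram"):  # no double prefixes
            continue
        for prefix, factor in _PREFIXES.items():
            token = prefix + name
            # do not shadow a base unit ('ms' is fine, but e.g. 'mA' vs base
            # names never collide in this set)
            if token in _BASE_UNITS:
                continue
            reg[token] = Quantity(factor * scale, dim)
    return reg


UNIT_REGISTRY: dict = _build_registry()


def is_unit_name(token: str) -> bool:
    return token in UNIT_REGISTRY


def unit_quantity(token: str) -> Quantity:
    try:
        return UNIT_REGISTRY[token]
    except KeyError:
        raise UnitParseError(f"unknown unit {token!r}") from None


def parse_unit(token: str) -> Quantity:
    """Parse a unit annotation into a scale factor plus dimension.

    Supports bare unit names with SI prefixes (``mV``), ``1`` for
    dimensionless, and products/quotients/powers of units such as
    ``volt/second`` or ``metre**2``.
    """
    token = token.strip()
    if token == "1":
        return Quantity(1.0, DIMENSIONLESS)
    try:
        tree = ast.parse(token, mode="eval")
    except SyntaxError:
        raise UnitParseError(f"malformed unit {token!r}") from None
    return _eval_unit_node(tree.body, token)


def _eval_unit_node(node: ast.AST, token: str) -> Quantity:
    if isinstance(node, ast.Name):
        try:
            return unit_quantity(node.id)
        except UnitParseError:
            raise UnitParseError(
                f"unknown unit {node.id!r} in annotation {token!r}"
            ) from None
    if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
        return Quantity(float(node.value), DIMENSIONLESS)
    if isinstance(node, ast.BinOp):
        left = _eval_unit_node(node.left, token)
        right = _eval_unit_node(node.right, token)
        if isinstance(node.op, ast.Mult):
            return left * right
        if isinstance(node.op, ast.Div):
            return left / right
        if isinstance(node.op, ast.Pow):
            if not right.dim.is_dimensionless:
                raise UnitParseError(f"dimensioned exponent in {token!r}")
            return left ** right.magnitude
        raise UnitParseError(f"unsupported operator in unit {token!r}")
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
        return Quantity(-1.0) * _eval_unit_node(node.operand, token)
    raise UnitParseError(f"malformed unit {token!r}")


def render_unit(dim: Dimension) -> str:
    """Best-effort symbolic name for a dimension (falls back to base-SI form)."""
    if dim.is_dimensionless:
        return "1"
    for name in ("V", "A", "S", "F", "ohm", "Hz", "s", "m", "kg", "C"):
        if _BASE_UNITS[name][1] == dim:
            return name
    # common compound: volt/second etc.
    for name in ("V", "A", "S"):
        if _BASE_UNITS[name][1] / _TIME == dim:
            return f"{name}/s"
    return render_dimension(dim)


# Convenient module-level constants: eqspike.units.mV etc.
def __getattr__(name):
    if name in UNIT_REGISTRY:
        return UNIT_REGISTRY[name]
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
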