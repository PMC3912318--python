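"""Neuron populations.

A group is defined by the four-component description: model equations,
threshold condition, reset statements and refractoriness condition.  State
is stored as base-SI float arrays; ``lastspike`` starts at ``-inf`` so that
refractory conditions of the form ``(t - lastspike) <= R`` are false before
the first spike.
"""

from __future__ import annotations

import numpy as np

from . import abstract_code as ac
from . import expressions as xp
from .equations import (
    DIFFERENTIAL,
    SUBEXPRESSION,
    EquationError,
    ModelEquations,
    check_equation_dimensions,
    parse_model,
    resolve_subexpressions,
)
from .schemes import apply_scheme, get_scheme
from .units import DIMENSIONLESS, DimensionError, Quantity, render_dimension

__all__ = ["NeuronGroup", "create_group"]


def _normalize_namespace(namespace):
    out = {}
    for name, value in (namespace or {}).items():
        if not isinstance(value, Quantity):
            value = Quantity(float(value), DIMENSIONLESS)
        out[name] = value
    return out


class NeuronGroup:
    """``N`` neurons sharing one model, threshold, reset and refractoriness.

    Parameters
    ----------
    N : int
        Population size (0 is a valid degenerate group).
    eqs : str or ModelEquations
        Model equations.
    threshold : str, optional
        Dimensionless boolean expression; true for an active neuron means a
        spike is emitted.
    reset : str, optional
        Abstract-code statements executed on the spiking subset.
    refractory : str, optional
        Condition evaluated on refractory neurons; when it turns false the
        neuron re-enters the active state.  If absent, neurons never become
        refractory.
    method : str or SchemeDescription
        Integration scheme (``euler``, ``midpoint``, ``euler_maruyama`` or a
        custom description).
    namespace : dict, optional
        External constants (name -> Quantity or plain number).
    """

    def __init__(self, N, eqs, threshold=None, reset=None, refractory=None,
                 method="euler", namespace=None, name="neurongroup"):
        self.N = int(N)
        self.name = name
        if isinstance(eqs, str):
            eqs = parse_model(eqs)
        self.eqs: ModelEquations = eqs
        for entry in eqs:
            if entry.flags & {"event-driven", "summed"}:
                raise EquationError(
                    f"flag {next(iter(entry.flags))!r} is not valid in neuron equations"
                )
        self.namespace = _normalize_namespace(namespace)

        violations = check_equation_dimensions(eqs, self.namespace)
        if violations:
            raise DimensionError("; ".join(violations))

        self._symbol_dims = self._build_symbol_dims()
        self.threshold = threshold
        self._threshold_ast = None
        if threshold is not None:
            self._threshold_ast = xp.parse_expression(threshold)
            self._check_dimensionless(self._threshold_ast, "threshold")
        self.refractory_condition = refractory
        self._refractory_ast = None
        if refractory is not None:
            self._refractory_ast = xp.parse_expression(refractory)
            self._check_dimensionless(self._refractory_ast, "refractory")
        self.reset = ac.parse_statements(reset) if reset else ac.AbstractCodeBlock([])
        self._check_block_dims(self.reset, "reset")

        self.scheme = get_scheme(method)
        resolved = resolve_subexpressions(eqs)
        self.integrator = apply_scheme(self.scheme, resolved)
        self._clamped = [
            e.name for e in eqs.by_kind(DIFFERENTIAL) if "unless refractory" in e.flags
        ]

        self.state = {
            var: np.zeros(self.N) for var in eqs.state_variable_names
        }
        self.lastspike = np.full(self.N, -np.inf)
        self.active = np.ones(self.N, dtype=bool)
        self.assignments: dict = {}

    # -- dimension bookkeeping ------------------------------------------
    def _build_symbol_dims(self):
        dims = {name: value.dim for name, value in self.namespace.items()}
        for entry in self.eqs:
            dims[entry.name] = entry.unit
        return dims

    def dim_of(self, var):
        if var in self.eqs:
            return self.eqs[var].unit
        if var in ("lastspike", "lastupdate", "t", "dt"):
            return xp.SECOND
        raise KeyError(var)

    def _check_dimensionless(self, node, what):
        dim = xp.dims_of_expression(node, self._symbol_dims)
        if not dim.is_dimensionless:
            raise DimensionError(
                f"{what} expression must be dimensionless, got {render_dimension(dim)}"
            )

    def _check_block_dims(self, block, what):
        for stmt in block.statements:
            if stmt.target in self.eqs or stmt.target in ("lastspike",):
                expected = self.dim_of(stmt.target)
                actual = xp.dims_of_expression(stmt.rhs_ast, self._symbol_dims)
                if stmt.op in ("*=", "/="):
                    continue  # scaling by dimensionless factors
                if actual != expected:
                    raise DimensionError(
                        f"{what}: {stmt.target!r} has dimension "
                        f"{render_dimension(expected)} but is assigned "
                        f"{render_dimension(actual)}"
                    )

    # -- runtime plumbing -----------------------------------------------
    def _views(self, subset=None):
        views = {}
        for var, array in self.state.items():
            views[var] = ac.ArrayView(array, subset)
        views["lastspike"] = ac.ArrayView(self.lastspike, subset)

        def index_view():
            idx = np.arange(self.N) if subset is None else np.asarray(subset)
            return idx.astype(float)

        views["i"] = ac.ComputedView(index_view)
        for entry in self.eqs.by_kind(SUBEXPRESSION):
            views[entry.name] = ac.ComputedView(
                self._subexpr_getter(entry, subset)
            )
        return views

    def _subexpr_getter(self, entry, subset):
        def getter():
            n = self.N if subset is None else len(subset)
            return ac.evaluate(
                entry.rhs_ast, self._views(subset), n,
                self._scalar_namespace(self._t_now, self._dt_now), rng=None
            )
        return getter

    _t_now = 0.0
    _dt_now = 0.0

    def _scalar_namespace(self, t, dt):
        ns = {name: value.magnitude for name, value in self.namespace.items()}
        ns.update({"t": t, "dt": dt, "N": float(self.N)})
        return ns

    # -- operations ------------------------------------------------------
    def assign_state(self, var, value, rng=None):
        """Set a state variable from a Quantity or expression string.

        Expressions are evaluated vectorized over all neurons and may
        reference other state variables, ``i``, ``N``, ``t``, ``rand()``,
        ``randn()`` and external constants.
        """
        if var not in self.state:
            raise KeyError(f"unknown state variable {var!r}")
        expected = self.dim_of(var)
        if isinstance(value, str):
            actual = xp.dims_of_expression(value, self._symbol_dims)
            if actual != expected:
                raise DimensionError(
                    f"cannot assign {render_dimension(actual)} to {var} "
                    f"({render_dimension(expected)})"
                )
            block = ac.AbstractCodeBlock([ac.AbstractStatement(var, "=", value)])
            ac.execute(block, self._views(), self.N,
                       self._scalar_namespace(self._t_now, self._dt_now), rng)
        else:
            if not isinstance(value, Quantity):
                value = Quantity(value, DIMENSIONLESS)
            if value.dim != expected:
                raise DimensionError(
                    f"cannot assign {render_dimension(value.dim)} to {var} "
                    f"({render_dimension(expected)})"
                )
            self.state[var][:] = value.magnitude
        self.assignments[var] = value

    def integration_step(self, t, dt, rng=None):
        """Advance all state variables by one step of the integrator.

        Variables flagged ``unless refractory`` are clamped (``dx/dt = 0``)
        for refractory neurons; all other variables evolve for everyone.
        """
        if self.N == 0 or not self.eqs.differential_names:
            return
        self._t_now, self._dt_now = t, dt
        frozen = ~self.active
        saved = None
        if self._clamped and frozen.any():
            saved = {var: self.state[var][frozen].copy() for var in self._clamped}
        ac.execute(self.integrator, self._views(), self.N,
                   self._scalar_namespace(t, dt), rng)
        if saved is not None:
            for var, values in saved.items():
                self.state[var][frozen] = values

    def refractory_exit(self, t):
        """Move refractory neurons whose condition is now false back to the
        active state."""
        if self._refractory_ast is None or self.N == 0:
            return
        inactive = np.flatnonzero(~self.active)
        if len(inactive) == 0:
            return
        self._t_now = t
        cond = ac.evaluate(self._refractory_ast, self._views(inactive),
                           len(inactive), self._scalar_namespace(t, self._dt_now))
        cond = np.broadcast_to(np.asarray(cond, dtype=bool), inactive.shape)
        self.active[inactive[~cond]] = True

    def detect_spikes(self, t, rng=None):
        """Indices of active neurons whose threshold condition is true."""
        if self._threshold_ast is None or self.N == 0:
            return np.empty(0, dtype=int)
        self._t_now = t
        cond = ac.evaluate(self._threshold_ast, self._views(), self.N,
                           self._scalar_namespace(t, self._dt_now), rng)
        cond = np.broadcast_to(np.asarray(cond, dtype=bool), (self.N,))
        return np.flatnonzero(cond & self.active)

    def apply_reset(self, spikes, t, rng=None):
        """Run the reset block on the spiking subset, stamp ``lastspike``
        and (if a refractory condition exists) enter the refractory state."""
        spikes = np.asarray(spikes, dtype=int)
        if len(spikes) == 0:
            return
        self._t_now = t
        if len(self.reset):
            ac.execute(self.reset, self._views(spikes), len(spikes),
                       self._scalar_namespace(t, self._dt_now), rng)
        self.lastspike[spikes] = t
        if self._refractory_ast is not None:
            self.active[spikes] = False

    def __len__(self):
        return self.N

    def __repr__(self):
        return f"<NeuronGroup {self.name!r}: N={self.N}>"


def create_group(N, eqs, threshold=None, reset=None, refractory=None,
                 scheme="euler", namespace=None) -> NeuronGroup:
    """Functional constructor mirroring :class:`NeuronGroup`."""
    return NeuronGroup(N, eqs, threshold=threshold, reset=reset,
                       refractory=refractory, method=scheme, namespace=namespace)
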