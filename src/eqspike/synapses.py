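"""Synapse populations.

Each synapse connects a source neuron ``i`` to a target neuron ``j``
(duplicates allowed — multiplicity).  Connectivity is built from condition /
probability / count expressions, defined to be exactly equivalent to the
naive double loop over all (i, j) pairs with a fixed pair-visit order
(``i`` outer, ``j`` inner; probability draws happen only for pairs whose
condition holds, in that order).

Spike effects run through pre/post pathways with per-synapse delays
discretized to the nearest ``dt`` multiple (ties to even).  Differential
equations flagged ``event-driven`` are converted to closed-form updates
executed at spike arrival (prepended to the pathway statements, with
``lastupdate = t`` stamped afterwards); the remaining differential
equations are integrated clock-driven every step.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from . import abstract_code as ac
from . import expressions as xp
from .equations import (
    DIFFERENTIAL,
    PARAMETER,
    SUBEXPRESSION,
    EquationEntry,
    EquationError,
    ModelEquations,
    check_equation_dimensions,
    parse_model,
    resolve_subexpressions,
)
from .schemes import apply_scheme, event_driven_updates, get_scheme
from .units import DIMENSIONLESS, DimensionError, Quantity, render_dimension

__all__ = ["Synapses", "Pathway", "SpikeQueue"]


class SpikeQueue:
    """Pending delayed spike effects, keyed by due step."""

    def __init__(self):
        self.pending = defaultdict(list)

    def push(self, due_step, synapse_indices):
        for step, idx in zip(due_step, synapse_indices):
            self.pending[int(step)].append(int(idx))

    def pop(self, step):
        """All synapse indices due exactly at ``step``, ascending."""
        indices = self.pending.pop(step, [])
        return np.array(sorted(indices), dtype=int)

    def __len__(self):
        return sum(len(v) for v in self.pending.values())


class Pathway:
    """One direction of spike propagation (pre or post)."""

    def __init__(self, direction, block):
        assert direction in ("pre", "post")
        self.direction = direction
        self.statements = block
        self.delay = np.zeros(0)
        self.queue = SpikeQueue()

    def grow(self, extra):
        self.delay = np.concatenate([self.delay, np.zeros(extra)])


class Synapses:
    """A store of synapses between a source and a target group."""

    def __init__(self, source, target, eqs=None, pre=None, post=None,
                 namespace=None, method="euler", name="synapses"):
        self.source = source
        self.target = target
        self.name = name
        if isinstance(eqs, str):
            eqs = parse_model(eqs)
        self.eqs: ModelEquations = eqs if eqs is not None else ModelEquations([])
        for entry in self.eqs:
            if "unless refractory" in entry.flags:
                raise EquationError(
                    "'unless refractory' is not valid in synaptic equations"
                )
        self.namespace = {}
        for key, value in (namespace or {}).items():
            if not isinstance(value, Quantity):
                value = Quantity(float(value), DIMENSIONLESS)
            self.namespace[key] = value

        self._symbol_dims = self._build_symbol_dims()
        violations = check_equation_dimensions(
            self.eqs, self.namespace, self._suffixed_dims()
        )
        if violations:
            raise DimensionError("; ".join(violations))
        self._check_summed_targets()

        # event-driven closed forms + pathway blocks
        ed_updates = event_driven_updates(self.eqs)
        prefix = [
            ac.AbstractStatement(var, "=", update)
            for var, update in ed_updates.items()
            if update != var
        ]
        suffix = [ac.AbstractStatement("lastupdate", "=", "t")]
        self.pathways = []
        for direction, text in (("pre", pre), ("post", post)):
            if text is None:
                continue
            block = ac.AbstractCodeBlock(
                prefix + list(ac.parse_statements(text).statements) + suffix
            )
            self._check_block_dims(block, direction)
            self.pathways.append(Pathway(direction, block))

        # clock-driven integrator over the non-event-driven equations
        clock_entries = []
        for entry in self.eqs:
            if entry.kind == DIFFERENTIAL and "event-driven" in entry.flags:
                clock_entries.append(
                    EquationEntry(entry.name, PARAMETER, None, entry.unit,
                                  entry.unit_str)
                )
            else:
                clock_entries.append(entry)
        clock_eqs = ModelEquations(clock_entries)
        if clock_eqs.differential_names:
            self.integrator = apply_scheme(
                get_scheme(method), resolve_subexpressions(clock_eqs)
            )
        else:
            self.integrator = None

        self.i = np.zeros(0, dtype=int)
        self.j = np.zeros(0, dtype=int)
        self.state = {v: np.zeros(0) for v in self.eqs.state_variable_names}
        self.lastupdate = np.zeros(0)
        self.assignments: dict = {}
        self._adjacency = {"pre": defaultdict(list), "post": defaultdict(list)}

    # ------------------------------------------------------------------
    @property
    def M(self):
        return len(self.i)

    def _suffixed_dims(self):
        dims = {}
        for entry in self.source.eqs:
            dims[f"{entry.name}_pre"] = entry.unit
        for entry in self.target.eqs:
            dims[f"{entry.name}_post"] = entry.unit
        return dims

    def _build_symbol_dims(self):
        dims = {name: value.dim for name, value in self.namespace.items()}
        dims.update(self._suffixed_dims())
        for entry in self.eqs:
            dims[entry.name] = entry.unit
        return dims

    def _check_summed_targets(self):
        for entry in self.eqs.by_kind(SUBEXPRESSION):
            if "summed" not in entry.flags:
                continue
            base = entry.name[: -len("_post")]
            if base not in self.target.state:
                raise EquationError(
                    f"summed variable {entry.name!r}: {base!r} is not a state "
                    "variable of the target group"
                )
            if self.target.dim_of(base) != entry.unit:
                raise DimensionError(
                    f"summed variable {entry.name!r} has dimension "
                    f"{render_dimension(entry.unit)} but target variable "
                    f"{base!r} has {render_dimension(self.target.dim_of(base))}"
                )

    def _dim_of_name(self, name):
        if name in self.eqs:
            return self.eqs[name].unit
        if name == "lastupdate":
            return xp.SECOND
        if name in self._symbol_dims:
            return self._symbol_dims[name]
        raise KeyError(name)

    def _check_block_dims(self, block, what):
        for stmt in block.statements:
            try:
                expected = self._dim_of_name(stmt.target)
            except KeyError:
                continue  # temporary
            if stmt.op in ("*=", "/="):
                continue
            actual = xp.dims_of_expression(stmt.rhs_ast, self._symbol_dims)
            if actual != expected:
                raise DimensionError(
                    f"{what} statement: {stmt.target!r} has dimension "
                    f"{render_dimension(expected)} but is assigned "
                    f"{render_dimension(actual)}"
                )

    # ------------------------------------------------------------------
    def connect(self, condition=None, p=None, n=None, rng=None, t=0.0):
        """Create synapses from condition / probability / count expressions.

        Equivalent to the double loop over all pairs (i outer, j inner):
        for every pair where ``condition`` holds (all pairs if absent), if
        ``p`` is given a uniform draw decides creation (``draw < p``), and
        ``n`` synapses (default 1) are created.  Returns the number created.
        """
        if p is not None and rng is None:
            raise ValueError("probabilistic connect requires an rng")
        new_i, new_j = [], []
        n_post = self.target.N
        j_vector = np.arange(n_post, dtype=float)
        cond_ast = xp.parse_expression(condition) if isinstance(condition, str) else None
        p_ast = xp.parse_expression(p) if isinstance(p, str) else None
        n_ast = xp.parse_expression(n) if isinstance(n, str) else None
        if cond_ast is not None:
            dim = xp.dims_of_expression(cond_ast, self._connect_dims())
            if not dim.is_dimensionless:
                raise DimensionError("connect condition must be dimensionless")

        for i_val in range(self.source.N):
            views = self._connect_views(i_val, j_vector)
            ns = self._connect_namespace(i_val)
            if cond_ast is None:
                admitted = np.arange(n_post)
            else:
                cond = ac.evaluate(cond_ast, views, n_post, ns, rng)
                cond = np.broadcast_to(np.asarray(cond, dtype=bool), (n_post,))
                admitted = np.flatnonzero(cond)
            if len(admitted) == 0:
                continue
            if p is not None:
                if p_ast is not None:
                    p_vals = ac.evaluate(p_ast, views, n_post, ns, rng)
                    p_vals = np.broadcast_to(np.asarray(p_vals, float), (n_post,))
                    p_vals = p_vals[admitted]
                else:
                    p_vals = np.full(len(admitted), float(p))
                if np.any((p_vals < 0) | (p_vals > 1)):
                    raise ValueError("connection probability outside [0, 1]")
                draws = rng.random(len(admitted))
                admitted = admitted[draws < p_vals]
                if len(admitted) == 0:
                    continue
            if n is None:
                counts = np.ones(len(admitted), dtype=int)
            else:
                if n_ast is not None:
                    n_vals = ac.evaluate(n_ast, views, n_post, ns, rng)
                    n_vals = np.broadcast_to(np.asarray(n_vals, float), (n_post,))
                    n_vals = n_vals[admitted]
                else:
                    n_vals = np.full(len(admitted), float(n))
                if np.any(n_vals != np.round(n_vals)) or np.any(n_vals <= 0):
                    raise ValueError("synapse count n must be a positive integer")
                counts = np.round(n_vals).astype(int)
            new_i.append(np.repeat(i_val, counts.sum()))
            new_j.append(np.repeat(admitted, counts))

        created = 0
        if new_i:
            add_i = np.concatenate(new_i)
            add_j = np.concatenate(new_j)
            created = len(add_i)
            offset = self.M
            self.i = np.concatenate([self.i, add_i])
            self.j = np.concatenate([self.j, add_j])
            for var in self.state:
                self.state[var] = np.concatenate([self.state[var], np.zeros(created)])
            self.lastupdate = np.concatenate(
                [self.lastupdate, np.full(created, float(t))]
            )
            for pathway in self.pathways:
                pathway.grow(created)
            for s in range(offset, offset + created):
                self._adjacency["pre"][int(self.i[s])].append(s)
                self._adjacency["post"][int(self.j[s])].append(s)
        return created

    def _connect_dims(self):
        dims = dict(self._symbol_dims)
        dims["i"] = DIMENSIONLESS
        dims["j"] = DIMENSIONLESS
        return dims

    def _connect_views(self, i_val, j_vector):
        views = {"j": ac.ComputedView(lambda: j_vector)}
        for var, array in self.source.state.items():
            views[f"{var}_pre"] = ac.ArrayView(array, np.full(1, i_val))
        for var, array in self.target.state.items():
            views[f"{var}_post"] = ac.ArrayView(array)
        return views

    def _connect_namespace(self, i_val):
        ns = {name: value.magnitude for name, value in self.namespace.items()}
        ns.update({
            "i": float(i_val),
            "N_pre": float(self.source.N),
            "N_post": float(self.target.N),
        })
        if self.source.N == self.target.N:
            ns["N"] = float(self.source.N)
        return ns

    # ------------------------------------------------------------------
    def _views(self, subset=None):
        views = {}
        idx = np.arange(self.M) if subset is None else np.asarray(subset, dtype=int)
        for var, array in self.state.items():
            views[var] = ac.ArrayView(array, subset)
        views["lastupdate"] = ac.ArrayView(self.lastupdate, subset)
        views["i"] = ac.ComputedView(lambda: self.i[idx].astype(float))
        views["j"] = ac.ComputedView(lambda: self.j[idx].astype(float))
        for var, array in self.source.state.items():
            views[f"{var}_pre"] = ac.ArrayView(array, self.i[idx])
        views["lastspike_pre"] = ac.ArrayView(self.source.lastspike, self.i[idx])
        for var, array in self.target.state.items():
            views[f"{var}_post"] = ac.ArrayView(array, self.j[idx])
        views["lastspike_post"] = ac.ArrayView(self.target.lastspike, self.j[idx])
        for entry in self.eqs.by_kind(SUBEXPRESSION):
            if "summed" in entry.flags:
                continue
            views[entry.name] = ac.ComputedView(
                lambda e=entry, s=subset: self._eval_over(e.rhs_ast, s)
            )
        return views

    def _scalar_namespace(self, t=0.0, dt=0.0):
        ns = {name: value.magnitude for name, value in self.namespace.items()}
        ns.update({
            "t": t, "dt": dt,
            "N_pre": float(self.source.N),
            "N_post": float(self.target.N),
        })
        return ns

    def _eval_over(self, node, subset, t=0.0, dt=0.0, rng=None):
        n = self.M if subset is None else len(subset)
        return ac.evaluate(node, self._views(subset), n,
                           self._scalar_namespace(t, dt), rng)

    # ------------------------------------------------------------------
    def assign_state(self, var, value, rng=None, pathway="pre"):
        """Set a synaptic state variable (or ``delay``) from a Quantity or
        an expression over synaptic and pre-/post-suffixed neuron variables."""
        if var == "delay":
            targets = [pw for pw in self.pathways if pw.direction == pathway]
            if not targets:
                raise KeyError(f"no {pathway!r} pathway to set delays on")
            array = targets[0].delay
            expected = xp.SECOND
        elif var in self.state:
            array = self.state[var]
            expected = self.eqs[var].unit
        else:
            raise KeyError(f"unknown synaptic variable {var!r}")

        if isinstance(value, str):
            dims = dict(self._symbol_dims)
            dims["i"] = DIMENSIONLESS
            dims["j"] = DIMENSIONLESS
            actual = xp.dims_of_expression(value, dims)
            if actual != expected:
                raise DimensionError(
                    f"cannot assign {render_dimension(actual)} to {var} "
                    f"({render_dimension(expected)})"
                )
            values = self._eval_over(xp.parse_expression(value), None, rng=rng)
            array[:] = values
        else:
            if not isinstance(value, Quantity):
                value = Quantity(float(value), DIMENSIONLESS)
            if value.dim != expected:
                raise DimensionError(
                    f"cannot assign {render_dimension(value.dim)} to {var} "
                    f"({render_dimension(expected)})"
                )
            array[:] = value.magnitude
        self.assignments[var] = value

    # keep the spec-facing alias
    assign_synaptic_state = assign_state

    # ------------------------------------------------------------------
    def integration_step(self, t, dt, rng=None):
        """Clock-driven integration of the non-event-driven synaptic
        equations over all synapses."""
        if self.integrator is None or self.M == 0:
            return
        ac.execute(self.integrator, self._views(), self.M,
                   self._scalar_namespace(t, dt), rng)

    def process_pathway(self, pathway, spikes, t, dt, rng=None):
        """Enqueue this step's spikes of the pathway's trigger group and
        execute every effect that is due this step.

        The due step is ``spike step + round(delay/dt)`` (ties to even);
        zero-delay effects therefore run in the same step.  Due effects run
        in ascending synapse index order: event-driven closed-form updates,
        then the pathway statements, then ``lastupdate = t``.
        """
        step = int(round(t / dt))
        spikes = np.asarray(spikes, dtype=int)
        if len(spikes):
            synapse_lists = [
                self._adjacency[pathway.direction][int(neuron)] for neuron in spikes
            ]
            synapse_indices = np.concatenate(
                [np.asarray(lst, dtype=int) for lst in synapse_lists]
            ) if synapse_lists else np.empty(0, dtype=int)
            if len(synapse_indices):
                due = step + np.rint(pathway.delay[synapse_indices] / dt).astype(int)
                pathway.queue.push(due, synapse_indices)
        due_now = pathway.queue.pop(step)
        if len(due_now):
            ac.execute(pathway.statements, self._views(due_now), len(due_now),
                       self._scalar_namespace(t, dt), rng)

    def summed_update(self, t=0.0):
        """Write, for every ``VAR_post (summed)`` subexpression, the
        per-target-neuron sum of the synaptic expression into the target
        group's variable ``VAR`` (0 for neurons with no synapses)."""
        for entry in self.eqs.by_kind(SUBEXPRESSION):
            if "summed" not in entry.flags:
                continue
            base = entry.name[: -len("_post")]
            total = self.target.state[base]
            total[:] = 0.0
            if self.M == 0:
                continue
            values = self._eval_over(entry.rhs_ast, None, t=t)
            values = np.broadcast_to(np.asarray(values, float), (self.M,))
            np.add.at(total, self.j, values)

    def __repr__(self):
        return f"<Synapses {self.name!r}: {self.M} synapses>"
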