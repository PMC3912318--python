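"""Clock, deterministic per-step schedule, run loop and monitors.

The per-step schedule is fixed:

1. summed-variable updates for all synapse stores
2. integration step for all neuron groups and synapse stores
3. refractory exit checks
4. spike detection
5. pathway processing (enqueue this step's spikes, execute due effects,
   including zero-delay ones)
6. resets
7. monitor recording
8. clock advance

Time is tracked by an integer step count (``t = step*dt`` exactly), one
global seeded generator drives every source of randomness, and monitors are
purely passive.
"""

from __future__ import annotations

import numpy as np

from .neurons import NeuronGroup
from .synapses import Synapses
from .units import Quantity, DimensionError

__all__ = ["Clock", "Network", "SpikeMonitor", "StateMonitor", "SimulationError"]


class SimulationError(RuntimeError):
    """Raised when a state array turns non-finite during a run."""


def _seconds(value):
    if isinstance(value, Quantity):
        from .expressions import SECOND

        if value.dim != SECOND:
            raise DimensionError("expected a time quantity")
        return float(value.magnitude)
    return float(value)


class Clock:
    """Integer-step clock; the step count is authoritative, ``t`` derived."""

    def __init__(self, dt=1e-4):
        self.dt = _seconds(dt)
        self.step = 0

    @property
    def t(self):
        return self.step * self.dt

    def advance(self):
        self.step += 1


class SpikeMonitor:
    """Records (time, neuron index) for every spike of one group."""

    def __init__(self, group):
        self.group = group
        self.times: list = []
        self.indices: list = []

    def record(self, t, spikes):
        for idx in spikes:
            self.times.append(t)
            self.indices.append(int(idx))

    @property
    def count(self):
        return len(self.times)

    def spike_trains(self):
        trains = {}
        for t, idx in zip(self.times, self.indices):
            trains.setdefault(idx, []).append(t)
        return {idx: np.array(ts) for idx, ts in trains.items()}


class StateMonitor:
    """Snapshots named variables of a group (or synapse store) every
    ``every``-th step."""

    def __init__(self, group, variables, record=None, every=1):
        self.group = group
        if isinstance(variables, str):
            variables = [variables]
        for var in variables:
            if var not in group.state:
                raise KeyError(f"unknown variable {var!r}")
        self.variables = list(variables)
        self.record_indices = record
        self.every = int(every)
        self.times: list = []
        self.values = {var: [] for var in self.variables}

    def record(self, t, step):
        if step % self.every != 0:
            return
        self.times.append(t)
        for var in self.variables:
            array = self.group.state[var]
            if self.record_indices is not None:
                array = array[self.record_indices]
            self.values[var].append(array.copy())

    def __getitem__(self, var):
        return np.array(self.values[var])

    @property
    def t(self):
        return np.array(self.times)


class Network:
    """A collection of groups, synapse stores and monitors sharing a clock."""

    def __init__(self, *objects, dt=1e-4, seed=None, check_finite=True):
        self.groups: list = []
        self.synapses: list = []
        self.monitors: list = []
        self.clock = Clock(dt)
        self.rng = np.random.default_rng(seed)
        self.check_finite = check_finite
        for obj in objects:
            self.add(obj)

    def add(self, obj):
        if isinstance(obj, NeuronGroup):
            self.groups.append(obj)
        elif isinstance(obj, Synapses):
            self.synapses.append(obj)
        elif isinstance(obj, (SpikeMonitor, StateMonitor)):
            self.monitors.append(obj)
        else:
            raise TypeError(f"cannot add {type(obj).__name__} to a network")
        return obj

    def reseed(self, seed):
        self.rng = np.random.default_rng(seed)

    def run(self, duration):
        """Advance the network by ``duration`` (``round(duration/dt)`` steps)."""
        n_steps = int(round(_seconds(duration) / self.clock.dt))
        dt = self.clock.dt
        for _ in range(n_steps):
            t = self.clock.t
            # (1) summed variables, so neuron equations see current sums
            for store in self.synapses:
                store.summed_update(t)
            # (2) continuous updates
            for group in self.groups:
                group.integration_step(t, dt, self.rng)
            for store in self.synapses:
                store.integration_step(t, dt, self.rng)
            # (3) refractory exit
            for group in self.groups:
                group.refractory_exit(t)
            # (4) threshold
            spikes = {id(g): g.detect_spikes(t, self.rng) for g in self.groups}
            # (5) synaptic propagation (zero-delay effects run this step)
            for store in self.synapses:
                for pathway in store.pathways:
                    trigger = store.source if pathway.direction == "pre" else store.target
                    store.process_pathway(
                        pathway, spikes.get(id(trigger), ()), t, dt, self.rng
                    )
            # (6) reset
            for group in self.groups:
                group.apply_reset(spikes[id(group)], t, self.rng)
            # (7) monitors
            for monitor in self.monitors:
                if isinstance(monitor, SpikeMonitor):
                    monitor.record(t, spikes.get(id(monitor.group), ()))
                else:
                    monitor.record(t, self.clock.step)
            # (8) advance
            self.clock.advance()
            if self.check_finite:
                self._guard()
        return self.monitors

    def _guard(self):
        for group in self.groups:
            for var, array in group.state.items():
                if array.size and not np.all(np.isfinite(array)):
                    raise SimulationError(
                        f"non-finite value in {group.name}.{var} at step "
                        f"{self.clock.step}"
                    )
        for store in self.synapses:
            for var, array in store.state.items():
                if array.size and not np.all(np.isfinite(array)):
                    raise SimulationError(
                        f"non-finite value in {store.name}.{var} at step "
                        f"{self.clock.step}"
                    )
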