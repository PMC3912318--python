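# eqspike

Equation-oriented specification and simulation of spiking neural network
models.  Models are written as plain-text mathematical descriptions —
differential equations with physical units, threshold/reset/refractoriness
conditions, synaptic pre/post statements and connectivity expressions — and
compiled symbolically into executable per-timestep update code.

## Highlights

* **Unit-checked equations.** Every variable carries an SI dimension
  (rational exponents, so `tau**-0.5` works); annotations like
  `dv/dt = -(v - v0)/tau_m : volt` are validated against the right-hand
  side (volt/second for differentials).
* **Textual integration schemes.** `euler`, `midpoint` (2nd-order
  Runge-Kutta) and `euler_maruyama` are built in, and new explicit schemes
  can be written as short statement lists over `x`, `t`, `dt`, `f(x,t)`,
  `g(x,t)` and `dW`.  Schemes are combined with model equations by a
  symbolic expansion step that produces *abstract code* — ordered
  `variable op expression` statements.
* **Hybrid dynamics.** Threshold conditions, reset statements,
  refractoriness conditions (including `unless refractory` clamping),
  per-synapse transmission delays, probabilistic transmission, STDP with
  automatic conversion of linear `(event-driven)` equations to closed-form
  spike-time updates, and `(summed)` variables (NMDA totals, gap junctions).
* **Expression-based connectivity.** `connect(condition=..., p=..., n=...)`
  over `i`, `j` and `_pre`/`_post` neuron variables, defined to match the
  naive double loop exactly (including the random stream).
* **Automatic documentation.** Models render themselves to LaTeX or plain
  text, including human-readable descriptions of state assignments
  (`τ_m = 20 ms + 5 ms · N(0, 1)`).

## Library quick start

```python
import numpy as np
from eqspike import Network, NeuronGroup, SpikeMonitor, Synapses
from eqspike.units import UNIT_REGISTRY as U
from eqspike import Quantity

mV, ms = U["mV"], U["ms"]
ns = {"v0": Quantity(-40e-3, mV.dim), "v_r": Quantity(-70e-3, mV.dim),
      "v_th": Quantity(-50e-3, mV.dim), "tau_m": Quantity(10e-3, ms.dim)}

group = NeuronGroup(100, "dv/dt = -(v - v0)/tau_m : volt",
                    threshold="v > v_th", reset="v = v_r",
                    refractory="(t - lastspike) <= 2*ms", namespace=ns)
net = Network(group, dt=1e-4, seed=42)
group.assign_state("v", "v_r + rand()*20*mV", rng=net.rng)

syn = Synapses(group, group, eqs="w : volt", pre="v_post += w")
syn.connect(condition="i != j", p=0.1, rng=net.rng)
syn.assign_state("w", "rand()*2*mV", rng=net.rng)
net.add(syn)

monitor = net.add(SpikeMonitor(group))
net.run(1.0)          # seconds
print(monitor.count)
```

## Command line

Model files use `[neurons NAME]`, `[synapses NAME SOURCE TARGET]` and
`[run]` sections (see `eqspike.modelfile` for the format):

```bash
eqspike run model.eqs --duration 1*second --dt 0.1*ms --seed 42 \
    --spikes spikes.csv --states states.csv --dump-code code/
eqspike document model.eqs --format latex -o report.tex
```

## Layout

| module | role |
| --- | --- |
| `eqspike.units` | dimensions, quantities, unit parsing |
| `eqspike.expressions` | expression parsing, dimension inference, SymPy bridge, vectorized evaluation |
| `eqspike.equations` | model-description parsing, subexpression resolution, drift/diffusion split |
| `eqspike.schemes` | integration-scheme parsing and symbolic application; event-driven closed forms |
| `eqspike.abstract_code` | the statement IR: analysis, vectorized execution, loop-dialect rendering |
| `eqspike.neurons` | neuron groups (threshold, reset, refractoriness, assignments) |
| `eqspike.synapses` | synapse stores (connectivity, pathways, delays, summed variables) |
| `eqspike.network` | clock, per-step schedule, run loop, monitors |
| `eqspike.docgen` | LaTeX/plain-text model reports |
| `eqspike.modelfile` / `eqspike.cli` | model files and the `eqspike` command |

## Semantics worth knowing

* The per-step schedule is: summed updates → integration → refractory exit
  → threshold → synaptic propagation (zero-delay effects land in the same
  step) → reset → monitors → clock advance.
* Delays are rounded to the nearest `dt` multiple (ties to even).
* When several synapses share a target, `+=`-family updates accumulate all
  contributions (exactly as a per-instance loop); plain `=` follows
  ascending-index last-write-wins.
* `rand()`/`randn()` draw per instance and per occurrence, in a fixed
  order, so a fixed seed gives bit-identical runs.
* `lastspike` starts at `-inf`: `(t - lastspike) <= R` is false before the
  first spike.
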