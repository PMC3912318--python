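import numpy as np
import pytest

from eqspike.units import UNIT_REGISTRY, Quantity


def q(value, unit):
    """Shortcut: a scalar quantity like q(-70, 'mV')."""
    u = UNIT_REGISTRY[unit]
    return Quantity(value * u.magnitude, u.dim)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def lif_namespace():
    return {
        "v0": q(-40, "mV"),
        "v_r": q(-70, "mV"),
        "v_th": q(-50, "mV"),
        "tau_m": q(10, "ms"),
    }


LIF_EQS = "dv/dt = -(v - v0)/tau_m : volt"


@pytest.fixture
def lif_group(lif_namespace):
    from eqspike import NeuronGroup

    group = NeuronGroup(
        5,
        LIF_EQS,
        threshold="v > v_th",
        reset="v = v_r",
        namespace=lif_namespace,
    )
    group.assign_state("v", q(-70, "mV"))
    return group
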