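"""Plain-text model files for the command line interface.

A model file is UTF-8 text with sections::

    [neurons NAME]
    N = 100
    equations:
        dv/dt = -(v - v0)/tau_m : volt
    threshold = v > v_th
    reset:
        v = v0
    refractory = (t - lastspike) <= 2*ms
    method = euler
    const v0 = -70*mV
    set v = v0 + rand()*10*mV

    [synapses NAME SOURCE TARGET]
    equations: ...            # optional
    pre:
        g_post += w
    connect = i != j
    p = 0.1
    n = 1
    set w = 0.5*nS
    set delay = 1*ms

    [run]
    duration = 100*ms
    dt = 0.1*ms
    seed = 42

Keys taking a block (``equations``, ``reset``, ``pre``, ``post``) end with a
colon and collect the following indented lines.  Scalar values such as
``20*ms`` are unit expressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import Network, SpikeMonitor
from .neurons import NeuronGroup
from .synapses import Synapses
from .units import parse_unit

__all__ = ["ModelFileError", "parse_model_file", "build_network"]

_BLOCK_KEYS = {"equations", "reset", "pre", "post"}
_LINE_KEYS = {"N", "threshold", "refractory", "method", "connect", "p", "n",
              "duration", "dt", "seed"}


class ModelFileError(ValueError):
    pass


@dataclass
class SectionSpec:
    kind: str                      # 'neurons' | 'synapses' | 'run'
    name: str
    args: tuple = ()
    values: dict = field(default_factory=dict)   # scalar keys
    blocks: dict = field(default_factory=dict)   # block keys -> text
    consts: dict = field(default_factory=dict)   # name -> value string
    sets: list = field(default_factory=list)     # ordered (var, expr)


def parse_model_file(text: str) -> list:
    """Parse a model file into an ordered list of :class:`SectionSpec`."""
    sections = []
    current = None
    block_key = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.split("#", 1)[0].rstrip()
        if not stripped.strip():
            continue
        indented = stripped[:1].isspace()
        line = stripped.strip()
        if line.startswith("[") and line.endswith("]"):
            parts = line[1:-1].split()
            if not parts:
                raise ModelFileError(f"line {lineno}: empty section header")
            kind = parts[0]
            if kind == "run":
                current = SectionSpec("run", "run")
            elif kind == "neurons":
                if len(parts) != 2:
                    raise ModelFileError(f"line {lineno}: [neurons NAME] expected")
                current = SectionSpec("neurons", parts[1])
            elif kind == "synapses":
                if len(parts) != 4:
                    raise ModelFileError(
                        f"line {lineno}: [synapses NAME SOURCE TARGET] expected"
                    )
                current = SectionSpec("synapses", parts[1], args=(parts[2], parts[3]))
            else:
                raise ModelFileError(f"line {lineno}: unknown section {kind!r}")
            sections.append(current)
            block_key = None
            continue
        if current is None:
            raise ModelFileError(f"line {lineno}: content before any section")
        if indented and block_key is not None:
            current.blocks[block_key] += line + "\n"
            continue
        block_key = None
        if line.endswith(":") and line[:-1].strip() in _BLOCK_KEYS:
            block_key = line[:-1].strip()
            current.blocks.setdefault(block_key, "")
            continue
        if "=" not in line:
            raise ModelFileError(f"line {lineno}: cannot parse {line!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key.startswith("const "):
            current.consts[key[len("const "):].strip()] = value
        elif key.startswith("set "):
            current.sets.append((key[len("set "):].strip(), value))
        elif key in _LINE_KEYS:
            current.values[key] = value
        elif key in _BLOCK_KEYS:
            current.blocks[key] = value + "\n"
        else:
            raise ModelFileError(f"line {lineno}: unknown key {key!r}")
    return sections


def build_network(sections, dt=None, seed=None, duration=None):
    """Instantiate a :class:`~eqspike.network.Network` from parsed sections.

    Returns ``(network, objects, run_config)`` where ``objects`` maps
    section names to the created groups/stores and ``run_config`` carries
    the requested duration.
    """
    run_cfg = {}
    for section in sections:
        if section.kind == "run":
            run_cfg = section.values
    if dt is None:
        dt = parse_unit(run_cfg.get("dt", "0.1*ms")).magnitude
    if seed is None and "seed" in run_cfg:
        seed = int(run_cfg["seed"])
    if duration is None and "duration" in run_cfg:
        duration = parse_unit(run_cfg["duration"]).magnitude

    net = Network(dt=dt, seed=seed)
    objects = {}
    for section in sections:
        if section.kind != "neurons":
            continue
        namespace = {name: parse_unit(value) for name, value in section.consts.items()}
        group = NeuronGroup(
            int(section.values.get("N", 1)),
            section.blocks.get("equations", ""),
            threshold=section.values.get("threshold"),
            reset=section.blocks.get("reset"),
            refractory=section.values.get("refractory"),
            method=section.values.get("method", "euler"),
            namespace=namespace,
            name=section.name,
        )
        for var, expr in section.sets:
            group.assign_state(var, expr, net.rng)
        net.add(group)
        objects[section.name] = group
    for section in sections:
        if section.kind != "synapses":
            continue
        source_name, target_name = section.args
        try:
            source, target = objects[source_name], objects[target_name]
        except KeyError as exc:
            raise ModelFileError(f"unknown group {exc.args[0]!r}") from None
        namespace = {name: parse_unit(value) for name, value in section.consts.items()}
        store = Synapses(
            source, target,
            eqs=section.blocks.get("equations"),
            pre=section.blocks.get("pre"),
            post=section.blocks.get("post"),
            namespace=namespace,
            method=section.values.get("method", "euler"),
            name=section.name,
        )
        p = section.values.get("p")
        n = section.values.get("n")
        store.connect(
            condition=section.values.get("connect"),
            p=p if p is None or not _is_number(p) else float(p),
            n=n if n is None or not _is_number(n) else int(n),
            rng=net.rng,
        )
        for var, expr in section.sets:
            store.assign_state(var, expr, net.rng)
        net.add(store)
        objects[section.name] = store
    return net, objects, {"duration": duration}


def _is_number(text):
    try:
        float(text)
        return True
    except ValueError:
        return False
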