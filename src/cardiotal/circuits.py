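"""Generic lumped-parameter circuit representation and time integration.

The circulation is described as an electrical analogue: pressure plays the
role of voltage, flow of current, and vessels are resistor / inductor /
capacitor branches.  Heart chambers are time-varying elastance elements
(nonlinear capacitors).  Every node of the network must carry exactly one
storage element (capacitor or chamber), which makes all node pressures
algebraic functions of the state; the state itself consists of the stored
volumes plus the flows of inertial branches.

The default integrator is explicit Euler with a 0.1 ms step; a classical
4th-order Runge-Kutta on the same equations is available as a cross-check.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from . import _kernel

__all__ = [
    "CircuitElement",
    "Network",
    "State",
    "SimulationResult",
    "StateEquations",
    "TopologyError",
    "IntegrationError",
    "InstabilityError",
    "NonConvergenceError",
    "assemble_state_equations",
    "euler_step",
    "simulate",
    "run_to_periodic_steady_state",
    "resistor",
    "valve",
    "inductive",
    "capacitor",
    "chamber",
]

DEFAULT_DT = 1e-4  # s
DEFAULT_BOUND = 1e5  # divergence guard on any state entry
_REF_CODES = {
    "ambient": _kernel.REF_AMBIENT,
    "intrathoracic": _kernel.REF_INTRATHORACIC,
    "intramyocardial": _kernel.REF_INTRAMYOCARDIAL,
}
_STORAGE_KINDS = ("capacitor", "chamber")
_BRANCH_KINDS = ("resistor", "valve", "inductor", "flow-resistor")


class TopologyError(ValueError):
    """The network graph does not define a pressure at every node."""


class IntegrationError(RuntimeError):
    """The integrator produced a non-finite derivative."""


class InstabilityError(IntegrationError):
    """A state entry left the divergence bound; the step is likely too large."""


class NonConvergenceError(IntegrationError):
    """Periodic steady state was not reached within the cycle budget."""


def _is_disabled(value) -> bool:
    return value is None or (isinstance(value, float) and math.isinf(value))


@dataclass(frozen=True)
class CircuitElement:
    """One element of the electrical analogue.

    Branch kinds connect two nodes: ``resistor`` (R), ``valve`` (ideal diode
    in series with R), ``inductor`` (L with optional series R, one flow
    state), ``flow-resistor`` (dP = R*Q + k*Q*|Q|).  Storage kinds sit on a
    single node (``node_a``) against an external pressure reference:
    ``capacitor`` (C, one volume state) and ``chamber`` (time-varying
    elastance, one volume state).  A resistance of ``inf``/``None`` marks the
    branch as disabled: it is removed from the dynamics and carries no flow.
    """

    name: str
    kind: str
    node_a: str
    node_b: str | None = None
    params: Mapping[str, float] = field(default_factory=dict)
    pressure_ref: str = "ambient"
    enabled: bool = True

    def __post_init__(self):
        if self.kind not in _STORAGE_KINDS + _BRANCH_KINDS:
            raise ValueError(f"unknown element kind {self.kind!r}")
        p = dict(self.params)
        if self.kind in _BRANCH_KINDS:
            if self.node_b is None or self.node_a == self.node_b:
                raise ValueError(
                    f"branch {self.name!r} must connect two distinct nodes")
            if self.kind == "resistor" or self.kind == "valve":
                if _is_disabled(p.get("R")):
                    object.__setattr__(self, "enabled", False)
                elif p.get("R", 0.0) <= 0.0:
                    raise ValueError(f"{self.name}: resistance must be > 0")
            elif self.kind == "inductor":
                if _is_disabled(p.get("R", 0.0)) or _is_disabled(p.get("L")):
                    object.__setattr__(self, "enabled", False)
                else:
                    if p.get("L", 0.0) <= 0.0:
                        raise ValueError(f"{self.name}: inertance must be > 0")
                    if p.get("R", 0.0) < 0.0:
                        raise ValueError(f"{self.name}: resistance must be >= 0")
            else:  # flow-resistor
                if _is_disabled(p.get("R")) or _is_disabled(p.get("k", 0.0)):
                    object.__setattr__(self, "enabled", False)
                else:
                    r0, k = p.get("R", 0.0), p.get("k", 0.0)
                    if r0 < 0.0 or k < 0.0 or (r0 == 0.0 and k == 0.0):
                        raise ValueError(
                            f"{self.name}: need R >= 0, k >= 0, not both zero")
        else:
            if self.pressure_ref not in _REF_CODES:
                raise ValueError(
                    f"{self.name}: unknown pressure reference "
                    f"{self.pressure_ref!r}")
            if self.kind == "capacitor" and p.get("C", 0.0) <= 0.0:
                raise ValueError(f"{self.name}: compliance must be > 0")
            if self.kind == "chamber":
                emax, emin = p.get("Emax", 0.0), p.get("Emin", 0.0)
                if not (emax >= emin > 0.0):
                    raise ValueError(
                        f"{self.name}: need Emax >= Emin > 0")
                if p.get("Tsys", 0.0) <= 0.0:
                    raise ValueError(f"{self.name}: Tsys must be > 0")
            # the reference acts as the second terminal of a storage element
            if self.node_b is None:
                object.__setattr__(self, "node_b", f"ref:{self.pressure_ref}")

    @property
    def is_storage(self) -> bool:
        return self.kind in _STORAGE_KINDS

    @property
    def has_flow_state(self) -> bool:
        return self.kind == "inductor"


@dataclass
class Network:
    """A closed-loop circuit plus its global environment.

    ``period`` is the cardiac period (s) shared by all elastance chambers;
    ``pt`` the mean intrathoracic pressure (mmHg) behind intrathoracic
    compliances; ``gamma`` the intramyocardial coupling (the external pressure
    of an ``intramyocardial``-referenced capacitor is gamma * P_lv).
    ``aliases`` maps physiological waveform names (e.g. ``Ppam``) onto the
    generic keys ``P:<node>`` / ``Q:<element>`` / ``V:<element>``.
    """

    name: str
    elements: list[CircuitElement]
    pt: float = 0.0
    period: float | None = None
    gamma: float = 0.0
    lv_chamber: str | None = None
    rv_chamber: str | None = None
    septal_coupling: float = 0.0
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        names = [e.name for e in self.elements]
        if len(set(names)) != len(names):
            raise ValueError("element names must be unique")
        self._compiled = None

    def element(self, name: str) -> CircuitElement:
        for e in self.elements:
            if e.name == name:
                return e
        raise KeyError(name)

    def replace_element(self, name: str, new: CircuitElement) -> "Network":
        self.element(name)  # raises KeyError if absent
        elements = [new if e.name == name else e for e in self.elements]
        return dataclasses.replace(self, elements=elements)

    @property
    def storages(self) -> list[CircuitElement]:
        return [e for e in self.elements if e.is_storage and e.enabled]

    @property
    def branches(self) -> list[CircuitElement]:
        return [e for e in self.elements if not e.is_storage and e.enabled]

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.storages:
            seen.setdefault(e.node_a)
        for e in self.branches:
            seen.setdefault(e.node_a)
            seen.setdefault(e.node_b)
        return list(seen)

    @property
    def state_labels(self) -> tuple[str, ...]:
        labels = [f"V:{e.name}" for e in self.storages]
        labels += [f"Q:{e.name}" for e in self.branches if e.has_flow_state]
        return tuple(labels)

    def compiled(self) -> "_Compiled":
        if self._compiled is None:
            self._compiled = _Compiled(self)
        return self._compiled


class _Compiled:
    """Flat-array view of a network, consumed by the kernel."""

    def __init__(self, net: Network):
        storages = net.storages
        branches = net.branches
        node_index: dict[str, int] = {}
        for e in storages:
            if e.node_a in node_index:
                raise TopologyError(
                    f"node {e.node_a!r} carries more than one storage element;"
                    " its pressure would be over-determined")
            node_index[e.node_a] = len(node_index)
        for e in branches:
            for node in (e.node_a, e.node_b):
                if node not in node_index:
                    raise TopologyError(
                        f"node {node!r} has no capacitor or chamber defining"
                        " its pressure")

        ns, nb = len(storages), len(branches)
        self.storages = storages
        self.branches = branches
        self.node_index = node_index
        self.node_names = list(node_index)
        self.s_node = np.array([node_index[e.node_a] for e in storages],
                               dtype=np.int64)
        self.s_kind = np.array(
            [_kernel.CHAMBER if e.kind == "chamber" else _kernel.CAPACITOR
             for e in storages], dtype=np.int64)
        self.s_C = np.array([e.params.get("C", 1.0) for e in storages])
        self.s_emax = np.array([e.params.get("Emax", 0.0) for e in storages])
        self.s_emin = np.array([e.params.get("Emin", 0.0) for e in storages])
        self.s_v0 = np.array([e.params.get("V0", 0.0) for e in storages])
        self.s_onset = np.array([e.params.get("onset", 0.0) for e in storages])
        self.s_tsys = np.array([e.params.get("Tsys", 1.0) for e in storages])
        self.s_ref = np.array([_REF_CODES[e.pressure_ref] for e in storages],
                              dtype=np.int64)
        node_store = np.full(len(node_index), -1, dtype=np.int64)
        for i, e in enumerate(storages):
            node_store[node_index[e.node_a]] = i
        self.node_store = node_store

        kind_code = {"resistor": _kernel.B_RESISTOR, "valve": _kernel.B_VALVE,
                     "inductor": _kernel.B_RL,
                     "flow-resistor": _kernel.B_FLOWDEP}
        self.b_kind = np.array([kind_code[e.kind] for e in branches],
                               dtype=np.int64)
        self.b_a = np.array([node_index[e.node_a] for e in branches],
                            dtype=np.int64)
        self.b_b = np.array([node_index[e.node_b] for e in branches],
                            dtype=np.int64)
        self.b_R = np.array([e.params.get("R", 0.0) for e in branches])
        self.b_L = np.array([e.params.get("L", 1.0) for e in branches])
        self.b_K = np.array([e.params.get("k", 0.0) for e in branches])
        slot = ns
        slots = []
        for e in branches:
            if e.has_flow_state:
                slots.append(slot)
                slot += 1
            else:
                slots.append(-1)
        self.b_slot = np.array(slots, dtype=np.int64)
        self.n_state = slot
        self.n_storage = ns

        if any(self.s_kind == _kernel.CHAMBER) and not net.period:
            raise ValueError("networks with chambers need a cardiac period")
        self.period = float(net.period) if net.period else 1.0
        self.pt = float(net.pt)
        self.gamma = float(net.gamma)
        self.lv_node = (node_index[net.element(net.lv_chamber).node_a]
                        if net.lv_chamber else -1)
        self.rv_node = (node_index[net.element(net.rv_chamber).node_a]
                        if net.rv_chamber else -1)
        self.septum = float(net.septal_coupling)

        self.state_labels = tuple(
            [f"V:{e.name}" for e in storages]
            + [f"Q:{e.name}" for e in branches if e.has_flow_state])
        self.pressure_keys = tuple(f"P:{n}" for n in self.node_names)
        self.flow_keys = tuple(f"Q:{e.name}" for e in branches)
        self.volume_keys = tuple(f"V:{e.name}" for e in storages)

    def kernel_args(self):
        return (self.s_node, self.s_kind, self.s_C, self.s_emax, self.s_emin,
                self.s_v0, self.s_onset, self.s_tsys, self.s_ref,
                self.node_store, self.b_kind, self.b_a, self.b_b, self.b_R,
                self.b_L, self.b_K, self.b_slot, self.period, self.pt,
                self.gamma, self.lv_node, self.rv_node, self.septum)


@dataclass(frozen=True)
class State:
    """Instantaneous state: stored volumes then inertial flows."""

    time: float
    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.values) != len(self.labels):
            raise ValueError("state length does not match its registry")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("state entries must be finite")

    def __getitem__(self, label: str) -> float:
        return float(self.values[self.labels.index(label)])


@dataclass
class SimulationResult:
    """Uniformly sampled waveforms of one simulation run."""

    time: np.ndarray
    waveforms: dict[str, np.ndarray]
    cycle_boundaries: np.ndarray
    dt: float
    record_every: int
    aliases: dict[str, str]
    final_state: State

    def __getitem__(self, name: str) -> np.ndarray:
        key = self.aliases.get(name, name)
        if key not in self.waveforms and name in self.aliases:
            # an aliased element that is disabled carries no flow by definition
            return np.zeros_like(self.time)
        return self.waveforms[key]

    def __contains__(self, name: str) -> bool:
        return name in self.waveforms or self.aliases.get(name) in self.waveforms

    @property
    def names(self) -> list[str]:
        return list(self.aliases) + list(self.waveforms)


class StateEquations:
    """Derivative function assembled from a network.

    Calling the object with ``(t, y)`` returns ``dy/dt``; ``evaluate``
    additionally returns the algebraic node pressures and branch flows.
    """

    def __init__(self, compiled: _Compiled):
        self._c = compiled
        self.labels = compiled.state_labels
        self.pressure_keys = compiled.pressure_keys
        self.flow_keys = compiled.flow_keys

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.evaluate(t, y)[0]

    def evaluate(self, t: float, y: np.ndarray):
        c = self._c
        y = np.asarray(y, dtype=float)
        if y.shape != (c.n_state,):
            raise ValueError(
                f"state must have {c.n_state} entries, got {y.shape}")
        P = np.empty(len(c.node_names))
        Q = np.empty(len(c.branches))
        dy = np.empty(c.n_state)
        _kernel.eval_rhs(float(t), y, P, Q, dy, *c.kernel_args())
        return dy, P, Q


def assemble_state_equations(network: Network) -> StateEquations:
    """Build the state equations of a network.

    Node pressures are algebraic (P = V/C + P_ref for capacitors, the
    elastance law for chambers), resistive and valve flows follow Ohm's law,
    dV/dt is the net inflow of each storage node and dQ/dt = (dP - R*Q)/L for
    inertial branches.  Raises :class:`TopologyError` for nodes whose
    pressure is undefined.
    """
    return StateEquations(network.compiled())


def initial_zero_state(network: Network) -> State:
    c = network.compiled()
    return State(0.0, np.zeros(c.n_state), c.state_labels)


def make_state(network: Network, values: Mapping[str, float],
               time: float = 0.0) -> State:
    """Build a State from a {label: value} mapping (missing entries are 0)."""
    c = network.compiled()
    y = np.zeros(c.n_state)
    for label, v in values.items():
        y[c.state_labels.index(label)] = v
    return State(time, y, c.state_labels)


def euler_step(state: State, derivative: Callable[[float, np.ndarray], np.ndarray],
               dt: float) -> State:
    """One explicit-Euler step: x(t+dt) = x(t) + dt * f(x(t), t)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    dy = np.asarray(derivative(state.time, state.values), dtype=float)
    bad = np.flatnonzero(~np.isfinite(dy))
    if bad.size:
        raise IntegrationError(
            f"non-finite derivative in state slot {state.labels[bad[0]]!r}")
    return State(state.time + dt, state.values + dt * dy, state.labels)


def simulate(network: Network, initial: State, duration: float,
             dt: float = DEFAULT_DT, record_every: int = 1,
             method: str = "euler", bound: float = DEFAULT_BOUND,
             t0: float | None = None) -> SimulationResult:
    """Integrate the network over ``duration`` seconds.

    Waveforms are sampled every ``record_every`` steps and include all node
    pressures (``P:<node>``), all branch flows (``Q:<element>``) and all
    stored volumes (``V:<element>``), reachable through the network's
    physiological aliases as well.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    c = network.compiled()
    if initial is None:
        initial = initial_zero_state(network)
    if tuple(initial.labels) != c.state_labels:
        raise ValueError("initial state registry does not match the network")
    start = initial.time if t0 is None else t0
    n_steps = int(round(duration / dt))
    method_code = {"euler": 0, "rk4": 1}[method]
    status, bad, n_rec, T, Y, P, Q, y_final = _kernel.integrate(
        np.asarray(initial.values, dtype=float), float(start), n_steps,
        float(dt), int(record_every), method_code, float(bound),
        *c.kernel_args())
    if status == _kernel.NONFINITE_DERIVATIVE:
        raise IntegrationError(
            f"non-finite derivative in state slot {c.state_labels[bad]!r}")
    if status == _kernel.STATE_OUT_OF_BOUNDS:
        raise InstabilityError(
            f"state slot {c.state_labels[bad]!r} exceeded |{bound:g}|;"
            " the integration is unstable - try a smaller dt")

    T, Y, P, Q = T[:n_rec], Y[:n_rec], P[:n_rec], Q[:n_rec]
    waveforms: dict[str, np.ndarray] = {}
    for i, key in enumerate(c.pressure_keys):
        waveforms[key] = P[:, i]
    for i, key in enumerate(c.flow_keys):
        waveforms[key] = Q[:, i]
    for i, key in enumerate(c.volume_keys):
        waveforms[key] = Y[:, i]

    boundaries = [0]
    if network.period:
        spc = network.period / dt
        k = 1
        while k * spc <= n_steps + 0.5:
            idx = int(round(k * spc / record_every))
            if 0 < idx < n_rec:
                boundaries.append(idx)
            k += 1
    if boundaries[-1] != n_rec - 1 and n_rec > 1:
        pass  # an incomplete trailing cycle is allowed
    final = State(float(T[-1]) if n_rec else start, y_final, c.state_labels)
    return SimulationResult(T, waveforms, np.asarray(boundaries), dt,
                            record_every, dict(network.aliases), final)


def _cycle_metrics(result: SimulationResult, c: _Compiled) -> np.ndarray:
    """Cycle means of all node pressures plus each chamber's stroke volume."""
    t = result.time
    vals = []
    for key in c.pressure_keys:
        x = result.waveforms[key]
        vals.append(np.trapezoid(x, t) / (t[-1] - t[0]))
    for e, kind in zip(c.storages, c.s_kind):
        if kind == _kernel.CHAMBER:
            v = result.waveforms[f"V:{e.name}"]
            vals.append(v.max() - v.min())
    return np.asarray(vals)


def run_to_periodic_steady_state(
        network: Network, initial: State, dt: float = DEFAULT_DT,
        tol: float = 1e-3, max_cycles: int = 60, min_cycles: int = 4,
        record_every: int = 1,
) -> tuple[SimulationResult, int]:
    """Integrate whole cardiac cycles until the periodic orbit is reached.

    Convergence requires the relative change of every cycle-mean node
    pressure and every chamber stroke volume to stay below ``tol`` for three
    consecutive cycles (and at least ``min_cycles`` cycles in total).
    Returns the last cycle's waveforms and the number of cycles used.
    """
    if not network.period:
        raise ValueError("periodic steady state needs a cardiac period"
                         " (at least one elastance chamber)")
    c = network.compiled()
    state = initial
    prev = None
    residuals: list[float] = []
    for cycle in range(1, max_cycles + 1):
        res = simulate(network, state, network.period, dt=dt,
                       record_every=record_every, t0=(cycle - 1) * network.period)
        state = res.final_state
        metrics = _cycle_metrics(res, c)
        if prev is not None:
            denom = np.maximum(np.abs(prev), 1e-2)
            residuals.append(float(np.max(np.abs(metrics - prev) / denom)))
        prev = metrics
        if (cycle >= min_cycles and len(residuals) >= 3
                and all(r < tol for r in residuals[-3:])):
            return res, cycle
    raise NonConvergenceError(
        f"no periodic steady state after {max_cycles} cycles"
        f" (last residuals: {['%.3g' % r for r in residuals[-3:]]})")


# --- element construction helpers -------------------------------------------

def resistor(name, a, b, R):
    return CircuitElement(name, "resistor", a, b, params={"R": R})


def valve(name, a, b, R):
    return CircuitElement(name, "valve", a, b, params={"R": R})


def inductive(name, a, b, R, L):
    return CircuitElement(name, "inductor", a, b, params={"R": R, "L": L})


def flow_resistor(name, a, b, R0, k):
    return CircuitElement(name, "flow-resistor", a, b, params={"R": R0, "k": k})


def capacitor(name, node, C, ref="ambient"):
    return CircuitElement(name, "capacitor", node, params={"C": C},
                          pressure_ref=ref)


def chamber(name, node, Emax, Emin, V0, onset, Tsys, ref="intrathoracic"):
    return CircuitElement(name, "chamber", node,
                          params={"Emax": Emax, "Emin": Emin, "V0": V0,
                                  "onset": onset, "Tsys": Tsys},
                          pressure_ref=ref)
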