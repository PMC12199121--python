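"""Hydraulic-electric network solver and three-phase chip simulation.

The chip is mapped onto an equivalent electrical circuit: pressure plays the
role of voltage, volumetric flow the role of current, wetted channel
sections are resistors, menisci and the wicking pad are pressure sources,
air openings are grounds, and the passive vent is an automatic cut-off
switch that opens (cuts air access) the moment liquid wets its last branch.
Modified nodal analysis (conservation of flow at every internal node) gives
pressures and branch flows at each instant; menisci are advanced explicitly
between solves, with segment-boundary, valve-contact and vent-closure events
resolved within the step.

Three phases are simulated in sequence:

1. **loading** - the sample wicks from the inlet along the main channel,
   branching into each well as it passes; wells vent through the PV (or
   their own Norm-V holes) and stop at their valves; the delay channel's
   completion closes the PV; the front finally reaches the pad.
2. **evacuation** - the pad drains the main channel from the inlet side.
   With the PV cut off the wells are sealed dead-ends and keep their
   contents; with per-well Norm-V vents the wells drain too and the chip
   fails as soon as air breaks through a well into the channel.
3. **oil fill** - an immiscible oil refills the main channel by
   capillarity, sealing the aqueous droplets in place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.sparse.csgraph import connected_components

from .capillary_physics import (
    PRESSURE_EPS,
    burst_pressure,
    capillary_pressure,
    hydraulic_resistance,
)
from .device_model import (
    ChannelSegment,
    ChipLayout,
    FluidProperties,
    Microwell,
    Variant,
    VentKind,
    nominal_well_volume,
)
from .errors import ConfigurationError, SolverError
from .pump_and_trap import PumpCurve, constant_pump_curve

PV_OPEN = "open_to_air"
PV_CUT = "cut_off"

#: initial wetted length seeded when a meniscus enters a segment, as a
#: fraction of the segment length (keeps the entry resistance finite)
_SEED_FRACTION = 1e-3
#: floor on the pump's internal resistance when used inside the network
#: (a calibrated delivered-pressure curve carries none of its own)
_PUMP_R_FLOOR = 1e9
_TOL = 1e-12


# ---------------------------------------------------------------------------
# graph + MNA


@dataclass(frozen=True)
class Edge:
    """Resistive branch u -> v with an optional series pressure source.

    Flow convention: ``q = (p_u - p_v + source) / resistance``, positive
    from ``u`` to ``v``; ``source`` drives liquid from u toward v.
    """

    id: str
    u: str
    v: str
    resistance: float
    source: float = 0.0


@dataclass
class HydraulicGraph:
    nodes: set[str]
    edges: list[Edge]
    grounds: set[str]
    switches: dict[str, str] = field(default_factory=dict)


@dataclass
class MnaSolution:
    pressures: dict[str, float]
    flows: dict[str, float]
    residual: float  # max node imbalance relative to the largest branch flow


def mna_solve(graph: HydraulicGraph) -> MnaSolution:
    """Solve node pressures and branch flows by modified nodal analysis."""
    if not graph.grounds:
        raise SolverError("network has no ground (air opening) - singular")
    for e in graph.edges:
        if e.resistance <= 0:
            raise SolverError(f"edge {e.id!r} has non-positive resistance")

    nodes = sorted(graph.nodes | {n for e in graph.edges for n in (e.u, e.v)} | graph.grounds)
    index = {n: i for i, n in enumerate(nodes)}

    # floating components holding a source cannot be solved
    if graph.edges:
        adj = np.zeros((len(nodes), len(nodes)))
        for e in graph.edges:
            adj[index[e.u], index[e.v]] = 1
            adj[index[e.v], index[e.u]] = 1
        n_comp, labels = connected_components(adj, directed=False)
        grounded = {labels[index[g]] for g in graph.grounds if g in index}
        for e in graph.edges:
            comp = labels[index[e.u]]
            if comp not in grounded and abs(e.source) > 0:
                members = [n for n in nodes if labels[index[n]] == comp]
                raise SolverError(
                    f"floating subgraph with a pressure source but no ground: {members}"
                )

    unknown = [n for n in nodes if n not in graph.grounds]
    uidx = {n: i for i, n in enumerate(unknown)}
    m = len(unknown)
    G = np.zeros((m, m))
    b = np.zeros(m)
    for e in graph.edges:
        g = 1.0 / e.resistance
        iu = uidx.get(e.u)
        iv = uidx.get(e.v)
        if iu is not None:
            G[iu, iu] += g
            b[iu] -= g * e.source
            if iv is not None:
                G[iu, iv] -= g
        if iv is not None:
            G[iv, iv] += g
            b[iv] += g * e.source
            if iu is not None:
                G[iv, iu] -= g
    pressures = {n: 0.0 for n in graph.grounds}
    if m:
        # nodes in ungrounded passive components have zero diagonal; pin them
        loose = np.where(np.diag(G) == 0)[0]
        for i in loose:
            G[i, i] = 1.0
        try:
            p = np.linalg.solve(G, b)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise SolverError(f"singular hydraulic network: {exc}") from exc
        pressures.update({n: float(p[uidx[n]]) for n in unknown})
    flows = {
        e.id: (pressures[e.u] - pressures[e.v] + e.source) / e.resistance
        for e in graph.edges
    }
    # conservation check at internal nodes
    imbalance: dict[str, float] = {n: 0.0 for n in unknown}
    for e in graph.edges:
        q = flows[e.id]
        if e.u in imbalance:
            imbalance[e.u] -= q
        if e.v in imbalance:
            imbalance[e.v] += q
    qmax = max((abs(q) for q in flows.values()), default=0.0)
    residual = max((abs(x) for x in imbalance.values()), default=0.0)
    return MnaSolution(
        pressures=pressures,
        flows=flows,
        residual=residual / qmax if qmax > 0 else residual,
    )


# ---------------------------------------------------------------------------
# interface state


@dataclass
class InterfaceState:
    """Wetted lengths plus vent-switch state at one instant."""

    time: float
    wetted: dict[str, float]
    pv_state: str = PV_OPEN
    events: list[tuple[float, str]] = field(default_factory=list)

    def log(self, message: str) -> None:
        self.events.append((self.time, message))


@dataclass
class PhaseReport:
    phase: str  # loading | evacuation | oil_fill
    outcome: str  # success | failed_* (see module docs)
    duration: float
    per_well_fill_time: Optional[list[Optional[float]]] = None
    per_well_drained_volume: Optional[list[float]] = None
    per_well_trapped_volume: Optional[list[float]] = None
    sv_burst: Optional[list[bool]] = None
    pv_closure_time: Optional[float] = None
    pump_contact_time: Optional[float] = None
    events: list[tuple[float, str]] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    @property
    def success(self) -> bool:
        return self.outcome == "success"


# ---------------------------------------------------------------------------
# layout -> chain helpers


def _chain(layout: ChipLayout) -> tuple[list[ChannelSegment], list[str]]:
    """Ordered main-channel path and its node names, inlet to terminal."""
    segs = list(layout.mf_segments)
    nodes = ["inlet"] + [f"j{k}" for k in range(1, layout.n_wells + 1)] + ["jd"]
    if layout.bubble_trap is not None:
        segs.append(layout.bubble_trap.segment)
        nodes.append("pump")
    elif layout.tail is not None:
        segs.append(layout.tail)
        nodes.append("outlet")
    else:  # pragma: no cover - layouts always carry one of the two
        nodes.append("end")
    return segs, nodes


def _well_fill_stages(well: Microwell) -> list[ChannelSegment]:
    """Segments liquid actually fills during loading (the SV is a barrier)."""
    return [s for s in (well.body, well.pr) if s is not None]


def initial_state(layout: ChipLayout) -> InterfaceState:
    segs, _ = _chain(layout)
    wetted = {s.id: 0.0 for s in segs}
    for w in layout.wells:
        for s in w.segments:
            wetted[s.id] = 0.0
    if layout.vent.delay is not None:
        wetted[layout.vent.delay.id] = 0.0
    return InterfaceState(time=0.0, wetted=wetted, pv_state=PV_OPEN)


def _check_state(layout: ChipLayout, state: InterfaceState) -> None:
    segs, _ = _chain(layout)
    all_segs = list(segs) + [s for w in layout.wells for s in w.segments]
    if layout.vent.delay is not None:
        all_segs.append(layout.vent.delay)
    for s in all_segs:
        x = state.wetted.get(s.id, 0.0)
        if x < -_TOL or x > s.length * (1 + 1e-9):
            raise SolverError(
                f"inconsistent state: meniscus at {x} outside segment {s.id!r} "
                f"of length {s.length}"
            )


def build_graph(
    layout: ChipLayout, fluid: FluidProperties, state: InterfaceState
) -> HydraulicGraph:
    """Loading-phase network for the given interface state.

    One collapsed resistive edge per (partially) wetted branch; every
    advancing meniscus appears as a branch to the shared air ground with its
    own capillary source.  Well branches are present only while they have an
    air path: always for Norm-V wells, and only while the PV switch is
    ``open_to_air`` for PV chips.
    """
    _check_state(layout, state)
    segs, nodes_chain = _chain(layout)
    edges: list[Edge] = []
    grounds = {"inlet"}
    nodes: set[str] = {"inlet"}

    frontier = len(segs)
    for i, s in enumerate(segs):
        if state.wetted[s.id] < s.length * (1 - 1e-12):
            frontier = i
            break
    for i in range(frontier):
        edges.append(
            Edge(
                id=f"seg:{segs[i].id}",
                u=nodes_chain[i],
                v=nodes_chain[i + 1],
                resistance=hydraulic_resistance(segs[i], fluid, segs[i].length),
            )
        )
        nodes.update((nodes_chain[i], nodes_chain[i + 1]))
    if frontier < len(segs):
        s = segs[frontier]
        x = state.wetted[s.id]
        if x > 0:
            edges.append(
                Edge(
                    id="fill:chain",
                    u=nodes_chain[frontier],
                    v="air",
                    resistance=hydraulic_resistance(s, fluid, x),
                    source=capillary_pressure(s.cross_section, fluid, "advancing").value,
                )
            )
            nodes.add(nodes_chain[frontier])

    pv_vent = layout.vent.kind is VentKind.pv
    wells_vented = (layout.vent.kind is VentKind.norm_v) or (
        pv_vent and state.pv_state == PV_OPEN
    )
    for well in layout.wells:
        stages = _well_fill_stages(well)
        r_done = 0.0
        active: Optional[tuple[ChannelSegment, float]] = None
        for s in stages:
            x = state.wetted[s.id]
            if x >= s.length * (1 - 1e-12):
                r_done += hydraulic_resistance(s, fluid, s.length)
                continue
            if x > 0:
                active = (s, x)
            break
        if active is not None and wells_vented:
            s, x = active
            edges.append(
                Edge(
                    id=f"fill:well{well.index}",
                    u=f"j{well.index}",
                    v="air",
                    resistance=r_done + hydraulic_resistance(s, fluid, x),
                    source=capillary_pressure(s.cross_section, fluid, "advancing").value,
                )
            )
            nodes.add(f"j{well.index}")

    delay = layout.vent.delay
    if delay is not None and state.pv_state == PV_OPEN:
        x = state.wetted[delay.id]
        if 0 < x < delay.length * (1 - 1e-12):
            edges.append(
                Edge(
                    id="fill:delay",
                    u="jd",
                    v="air",
                    resistance=hydraulic_resistance(delay, fluid, x),
                    source=capillary_pressure(delay.cross_section, fluid, "advancing").value,
                )
            )
            nodes.add("jd")

    if any(e.v == "air" for e in edges):
        grounds.add("air")
        nodes.add("air")
    switches = {"PV": state.pv_state} if pv_vent else {}
    return HydraulicGraph(nodes=nodes, edges=edges, grounds=grounds, switches=switches)


# ---------------------------------------------------------------------------
# loading


def _failed_report(phase: str, outcome: str, layout: ChipLayout, message: str) -> PhaseReport:
    n = layout.n_wells
    report = PhaseReport(
        phase=phase,
        outcome=outcome,
        duration=0.0,
        per_well_fill_time=[None] * n,
        sv_burst=[False] * n,
        events=[(0.0, message)],
    )
    return report


def simulate_loading(
    layout: ChipLayout,
    fluid: FluidProperties,
    step_fraction: float = 0.05,
    max_steps: int = 500_000,
) -> tuple[PhaseReport, InterfaceState]:
    """Event-driven loading simulation.

    Explicit time stepping with a per-step MNA solve; the step is chosen so
    no meniscus crosses more than ``step_fraction`` of its segment, and is
    clipped to land exactly on the next completion event.  Records per-well
    fill times, valve-burst flags, PV closure and pad-contact times.
    """
    segs, nodes_chain = _chain(layout)
    n = layout.n_wells
    p_mf = capillary_pressure(segs[0].cross_section, fluid, "advancing").value
    if p_mf <= PRESSURE_EPS:
        return (
            _failed_report(
                "loading",
                "failed_no_wetting",
                layout,
                f"no spontaneous filling: MF advancing pressure {p_mf:.3g} Pa <= 0",
            ),
            initial_state(layout),
        )

    state = initial_state(layout)
    pv_vent = layout.vent.kind is VentKind.pv
    seg_index = {s.id: i for i, s in enumerate(segs)}
    state.wetted[segs[0].id] = _SEED_FRACTION * segs[0].length
    state.log("sample enters the main channel at the inlet")

    fill_time: list[Optional[float]] = [None] * n
    burst_flags = [False] * n
    pv_closure: Optional[float] = None
    pump_contact: Optional[float] = None
    pv_timing_failed = False
    burst = False
    areas = {}
    lengths = {}
    for s in segs + [x for w in layout.wells for x in w.segments]:
        areas[s.id] = s.cross_section.area
        lengths[s.id] = s.length
    if layout.vent.delay is not None:
        areas[layout.vent.delay.id] = layout.vent.delay.cross_section.area
        lengths[layout.vent.delay.id] = layout.vent.delay.length

    def branch_segment(edge_id: str) -> ChannelSegment:
        if edge_id == "fill:chain":
            for s in segs:
                if state.wetted[s.id] < s.length * (1 - 1e-12):
                    return s
        if edge_id == "fill:delay":
            return layout.vent.delay  # type: ignore[return-value]
        k = int(edge_id.removeprefix("fill:well"))
        for s in _well_fill_stages(layout.wells[k - 1]):
            if state.wetted[s.id] < s.length * (1 - 1e-12):
                return s
        raise SolverError(f"no active segment for branch {edge_id}")

    last_solution: Optional[MnaSolution] = None
    for _ in range(max_steps):
        graph = build_graph(layout, fluid, state)
        sol = mna_solve(graph)
        last_solution = sol
        fill_edges = [e for e in graph.edges if e.id.startswith("fill:")]
        moving = []
        for e in fill_edges:
            q = sol.flows[e.id]
            if q > 0:
                moving.append((e, q, branch_segment(e.id)))
        if not moving:
            return (
                PhaseReport(
                    phase="loading",
                    outcome="failed_no_wetting",
                    duration=state.time,
                    per_well_fill_time=fill_time,
                    sv_burst=burst_flags,
                    pv_closure_time=pv_closure,
                    pump_contact_time=pump_contact,
                    events=state.events + [(state.time, "capillary filling stalled")],
                ),
                state,
            )
        dt = math.inf
        for e, q, s in moving:
            v = q / areas[s.id]
            remaining = lengths[s.id] - state.wetted[s.id]
            dt = min(dt, step_fraction * lengths[s.id] / v, remaining / v)
        completed: list[tuple[str, ChannelSegment]] = []
        for e, q, s in moving:
            dx = (q / areas[s.id]) * dt
            new = min(state.wetted[s.id] + dx, lengths[s.id])
            state.wetted[s.id] = new
            if new >= lengths[s.id] * (1 - 1e-12):
                state.wetted[s.id] = lengths[s.id]
                completed.append((e.id, s))
        state.time += dt

        stop = False
        for edge_id, s in completed:
            if edge_id == "fill:chain":
                i = seg_index[s.id]
                arrival = nodes_chain[i + 1]
                state.log(f"main-channel front reaches {arrival}")
                if arrival.startswith("j") and arrival != "jd":
                    k = int(arrival[1:])
                    body = layout.wells[k - 1].body
                    if state.wetted[body.id] == 0.0:
                        state.wetted[body.id] = _SEED_FRACTION * body.length
                        state.log(f"well {k} starts filling")
                if arrival == "jd" and layout.vent.delay is not None:
                    d = layout.vent.delay
                    if state.wetted[d.id] == 0.0:
                        state.wetted[d.id] = _SEED_FRACTION * d.length
                        state.log("delay channel starts filling")
                if i + 1 < len(segs):
                    nxt = segs[i + 1]
                    if state.wetted[nxt.id] == 0.0:
                        state.wetted[nxt.id] = _SEED_FRACTION * nxt.length
                else:
                    pump_contact = state.time
                    state.log(
                        "front contacts the wicking pad"
                        if layout.bubble_trap is not None
                        else "front reaches the outlet reservoir"
                    )
            elif edge_id == "fill:delay":
                pv_closure = state.time
                state.pv_state = PV_CUT
                state.log("PV last branch wetted: passive vent cuts off air access")
                unfilled = [k + 1 for k in range(n) if fill_time[k] is None]
                if unfilled:
                    pv_timing_failed = True
                    state.log(f"PV closed before wells {unfilled} filled")
            else:
                k = int(edge_id.removeprefix("fill:well"))
                well = layout.wells[k - 1]
                stages = _well_fill_stages(well)
                pos = stages.index(s)
                if pos + 1 < len(stages):
                    nxt = stages[pos + 1]
                    if state.wetted[nxt.id] == 0.0:
                        state.wetted[nxt.id] = _SEED_FRACTION * nxt.length
                    continue
                # branch complete: valve contact (or vent-hole pinning)
                if well.sv is None:
                    fill_time[k - 1] = state.time
                    state.log(f"well {k} filled; meniscus pinned at Norm-V")
                    continue
                p_node = sol.pressures.get(f"j{k}", 0.0)
                p_local = capillary_pressure(s.cross_section, fluid, "advancing").value
                p_face = p_node + p_local
                threshold = burst_pressure(well.sv, fluid)
                if p_face > threshold:
                    burst_flags[k - 1] = True
                    burst = True
                    state.log(
                        f"SV burst at well {k}: face pressure {p_face:.1f} Pa > "
                        f"threshold {threshold:.1f} Pa"
                    )
                    stop = True
                else:
                    fill_time[k - 1] = state.time
                    state.log(
                        f"well {k} filled; SV holds ({p_face:.1f} Pa <= {threshold:.1f} Pa)"
                    )
        if stop:
            break
        done_chain = pump_contact is not None
        done_pv = (not pv_vent) or state.pv_state == PV_CUT
        # PV chips: closure freezes any unfilled well, so the phase is over;
        # Norm-V chips keep venting, so wait for every well to finish
        done_wells = (pv_vent and state.pv_state == PV_CUT) or all(
            t is not None for t in fill_time
        )
        if done_chain and done_pv and done_wells:
            break
    else:
        raise SolverError(f"loading did not finish within {max_steps} steps")

    if burst:
        outcome = "failed_sv_burst"
    elif pv_timing_failed or any(t is None for t in fill_time):
        outcome = "failed_pv_timing"
    elif pump_contact is None:
        outcome = "failed_no_wetting"
    else:
        outcome = "success"
    report = PhaseReport(
        phase="loading",
        outcome=outcome,
        duration=state.time,
        per_well_fill_time=fill_time,
        sv_burst=burst_flags,
        pv_closure_time=pv_closure,
        pump_contact_time=pump_contact,
        events=list(state.events),
        extras={
            "mna_residual": last_solution.residual if last_solution else 0.0,
            "loading_time_s": pump_contact,
        },
    )
    return report, state


# ---------------------------------------------------------------------------
# evacuation


def _meniscus_depth(well: Microwell) -> float:
    """Depth of the emptied cap at a well mouth after evacuation (w/2)."""
    return well.body.cross_section.width / 2.0


def emptied_volume(well: Microwell) -> float:
    """Volume of the emptied meniscus cap at a well mouth: (pi/8) w^2 h."""
    cs = well.body.cross_section
    return math.pi / 8.0 * cs.width**2 * cs.height


def simulate_evacuation(
    layout: ChipLayout,
    fluid: FluidProperties,
    pump: Optional[PumpCurve] = None,
    suction_pressure: float = 5000.0,
    step_fraction: float = 0.05,
    max_steps: int = 500_000,
) -> PhaseReport:
    """Drain the main channel through the wicking pad (or lab suction).

    Starts from the post-loading state: chain fully wet, wells full, PV cut
    off (PV chips).  The receding meniscus retreats from the inlet toward
    the pad; Norm-V wells drain in parallel through their vent holes and the
    run fails with ``failed_disconnect`` the moment any of them empties (air
    then separates the pad from the liquid column).  The pad acts as a
    fill-fraction-dependent pressure source behind its internal resistance.
    """
    segs, nodes_chain = _chain(layout)
    n = layout.n_wells
    terminal = nodes_chain[-1]
    if pump is None:
        pump = layout.pump
    if pump is None:
        if layout.variant is Variant.capdrop_cell:
            # external suction stub: constant pressure, effectively unlimited
            pump = constant_pump_curve(
                p0=suction_pressure, capacity=1.0, internal_resistance=1e10
            )
        else:
            raise ConfigurationError(
                f"variant {layout.variant.value} requires a wicking pad for evacuation"
            )

    pv_vent = layout.vent.kind is VentKind.pv
    wells_drain = layout.vent.kind is VentKind.norm_v
    # receding end-cap pressures (oppose drainage)
    p_rec_chain = [
        capillary_pressure(s.cross_section, fluid, "receding").value for s in segs
    ]
    p_rec_well = [
        capillary_pressure(w.body.cross_section, fluid, "receding").value
        for w in layout.wells
    ]

    drained = {s.id: 0.0 for s in segs}
    well_wet = [w.body.length for w in layout.wells]
    drained_vol = [0.0] * n
    pad_volume = 0.0
    t = 0.0
    events: list[tuple[float, str]] = [(0.0, "evacuation starts: pad pulls on the main channel")]
    traj_t: list[float] = []
    traj_q: list[float] = []
    outcome = None
    residual = 0.0

    for _ in range(max_steps):
        front = len(segs)
        for i, s in enumerate(segs):
            if drained[s.id] < s.length * (1 - 1e-12):
                front = i
                break
        if front == len(segs):
            outcome = "success"
            events.append((t, "main channel fully drained"))
            break
        fill_fraction = min(pad_volume / pump.capacity, 1.0)
        if fill_fraction >= 1.0:
            outcome = "failed_disconnect"
            events.append((t, "wicking pad saturated before the channel emptied"))
            break

        edges = [
            Edge(
                id="front",
                u="air_front",
                v=nodes_chain[front + 1],
                resistance=hydraulic_resistance(
                    segs[front], fluid, segs[front].length - drained[segs[front].id]
                ),
                source=-p_rec_chain[front],
            )
        ]
        for i in range(front + 1, len(segs)):
            edges.append(
                Edge(
                    id=f"seg:{segs[i].id}",
                    u=nodes_chain[i],
                    v=nodes_chain[i + 1],
                    resistance=hydraulic_resistance(segs[i], fluid, segs[i].length),
                )
            )
        active_wells = []
        if wells_drain:
            for k in range(1, n + 1):
                if well_wet[k - 1] <= 0 or k <= front:
                    continue  # emptied, or mouth already behind the front
                wellseg = layout.wells[k - 1].body
                edges.append(
                    Edge(
                        id=f"well{k}",
                        u=f"norm_v_{k}",
                        v=f"j{k}",
                        resistance=hydraulic_resistance(wellseg, fluid, well_wet[k - 1]),
                        source=-p_rec_well[k - 1],
                    )
                )
                active_wells.append(k)
        r_pump = max(pump.internal_resistance(fill_fraction), _PUMP_R_FLOOR)
        edges.append(
            Edge(
                id="pump",
                u=terminal,
                v="wiki_v",
                resistance=r_pump,
                source=pump.pressure(fill_fraction),
            )
        )
        grounds = {"air_front", "wiki_v"} | {f"norm_v_{k}" for k in active_wells}
        graph = HydraulicGraph(
            nodes={x for e in edges for x in (e.u, e.v)},
            edges=edges,
            grounds=grounds,
            switches={"PV": PV_CUT} if pv_vent else {},
        )
        sol = mna_solve(graph)
        residual = max(residual, sol.residual)
        q_pump = sol.flows["pump"]
        q_front = sol.flows["front"]
        if q_pump <= 0:
            outcome = "failed_no_wetting"
            events.append((t, "evacuation stalled: pad pressure cannot overcome the receding meniscus"))
            break

        front_seg = segs[front]
        a_front = front_seg.cross_section.area
        dt = math.inf
        if q_front > 0:
            v = q_front / a_front
            remaining = front_seg.length - drained[front_seg.id]
            dt = min(dt, step_fraction * front_seg.length / v, remaining / v)
        for k in active_wells:
            qk = sol.flows[f"well{k}"]
            if qk > 0:
                a = layout.wells[k - 1].body.cross_section.area
                v = qk / a
                dt = min(
                    dt,
                    step_fraction * layout.wells[k - 1].body.length / v,
                    well_wet[k - 1] / v,
                )
        dt = min(dt, 0.02 * pump.capacity / q_pump)
        if not math.isfinite(dt) or dt <= 0:
            outcome = "failed_no_wetting"
            events.append((t, "evacuation stalled"))
            break

        if q_front > 0:
            drained[front_seg.id] = min(
                drained[front_seg.id] + (q_front / a_front) * dt, front_seg.length
            )
        emptied_now = []
        for k in active_wells:
            qk = sol.flows[f"well{k}"]
            if qk > 0:
                a = layout.wells[k - 1].body.cross_section.area
                well_wet[k - 1] = max(well_wet[k - 1] - (qk / a) * dt, 0.0)
                drained_vol[k - 1] += qk * dt
                if well_wet[k - 1] <= 0:
                    emptied_now.append(k)
        pad_volume += q_pump * dt
        t += dt
        traj_t.append(t)
        traj_q.append(q_pump)
        if drained[front_seg.id] >= front_seg.length * (1 - 1e-12):
            drained[front_seg.id] = front_seg.length
            events.append((t, f"front passes {nodes_chain[front + 1]}"))
        if emptied_now:
            outcome = "failed_disconnect"
            events.append(
                (
                    t,
                    f"air broke through Norm-V of well(s) {emptied_now} into the "
                    f"channel: pad disconnected from the sample",
                )
            )
            break
    else:
        raise SolverError(f"evacuation did not finish within {max_steps} steps")

    trapped = None
    if outcome == "success" and pv_vent:
        trapped = [
            nominal_well_volume(w) - emptied_volume(w) for w in layout.wells
        ]
    mf_drained = sum(drained[s.id] * s.cross_section.area for s in segs)
    return PhaseReport(
        phase="evacuation",
        outcome=outcome or "failed_no_wetting",
        duration=t,
        per_well_drained_volume=list(drained_vol),
        per_well_trapped_volume=trapped,
        events=events,
        extras={
            "flow_times": np.asarray(traj_t),
            "flow_rates": np.asarray(traj_q),
            "mf_drained_volume": mf_drained,
            "pad_volume": pad_volume,
            "pad_fill_fraction": pad_volume / pump.capacity,
            "mna_residual": residual,
        },
    )


# ---------------------------------------------------------------------------
# oil fill


def simulate_oil_fill(layout: ChipLayout, oil: FluidProperties) -> PhaseReport:
    """Refill the (evacuated) main channel with oil by capillarity.

    The aqueous plugs in the wells are immobile boundaries, so only the main
    chain fills; air ahead of the oil leaves through the terminal vent.  The
    quasi-steady model integrates exactly per segment: with upstream
    resistance ``R0`` and per-length resistance ``r_u``,
    ``t_seg = A (R0 L + r_u L^2 / 2) / P``.
    """
    segs, nodes_chain = _chain(layout)
    events: list[tuple[float, str]] = []
    t = 0.0
    r_upstream = 0.0
    seg_times = []
    for i, s in enumerate(segs):
        p = capillary_pressure(s.cross_section, oil, "advancing").value
        if p <= PRESSURE_EPS:
            return PhaseReport(
                phase="oil_fill",
                outcome="failed_no_wetting",
                duration=t,
                events=events
                + [(t, f"no spontaneous oil filling in {s.id} (pressure {p:.3g} Pa)")],
                extras={"crosstalk_eliminated": False},
            )
        a = s.cross_section.area
        r_full = hydraulic_resistance(s, oil, s.length)
        r_u = r_full / s.length
        t += a * (r_upstream * s.length + 0.5 * r_u * s.length**2) / p
        r_upstream += r_full
        seg_times.append(t)
        events.append((t, f"oil front reaches {nodes_chain[i + 1]}"))
    events.append((t, "main channel oil-filled: wells sealed, crosstalk eliminated"))
    return PhaseReport(
        phase="oil_fill",
        outcome="success",
        duration=t,
        events=events,
        extras={
            "crosstalk_eliminated": True,
            "segment_fill_times": seg_times,
            "oil_volume": sum(s.volume for s in segs),
        },
    )


# ---------------------------------------------------------------------------
# workflow


def run_workflow(
    layout: ChipLayout,
    sample_fluid: FluidProperties,
    oil: FluidProperties,
    pump: Optional[PumpCurve] = None,
) -> list[PhaseReport]:
    """Loading -> evacuation -> oil fill, aborting at the first failure."""
    loading, _state = simulate_loading(layout, sample_fluid)
    reports = [loading]
    if not loading.success:
        return reports
    evacuation = simulate_evacuation(layout, sample_fluid, pump=pump)
    reports.append(evacuation)
    if not evacuation.success:
        return reports
    reports.append(simulate_oil_fill(layout, oil))
    return reports
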