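"""Network solver and three-phase simulation behavior."""

import numpy as np
import pytest

import capdrop as cd
from capdrop.eec_solver import (
    PV_CUT,
    PV_OPEN,
    Edge,
    HydraulicGraph,
    build_graph,
    initial_state,
    mna_solve,
)
from capdrop.errors import SolverError


# ---------------------------------------------------------------------------
# MNA


def brute_force_solve(graph):
    """Independent least-squares solve of the stacked KCL + ground system."""
    nodes = sorted({n for e in graph.edges for n in (e.u, e.v)} | graph.grounds)
    idx = {n: i for i, n in enumerate(nodes)}
    rows, rhs = [], []
    for n in nodes:
        if n in graph.grounds:
            continue
        row = np.zeros(len(nodes))
        c = 0.0
        for e in graph.edges:
            g = 1.0 / e.resistance
            if e.v == n:  # inflow (p_u - p_v + E) g
                row[idx[e.u]] += g
                row[idx[e.v]] -= g
                c -= g * e.source
            if e.u == n:  # outflow
                row[idx[e.u]] -= g
                row[idx[e.v]] += g
                c += g * e.source
        rows.append(row)
        rhs.append(c)
    for gnd in graph.grounds:
        row = np.zeros(len(nodes))
        row[idx[gnd]] = 1.0
        rows.append(row)
        rhs.append(0.0)
    A = np.asarray(rows)
    b = np.asarray(rhs)
    # equilibrate: KCL rows carry conductance scales ~1e-10, ground rows ~1
    norms = np.abs(A).max(axis=1)
    p, *_ = np.linalg.lstsq(A / norms[:, None], b / norms, rcond=None)
    return {n: p[idx[n]] for n in nodes}


def random_graph(rng, max_nodes=20):
    n = rng.integers(3, max_nodes + 1)
    names = [f"n{i}" for i in range(n)]
    edges = []
    for i in range(1, n):  # random spanning tree keeps it connected
        j = int(rng.integers(0, i))
        edges.append(
            Edge(
                id=f"e{i}",
                u=names[j],
                v=names[i],
                resistance=float(10 ** rng.uniform(9, 11)),
                source=float(rng.normal(0, 500)),
            )
        )
    for k in range(int(rng.integers(0, n))):
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        edges.append(
            Edge(
                id=f"x{k}",
                u=names[int(i)],
                v=names[int(j)],
                resistance=float(10 ** rng.uniform(9, 11)),
                source=float(rng.normal(0, 500)),
            )
        )
    # at least two grounds so the network carries real through-flow
    grounds = set(rng.choice(names, size=int(rng.integers(2, 4)), replace=False))
    return HydraulicGraph(nodes=set(names), edges=edges, grounds=grounds)


class TestMnaSolve:
    def test_single_edge_is_ohms_law(self):
        g = HydraulicGraph(
            nodes={"a", "gnd"},
            edges=[Edge(id="e", u="a", v="gnd", resistance=1e10, source=100.0)],
            grounds={"gnd", "a"},
        )
        sol = mna_solve(g)
        assert sol.flows["e"] == pytest.approx(100.0 / 1e10)

    def test_parallel_resistors_split_evenly(self):
        edges = [
            Edge(id="feed", u="src", v="mid", resistance=1e9, source=1000.0),
            Edge(id="a", u="mid", v="gnd", resistance=1e10),
            Edge(id="b", u="mid", v="gnd", resistance=1e10),
        ]
        sol = mna_solve(
            HydraulicGraph(nodes={"src", "mid", "gnd"}, edges=edges, grounds={"src", "gnd"})
        )
        assert sol.flows["a"] == pytest.approx(sol.flows["b"])
        assert sol.flows["feed"] == pytest.approx(sol.flows["a"] + sol.flows["b"])

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            g = random_graph(rng)
            sol = mna_solve(g)
            ref = brute_force_solve(g)
            q_ref = {
                e.id: (ref[e.u] - ref[e.v] + e.source) / e.resistance
                for e in g.edges
            }
            scale = max(abs(q) for q in q_ref.values())
            for e in g.edges:
                assert abs(sol.flows[e.id] - q_ref[e.id]) <= 1e-9 * scale
            p_scale = max(abs(p) for p in ref.values())
            for n, p in sol.pressures.items():
                assert abs(p - ref[n]) <= 1e-9 * p_scale
            assert sol.residual <= 1e-12

    def test_floating_source_component_is_named(self):
        edges = [
            Edge(id="ok", u="a", v="gnd", resistance=1e10, source=10.0),
            Edge(id="float", u="b", v="c", resistance=1e10, source=10.0),
        ]
        with pytest.raises(SolverError, match="b"):
            mna_solve(
                HydraulicGraph(nodes={"a", "b", "c", "gnd"}, edges=edges, grounds={"gnd", "a"})
            )

    def test_no_ground_rejected(self):
        with pytest.raises(SolverError, match="ground"):
            mna_solve(HydraulicGraph(nodes={"a"}, edges=[], grounds=set()))


# ---------------------------------------------------------------------------
# build_graph


class TestBuildGraph:
    def test_empty_chip_has_no_resistive_edges(self, capdrop10, water):
        g = build_graph(capdrop10, water, initial_state(capdrop10))
        assert g.edges == []
        assert g.grounds == {"inlet"}

    def test_loading_state_has_vented_well_branches(self, capdrop10, water):
        state = initial_state(capdrop10)
        # front inside segment 3; wells 1-2 filling
        for s in capdrop10.mf_segments[:3]:
            state.wetted[s.id] = s.length
        state.wetted[capdrop10.mf_segments[3].id] = capdrop10.mf_segments[3].length / 2
        for k in (1, 2):
            body = capdrop10.wells[k - 1].body
            state.wetted[body.id] = body.length / 2
        g = build_graph(capdrop10, water, state)
        ids = {e.id for e in g.edges}
        assert {"fill:chain", "fill:well1", "fill:well2"} <= ids
        assert g.switches["PV"] == PV_OPEN
        assert "air" in g.grounds

    def test_pv_closure_removes_air_paths(self, capdrop10, water):
        state = initial_state(capdrop10)
        for s in capdrop10.mf_segments:
            state.wetted[s.id] = s.length
        state.wetted[capdrop10.bubble_trap.segment.id] = capdrop10.bubble_trap.segment.length
        for w in capdrop10.wells:
            for s in (w.body, w.pr):
                state.wetted[s.id] = s.length
        state.wetted[capdrop10.vent.delay.id] = capdrop10.vent.delay.length
        state.pv_state = PV_CUT
        g = build_graph(capdrop10, water, state)
        assert g.grounds == {"inlet"}
        assert g.switches["PV"] == PV_CUT
        assert not any(e.id.startswith("fill:") for e in g.edges)

    def test_unvented_wells_do_not_fill_after_closure(self, capdrop10, water):
        state = initial_state(capdrop10)
        for s in capdrop10.mf_segments[:2]:
            state.wetted[s.id] = s.length
        body = capdrop10.wells[0].body
        state.wetted[body.id] = body.length / 2
        state.pv_state = PV_CUT
        g = build_graph(capdrop10, water, state)
        assert "fill:well1" not in {e.id for e in g.edges}

    def test_inconsistent_state_rejected(self, capdrop10, water):
        state = initial_state(capdrop10)
        state.wetted[capdrop10.mf_segments[0].id] = 10.0  # way past the end
        with pytest.raises(SolverError, match="outside segment"):
            build_graph(capdrop10, water, state)


# ---------------------------------------------------------------------------
# loading


class TestLoading:
    def test_capdrop_defaults_succeed(self, loading_capdrop):
        report, state = loading_capdrop
        assert report.outcome == "success"
        assert all(t is not None for t in report.per_well_fill_time)
        assert not any(report.sv_burst)
        assert report.pump_contact_time is not None
        # the PV must close only after the last well has filled
        assert report.pv_closure_time > max(report.per_well_fill_time)
        assert state.pv_state == PV_CUT

    def test_capdrop_n_loads_successfully(self, capdropn10, water):
        report, _ = cd.simulate_loading(capdropn10, water)
        assert report.outcome == "success"
        assert all(t is not None for t in report.per_well_fill_time)

    def test_sv1_style_valve_passes_liquid(self, water):
        lay = cd.build_layout(
            "capdrop", 2, geometry={"sv_style": "sv1", "mf_length": "4 cm", "delay_length": "1 cm"}
        )
        report, _ = cd.simulate_loading(lay, water)
        assert report.outcome == "failed_sv_burst"
        assert any(report.sv_burst)

    @pytest.mark.parametrize("sv_width", ["120 um", "300 um", "500 um"])
    def test_sweat_bursts_at_every_valve_width(self, sweat, sv_width):
        lay = cd.build_layout(
            "capdrop", 2,
            geometry={"sv_width": sv_width, "mf_length": "4 cm", "delay_length": "1 cm"},
        )
        report, _ = cd.simulate_loading(lay, sweat)
        assert report.outcome == "failed_sv_burst"

    def test_non_wetting_fluid_fails_immediately(self, capdrop10):
        from test_capillary_physics import fluid_with_angles

        report, _ = cd.simulate_loading(capdrop10, fluid_with_angles(120, 120))
        assert report.outcome == "failed_no_wetting"
        assert report.duration == 0.0

    def test_too_short_delay_closes_pv_early(self, water):
        lay = cd.build_layout(
            "capdrop", 1,
            geometry={"mf_length": "2 mm", "delay_length": "0.2 mm", "mw_length": "10 mm"},
        )
        report, _ = cd.simulate_loading(lay, water)
        assert report.outcome == "failed_pv_timing"

    def test_pv_never_reopens(self, loading_capdrop):
        report, state = loading_capdrop
        closures = [m for _, m in report.events if "cuts off" in m]
        assert len(closures) == 1
        assert state.pv_state == PV_CUT

    def test_loading_time_monotone_in_viscosity_and_pressure(self):
        from test_capillary_physics import fluid_with_angles

        lay = cd.build_layout(
            "capdrop", 2, geometry={"mf_length": "4 cm", "delay_length": "1 cm"}
        )
        times = np.empty((3, 3))
        for i, mu in enumerate((1e-3, 2e-3, 4e-3)):
            for j, gamma in enumerate((0.05, 0.072, 0.09)):
                f = fluid_with_angles(40, 110, gamma=gamma, mu=mu,
                                      film_rec=20, adh_rec=80)
                report, _ = cd.simulate_loading(lay, f)
                assert report.outcome == "success"
                times[i, j] = report.pump_contact_time
        # nondecreasing in viscosity (rows), nonincreasing in driving pressure
        assert np.all(np.diff(times, axis=0) > 0)
        assert np.all(np.diff(times, axis=1) < 0)
        # quasi-steady scaling: time is exactly linear in viscosity
        assert times[1, 0] == pytest.approx(2 * times[0, 0], rel=1e-6)

    def test_mass_conservation_at_internal_nodes(self, loading_capdrop):
        report, _ = loading_capdrop
        assert report.extras["mna_residual"] <= 1e-12


# ---------------------------------------------------------------------------
# evacuation


class TestEvacuation:
    def test_pv_chip_drains_channel_but_not_wells(self, evac_capdrop, capdrop10):
        report = evac_capdrop
        assert report.outcome == "success"
        assert max(report.per_well_drained_volume) == 0.0
        mf_volume = sum(s.volume for s in capdrop10.mf_segments) + (
            capdrop10.bubble_trap.segment.volume
        )
        assert report.extras["mf_drained_volume"] == pytest.approx(mf_volume)

    def test_trapped_volume_is_nominal_minus_meniscus_cap(self, evac_capdrop, capdrop10):
        well = capdrop10.wells[0]
        expected = cd.nominal_well_volume(well) - cd.emptied_volume(well)
        assert report_trapped(evac_capdrop)[0] == pytest.approx(expected)
        assert all(v > 0 for v in report_trapped(evac_capdrop))

    def test_norm_v_chip_fails_by_disconnect(self, evac_capdropn):
        report = evac_capdropn
        assert report.outcome == "failed_disconnect"

    def test_norm_v_drainage_peaks_at_wells_9_and_10(self, evac_capdropn):
        drained = np.asarray(evac_capdropn.per_well_drained_volume)
        top_two = set(np.argsort(drained)[-2:] + 1)
        assert top_two == {9, 10}
        assert drained[-1] > 0

    def test_zero_pressure_pump_moves_nothing(self, capdrop10, water):
        dead = cd.PumpCurve(capacity=1e-7, fill_knots=[0, 1], pressure_knots=[0.0, 0.0])
        report = cd.simulate_evacuation(capdrop10, water, pump=dead)
        assert not report.success
        assert report.extras["mf_drained_volume"] == 0.0

    def test_missing_pump_is_a_configuration_error(self, capdropn10, water):
        stripped = capdropn10.model_copy(update={"pump": None})
        with pytest.raises(cd.ConfigurationError, match="wicking pad"):
            cd.simulate_evacuation(stripped, water)

    def test_falling_pump_curve_flattens_evacuation_rate(self, capdrop10, water, evac_capdrop):
        q_falling = evac_capdrop.extras["flow_rates"]
        const = cd.simulate_evacuation(capdrop10, water, pump=cd.constant_pump_curve())
        q_const = const.extras["flow_rates"]
        cv_falling = q_falling.std() / q_falling.mean()
        cv_const = q_const.std() / q_const.mean()
        assert cv_falling < cv_const

    def test_capdrop_cell_uses_suction_stub(self, water):
        lay = cd.build_layout("capdrop_cell", 5)
        report = cd.simulate_evacuation(lay, water)
        assert report.outcome == "success"

    def test_mass_conservation(self, evac_capdrop):
        assert evac_capdrop.extras["mna_residual"] <= 1e-12
        # everything the pad absorbed left the main channel
        assert evac_capdrop.extras["pad_volume"] == pytest.approx(
            evac_capdrop.extras["mf_drained_volume"], rel=1e-6
        )


def report_trapped(report):
    return report.per_well_trapped_volume


# ---------------------------------------------------------------------------
# oil fill and workflow


class TestOilFill:
    def test_default_oil_seals_the_channel(self, capdrop10, oil):
        report = cd.simulate_oil_fill(capdrop10, oil)
        assert report.success
        assert report.extras["crosstalk_eliminated"] is True

    def test_neutral_oil_cannot_fill(self, capdrop10):
        from test_capillary_physics import fluid_with_angles

        report = cd.simulate_oil_fill(capdrop10, fluid_with_angles(90, 90))
        assert report.outcome == "failed_no_wetting"
        assert report.extras["crosstalk_eliminated"] is False

    def test_lower_contact_angle_fills_faster(self, capdrop10):
        from test_capillary_physics import fluid_with_angles

        slow = cd.simulate_oil_fill(capdrop10, fluid_with_angles(60, 60, mu=25e-3))
        fast = cd.simulate_oil_fill(capdrop10, fluid_with_angles(20, 20, mu=25e-3))
        assert slow.success and fast.success
        assert slow.duration > fast.duration


class TestWorkflow:
    def test_capdrop_runs_all_three_phases(self, capdrop10, water, oil):
        reports = cd.run_workflow(capdrop10, water, oil)
        assert [r.phase for r in reports] == ["loading", "evacuation", "oil_fill"]
        assert all(r.success for r in reports)

    def test_capdrop_n_aborts_at_evacuation(self, capdropn10, water, oil):
        reports = cd.run_workflow(capdropn10, water, oil)
        assert [r.outcome for r in reports] == ["success", "failed_disconnect"]

    def test_single_well_chip_traps_corrected_volume(self, water, oil):
        lay = cd.build_layout("capdrop", 1)
        reports = cd.run_workflow(lay, water, oil)
        assert all(r.success for r in reports)
        well = lay.wells[0]
        expected = cd.nominal_well_volume(well) - cd.emptied_volume(well)
        assert reports[1].per_well_trapped_volume[0] == pytest.approx(expected)
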