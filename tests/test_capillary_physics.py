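"""Closed-form capillary primitives against hand values and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import capdrop as cd
from capdrop.capillary_physics import resistance_per_length
from capdrop.device_model import AngleSet, ChannelSegment, CrossSection, Material, Role
from capdrop.errors import ConfigurationError, NoSpontaneousFilling


def fluid_with_angles(film_adv, adh_adv, gamma=0.072, mu=1e-3, film_rec=None, adh_rec=None):
    return cd.FluidProperties(
        name="custom",
        viscosity=mu,
        surface_tension=gamma,
        density=1000.0,
        contact_angle={
            Material.hydrophilic_film: AngleSet(
                advancing=film_adv, receding=film_adv if film_rec is None else film_rec
            ),
            Material.adhesive: AngleSet(
                advancing=adh_adv, receding=adh_adv if adh_rec is None else adh_rec
            ),
        },
    )


def duct(width, height, top=Material.hydrophilic_film, bottom=Material.hydrophilic_film,
         role=Role.MF, length=0.01):
    return ChannelSegment(
        id="seg",
        length=length,
        cross_section=CrossSection(
            width=width,
            height=height,
            walls={"top": top, "bottom": bottom,
                   "left": Material.adhesive, "right": Material.adhesive},
        ),
        role=role,
    )


class TestCapillaryPressure:
    def test_neutral_wetting_gives_zero(self):
        f = fluid_with_angles(90, 90)
        p = cd.capillary_pressure(duct(1e-3, 0.3e-3).cross_section, f)
        assert p.value == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_mixed_walls(self):
        # gamma=0.072, theta top/bottom=0, sides=180, h=0.3mm, w=1mm:
        # 0.072 * (2/3e-4 - 2/1e-3) = 336 Pa
        f = fluid_with_angles(0, 180)
        p = cd.capillary_pressure(duct(1e-3, 0.3e-3).cross_section, f)
        assert p.value == pytest.approx(336.0, rel=1e-9)

    def test_inverse_scaling_with_size(self):
        f = fluid_with_angles(30, 110)
        p1 = cd.capillary_pressure(duct(1e-3, 0.3e-3).cross_section, f).value
        p2 = cd.capillary_pressure(duct(2e-3, 0.6e-3).cross_section, f).value
        assert p2 == pytest.approx(p1 / 2)

    @settings(derandomize=True, max_examples=50)
    @given(
        film=st.floats(0, 180),
        adh=st.floats(0, 180),
        w=st.floats(1e-4, 5e-3),
        h=st.floats(1e-4, 5e-3),
    )
    def test_antisymmetric_under_angle_reflection(self, film, adh, w, h):
        f = fluid_with_angles(film, adh)
        g = fluid_with_angles(180 - film, 180 - adh)
        cs = duct(w, h).cross_section
        assert cd.capillary_pressure(cs, f).value == pytest.approx(
            -cd.capillary_pressure(cs, g).value, abs=1e-6
        )

    def test_missing_material_raises(self):
        f = cd.FluidProperties(
            name="filmonly", viscosity=1e-3, surface_tension=0.07, density=1000,
            contact_angle={Material.hydrophilic_film: AngleSet(advancing=40, receding=20)},
        )
        with pytest.raises(ConfigurationError, match="adhesive"):
            cd.capillary_pressure(duct(1e-3, 3e-4).cross_section, f)


class TestBurstPressure:
    def test_neutral_valve_has_zero_threshold(self):
        f = fluid_with_angles(90, 90)
        sv = duct(2e-4, 1e-4, top=Material.adhesive, bottom=Material.adhesive, role=Role.SV)
        assert cd.burst_pressure(sv, f) == pytest.approx(0.0, abs=1e-12)

    def test_narrower_valve_bursts_harder(self):
        f = fluid_with_angles(40, 110)
        narrow = duct(120e-6, 1e-4, Material.adhesive, Material.adhesive, Role.SV)
        wide = duct(500e-6, 1e-4, Material.adhesive, Material.adhesive, Role.SV)
        assert cd.burst_pressure(narrow, f) > cd.burst_pressure(wide, f) > 0

    def test_strictly_decreasing_in_width_and_height(self):
        f = fluid_with_angles(40, 110)
        widths = np.linspace(120e-6, 500e-6, 8)
        bursts = [
            cd.burst_pressure(duct(w, 1e-4, Material.adhesive, Material.adhesive, Role.SV), f)
            for w in widths
        ]
        assert np.all(np.diff(bursts) < 0)
        heights = np.linspace(0.8e-4, 2e-4, 6)
        bursts_h = [
            cd.burst_pressure(duct(2e-4, h, Material.adhesive, Material.adhesive, Role.SV), f)
            for h in heights
        ]
        assert np.all(np.diff(bursts_h) < 0)

    def test_wetting_fluid_defeats_any_width(self, sweat):
        for w in (120e-6, 250e-6, 500e-6):
            sv = duct(w, 1e-4, Material.adhesive, Material.adhesive, Role.SV)
            assert cd.burst_pressure(sv, sweat) <= 0


def _fd_resistance(width, height, mu, length, n=80):
    """Independent oracle: finite-difference Poisson solve on the duct
    cross-section (-lap phi = 1, phi = 0 on walls), R = mu L / int(phi)."""
    nx = n
    ny = max(10, int(round(n * height / width)))
    dx, dy = width / (nx + 1), height / (ny + 1)
    N = nx * ny
    A = np.zeros((N, N))
    b = np.ones(N)
    def idx(i, j):
        return j * nx + i
    for j in range(ny):
        for i in range(nx):
            k = idx(i, j)
            A[k, k] = 2 / dx**2 + 2 / dy**2
            if i > 0:
                A[k, idx(i - 1, j)] = -1 / dx**2
            if i < nx - 1:
                A[k, idx(i + 1, j)] = -1 / dx**2
            if j > 0:
                A[k, idx(i, j - 1)] = -1 / dy**2
            if j < ny - 1:
                A[k, idx(i, j + 1)] = -1 / dy**2
    phi = np.linalg.solve(A, b)
    integral = phi.sum() * dx * dy
    return mu * length / integral


class TestHydraulicResistance:
    def test_linear_in_wetted_length(self, water):
        seg = duct(1e-3, 3e-4)
        r_half = cd.hydraulic_resistance(seg, water, seg.length / 2)
        r_full = cd.hydraulic_resistance(seg, water, seg.length)
        assert r_full == pytest.approx(2 * r_half)

    def test_zero_wetted_length_is_open_mouth(self, water):
        assert cd.hydraulic_resistance(duct(1e-3, 3e-4), water, 0.0) == 0.0

    def test_slab_limit_matches_parallel_plates(self, water):
        seg = duct(50e-3, 0.1e-3)  # w/h = 500
        r = cd.hydraulic_resistance(seg, water, seg.length)
        r_slab = 12 * water.viscosity * seg.length / (50e-3 * (0.1e-3) ** 3)
        assert r == pytest.approx(r_slab, rel=0.01)

    @pytest.mark.parametrize("w,h", [(3e-4, 3e-4), (6e-4, 3e-4), (1.5e-3, 3e-4)])
    def test_matches_finite_difference_poisson_oracle(self, water, w, h):
        seg = duct(w, h)
        r = cd.hydraulic_resistance(seg, water, seg.length)
        r_fd = _fd_resistance(w, h, water.viscosity, seg.length)
        assert r == pytest.approx(r_fd, rel=0.01)

    @settings(derandomize=True, max_examples=25)
    @given(w=st.floats(1e-4, 3e-3), h=st.floats(1e-4, 3e-3))
    def test_symmetric_in_width_height_exchange(self, water, w, h):
        a = cd.hydraulic_resistance(duct(w, h), water, 0.01)
        b = cd.hydraulic_resistance(duct(h, w), water, 0.01)
        assert a == pytest.approx(b, rel=1e-9)

    def test_out_of_range_wetted_length_raises(self, water):
        with pytest.raises(ValueError):
            cd.hydraulic_resistance(duct(1e-3, 3e-4, length=0.01), water, 0.02)


class TestFlowRate:
    def test_hagen_poiseuille_arithmetic(self):
        assert cd.flow_rate(0.0, 1e10) == 0.0
        assert cd.flow_rate(100.0, 1e12) == pytest.approx(1e-10)
        assert cd.flow_rate(100.0, 2e12) == pytest.approx(cd.flow_rate(100.0, 1e12) / 2)

    def test_nonpositive_resistance_rejected(self):
        with pytest.raises(ValueError):
            cd.flow_rate(10.0, 0.0)


class TestFillProfile:
    def test_starts_at_zero_and_reaches_the_end(self, water):
        seg = duct(1e-3, 3e-4, length=0.05)
        traj = cd.fill_profile(seg, water)
        assert traj.positions[0] == 0.0
        assert traj.times[0] == 0.0
        assert traj.positions[-1] == pytest.approx(seg.length)

    def test_matches_washburn_closed_form(self, water):
        seg = duct(1e-3, 3e-4, length=0.05)
        traj = cd.fill_profile(seg, water)
        r_u = resistance_per_length(seg, water)
        area = seg.cross_section.area
        x_closed = np.sqrt(2 * traj.driving_pressure * traj.times[1:] / (r_u * area))
        rel = np.abs(traj.positions[1:] - x_closed) / x_closed
        assert rel.max() < 0.005

    def test_flow_rate_strictly_decreases(self, water):
        traj = cd.fill_profile(duct(1e-3, 3e-4, length=0.05), water)
        q = traj.flow_rates[1:]  # index 0 is the open-mouth limit
        assert np.all(np.diff(q) < 0)

    def test_fill_time_linear_in_viscosity(self):
        times = []
        for mu in (1e-3, 10e-3, 100e-3):
            f = fluid_with_angles(40, 110, mu=mu)
            times.append(cd.fill_profile(duct(1e-3, 3e-4, length=0.05), f).fill_time)
        assert times[1] == pytest.approx(10 * times[0], rel=1e-6)
        assert times[2] == pytest.approx(100 * times[0], rel=1e-6)

    def test_non_wetting_fluid_refused(self):
        f = fluid_with_angles(120, 120)
        with pytest.raises(NoSpontaneousFilling, match="no spontaneous filling"):
            cd.fill_profile(duct(1e-3, 3e-4), f)
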