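"""Capillary pressures, valve burst thresholds and duct resistance.

Builds the default chip geometry and prints, for a few fluids, the
Young-Laplace pressures that drive (or stop) each element: the main
channel and well pull the sample forward, the pressure-reducer step pulls
much more weakly (protecting the valve), and the all-hydrophobic stop
valve opposes entry with a positive burst threshold - except for the
sweat-like fluid, which wets the adhesive and cannot be stopped at all.
"""

import capdrop as cd

layout = cd.build_layout("capdrop", n_wells=1)
well = layout.wells[0]
mf = layout.mf_segments[0]

print(f"{'fluid':12s} {'P_mf [Pa]':>10s} {'P_mw [Pa]':>10s} {'P_pr [Pa]':>10s} {'burst [Pa]':>10s}")
for name in ("water", "blood_like", "plasma_like", "saliva_like", "sweat_like"):
    fluid = cd.make_fluid(name)
    p_mf = cd.capillary_pressure(mf.cross_section, fluid, "advancing").value
    p_mw = cd.capillary_pressure(well.body.cross_section, fluid, "advancing").value
    p_pr = cd.capillary_pressure(well.pr.cross_section, fluid, "advancing").value
    burst = cd.burst_pressure(well.sv, fluid)
    print(f"{name:12s} {p_mf:10.1f} {p_mw:10.1f} {p_pr:10.1f} {burst:10.1f}")

r_full = cd.hydraulic_resistance(mf, cd.make_fluid("water"), mf.length)
print(f"\nmain-channel segment resistance (water, fully wetted): {r_full:.3g} Pa*s/m^3")
print("a positive burst threshold means the valve resists entry; sweat's")
print("negative threshold means no valve width can stop it")
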