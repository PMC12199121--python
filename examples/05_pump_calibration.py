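"""Characterising the wicking pad from an absorption experiment.

86 uL of water is driven through a straight reference channel into the
pad while the absorbed volume is recorded over time (here simulated, with
1% observation noise on the cumulative volumes).  Because the channel's
resistance is known and constant, the pressure the pad delivers is just
flow x resistance at every instant - recovering the pad's pressure-vs-fill
curve, which falls as the pad fills.
"""

import numpy as np

import capdrop as cd
from capdrop.synthetic_data import default_calibration_channel

water = cd.make_fluid("water")
channel = default_calibration_channel()
truth = cd.PumpCurve(capacity=1.5e-7, fill_knots=[0, 1], pressure_knots=[5000.0, 0.0])

trace = cd.make_absorption_trace(
    truth, channel, water, injected_volume=86e-9, noise_sd=0.01 * 86e-9, seed=42
)
print(f"trace: {len(trace.times)} samples over {trace.times[-1]:.2f} s, "
      f"{trace.cumulative_volume[-1]*1e9:.1f} uL absorbed")

curve = cd.calibrate_pump_curve(trace, channel, water, capacity=truth.capacity)
print(f"\n{'fill':>6s} {'P_recovered [Pa]':>17s} {'P_true [Pa]':>12s}")
for f in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
    p_rec = cd.pump_pressure(curve, f)
    p_true = np.interp(f, truth.fill_knots, truth.pressure_knots)
    print(f"{f:6.2f} {p_rec:17.0f} {p_true:12.0f}")

grid = np.linspace(0, 86e-9 / truth.capacity, 200)
p_rec = np.array([cd.pump_pressure(curve, x) for x in grid])
p_true = np.interp(grid, truth.fill_knots, truth.pressure_knots)
rms = np.sqrt(np.mean((p_rec - p_true) ** 2)) / p_true.max()
print(f"\nRMS recovery error: {100*rms:.1f}% of the fresh-pad pressure")
print("the falling delivered pressure, paired with the falling channel")
print("resistance as the chip drains, is what keeps the evacuation rate steady")
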