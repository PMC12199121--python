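# capdrop

Lumped-element simulation of **self-powered capillary droplet-array chips** —
lab-on-chip devices that digitize a biofluid sample into >100 stationary
nanolitre droplets using nothing but surface tension: no pumps, no actuators,
no electronics.

## Who this is for

Designers and modellers of passive capillary microfluidics who want to reason
about a chip *before* cutting it: will the stop valves hold this fluid, will
the vent close after the last well fills, will the wicking pad drain the
channel without emptying the wells, how uniform will the droplet array be.
The package is a library first (`import capdrop`), with narrative scripts in
`examples/` and a thin `capdrop` command-line wrapper.

## The model

A chip is an ordered main flow channel (MF) carrying microwells (MWs), each
ending in a pressure-reducer step (PR) and a hydrophobic stop valve (SV)
attached to a vent network, plus a bubble trap (BT) and a wicking-pad pump
(Wp). Everything is quasi-steady Stokes flow in rectangular ducts:

- **Meniscus pressure** (Young–Laplace, per-wall wettability):
  `P = γ [ (cos θ_t + cos θ_b)/h + (cos θ_l + cos θ_r)/w ]`,
  with advancing angles while loading and receding angles while draining.
- **Stop-valve burst threshold**: the same expression negated for the
  all-hydrophobic valve duct — positive means the valve resists entry;
  a fluid with θ ≤ 90° on the walls (sweat-like) can never be stopped.
- **Duct resistance**: the exact rectangular-duct Fourier-series solution,
  truncated at 1e-10 relative, linear in wetted length and viscosity.
- **Network solve**: the chip at any instant is an equivalent electrical
  circuit — pressure ↔ voltage, flow `Q` ↔ current, wetted sections ↔
  resistors `R_m`/`R_w`, menisci and the pad ↔ sources `V_wp`/`V_r`, air
  openings ↔ grounds, and the passive vent (PV) ↔ an automatic cut-off
  switch. Modified nodal analysis enforces conservation at every node;
  menisci advance explicitly between solves with event detection
  (segment boundaries, valve contact, vent closure).
- **Single-channel filling** reduces to Washburn dynamics,
  `x(t) = sqrt(2 P t / (r_u A))`.

Three phases compose the workflow: **loading** → **evacuation** →
**oil fill**, each returning a `PhaseReport` with per-well fill times,
drained/trapped volumes, valve-burst flags and a timestamped event log.
On top sit the design sweeps (MF width, MW width, SV width), the
wicking-pad calibration-from-absorption procedure, the bubble-trap fate
rule, and droplet-uniformity / Poisson-partition statistics.

All fluid property tables shipped with the package are flagged
`synthetic_default` — plausible values for water-, blood-, plasma-,
saliva-, sweat-like fluids, a 300 mPa·s hydrogel precursor and a
surfactant-doped mineral oil.

## Worked example

```python
import capdrop as cd

layout = cd.build_layout("capdrop", n_wells=10)   # canonical PV chip
reports = cd.run_workflow(layout, cd.make_fluid("water"), cd.make_fluid("oil_span20"))
```

Running `python examples/03_full_workflow.py` prints:

```
loading      -> success (t = 15.69 s)
evacuation   -> success (t = 2.76 s)
oil_fill     -> success (t = 454.84 s)

sample reaches the wicking pad at t = 1.95 s
passive vent closes at t = 15.69 s (after the last well fills at t = 1.97 s)
wells drained during evacuation: 0.0 nL (max over wells)
nominal well volume: 304.5 nL; trapped after the meniscus cap empties: 246.8 nL
crosstalk eliminated by the oil phase: True
```

Reading it: the sample wicks 20 cm to the pad in ~2 s; the slow delay
channel keeps the vent open until every well has filled and its valve has
held (so the vent closes *after* the last well — the design's whole point);
evacuation then drains the channel into the pad while the sealed wells lose
only the meniscus cap at their mouth (304.5 → 246.8 nL); the oil phase
isolates the droplets. Swap in `"capdrop_n"` (per-well vent holes instead
of the PV) and evacuation fails with `failed_disconnect` after air breaks
through the two wells nearest the pad — run
`python examples/04_vent_comparison.py` to see the drained-volume profile.

The other examples cover the capillary primitives (`01`), Washburn filling
(`02`), pad calibration from a noisy absorption trace (`05`), the three
design sweeps (`06`) and particle statistics (`07`).

## Command line

```sh
capdrop gen layout --variant capdrop --n-wells 10 --out chip.json
capdrop gen fluid --name water --out water.json
capdrop gen fluid --name oil_span20 --out oil.json
capdrop run --layout chip.json --fluid water.json --oil oil.json --seed 1 --out report/
capdrop sweep sv-width --out sv.csv
capdrop stats partition --concentration 3e11 --seed 7 --out counts.csv
```

`run` writes per-phase CSVs, a summary and a manifest; it exits 1 with the
failing phase and outcome when a workflow fails, 2 on bad inputs.

## Layout

```
src/capdrop/
  device_model.py       chip/fluid types, variant builders, JSON I/O
  capillary_physics.py  Young-Laplace, burst, duct resistance, Washburn
  eec_solver.py         hydraulic graph, MNA, three-phase simulation
  pump_and_trap.py      wicking-pad curves + calibration, bubble trap
  design_analysis.py    width sweeps, CV, particle partitioning
  synthetic_data.py     fluid library, fabrication jitter, pad traces
  cli.py                thin click CLI
docs/methods.md         model assumptions, parameters, limitations
examples/               one narrative script per capability
```
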