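# Methods

## Scope and model class

`capdrop` models passive droplet-array chips as lumped hydraulic networks
in the quasi-steady Stokes regime. Inertia, dynamic (velocity-dependent)
contact angles, bubble nucleation physics and full two-phase CFD are out of
scope; the claim of the lumped model is that the chip's *switching logic*
(which element fills, stops, closes or drains, and in what order) and its
first-order timing are set by capillary pressures, duct resistances and
network topology alone.

## Capillary primitives

**Meniscus pressure.** A meniscus spanning a rectangular duct of width `w`
and height `h` contributes
`P = γ [ (cos θ_top + cos θ_bottom)/h + (cos θ_left + cos θ_right)/w ]`,
each wall's contact angle taken per wall material (hydrophilic PET film or
hydrophobic adhesive) and per mode — advancing while liquid invades,
receding while it retreats. Positive `P` pulls liquid into the dry section.
Contact-angle hysteresis (receding ≤ advancing, a per-fluid table entry) is
what makes the same channel pull forward during loading yet resist draining
during evacuation.

**Stop-valve burst.** A valve holds until the pressure on its face exceeds
`P_burst = −P_advancing(valve duct)`. With all four valve walls hydrophobic
this is positive and grows as the valve narrows (the design knob); if any
wetting combination dominates, `P_burst ≤ 0` and the valve passes liquid
unconditionally — this is how the sv1/sv2 design iterations and the
sweat-like fluid fail.

**Duct resistance.** The exact series solution
`R = 12 μ L / (b a³ f)`, `f = 1 − (192 a / π⁵ b) Σ_{n odd} tanh(nπb/2a)/n⁵`
with `a = min(w,h)`, `b = max(w,h)`, truncated when a term changes the sum
by < 1e-10 relative. It is linear in wetted length and viscosity and
symmetric in `w ↔ h`; tests pin it against the parallel-plate limit and an
independent finite-difference Poisson solve of the duct cross-section.
(The popular `(1 − 0.63 h/w)⁻¹` closed form is a ~13% overestimate at
square aspect, so it is used only as the slab-limit sanity check, not as
the oracle.)

**Washburn filling.** A single dead-headed channel fills with
`dx/dt = P/(r_u x A)`; the implementation accumulates
`t(x) = ∫ A R(x)/P dx` by trapezoid over a fine position grid, using the
series resistance at each interface position, and matches
`x(t) = sqrt(2Pt/(r_u A))` to machine precision for uniform ducts.
Driving pressures below 1e-9 Pa are treated as non-wetting (a nominal 90°
angle lands at ~1e-13 Pa through floating-point cosines).

## The equivalent circuit and its solver

At any instant the wet part of the chip maps to a circuit: junction nodes,
resistive edges for wetted sections, a pressure source per advancing or
receding meniscus (the capillary end-cap of its own cross-section), the
pad as a fill-fraction-dependent source behind an internal resistance, and
grounds at every node with an air path. Modified nodal analysis solves the
conservation system for the non-ground nodes (dense `numpy` solve; the
graphs have tens of nodes); the solution's node imbalance is checked to
≤ 1e-12 of the largest branch flow at every step. Partially wetted
branches are collapsed into a single edge (full upstream resistance plus
the partial frontier section) — interior pressures of a series chain are
never needed.

**Time stepping and events.** Menisci advance explicitly between solves.
The step is the minimum over active menisci of (5% of the segment length) /
(meniscus speed), further clipped so the fastest meniscus lands exactly on
its segment boundary — events (well activation, valve contact, vent
closure, pad contact, well emptied) are therefore resolved at their exact
step-bounded time rather than located a posteriori. A new frontier segment
is seeded with 0.1% of its length wetted so its entry resistance is finite;
the volume error is cubic in that fraction and negligible.

**Valve-contact test.** When a well's last pre-valve segment completes, the
pressure on the valve face is taken as the (static, MNA) junction pressure
plus the advancing capillary pressure of the feeding cross-section, and
compared against `P_burst`. The pressure-reducer step protects the valve
*geometrically*: its adhesive roof and reduced height make its advancing
pressure ~82 Pa versus ~297 Pa for the well body (water defaults), so the
valve face sees a fraction of the pressure it would otherwise. No inertial
surge term is added. When two events coincide within a step, valve contacts
are processed before vent closure (the conservative order: the valve is
tested while still air-vented).

**Passive-vent logic.** Well branches are grounded through the shared vent
network while the PV switch is `open_to_air`; the delay channel is a
PV-path segment whose completed fill flips the switch to `cut_off`
(irreversibly within a run), removing every well's air path at once. Wells
not yet full at that moment freeze, and the phase reports
`failed_pv_timing`.

## Why the delay channel is slow and weak (a load-bearing design choice)

The delay channel is modelled as a shallower duct with an adhesive roof
(the geometry it has where it runs under the third adhesive layer), width
0.5 mm, height 0.2 mm, default length 4 cm. This matters twice. Its weak
advancing pressure (~54 Pa for water) makes it fill slowly — that slowness
*is* the delay. And while it fills, it is the only suction acting on the
main channel, so junction pressures relax from the −250..−300 Pa the
advancing channel front imposes to a few tens of Pa. The far wells'
pressure-reducer steps (~82 Pa of driving) can only complete against that
relaxed suction; with a strongly-pulling (main-channel-like) delay duct
the chip would deadlock: the vent would close at the very moment the
suction that stalled the far wells disappears. Under the defaults the last
well fills ~0.02 s after pad contact and the vent closes ~14 s later.

## Evacuation

Starts from the post-loading state: chain fully wet, wells full, PV cut
(PV variants). A receding meniscus retreats from the inlet toward the pad;
its receding end-cap (~476 Pa for water in the main channel) *opposes* the
pad. Per-well-vented (Norm-V) chips additionally drain each well through
its vent hole against a receding end-cap at the well cross-section; the
wells nearest the pad see the least series resistance, drain fastest, and
the run fails with `failed_disconnect` the moment the first well empties
(air then separates pad from sample). Sealed wells in PV chips are simply
absent from the circuit — a dead-end branch carries exactly zero flow in an
incompressible network, so the reported per-well drained volumes are
identically zero rather than zero to tolerance.

After a successful evacuation each well keeps its nominal volume minus an
emptied meniscus cap at the mouth: depth `w/2` (the meniscus radius is set
by the well width), volume `(π/8) w² h`. The constant is a documented
modelling choice; only its `w²` scaling — which drives the well-width
uniformity sweep — is asserted.

**Pad model.** The wicking pad is a delivered-pressure curve `P(fill)`,
monotone non-increasing, behind an internal resistance schedule. Defaults
(flagged synthetic): 5 kPa fresh-pad pressure decaying linearly to zero,
150 µL capacity, 1e11 Pa·s/m³ internal resistance — plausible for a
cellulose pad and sized so the pad comfortably swallows the ~63 µL channel
content. Because `P(fill)` falls while the draining channel's resistance
falls too, the evacuation rate stays nearly constant; the test suite
asserts the flow-rate CV is smaller than with a constant-pressure pad on
the same chip. A calibrated curve carries no internal resistance of its own
(the calibration measures pressure *delivered to the channel*), so the
simulator floors the pump edge resistance at 1e9 Pa·s/m³.

**Calibration from absorption.** The characterisation experiment injects
86 µL through a straight, fully wetted reference channel into the pad and
films the absorbed volume; with constant channel resistance and a zero
inlet pressure (gravity neglected), `ΔP(t) = Q(t) · R_channel` is the
delivered pressure. `Q` is recovered from the noisy cumulative record by a
cubic smoothing spline differentiated analytically — the smoothing level is
set from the noise scale estimated by robust (MAD) second differences,
inflated 4× because derivative estimation wants a wider bandwidth than
function estimation — then forced monotone by isotonic regression over fill
fraction. An explicit `window` argument switches to a plain Savitzky–Golay
derivative instead. Recovery accuracy on simulated traces: ~0.2% RMS
noiseless, ≤5% RMS per realization at 1% cumulative-volume noise.

**Bubble trap.** Lumped fate rule, not transport: a bubble larger than the
trap's capacity saturates it; otherwise it is trapped iff the viscous drag
scale in the widened section, `k μ (Q/A_trap)/h` with `k = 3`, stays below
the trap's retention pressure. Only orderings (widened vs not, more vs
less flow) are asserted, never absolute forces.

## Design sweeps and statistics

- **MF width**: each width is run through the full loading simulation.
  Loading time is monotone decreasing in width under this model (both the
  per-length resistance and the inverse of the capillary pressure fall as
  the channel widens), diverging at the non-wetting critical width; the
  design optimum is the *tradeoff* between loading time and the sample
  volume parked in the channel, exposed as a `time × volume` score with an
  interior minimum (~0.5 mm for the water defaults).
- **MW width**: emptied-cap statistics from the `(π/8) w² h` model under
  truncated-normal fabrication jitter (default 1% per dimension, ±3 SD by
  rejection); widths above 1 mm are flagged for corner-flow bubbles.
- **SV width**: burst pressure per fluid; widths below the 120 µm
  laser-cutting floor are rejected.
- **Volume CV**: `100 · SD/mean` with the n−1 denominator.
- **Particle partitioning**: `count_i ~ Poisson(conc · V_i · e^{−k(i−1)})`
  — the simplest monotone sedimentation model; `k` defaults to 0 and the
  sweeps that need a visible depletion use `k = 0.03`/well.

## Synthetic data: what it does and does not emulate

The generators produce fluid tables, jittered layouts and pad-absorption
traces with the *structure* the pipeline assumes: Newtonian fluids with a
single advancing/receding angle pair per material, independent dimensional
jitter, uniform-time video-like sampling with additive noise on cumulative
volumes (then re-monotonised). They do not emulate shear-thinning rheology,
spatially correlated cutting errors, protein fouling, or any optical
artifacts of real video. Passing tests therefore demonstrate the solver
and estimators are correct *under the stated model*, not that a physical
chip will hit these numbers; the experimental CVs a fabricated chip
achieves depend on tolerances the jitter knobs only parameterise.

## Numerical choices, degenerate inputs, limitations

- SI units internally; config files accept `"0.7 mm"` / `"300 nL"` /
  `"5 kPa"` strings.
- The three adhesive layers are equal thirds of the 0.3 mm stack; the
  4-layer hydrophobic-top variant removes the top third (wells 0.2 mm
  deep, volume −1/3) and needs no pressure reducer.
- Zero wetted length ⇒ resistance 0 (open mouth); segment seeding keeps
  MNA edges positive.
- Simulation guards: a step budget (500k) raises rather than spinning;
  stalled phases (no meniscus with positive flow) report
  `failed_no_wetting`.
- Problem sizes: the canonical simulated chip is the 10-well, 20 cm
  variant (sub-second to a few seconds per phase); the 101-well layout is
  built and validated in full and simulated at reduced well counts in the
  sweeps, with solver cost dominated by the per-step dense solve.
- Evaporation is identically zero in all sealed phases (the enclosed
  design's premise) and is not modelled.
- Concurrent well filling is allowed; no fill-order assertion is made
  beyond what the pressures imply.
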