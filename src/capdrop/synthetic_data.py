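"""Synthetic inputs: fluid property sets, fabrication jitter, pad traces.

Quantitative wetting/rheology tables for the real biofluids are not shipped
with the model, so every fluid here is an explicitly flagged synthetic
default with magnitudes a microfluidicist would call plausible: water-like
through blood-like viscosities, a 300 mPa*s hydrogel-precursor entry at the
platform's demonstrated upper end, a surfactant-doped mineral oil that wets
the adhesive walls, and a sweat-like fluid whose contact angle on adhesive
is below 90 degrees - the property that makes hydrophobic stop valves
unable to hold it, whatever their width.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field

from .device_model import AngleSet, ChannelSegment, ChipLayout, FluidProperties, Material
from .errors import ConfigurationError
from .pump_and_trap import AbsorptionTrace, PumpCurve

SYNTHETIC = "synthetic_default"

#: per-fluid defaults: viscosity Pa*s, surface tension N/m, density kg/m^3,
#: contact angles (advancing, receding) on the PET film and on the adhesive
_FLUID_TABLE: dict[str, tuple[float, float, float, tuple[float, float], tuple[float, float]]] = {
    "water": (1.0e-3, 0.072, 1000.0, (40.0, 20.0), (110.0, 80.0)),
    "blood_like": (4.0e-3, 0.058, 1060.0, (55.0, 35.0), (105.0, 85.0)),
    "plasma_like": (1.8e-3, 0.060, 1025.0, (50.0, 30.0), (108.0, 82.0)),
    "saliva_like": (1.5e-3, 0.053, 1005.0, (45.0, 25.0), (102.0, 80.0)),
    # sweat wets the adhesive (theta <= 90): hydrophobic valves cannot stop it
    "sweat_like": (1.0e-3, 0.045, 1000.0, (30.0, 15.0), (85.0, 60.0)),
    # mineral oil + Span 20 at the critical micelle concentration: low angle
    # on the adhesive so the oil phase self-drives through the main channel
    "oil_span20": (25e-3, 0.028, 850.0, (35.0, 20.0), (30.0, 15.0)),
    # 5 wt% gelatin-methacryloyl-like precursor: the viscous end of the range
    "gelma_like": (0.300, 0.055, 1020.0, (50.0, 28.0), (100.0, 78.0)),
}

FLUID_NAMES = tuple(_FLUID_TABLE)


def make_fluid(name: str) -> FluidProperties:
    """Return one of the shipped synthetic fluid property sets."""
    if name not in _FLUID_TABLE:
        raise ConfigurationError(
            f"unknown fluid {name!r}; options: {', '.join(FLUID_NAMES)}"
        )
    mu, gamma, rho, film, adhesive = _FLUID_TABLE[name]
    return FluidProperties(
        name=name,
        viscosity=mu,
        surface_tension=gamma,
        density=rho,
        contact_angle={
            Material.hydrophilic_film: AngleSet(advancing=film[0], receding=film[1]),
            Material.adhesive: AngleSet(advancing=adhesive[0], receding=adhesive[1]),
        },
        provenance=SYNTHETIC,
    )


class JitterModel(BaseModel):
    """Fabrication jitter: independent relative errors on w, l, h.

    Draws are normal with the given relative SDs, truncated at +-3 SD by
    rejection (laser-cut tolerances have no extreme outliers and dimensions
    must stay positive).
    """

    rel_sd_width: float = Field(default=0.01, ge=0)
    rel_sd_length: float = Field(default=0.01, ge=0)
    rel_sd_height: float = Field(default=0.01, ge=0)
    seed: int = 0

    def _check_feasible(self) -> None:
        worst = max(self.rel_sd_width, self.rel_sd_length, self.rel_sd_height)
        if 3 * worst >= 1.0:
            raise ConfigurationError(
                f"jitter SD {worst} is so large that truncation would reject most "
                f"draws / allow non-physical dimensions; use rel SD < 1/3"
            )

    def draw_factors(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """(n, 3) multiplicative factors for (width, length, height)."""
        self._check_feasible()
        sds = np.array([self.rel_sd_width, self.rel_sd_length, self.rel_sd_height])
        out = np.empty((n, 3))
        for j, s in enumerate(sds):
            if s == 0:
                out[:, j] = 1.0
                continue
            z = rng.standard_normal(n)
            bad = np.abs(z) > 3.0
            while bad.any():  # rejection keeps the distribution truncated-normal
                z[bad] = rng.standard_normal(int(bad.sum()))
                bad = np.abs(z) > 3.0
            out[:, j] = 1.0 + s * z
        return out


def jitter_layout(layout: ChipLayout, model: JitterModel) -> ChipLayout:
    """Perturb every well body's dimensions per the jitter model.

    Deterministic under the model's seed; mean dimensions are unbiased.
    Only well bodies are perturbed (they set the trapped volumes); channel
    segments keep their nominal geometry.
    """
    rng = np.random.default_rng(model.seed)
    factors = model.draw_factors(rng, len(layout.wells))
    new = layout.model_copy(deep=True)
    for well, (fw, fl, fh) in zip(new.wells, factors):
        cs = well.body.cross_section
        well.body = ChannelSegment(
            id=well.body.id,
            length=well.body.length * fl,
            cross_section=cs.model_copy(
                update={"width": cs.width * fw, "height": cs.height * fh}
            ),
            role=well.body.role,
        )
    return new


def make_absorption_trace(
    pump_truth: PumpCurve,
    channel: ChannelSegment,
    fluid: FluidProperties,
    injected_volume: float = 86e-9,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_samples: int = 40,
    substeps: int = 200,
) -> AbsorptionTrace:
    """Emulate the pad-characterisation experiment.

    A known volume (default 86 uL of water) is driven through a fully wetted
    straight channel into the pad; the pad's delivered pressure sets the
    flow, ``Q = P(fill) / (R_channel + R_internal(fill))``, which is
    integrated forward until the volume is absorbed.  Observation noise (SD
    in m^3) is added to the *cumulative* volumes - that is what video image
    processing measures - and the series is re-monotonised.
    """
    from .capillary_physics import hydraulic_resistance  # local: avoids cycle

    if injected_volume > pump_truth.capacity:
        raise ConfigurationError(
            f"injected volume {injected_volume} exceeds pad capacity "
            f"{pump_truth.capacity}"
        )
    r_mf = hydraulic_resistance(channel, fluid, channel.length)
    # fine fixed-volume integration gives t(V) exactly on a smooth grid ...
    n_grid = n_samples * substeps
    vol = 0.0
    t = 0.0
    ts = [0.0]
    vs = [0.0]
    dv = injected_volume / n_grid
    for _ in range(n_grid):
        f = min(vol / pump_truth.capacity, 1.0)
        p = pump_truth.pressure(f)
        r = r_mf + pump_truth.internal_resistance(f)
        q = p / r
        if q <= 0:
            break
        t += dv / q
        vol += dv
        ts.append(t)
        vs.append(vol)
    # ... then resample at uniform time, the way video frames sample it
    times = np.linspace(0.0, ts[-1], n_samples + 1)
    volumes = np.interp(times, ts, vs)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = volumes + rng.normal(0.0, noise_sd, volumes.shape)
        noisy[0] = 0.0
        volumes = np.maximum.accumulate(np.clip(noisy, 0.0, None))
    return AbsorptionTrace(times=times.tolist(), cumulative_volume=volumes.tolist())


def default_calibration_channel() -> ChannelSegment:
    """The straight reference channel used in the pad characterisation."""
    from .device_model import CrossSection, Role

    return ChannelSegment(
        id="calibration_channel",
        length=0.05,
        cross_section=CrossSection(
            width=1.0e-3,
            height=0.3e-3,
            walls={
                "top": Material.hydrophilic_film,
                "bottom": Material.hydrophilic_film,
                "left": Material.adhesive,
                "right": Material.adhesive,
            },
        ),
        role=Role.MF,
    )
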