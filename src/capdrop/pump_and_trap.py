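"""Wicking-pad pump model and bubble-trap fate rule.

The wicking pad is the chip's only power source during main-channel
evacuation.  It is characterised as a *delivered-pressure curve*: the
pressure the pad applies to the channel network as a function of its fill
fraction, plus an optional internal (entry) resistance schedule.  The curve
can be calibrated from the same experiment the pad is characterised with in
practice: inject a known water volume through a straight channel of known
resistance into the pad, film the absorbed volume over time, and recover
``dP(t) = Q(t) * R_channel`` (inlet at atmospheric pressure, gravity
neglected).

The bubble trap is a widened region before the pad: widening drops the local
velocity and hence the viscous drag on a bubble, so a bubble parks there
instead of reaching the pad - up to a finite volume capacity.
"""

from __future__ import annotations

import warnings
from enum import Enum
from typing import TYPE_CHECKING, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.signal import savgol_filter

from .errors import ConfigurationError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .device_model import ChannelSegment, FluidProperties

#: dimensionless drag prefactor in the bubble-fate pressure scale.  Only the
#: ordering (trapped vs escaped) is ever asserted, never absolute forces.
DRAG_CONSTANT = 3.0


class PumpCurve(BaseModel):
    """Delivered pressure (and internal resistance) of a wicking pad.

    ``fill_knots`` are fill fractions in [0, 1]; ``pressure_knots`` (Pa) must
    be monotone non-increasing (a filling pad transfers less pressure);
    ``resistance_knots`` (Pa*s/m^3) are the pad's internal series resistance
    at the same fractions.  Between knots both are linearly interpolated and
    clamped at the endpoints.
    """

    capacity: float = Field(gt=0, description="absorbable volume, m^3")
    fill_knots: list[float]
    pressure_knots: list[float]
    resistance_knots: Optional[list[float]] = None
    power_knots: Optional[list[float]] = None  # delivered power W, reporting only

    @model_validator(mode="after")
    def _check(self) -> "PumpCurve":
        f = np.asarray(self.fill_knots, dtype=float)
        p = np.asarray(self.pressure_knots, dtype=float)
        if f.size < 2 or f.size != p.size:
            raise ValueError("fill_knots and pressure_knots need >= 2 matching entries")
        if f.min() < 0 or f.max() > 1 or np.any(np.diff(f) <= 0):
            raise ValueError("fill_knots must be strictly increasing within [0, 1]")
        if np.any(np.diff(p) > 1e-9 * max(1.0, abs(p[0]))):
            raise ValueError("pressure_knots must be monotone non-increasing")
        if np.any(p < 0):
            raise ValueError("pressure_knots must be >= 0")
        if self.resistance_knots is not None and len(self.resistance_knots) != f.size:
            raise ValueError("resistance_knots must match fill_knots in length")
        return self

    def pressure(self, fill_fraction: float) -> float:
        return pump_pressure(self, fill_fraction)

    def internal_resistance(self, fill_fraction: float) -> float:
        if not 0.0 <= fill_fraction <= 1.0:
            raise ValueError(f"fill_fraction must lie in [0, 1], got {fill_fraction}")
        if self.resistance_knots is None:
            return 0.0
        return float(
            np.interp(fill_fraction, self.fill_knots, self.resistance_knots)
        )


def default_pump_curve(
    p0: float = 5000.0,
    capacity: float = 1.5e-7,
    internal_resistance: float = 1.0e11,
) -> PumpCurve:
    """Synthetic default pad: linear pressure decay from ``p0`` to 0 over fill.

    A placeholder for an uncalibrated pad (flagged synthetic; the shipped
    magnitudes are plausible for a cellulose pad, not measured values).
    """
    return PumpCurve(
        capacity=capacity,
        fill_knots=[0.0, 1.0],
        pressure_knots=[p0, 0.0],
        resistance_knots=[internal_resistance, internal_resistance],
    )


def constant_pump_curve(
    p0: float = 5000.0,
    capacity: float = 1.5e-7,
    internal_resistance: float = 1.0e11,
) -> PumpCurve:
    """Reference pad whose delivered pressure does not fall as it fills."""
    return PumpCurve(
        capacity=capacity,
        fill_knots=[0.0, 1.0],
        pressure_knots=[p0, p0],
        resistance_knots=[internal_resistance, internal_resistance],
    )


def pump_pressure(curve: PumpCurve, fill_fraction: float) -> float:
    """Delivered pad pressure at a fill fraction; interpolated and clamped."""
    if not 0.0 <= fill_fraction <= 1.0:
        raise ValueError(f"fill_fraction must lie in [0, 1], got {fill_fraction}")
    return float(np.interp(fill_fraction, curve.fill_knots, curve.pressure_knots))


class AbsorptionTrace(BaseModel):
    """Cumulative absorbed volume over time, as measured from video."""

    times: list[float]  # s, strictly increasing
    cumulative_volume: list[float]  # m^3, non-decreasing, starts at 0

    @model_validator(mode="after")
    def _check(self) -> "AbsorptionTrace":
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.cumulative_volume, dtype=float)
        if t.size < 3:
            raise ValueError("trace needs at least 3 samples")
        if t.size != v.size:
            raise ValueError("times and cumulative_volume must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if abs(v[0]) > 0:
            raise ValueError("cumulative_volume must start at 0")
        if np.any(np.diff(v) < 0):
            raise ValueError("cumulative_volume must be non-decreasing")
        return self


def _smooth_rate(t: np.ndarray, v: np.ndarray, window: int | None) -> np.ndarray:
    """Absorption rate dV/dt from a noisy cumulative-volume record.

    Default: cubic smoothing spline whose smoothing level is set from the
    noise scale estimated via second differences (robust MAD), then
    differentiated analytically - accurate at the record's edges, where
    fixed-window finite differences are biased.  Passing ``window`` forces a
    plain Savitzky-Golay (local-linear) derivative with that window instead.
    """
    from scipy.interpolate import UnivariateSpline

    n = t.size
    if window is not None:
        window = max(5, window | 1)
        window = min(window, n if n % 2 else n - 1)
        dt = float(np.median(np.diff(t)))
        if window < 5:
            return np.gradient(v, t)
        return savgol_filter(v, window_length=window, polyorder=1, deriv=1, delta=dt)
    d2 = np.diff(v, 2)
    sigma = np.median(np.abs(d2)) / (0.6745 * np.sqrt(6.0)) if d2.size else 0.0
    # the factor 4 over the n*sigma^2 residual target oversmooths slightly,
    # which derivative estimation wants (its optimal bandwidth is wider than
    # the function's)
    with warnings.catch_warnings():
        # near-noiseless records push s below what the fit can attain; the
        # returned interpolating approximation is exactly what we want then
        warnings.simplefilter("ignore", UserWarning)
        spline = UnivariateSpline(t, v, k=3, s=4.0 * n * sigma**2)
    return spline.derivative()(t)


def calibrate_pump_curve(
    trace: AbsorptionTrace,
    channel: "ChannelSegment",
    fluid: "FluidProperties",
    capacity: float | None = None,
    window: int | None = None,
) -> PumpCurve:
    """Recover the pad's delivered-pressure curve from an absorption trace.

    The calibration channel is fully wetted throughout, so its resistance
    ``R_mf`` is constant; with the inlet at zero pressure and gravity
    neglected, the whole pressure drop across the channel is the pad's:
    ``dP(t) = Q(t) * R_mf``.  The fill fraction is the absorbed volume over
    the pad capacity (defaulting to the final absorbed volume, i.e. the pad
    is taken as saturated at the end of the record).  The delivered power
    ``P_w = dP * Q`` is stored on the returned curve for reporting.
    """
    from .capillary_physics import hydraulic_resistance  # local import: avoids cycle

    t = np.asarray(trace.times, dtype=float)
    v = np.asarray(trace.cumulative_volume, dtype=float)
    r_mf = hydraulic_resistance(channel, fluid, channel.length)
    q = np.clip(_smooth_rate(t, v, window), 0.0, None)
    dp = q * r_mf
    cap = float(v[-1]) if capacity is None else float(capacity)
    if cap <= 0:
        raise ConfigurationError("pad capacity must be positive")
    fill = np.clip(v / cap, 0.0, 1.0)
    # enforce the physical monotonicity: delivered pressure cannot rise as
    # the pad fills -> isotonic (decreasing) regression over fill
    from sklearn.isotonic import IsotonicRegression

    dp_mono = IsotonicRegression(increasing=False).fit_transform(fill, dp)
    # deduplicate fill knots (flat stretches after clipping)
    knots_f, idx = np.unique(fill, return_index=True)
    knots_p = dp_mono[idx]
    if knots_f.size < 2:
        raise ConfigurationError("trace spans too small a fill range to calibrate")
    power = knots_p * (knots_p / r_mf)
    return PumpCurve(
        capacity=cap,
        fill_knots=knots_f.tolist(),
        pressure_knots=knots_p.tolist(),
        resistance_knots=None,
        power_knots=power.tolist(),
    )


class BubbleFate(str, Enum):
    trapped = "trapped"
    escaped = "escaped"
    saturated = "saturated"


class BubbleTrap(BaseModel):
    """Widened-channel bubble trap parameters (lumped; shape not resolved)."""

    throat_width: float = Field(gt=0, description="upstream channel width, m")
    trap_width: float = Field(gt=0, description="widened trap width, m")
    height: float = Field(gt=0, description="channel height, m")
    capacity: float = Field(gt=0, description="bubble volume the trap can hold, m^3")
    retention_pressure: float = Field(
        gt=0, description="pinning pressure scale holding a bubble in place, Pa"
    )

    @model_validator(mode="after")
    def _check(self) -> "BubbleTrap":
        # equality is allowed as the degenerate "no trap" reference used when
        # quantifying how much the widening helps; narrower than the throat
        # is never physical
        if self.trap_width < self.throat_width:
            raise ValueError("trap_width must be >= throat_width")
        return self


def bubble_fate(
    trap: BubbleTrap,
    bubble_volume: float,
    upstream_flow: float,
    fluid: "FluidProperties",
) -> BubbleFate:
    """Fate of a bubble carried into the trap at a given upstream flow.

    ``saturated`` if the bubble exceeds the trap's holding capacity.
    Otherwise the viscous drag pressure scale in the *widened* section,
    ``k * mu * (Q / A_trap) / h``, is compared with the retention pressure:
    below it the bubble is ``trapped`` (velocity driven to zero), above it
    drag sweeps the bubble through (``escaped``).  Widening the trap lowers
    the drag scale at fixed flow - the design's whole point.
    """
    if bubble_volume <= 0 or upstream_flow < 0:
        raise ValueError("bubble_volume must be > 0 and upstream_flow >= 0")
    if bubble_volume > trap.capacity:
        return BubbleFate.saturated
    a_trap = trap.trap_width * trap.height
    drag = DRAG_CONSTANT * fluid.viscosity * (upstream_flow / a_trap) / trap.height
    return BubbleFate.trapped if drag < trap.retention_pressure else BubbleFate.escaped
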