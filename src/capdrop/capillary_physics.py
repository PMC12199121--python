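"""Closed-form capillary physics for rectangular microchannels.

Everything the network solver needs reduces to four primitives:

* the Young-Laplace pressure of a meniscus spanning a rectangular duct with
  per-wall wettability,
* the burst threshold of a hydrophobic stop valve (the same expression with
  the sign flipped),
* the exact series solution for the viscous resistance of a rectangular duct,
* quasi-steady (Washburn) filling of a single channel, where the resistance
  grows with the wetted length while the meniscus pressure stays constant.

Sign convention: a positive pressure drives liquid *forward* into the dry
section; a stop valve therefore reports a positive burst threshold when all
of its walls are hydrophobic.  All quantities are SI.

The functions are duck-typed on the ``CrossSection`` / ``ChannelSegment`` /
``FluidProperties`` models from :mod:`capdrop.device_model` so that this
module stays free of package imports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Literal

import numpy as np

from .errors import ConfigurationError, NoSpontaneousFilling

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .device_model import ChannelSegment, CrossSection, FluidProperties

Mode = Literal["advancing", "receding"]

#: relative tolerance at which the duct series is truncated
SERIES_RTOL = 1e-10

#: driving pressures at or below this (Pa) count as non-wetting; a nominal
#: 90-degree contact angle lands at ~1e-13 Pa through floating-point cosines
PRESSURE_EPS = 1e-9


@dataclass(frozen=True)
class PressureResult:
    """A signed capillary pressure (Pa); positive pulls liquid forward."""

    value: float
    mode: Mode


def capillary_pressure(
    cs: "CrossSection", fluid: "FluidProperties", mode: Mode = "advancing"
) -> PressureResult:
    """Young-Laplace pressure of a meniscus in a rectangular duct.

    ``P = gamma * [(cos th_top + cos th_bottom)/h + (cos th_left + cos th_right)/w]``
    with each wall's contact angle looked up per wall material at the given
    mode (advancing angles during forward filling, receding during drainage).
    """
    if mode not in ("advancing", "receding"):
        raise ValueError(f"mode must be 'advancing' or 'receding', got {mode!r}")
    try:
        cos_t = math.cos(math.radians(fluid.angle(cs.walls["top"], mode)))
        cos_b = math.cos(math.radians(fluid.angle(cs.walls["bottom"], mode)))
        cos_l = math.cos(math.radians(fluid.angle(cs.walls["left"], mode)))
        cos_r = math.cos(math.radians(fluid.angle(cs.walls["right"], mode)))
    except KeyError as exc:
        raise ConfigurationError(
            f"fluid {fluid.name!r} has no contact angle for material {exc}"
        ) from exc
    value = fluid.surface_tension * (
        (cos_t + cos_b) / cs.height + (cos_l + cos_r) / cs.width
    )
    return PressureResult(value=value, mode=mode)


def burst_pressure(sv: "ChannelSegment", fluid: "FluidProperties") -> float:
    """Burst threshold of a stop valve, Pa.

    The external pressure that must be applied at the valve face to push the
    meniscus through: minus the (advancing) capillary pressure of the valve
    duct.  Positive when every wall is hydrophobic; non-positive means the
    valve cannot stop this fluid at all (the meniscus advances on its own).
    """
    if getattr(sv.role, "value", sv.role) != "SV":
        raise ValueError(f"burst_pressure expects a segment with role SV, got {sv.role}")
    return -capillary_pressure(sv.cross_section, fluid, "advancing").value


def _duct_correction(width: float, height: float) -> float:
    """Bracketed series factor of the exact rectangular-duct solution.

    With ``a = min(w, h)`` and ``b = max(w, h)``:

    ``f = 1 - (192 a / pi^5 b) * sum_{n odd} tanh(n pi b / 2 a) / n^5``

    so that ``R = 12 mu L / (b a^3 f)``.  The sum is truncated once the next
    term changes it by less than ``SERIES_RTOL`` relative.
    """
    a, b = min(width, height), max(width, height)
    total = 0.0
    n = 1
    while True:
        term = math.tanh(n * math.pi * b / (2.0 * a)) / n**5
        total += term
        if term < SERIES_RTOL * total:
            break
        n += 2
        if n > 20001:  # pragma: no cover - defensive; converges in a few terms
            break
    return 1.0 - (192.0 * a / (math.pi**5 * b)) * total


def hydraulic_resistance(
    seg: "ChannelSegment", fluid: "FluidProperties", wetted_length: float | None = None
) -> float:
    """Viscous resistance (Pa*s/m^3) of the wetted part of a rectangular duct.

    Exact single-phase series solution; linear in both the wetted length and
    the viscosity, and symmetric under exchange of width and height.  A zero
    wetted length returns the defined limit 0 (open meniscus at the mouth).
    """
    L = seg.length if wetted_length is None else wetted_length
    if L < 0 or L > seg.length * (1 + 1e-12):
        raise ValueError(
            f"wetted_length {L} outside [0, {seg.length}] for segment {seg.id!r}"
        )
    if L == 0:
        return 0.0
    w, h = seg.cross_section.width, seg.cross_section.height
    a, b = min(w, h), max(w, h)
    return 12.0 * fluid.viscosity * L / (b * a**3 * _duct_correction(w, h))


def resistance_per_length(seg: "ChannelSegment", fluid: "FluidProperties") -> float:
    """Resistance per unit wetted length (Pa*s/m^4)."""
    return hydraulic_resistance(seg, fluid, seg.length) / seg.length


def flow_rate(delta_p: float, resistance: float) -> float:
    """Hagen-Poiseuille: volumetric flow Q = dP / R (m^3/s)."""
    if resistance <= 0:
        raise ValueError(f"resistance must be positive, got {resistance}")
    return delta_p / resistance


@dataclass(frozen=True)
class FillTrajectory:
    """Interface position over time for a spontaneously filling channel."""

    times: np.ndarray  # s, strictly increasing, times[0] = 0
    positions: np.ndarray  # m, positions[0] = 0, ends at channel length
    flow_rates: np.ndarray  # m^3/s at each sample
    driving_pressure: float  # Pa

    @property
    def fill_time(self) -> float:
        return float(self.times[-1])


def fill_profile(
    seg: "ChannelSegment", fluid: "FluidProperties", n_steps: int = 2000
) -> FillTrajectory:
    """Quasi-steady filling of a single dead-headed channel from its mouth.

    The channel is divided into small slices of nearly constant resistance;
    for each interface position the flow follows Hagen-Poiseuille under the
    constant advancing meniscus pressure, and the time to cross each slice is
    accumulated (trapezoidal quadrature of ``dt = A R(x)/P dx``).  For a
    uniform channel this reproduces the Washburn closed form
    ``x(t) = sqrt(2 P t / (r_u A))``.
    """
    P = capillary_pressure(seg.cross_section, fluid, "advancing").value
    if P <= PRESSURE_EPS:
        raise NoSpontaneousFilling(
            f"no spontaneous filling: advancing capillary pressure {P:.3g} Pa <= 0 "
            f"for segment {seg.id!r} with fluid {fluid.name!r}"
        )
    area = seg.cross_section.area
    x = np.linspace(0.0, seg.length, n_steps + 1)
    # resistance of the wetted column at each interface position
    r = np.array([hydraulic_resistance(seg, fluid, xi) for xi in x])
    integrand = area * r / P  # dt/dx
    t = np.concatenate(([0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(x))))
    with np.errstate(divide="ignore"):
        q = np.where(r > 0, P / np.where(r > 0, r, 1.0), np.inf)
    return FillTrajectory(times=t, positions=x, flow_rates=q, driving_pressure=P)
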