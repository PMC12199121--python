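"""Design sweeps and digitization statistics on top of the solver.

These mirror the optimisation studies a chip designer runs before cutting a
device: how the main-channel width trades loading time against dead volume,
how well width drives the variability of the emptied meniscus cap (and the
corner-flow bubble risk above 1 mm), how stop-valve width sets the burst
margin per biofluid, and how uniformly particles partition into >100 wells
under Poisson loading with sedimentation along the channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .capillary_physics import burst_pressure, capillary_pressure
from .device_model import (
    ChannelSegment,
    CrossSection,
    FluidProperties,
    Geometry,
    Material,
    Role,
    Variant,
    build_layout,
    MIN_SV_WIDTH,
)
from .eec_solver import emptied_volume, simulate_loading
from .errors import LayoutError
from .synthetic_data import JitterModel, jitter_layout

#: well widths above this develop corner-flow bubbles at the well's end
BUBBLE_WIDTH_LIMIT = 1.0e-3


@dataclass
class SweepTable:
    """One parameter sweep: rows sorted by the swept value, plus metadata."""

    parameter: str
    unit: str
    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class ParticleLoad:
    """Per-well particle counts and the model that generated them."""

    counts: np.ndarray  # non-negative ints, one per well
    concentration: float  # particles / m^3
    sedimentation_k: float  # decay per well index
    seed: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("particle counts must be non-negative")


def mf_width_sweep(
    fluid: FluidProperties,
    widths: list[float],
    n_wells: int = 3,
    geometry: Geometry | dict | None = None,
    variant: Variant | str = Variant.capdrop,
) -> SweepTable:
    """Loading time and retained main-channel volume versus MF width.

    Each width is simulated through the full loading phase.  Narrowing the
    channel raises its viscous resistance *and* (with hydrophobic side
    walls) lowers the net capillary pressure, so loading time grows without
    bound toward the non-wetting critical width, while the sample volume
    parked in the main channel grows linearly with width: the ``tradeoff``
    column (time x volume) exposes the interior optimum between the two.
    Non-wetting widths are flagged, not raised.
    """
    base = geometry if isinstance(geometry, dict) else (
        geometry.model_dump() if isinstance(geometry, Geometry) else {}
    )
    rows = []
    for w in sorted(widths):
        if w <= 0:
            raise LayoutError("widths must be positive")
        geom = Geometry(**{**base, "mf_width": w})
        layout = build_layout(variant, n_wells=n_wells, geometry=geom)
        mf_volume = sum(s.volume for s in layout.mf_segments)
        p_adv = capillary_pressure(
            layout.mf_segments[0].cross_section, fluid, "advancing"
        ).value
        if p_adv <= 0:
            rows.append(
                {
                    "mf_width_m": w,
                    "wetting": False,
                    "loading_time_s": np.nan,
                    "retained_mf_volume_m3": mf_volume,
                    "tradeoff_s_m3": np.nan,
                }
            )
            continue
        report, _ = simulate_loading(layout, fluid)
        t_load = report.pump_contact_time if report.success else np.nan
        rows.append(
            {
                "mf_width_m": w,
                "wetting": True,
                "loading_time_s": t_load,
                "retained_mf_volume_m3": mf_volume,
                "tradeoff_s_m3": t_load * mf_volume if t_load == t_load else np.nan,
            }
        )
    return SweepTable(
        parameter="mf_width",
        unit="m",
        table=pd.DataFrame(rows),
        metadata={"fluid": fluid.name, "n_wells": n_wells, "variant": Variant(variant).value},
    )


def mw_width_sweep(
    fluid: FluidProperties,
    widths: list[float],
    jitter: JitterModel | None = None,
    seed: int = 0,
    n_wells: int = 10,
    geometry: Geometry | dict | None = None,
) -> SweepTable:
    """Emptied-cap statistics and bubble risk versus well width.

    During evacuation each well loses a meniscus-shaped cap of volume
    ``(pi/8) w^2 h`` at its mouth; fabrication jitter on the well dimensions
    makes that cap - and hence the digitized volume - variable, more so for
    wide wells.  Wells wider than 1 mm are flagged for corner-flow bubble
    formation at the well's end.
    """
    if jitter is None:
        jitter = JitterModel(seed=seed)
    base = geometry if isinstance(geometry, dict) else (
        geometry.model_dump() if isinstance(geometry, Geometry) else {}
    )
    rows = []
    for i, w in enumerate(sorted(widths)):
        if w <= 0:
            raise LayoutError("widths must be positive")
        geom = Geometry(**{**base, "mw_width": w})
        layout = build_layout(Variant.capdrop, n_wells=n_wells, geometry=geom)
        model = jitter.model_copy(update={"seed": int(jitter.seed + i)})
        jittered = jitter_layout(layout, model)
        caps = np.array([emptied_volume(well) for well in jittered.wells])
        rows.append(
            {
                "mw_width_m": w,
                "emptied_volume_mean_m3": float(caps.mean()),
                "emptied_volume_sd_m3": float(caps.std(ddof=1)) if len(caps) > 1 else 0.0,
                "bubble_flag": bool(w > BUBBLE_WIDTH_LIMIT),
            }
        )
    return SweepTable(
        parameter="mw_width",
        unit="m",
        table=pd.DataFrame(rows),
        metadata={"fluid": fluid.name, "n_wells": n_wells, "seed": seed},
    )


def sv_width_sweep(
    fluids: list[FluidProperties],
    widths: list[float],
    height: float = 0.1e-3,
    length: float = 0.5e-3,
) -> SweepTable:
    """Stop-valve burst pressure per fluid across valve widths.

    Widths below the 120 um fabrication floor are rejected.  Fluids whose
    angle on the valve walls is at or below 90 degrees report non-positive
    burst pressures at every width: the valve cannot stop them at all.
    """
    ws = sorted(widths)
    if any(w < MIN_SV_WIDTH for w in ws):
        raise LayoutError(
            f"SV widths below the 120 um fabrication minimum: "
            f"{[w for w in ws if w < MIN_SV_WIDTH]}"
        )
    rows = []
    for w in ws:
        sv = ChannelSegment(
            id="sv",
            length=length,
            cross_section=CrossSection(
                width=w,
                height=height,
                walls={s: Material.adhesive for s in ("top", "bottom", "left", "right")},
            ),
            role=Role.SV,
        )
        row = {"sv_width_m": w}
        for fluid in fluids:
            row[f"burst_pa_{fluid.name}"] = burst_pressure(sv, fluid)
        rows.append(row)
    return SweepTable(
        parameter="sv_width",
        unit="m",
        table=pd.DataFrame(rows),
        metadata={"height_m": height, "fluids": [f.name for f in fluids]},
    )


def volume_cv(volumes) -> float:
    """Coefficient of variation in percent: 100 * SD / mean (SD with n-1)."""
    v = np.asarray(list(volumes), dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 values")
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    return float(100.0 * v.std(ddof=1) / v.mean())


def particle_partition(
    n_wells: int,
    well_volumes,
    concentration: float,
    sedimentation_k: float = 0.0,
    seed: int = 0,
) -> ParticleLoad:
    """Poisson particle counts per well with sedimentation along the channel.

    ``count_i ~ Poisson(lambda_i)`` with
    ``lambda_i = concentration * V_i * exp(-k (i - 1))``: suspended
    particles settle out of the sample as it travels down the channel, so
    later wells see an exponentially thinned concentration.
    """
    if n_wells < 1 or concentration < 0 or sedimentation_k < 0:
        raise ValueError("need n_wells >= 1, concentration >= 0, k >= 0")
    v = np.broadcast_to(np.asarray(well_volumes, dtype=float), (n_wells,))
    if np.any(v <= 0):
        raise ValueError("well volumes must be positive")
    lam = concentration * v * np.exp(-sedimentation_k * np.arange(n_wells))
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam)
    return ParticleLoad(
        counts=counts,
        concentration=concentration,
        sedimentation_k=sedimentation_k,
        seed=seed,
    )


def expected_counts(
    n_wells: int, well_volumes, concentration: float, sedimentation_k: float = 0.0
) -> np.ndarray:
    """Expected per-well counts (the lambda_i of :func:`particle_partition`)."""
    v = np.broadcast_to(np.asarray(well_volumes, dtype=float), (n_wells,))
    return concentration * v * np.exp(-sedimentation_k * np.arange(n_wells))


def uniformity_report(values) -> dict:
    """Summary of a per-well vector: mean, SD, CV% and per-index trend slope."""
    x = np.asarray(
        values.counts if isinstance(values, ParticleLoad) else list(values),
        dtype=float,
    )
    if x.size == 0:
        raise ValueError("empty input")
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    if x.size > 1:
        slope = float(np.polyfit(np.arange(1, x.size + 1), x, 1)[0])
    else:
        slope = 0.0
    return {
        "n": int(x.size),
        "mean": mean,
        "sd": sd,
        "cv_percent": 100.0 * sd / mean if mean != 0 else float("nan"),
        "trend_slope_per_index": slope,
    }
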