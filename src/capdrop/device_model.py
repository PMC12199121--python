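"""Typed description of capillary droplet-array chips.

A chip is a stack of laser-cut layers: hydrophilic PET film on top and
bottom, three hydrophobic double-sided adhesive layers in between (each a
third of the 0.3 mm channel height).  The lumped model only cares about
topology and per-segment geometry/wettability, so a chip is described as an
ordered main flow channel (MF) carrying microwells (MWs), each well ending
in a pressure-reducer step (PR) and a stop valve (SV) that connects to a
vent network, plus an optional bubble trap (BT) and wicking-pad pump.

Four canonical variants are built here:

``capdrop``
    shared passive vent (PV) with a delay channel, bubble trap and wicking
    pad; the only air openings are the inlet and the pad's vent (Wiki-V).
``capdrop_n``
    one normal vent hole (Norm-V) per well instead of the PV network; no
    stop valves.  Loads fine, fails evacuation - the reference design.
``capdrop_b``
    hydrophobic top layer and no third adhesive: wells are one layer
    shallower (0.2 mm) and have no PR; made for drop-casting workflows.
``capdrop_cell``
    101-well cell-culture version with dual reservoirs and no wicking pad
    (evacuation by lab suction).

All stored quantities are SI; config files may use unit-suffixed strings
("0.7 mm", "300 nL") which are converted on read.
"""

from __future__ import annotations

import json
from enum import Enum
from pathlib import Path
from typing import Annotated, Optional

from pydantic import (
    BaseModel,
    BeforeValidator,
    Field,
    ValidationError,
    model_validator,
)

from .errors import LayoutError
from .pump_and_trap import PumpCurve, default_pump_curve
from .units import parse_length, parse_volume

Length = Annotated[float, BeforeValidator(parse_length), Field(gt=0)]
Volume = Annotated[float, BeforeValidator(parse_volume), Field(gt=0)]

#: narrowest stop valve the CO2 laser process can cut reliably
MIN_SV_WIDTH = 120e-6


class Material(str, Enum):
    """Wall materials, each with its own contact-angle pair per fluid."""

    hydrophilic_film = "hydrophilic_film"  # PET film (top/bottom layers)
    adhesive = "adhesive"  # hydrophobic double-sided adhesive


class Role(str, Enum):
    MF = "MF"
    MW = "MW"
    SV = "SV"
    PR = "PR"
    PV = "PV"
    DELAY = "DELAY"
    BT = "BT"
    INLET = "INLET"
    RESERVOIR = "RESERVOIR"


class Variant(str, Enum):
    capdrop = "capdrop"
    capdrop_n = "capdrop_n"
    capdrop_b = "capdrop_b"
    capdrop_cell = "capdrop_cell"


class VentKind(str, Enum):
    pv = "pv"  # shared passive vent with delay channel
    norm_v = "norm_v"  # per-well vent hole
    none = "none"


class AngleSet(BaseModel):
    """Advancing/receding contact angle pair, degrees."""

    advancing: float = Field(ge=0, le=180)
    receding: float = Field(ge=0, le=180)

    @model_validator(mode="after")
    def _hysteresis(self) -> "AngleSet":
        if self.receding > self.advancing:
            raise ValueError(
                f"receding angle {self.receding} exceeds advancing {self.advancing}"
            )
        return self


class FluidProperties(BaseModel):
    """Bulk and wetting properties of a working fluid.

    ``contact_angle`` maps each wall material to its advancing/receding
    angles for this fluid; hysteresis is what flips the meniscus pressure
    between the loading and evacuation phases.
    """

    name: str
    viscosity: float = Field(gt=0, description="Pa*s")
    surface_tension: float = Field(gt=0, description="N/m")
    density: float = Field(gt=0, description="kg/m^3")
    contact_angle: dict[Material, AngleSet]
    provenance: Optional[str] = None  # e.g. "synthetic_default"

    def angle(self, material: Material | str, mode: str) -> float:
        """Contact angle (degrees) for a wall material at a meniscus mode."""
        key = Material(material)
        if key not in self.contact_angle:
            raise KeyError(key.value)
        return getattr(self.contact_angle[key], mode)


Wall = str  # "top" | "bottom" | "left" | "right"
_WALLS = ("top", "bottom", "left", "right")


class CrossSection(BaseModel):
    """Rectangular duct cross-section with per-wall material assignment."""

    width: Length
    height: Length
    walls: dict[Wall, Material]

    @model_validator(mode="after")
    def _all_walls(self) -> "CrossSection":
        missing = [w for w in _WALLS if w not in self.walls]
        if missing:
            raise ValueError(f"walls missing assignment for {missing}")
        return self

    @property
    def area(self) -> float:
        return self.width * self.height


class ChannelSegment(BaseModel):
    """A straight duct with a single role in the chip's topology."""

    id: str
    length: Length
    cross_section: CrossSection
    role: Role

    @model_validator(mode="after")
    def _sv_floor(self) -> "ChannelSegment":
        if self.role is Role.SV and self.cross_section.width < MIN_SV_WIDTH * (1 - 1e-9):
            raise ValueError(
                f"SV width {self.cross_section.width * 1e6:.0f} um is below the "
                f"120 um fabrication minimum"
            )
        return self

    @property
    def volume(self) -> float:
        return self.length * self.cross_section.area


class Microwell(BaseModel):
    """One well branch: body, optional PR step, optional SV, vent node."""

    index: int = Field(ge=1, description="1..n from inlet toward the pad")
    body: ChannelSegment
    pr: Optional[ChannelSegment] = None
    sv: Optional[ChannelSegment] = None
    vent_attachment: str

    @model_validator(mode="after")
    def _roles(self) -> "Microwell":
        if self.body.role is not Role.MW:
            raise ValueError(f"well {self.index}: body role must be MW")
        if self.pr is not None and self.pr.role is not Role.PR:
            raise ValueError(f"well {self.index}: pr role must be PR")
        if self.sv is not None and self.sv.role is not Role.SV:
            raise ValueError(f"well {self.index}: sv role must be SV")
        return self

    @property
    def segments(self) -> list[ChannelSegment]:
        return [s for s in (self.body, self.pr, self.sv) if s is not None]


class VentNetwork(BaseModel):
    kind: VentKind
    delay: Optional[ChannelSegment] = None  # PV-path segment; its fill closes the PV

    @model_validator(mode="after")
    def _delay_only_for_pv(self) -> "VentNetwork":
        if self.kind is VentKind.pv and self.delay is None:
            raise ValueError("a PV vent network requires a delay channel")
        if self.kind is not VentKind.pv and self.delay is not None:
            raise ValueError("only a PV vent network carries a delay channel")
        return self


class BubbleTrapSpec(BaseModel):
    segment: ChannelSegment
    capacity: Volume

    @model_validator(mode="after")
    def _role(self) -> "BubbleTrapSpec":
        if self.segment.role is not Role.BT:
            raise ValueError("bubble trap segment must have role BT")
        return self


class ChipLayout(BaseModel):
    """Full lumped description of one chip."""

    variant: Variant
    mf_segments: list[ChannelSegment]  # n_wells + 1 segments, inlet -> delay junction
    wells: list[Microwell]
    vent: VentNetwork
    pump: Optional[PumpCurve] = None
    bubble_trap: Optional[BubbleTrapSpec] = None
    tail: Optional[ChannelSegment] = None  # MF tail to the outlet (capdrop_cell)
    openings: list[str]

    @model_validator(mode="after")
    def _invariants(self) -> "ChipLayout":
        n = len(self.wells)
        if n < 1:
            raise ValueError("layout needs at least one well")
        if len(self.mf_segments) != n + 1:
            raise ValueError(
                f"expected {n + 1} MF segments for {n} wells, got {len(self.mf_segments)}"
            )
        if [w.index for w in self.wells] != list(range(1, n + 1)):
            raise ValueError("wells must be indexed 1..n in order")
        v = self.variant
        if v in (Variant.capdrop, Variant.capdrop_b):
            if self.vent.kind is not VentKind.pv:
                raise ValueError(f"{v.value} requires a PV vent network")
            if self.pump is None or self.bubble_trap is None:
                raise ValueError(f"{v.value} requires a wicking pad and bubble trap")
            if sorted(self.openings) != ["inlet", "wiki_v"]:
                raise ValueError(f"{v.value} must have exactly the openings inlet, wiki_v")
        elif v is Variant.capdrop_n:
            if self.vent.kind is not VentKind.norm_v:
                raise ValueError("capdrop_n requires per-well Norm-V vents")
            if self.pump is None:
                raise ValueError("capdrop_n requires a wicking pad")
            expected = sorted(["inlet", "wiki_v"] + [f"norm_v_{k}" for k in range(1, n + 1)])
            if sorted(self.openings) != expected:
                raise ValueError("capdrop_n must have inlet, wiki_v and one norm_v per well")
        elif v is Variant.capdrop_cell:
            if self.pump is not None:
                raise ValueError("capdrop_cell has no wicking pad")
            if self.tail is None:
                raise ValueError("capdrop_cell requires an MF tail to the outlet reservoir")
            if sorted(self.openings) != ["inlet", "outlet"]:
                raise ValueError("capdrop_cell must have exactly two reservoir openings")
        for k, well in enumerate(self.wells, start=1):
            if v is Variant.capdrop_n:
                if well.sv is not None or well.pr is not None:
                    raise ValueError("capdrop_n wells carry no SV or PR")
            else:
                if well.sv is None:
                    raise ValueError(f"well {k} requires an SV in variant {v.value}")
        return self

    @property
    def n_wells(self) -> int:
        return len(self.wells)


# ---------------------------------------------------------------------------
# builders


class Geometry(BaseModel):
    """Builder knobs, SI.  Defaults follow the reference chip: 0.7 x 1.45 x
    0.3 mm wells on a 20 cm main channel of 0.3 mm height.  Dimensions the
    source chip does not pin down (MF width, SV/PV/delay/trap geometry) are
    documented synthetic defaults."""

    mw_width: Length = 0.7e-3
    mw_length: Length = 1.45e-3
    mw_height: Length = 0.3e-3
    mf_width: Length = 1.0e-3
    mf_height: Length = 0.3e-3
    mf_length: Length = 0.20
    sv_width: Length = 200e-6
    sv_height: Length = 0.1e-3  # one adhesive layer (a third of the stack)
    sv_length: Length = 0.5e-3
    pr_fraction: float = Field(default=0.20, gt=0, lt=1)  # PR step = 20% of MW length
    delay_length: Length = 0.04
    delay_width: Length = 0.5e-3
    bt_width_factor: float = Field(default=2.0, ge=1.0)
    bt_length: Length = 5e-3
    sv_style: str = "sv3"  # sv3 (all adhesive) | sv2 (film bottom) | sv1 (film top+bottom)

    @model_validator(mode="after")
    def _style(self) -> "Geometry":
        if self.sv_style not in ("sv1", "sv2", "sv3"):
            raise ValueError("sv_style must be one of sv1, sv2, sv3")
        return self


def _cs(width: float, height: float, top: Material, bottom: Material) -> CrossSection:
    # vertical walls are always cut through adhesive
    return CrossSection(
        width=width,
        height=height,
        walls={
            "top": top,
            "bottom": bottom,
            "left": Material.adhesive,
            "right": Material.adhesive,
        },
    )


# (top, bottom) wall materials of the valve duct for the three design
# iterations: sv1 = bare constriction between hydrophilic layers, sv2 adds a
# hydrophobic floor, sv3 closes the roof too (the working design)
_SV_WALLS = {
    "sv1": (Material.hydrophilic_film, Material.hydrophilic_film),
    "sv2": (Material.hydrophilic_film, Material.adhesive),
    "sv3": (Material.adhesive, Material.adhesive),
}


def build_layout(
    variant: Variant | str,
    n_wells: int | None = None,
    geometry: Geometry | dict | None = None,
    pump: PumpCurve | None = None,
) -> ChipLayout:
    """Construct a validated canonical layout.

    ``n_wells`` defaults to 10 (101 for ``capdrop_cell``).  ``geometry``
    accepts a :class:`Geometry` or a dict of overrides (unit-suffixed strings
    allowed).  ``pump`` overrides the default synthetic pad curve.
    """
    try:
        variant = Variant(variant)
    except ValueError as exc:
        raise LayoutError(
            f"unknown variant {variant!r}; choose from "
            f"{[v.value for v in Variant]}"
        ) from exc
    if n_wells is None:
        n_wells = 101 if variant is Variant.capdrop_cell else 10
    if n_wells < 1:
        raise LayoutError("n_wells must be >= 1")
    if geometry is None:
        geom = Geometry()
    elif isinstance(geometry, Geometry):
        geom = geometry
    else:
        try:
            geom = Geometry(**geometry)
        except ValidationError as exc:
            raise LayoutError(f"invalid geometry: {exc}") from exc

    film, adh = Material.hydrophilic_film, Material.adhesive
    hydrophobic_top = variant is Variant.capdrop_b
    # capdrop_b drops the third adhesive layer: channels are one layer shallower
    stack_height = geom.mw_height * (2 / 3) if hydrophobic_top else geom.mw_height
    mf_height = geom.mf_height * (2 / 3) if hydrophobic_top else geom.mf_height
    top = adh if hydrophobic_top else film

    mf_cs = _cs(geom.mf_width, mf_height, top, film)
    seg_len = geom.mf_length / (n_wells + 1)
    mf_segments = [
        ChannelSegment(id=f"mf_{k}", length=seg_len, cross_section=mf_cs, role=Role.MF)
        for k in range(n_wells + 1)
    ]

    mw_cs = _cs(geom.mw_width, stack_height, top, film)
    # the PR step sits where the third adhesive still covers the well: the
    # local roof is adhesive and the duct loses the top third of its height
    pr_height = stack_height if hydrophobic_top else geom.mw_height * (2 / 3)
    pr_cs = _cs(geom.mw_width, pr_height, adh, film)
    sv_top, sv_bottom = _SV_WALLS[geom.sv_style]
    if hydrophobic_top and geom.sv_style == "sv3":
        sv_top = adh  # the hydrophobic top layer itself closes the valve
    sv_cs = _cs(geom.sv_width, geom.sv_height, sv_top, sv_bottom)

    wells: list[Microwell] = []
    for k in range(1, n_wells + 1):
        body = ChannelSegment(
            id=f"mw_{k}", length=geom.mw_length, cross_section=mw_cs, role=Role.MW
        )
        if variant is Variant.capdrop_n:
            wells.append(
                Microwell(index=k, body=body, vent_attachment=f"norm_v_{k}")
            )
            continue
        pr = None
        if not hydrophobic_top:  # capdrop_b has no third adhesive, hence no PR
            pr = ChannelSegment(
                id=f"pr_{k}",
                length=geom.pr_fraction * geom.mw_length,
                cross_section=pr_cs,
                role=Role.PR,
            )
        sv = ChannelSegment(
            id=f"sv_{k}", length=geom.sv_length, cross_section=sv_cs, role=Role.SV
        )
        wells.append(
            Microwell(index=k, body=body, pr=pr, sv=sv, vent_attachment="pv")
        )

    if variant is Variant.capdrop_n:
        vent = VentNetwork(kind=VentKind.norm_v)
    else:
        # the delay channel runs under the third adhesive: a shallower,
        # adhesive-roofed duct whose weak capillary pressure makes it fill
        # slowly (that slowness IS the delay) and pull only gently on the
        # junctions, so the far wells can finish filling before PV cut-off
        delay_cs = _cs(geom.delay_width, geom.mf_height * (2 / 3), adh, film)
        delay = ChannelSegment(
            id="delay", length=geom.delay_length, cross_section=delay_cs, role=Role.DELAY
        )
        vent = VentNetwork(kind=VentKind.pv, delay=delay)

    bubble_trap = None
    tail = None
    layout_pump: PumpCurve | None = None
    if variant is Variant.capdrop_cell:
        tail = ChannelSegment(
            id="mf_tail", length=seg_len, cross_section=mf_cs, role=Role.MF
        )
        openings = ["inlet", "outlet"]
    else:
        bt_cs = _cs(geom.mf_width * geom.bt_width_factor, mf_height, top, film)
        bt_seg = ChannelSegment(
            id="bt", length=geom.bt_length, cross_section=bt_cs, role=Role.BT
        )
        bubble_trap = BubbleTrapSpec(segment=bt_seg, capacity=bt_seg.volume)
        layout_pump = pump if pump is not None else default_pump_curve()
        openings = ["inlet", "wiki_v"]
        if variant is Variant.capdrop_n:
            openings += [f"norm_v_{k}" for k in range(1, n_wells + 1)]

    try:
        return ChipLayout(
            variant=variant,
            mf_segments=mf_segments,
            wells=wells,
            vent=vent,
            pump=layout_pump,
            bubble_trap=bubble_trap,
            tail=tail,
            openings=openings,
        )
    except ValidationError as exc:
        raise LayoutError(str(exc)) from exc


def nominal_well_volume(well: Microwell) -> float:
    """Nominal trapped volume of a well: width x length x height, m^3."""
    cs = well.body.cross_section
    return cs.width * well.body.length * cs.height


# ---------------------------------------------------------------------------
# serialization


def write_layout(layout: ChipLayout, path: str | Path) -> None:
    """Write the canonical JSON serialization (SI floats)."""
    Path(path).write_text(layout.model_dump_json(indent=2))


def read_layout(path: str | Path) -> ChipLayout:
    """Read and re-validate a layout; unit-suffixed strings are converted."""
    raw = json.loads(Path(path).read_text())
    try:
        return ChipLayout.model_validate(raw)
    except ValidationError as exc:
        locs = "; ".join(
            "/".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise LayoutError(f"invalid layout file {path}: {locs}") from exc


def write_fluid(fluid: FluidProperties, path: str | Path) -> None:
    Path(path).write_text(fluid.model_dump_json(indent=2))


def read_fluid(path: str | Path) -> FluidProperties:
    raw = json.loads(Path(path).read_text())
    try:
        return FluidProperties.model_validate(raw)
    except ValidationError as exc:
        locs = "; ".join(
            "/".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise LayoutError(f"invalid fluid file {path}: {locs}") from exc
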