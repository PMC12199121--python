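"""Unit-suffix parsing for configuration files.

The package is SI throughout internally (m, Pa, Pa*s, N/m, m^3, kg/m^3).
Chip and fluid config files may attach an explicit unit suffix to any
length, volume or pressure, e.g. ``"0.7 mm"``, ``"300 nL"`` or ``"5 kPa"``;
bare numbers are taken as already-SI.
"""

from __future__ import annotations

_LENGTH = {"m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "μm": 1e-6}
_VOLUME = {
    "m3": 1.0,
    "m^3": 1.0,
    "l": 1e-3,
    "ml": 1e-6,
    "ul": 1e-9,
    "µl": 1e-9,
    "μl": 1e-9,
    "nl": 1e-12,
    "pl": 1e-15,
}
_PRESSURE = {"pa": 1.0, "kpa": 1e3, "mbar": 1e2, "bar": 1e5}


class UnitError(ValueError):
    """A quantity string could not be parsed into SI units."""


def _parse(value: object, table: dict[str, float], kind: str) -> float:
    if isinstance(value, bool):  # bool is an int subclass; never a quantity
        raise UnitError(f"cannot interpret {value!r} as a {kind}")
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        parts = value.strip().split()
        try:
            if len(parts) == 1:
                return float(parts[0])
            if len(parts) == 2:
                magnitude = float(parts[0])
                unit = parts[1].lower()
                if unit not in table:
                    raise UnitError(
                        f"unknown {kind} unit {parts[1]!r} in {value!r}; "
                        f"accepted: {sorted(set(table))}"
                    )
                return magnitude * table[unit]
        except UnitError:
            raise
        except ValueError:
            pass
    raise UnitError(f"cannot interpret {value!r} as a {kind}")


def parse_length(value: object) -> float:
    """Parse a length as metres.  Accepts numbers or "<x> m|cm|mm|um"."""
    return _parse(value, _LENGTH, "length")


def parse_volume(value: object) -> float:
    """Parse a volume as cubic metres.  Accepts numbers or "<x> m3|mL|uL|nL"."""
    return _parse(value, _VOLUME, "volume")


def parse_pressure(value: object) -> float:
    """Parse a pressure as pascals.  Accepts numbers or "<x> Pa|kPa|mbar|bar"."""
    return _parse(value, _PRESSURE, "pressure")
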