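"""Unit conversions for dissolved species.

Hot-spring geochemistry is reported in a mix of molal (μmolal = μmol per kg
of solvent) and mass-based (ppm, ppb, mg/L) units, while the fringe
discriminant expects each variable in one canonical unit.  All conversions
here assume a solution density of 1 kg/L, so μmolal ≈ μmol/L and
ppm ≈ mg/L, ppb ≈ μg/L — an excellent approximation for dilute spring
waters.

Molal-to-mass conversions need a molar mass, so they are keyed by chemical
species.  Sulfide is converted as HS⁻ and ammonia as NH4⁺ by default; the
registry is open, so a caller who prefers to book total sulfide as H2S can
register that species and use it instead.
"""

from __future__ import annotations

from dataclasses import dataclass


class ConversionError(KeyError):
    """Unknown species or unsupported unit pair."""


# g/mol; conventional atomic weights
MOLAR_MASSES: dict[str, float] = {
    "sulfide": 33.073,       # as HS⁻
    "HS-": 33.073,
    "H2S": 34.081,
    "S": 32.065,
    "ammonia": 18.039,       # as NH4⁺
    "NH4+": 18.039,
    "phosphate": 94.971,     # as PO4³⁻
    "PO4-3": 94.971,
    "nitrate": 62.004,       # as NO3⁻
    "NO3-": 62.004,
    "Fe(II)": 55.845,
    "Mg": 24.305,
    "Co": 58.933,
    "Ni": 58.693,
    "Cu": 63.546,
    "Zn": 65.380,
    "As": 74.922,
    "Mo": 95.950,
    "Cd": 112.414,
    "W": 183.840,
    "Pb": 207.200,
}

# multiplicative factor to a common mass scale (ppb = μg/kg)
_MASS_UNITS: dict[str, float] = {
    "ppb": 1.0,
    "ug/L": 1.0,
    "ppm": 1e3,
    "mg/L": 1e3,
    "mg C/L": 1e3,
}

# molal units, factor to μmolal
_MOLAL_UNITS: dict[str, float] = {
    "umolal": 1.0,
    "μmolal": 1.0,
    "mmolal": 1e3,
}


def register_species(name: str, molar_mass: float) -> None:
    """Add or override a species in the molar-mass registry."""
    if molar_mass <= 0:
        raise ValueError(f"molar mass must be positive, got {molar_mass}")
    MOLAR_MASSES[name] = molar_mass


def convert_units(value: float, species: str, from_unit: str, to_unit: str) -> float:
    """Convert a concentration between molal and mass-based units.

    Parameters
    ----------
    value : concentration in ``from_unit``.
    species : registry key giving the molar mass (only consulted when the
        conversion crosses the molal/mass divide).
    from_unit, to_unit : any of μmolal/umolal/mmolal, ppb, ppm, mg/L,
        mg C/L, ug/L.

    The conversion is linear and exactly invertible: 1 μmolal of a species
    with molar mass M g/mol is M ppb (density-1 convention).
    """
    if from_unit == to_unit:
        return value
    in_molal = from_unit in _MOLAL_UNITS
    out_molal = to_unit in _MOLAL_UNITS
    if not in_molal and from_unit not in _MASS_UNITS:
        raise ConversionError(f"unknown unit {from_unit!r}")
    if not out_molal and to_unit not in _MASS_UNITS:
        raise ConversionError(f"unknown unit {to_unit!r}")

    if in_molal and out_molal:
        return value * _MOLAL_UNITS[from_unit] / _MOLAL_UNITS[to_unit]
    if not in_molal and not out_molal:
        return value * _MASS_UNITS[from_unit] / _MASS_UNITS[to_unit]

    if species not in MOLAR_MASSES:
        raise ConversionError(
            f"species {species!r} not in molar-mass registry; "
            f"register it with register_species()"
        )
    m = MOLAR_MASSES[species]
    if in_molal:
        umolal = value * _MOLAL_UNITS[from_unit]
        ppb = umolal * m
        return ppb / _MASS_UNITS[to_unit]
    ppb = value * _MASS_UNITS[from_unit]
    return ppb / m / _MOLAL_UNITS[to_unit]


@dataclass(frozen=True)
class UnitSpec:
    """A variable name bound to exactly one unit tag."""

    variable: str
    unit: str

    def __str__(self) -> str:  # header cell form
        return f"{self.variable}[{self.unit}]" if self.unit else self.variable
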