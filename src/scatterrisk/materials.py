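"""Tissue materials and the CT number / mass-density calibration.

Materials carry a mass density (g/cm^3) and an elemental mass-fraction
composition in the style of the ICRP reference-phantom tissue tables.  The
compositions shipped here are simplified reference-tissue values (air,
lung, adipose, breast, soft tissue, muscle, bone, water) sufficient for
photon cross-section evaluation; they are not a reproduction of any
specific phantom's 47-tissue table.

The CT calibration maps mass density to Hounsfield units by piecewise
linear interpolation (water = 0 HU, air = -1000 HU by convention) and is
strictly monotone, so the inverse assignment (HU back to density) is exact
inside the table range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Material",
    "CTDensityTable",
    "DEFAULT_CT_TABLE",
    "electrons_per_gram",
    "effective_z",
    "AIR",
    "WATER",
    "LUNG",
    "ADIPOSE",
    "BREAST_TISSUE",
    "SOFT_TISSUE",
    "MUSCLE",
    "BONE",
    "STANDARD_MATERIALS",
]

# element -> (Z, A)
_ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 1.008),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "Na": (11, 22.990),
    "Mg": (12, 24.305),
    "P": (15, 30.974),
    "S": (16, 32.06),
    "Cl": (17, 35.45),
    "Ar": (18, 39.948),
    "K": (19, 39.098),
    "Ca": (20, 40.078),
    "Fe": (26, 55.845),
}

_AVOGADRO = 6.02214076e23  # 1/mol


@dataclass(frozen=True)
class Material:
    """A tissue or medium: name, mass density, elemental composition.

    ``composition`` maps element symbol to mass fraction; fractions must
    sum to 1 within 1e-6.
    """

    name: str
    density: float  # g/cm^3
    composition: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"material {self.name!r}: density must be > 0")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"material {self.name!r}: mass fractions sum to {total}, not 1"
            )
        for el in self.composition:
            if el not in _ELEMENTS:
                raise ValueError(f"material {self.name!r}: unknown element {el!r}")

    def with_density(self, density: float) -> "Material":
        return Material(self.name, density, dict(self.composition))


def electrons_per_gram(material: Material) -> float:
    """Electron density N_A * sum(w_i * Z_i / A_i), electrons per gram."""
    zoa = sum(
        w * _ELEMENTS[el][0] / _ELEMENTS[el][1]
        for el, w in material.composition.items()
    )
    return _AVOGADRO * zoa


def effective_z(material: Material, power: float = 2.94) -> float:
    """Power-law effective atomic number (photoelectric weighting)."""
    num = 0.0
    den = 0.0
    for el, w in material.composition.items():
        z, a = _ELEMENTS[el]
        frac_e = w * z / a
        num += frac_e * z**power
        den += frac_e
    return (num / den) ** (1.0 / power)


# Simplified reference-tissue compositions (mass fractions).
AIR = Material(
    "air", 0.0012, {"N": 0.755, "O": 0.232, "Ar": 0.013}
)
WATER = Material("water", 1.000, {"H": 0.1119, "O": 0.8881})
LUNG = Material(
    "lung",
    0.26,
    {"H": 0.103, "C": 0.105, "N": 0.031, "O": 0.749, "P": 0.002, "S": 0.003,
     "Na": 0.002, "Cl": 0.003, "K": 0.002},
)
ADIPOSE = Material(
    "adipose",
    0.95,
    {"H": 0.114, "C": 0.598, "N": 0.007, "O": 0.278, "Na": 0.001, "S": 0.001,
     "Cl": 0.001},
)
BREAST_TISSUE = Material(
    "breast",
    0.99,
    {"H": 0.109, "C": 0.506, "N": 0.023, "O": 0.358, "P": 0.001, "S": 0.001,
     "Na": 0.001, "Cl": 0.001},
)
SOFT_TISSUE = Material(
    "soft_tissue",
    1.03,
    {"H": 0.105, "C": 0.256, "N": 0.027, "O": 0.602, "P": 0.002, "S": 0.003,
     "Na": 0.001, "Cl": 0.002, "K": 0.002},
)
MUSCLE = Material(
    "muscle",
    1.05,
    {"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.710, "P": 0.002, "S": 0.003,
     "Na": 0.001, "Cl": 0.001, "K": 0.004},
)
BONE = Material(
    "bone",
    1.85,
    {"H": 0.047, "C": 0.144, "N": 0.042, "O": 0.446, "Mg": 0.002, "P": 0.105,
     "S": 0.003, "Ca": 0.210, "Na": 0.001},
)

STANDARD_MATERIALS: dict[str, Material] = {
    m.name: m
    for m in (AIR, WATER, LUNG, ADIPOSE, BREAST_TISSUE, SOFT_TISSUE, MUSCLE, BONE)
}


class CTDensityTable:
    """Piecewise-linear CT-number / mass-density calibration.

    Both columns must be strictly increasing.  Conversions clamp at the
    table ends; inside the range the round trip density -> HU -> density is
    exact to floating-point precision.
    """

    def __init__(self, rows: list[tuple[float, float]]):
        """``rows``: list of (HU, density g/cm^3), strictly increasing in both."""
        rows = sorted(rows)
        self.hu = np.asarray([r[0] for r in rows], dtype=float)
        self.density = np.asarray([r[1] for r in rows], dtype=float)
        if len(rows) < 2:
            raise ValueError("calibration table needs at least two rows")
        if np.any(np.diff(self.hu) <= 0) or np.any(np.diff(self.density) <= 0):
            raise ValueError("calibration table must be strictly increasing in both columns")

    def density_to_hu(self, density):
        return np.interp(density, self.density, self.hu)

    def hu_to_density(self, hu):
        return np.interp(hu, self.hu, self.density)


#: Two-segment default: air / water / compact bone.
DEFAULT_CT_TABLE = CTDensityTable(
    [(-1000.0, 0.0012), (0.0, 1.0), (1300.0, 1.85)]
)
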