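"""Bead-level stoichiometry for luminescent polymer bead labels.

Back-of-the-envelope arithmetic that matters for assay design: how many
emitter complexes a bead of given size and loading carries, how densely
its surface groups are packed ("parking area"), how many proteins fit on
the surface, how efficiently an offered protein couples, and what the
resulting molar detection limit is.

All counts are returned as real numbers; rounding to significant figures
is left to the report layer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "AVOGADRO",
    "ATOMIC_MASSES",
    "BeadGeometry",
    "Loading",
    "SurfaceLayout",
    "parse_formula",
    "molar_mass",
    "complexes_per_bead",
    "bead_mass_g",
    "beads_from_mass",
    "parking_area",
    "max_surface_proteins",
    "detection_limit_mol",
    "coupling_efficiency",
    "proteins_from_biotin_endpoint",
]

AVOGADRO = 6.02214e23  # mol^-1

# IUPAC standard atomic weights, 5 significant figures.  Conventional
# values are used where IUPAC gives an interval (e.g. S = 32.06).
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "K": 39.098, "Ca": 40.078,
    "Fe": 55.845, "Cu": 63.546, "Zn": 65.38, "Br": 79.904, "I": 126.90,
    "La": 138.91, "Ce": 140.12, "Sm": 150.36, "Eu": 151.96, "Gd": 157.25,
    "Tb": 158.93, "Dy": 162.50, "Er": 167.26, "Yb": 173.05,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class BeadGeometry:
    """Spherical polymer bead: diameter in nm, polymer density in g/cm^3.

    Polystyrene density defaults to the handbook value 1.05 g/cm^3.
    """

    diameter: float
    polymer_density: float = 1.05

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.polymer_density <= 0:
            raise ValueError("diameter and density must be positive")

    @property
    def volume_cm3(self) -> float:
        import math

        return (math.pi / 6.0) * (self.diameter * 1e-7) ** 3

    @property
    def surface_area_A2(self) -> float:
        import math

        return math.pi * self.diameter**2 * 100.0  # nm^2 -> A^2


@dataclass(frozen=True)
class Loading:
    """Emitter loading of the bead polymer: mass fraction and molar mass (g/mol)."""

    mass_fraction: float
    molar_mass: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mass_fraction < 1.0:
            raise ValueError("mass_fraction must be in [0, 1)")
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")


@dataclass(frozen=True)
class SurfaceLayout:
    """Surface stoichiometry: functional-group count, per-group parking
    area (A^2), protein footprint diameter (nm) and biotin sites per protein."""

    n_groups: float
    parking_area: float
    protein_diameter: float
    sites_per_protein: int = 4

    def __post_init__(self) -> None:
        if self.sites_per_protein < 1:
            raise ValueError("sites_per_protein must be >= 1")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a flat chemical formula such as ``EuC72H114F9O8P2S3``."""
    composition: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos or not match.group(1):
            break
        composition[match.group(1)] = composition.get(match.group(1), 0) + int(
            match.group(2) or 1
        )
        pos = match.end()
    if pos != len(formula) or not composition:
        raise ValueError(f"cannot parse formula {formula!r}")
    return composition


def molar_mass(composition: dict[str, int] | str) -> float:
    """Molar mass (g/mol) from an element->count map or a formula string."""
    if isinstance(composition, str):
        composition = parse_formula(composition)
    unknown = sorted(set(composition) - set(ATOMIC_MASSES))
    if unknown:
        raise ValueError(f"unknown element symbol(s): {unknown}")
    return float(sum(ATOMIC_MASSES[el] * cnt for el, cnt in composition.items()))


def complexes_per_bead(geometry: BeadGeometry, loading: Loading) -> float:
    """Number of emitter complexes per bead.

    N = w * rho * (pi/6) d^3 * N_A / M.  A 100 nm polystyrene bead at 1% wt
    of a ~1600 g/mol complex carries about two thousand emitters — the
    amplification factor that makes bead labels bright.
    """
    mass_complex = loading.mass_fraction * geometry.polymer_density * geometry.volume_cm3
    return mass_complex * AVOGADRO / loading.molar_mass


def bead_mass_g(geometry: BeadGeometry) -> float:
    """Mass of a single bead in grams."""
    return geometry.polymer_density * geometry.volume_cm3


def beads_from_mass(total_mass_g: float, geometry: BeadGeometry) -> float:
    """Bead count corresponding to a total bead mass.

    Exposed so weight-percent dosing can be converted to bead counts; note
    that published per-well weight fractions and bead counts are not always
    mutually consistent, so counts stated directly should be preferred as
    inputs when available.
    """
    if total_mass_g < 0:
        raise ValueError("mass must be non-negative")
    return total_mass_g / bead_mass_g(geometry)


def parking_area(diameter: float, n_groups: float) -> float:
    """Surface area available per functional group, in A^2.

    pi * d^2 / n_groups with d in nm (1 nm^2 = 100 A^2).
    """
    import math

    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if n_groups <= 0:
        raise ValueError("n_groups must be positive")
    return math.pi * diameter**2 * 100.0 / n_groups


def max_surface_proteins(bead_diameter: float, protein_diameter: float) -> float:
    """Geometric protein capacity of a bead surface.

    Sphere area divided by the protein's circular footprint:
    (pi d_b^2) / (pi d_p^2 / 4) = (2 d_b / d_p)^2.  A plain footprint
    division (no hexagonal packing factor) is used.
    """
    if bead_diameter <= 0 or protein_diameter <= 0:
        raise ValueError("diameters must be positive")
    return (2.0 * bead_diameter / protein_diameter) ** 2


def detection_limit_mol(n_beads: float, molecules_per_bead: float) -> float:
    """Detection limit in moles of surface molecules: n_beads * per-bead count / N_A."""
    if n_beads < 0 or molecules_per_bead < 0:
        raise ValueError("inputs must be non-negative")
    return n_beads * molecules_per_bead / AVOGADRO


def coupling_efficiency(coupled_per_bead: float, offered_per_bead: float) -> float:
    """Fraction of offered protein that ended up coupled to the bead."""
    if offered_per_bead <= 0:
        raise ValueError("offered_per_bead must be positive")
    if coupled_per_bead < 0:
        raise ValueError("coupled_per_bead must be non-negative")
    return coupled_per_bead / offered_per_bead


def proteins_from_biotin_endpoint(biotin_per_bead: float, sites_per_protein: int = 4) -> float:
    """Surface protein count from a biotin-blocking endpoint.

    Tetrameric (Neutr)avidin binds 4 biotins, so the dose that saturates
    all sites divided by 4 counts the proteins.
    """
    if sites_per_protein < 1:
        raise ValueError("sites_per_protein must be >= 1")
    if biotin_per_bead < 0:
        raise ValueError("biotin_per_bead must be non-negative")
    return biotin_per_bead / sites_per_protein
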