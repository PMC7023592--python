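"""Molecular formula arithmetic and system composition bookkeeping.

Ionic liquid (IL)-water mixtures are specified either by weight percent
water (how solutions are prepared on a bench) or by mole percent water
(how simulations and phase behaviour are discussed).  This module converts
between the two, computes molar masses from Hill-notation formulas, and
carries the manifest of simulated tetrabutylphosphonium hydroxide
(TBPH)-water systems with their atom/molecule totals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = [
    "SpeciesFormula",
    "SystemComposition",
    "molar_mass",
    "parse_formula",
    "wt_to_mol_percent",
    "mol_to_wt_percent",
    "total_atoms",
    "table1_manifest",
    "manifest_frame",
    "round_half_up",
    "TBP_CATION",
    "HYDROXIDE",
    "CHLORIDE",
    "WATER",
    "BMIM_CATION",
    "TBA_CATION",
]

# IUPAC standard atomic weights (abridged, conventional values).
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Br": 79.904,
    "I": 126.904,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation formula string (e.g. ``C16H36P``) into counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        if not m.group(0):
            break
        pos = m.end()
        n = int(m.group(2)) if m.group(2) else 1
        counts[m.group(1)] = counts.get(m.group(1), 0) + n
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


@dataclass(frozen=True)
class SpeciesFormula:
    """A molecular species: element counts plus its counted atomic sites.

    ``sites_per_molecule`` is the number of atomic sites the species
    contributes to a simulation atom count.  By default it equals the sum
    of the element counts; water keeps 3 counted sites even under 4-site
    rigid models whose 4th site is massless.
    """

    name: str
    element_counts: dict[str, int] = field(default_factory=dict)
    sites_per_molecule: int | None = None

    def __post_init__(self) -> None:
        for el, n in self.element_counts.items():
            if n < 0:
                raise ValueError(f"negative count for element {el}")
        if self.sites_per_molecule is None:
            object.__setattr__(
                self, "sites_per_molecule", sum(self.element_counts.values())
            )
        if self.sites_per_molecule < 0:
            raise ValueError("sites_per_molecule must be non-negative")

    @classmethod
    def from_string(
        cls, name: str, formula: str, sites_per_molecule: int | None = None
    ) -> "SpeciesFormula":
        return cls(name, parse_formula(formula), sites_per_molecule)

    @property
    def molar_mass(self) -> float:
        return molar_mass(self)


def molar_mass(formula: SpeciesFormula) -> float:
    """Molar mass in g/mol from the built-in standard atomic-weight table."""
    total = 0.0
    for el, n in formula.element_counts.items():
        if el not in ATOMIC_WEIGHTS:
            raise KeyError(f"unknown element {el!r} in formula {formula.name!r}")
        total += n * ATOMIC_WEIGHTS[el]
    return total


TBP_CATION = SpeciesFormula.from_string("TBP+", "C16H36P")
HYDROXIDE = SpeciesFormula.from_string("OH-", "OH")
CHLORIDE = SpeciesFormula.from_string("Cl-", "Cl")
WATER = SpeciesFormula.from_string("water", "H2O")
BMIM_CATION = SpeciesFormula.from_string("BMIM+", "C8H15N2")
TBA_CATION = SpeciesFormula.from_string("TBA+", "C16H36N")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (display convention for percents)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def wt_to_mol_percent(wt_water: float, m_il: float, m_water: float) -> float:
    """Convert weight percent water to mole percent water.

    x = (w/M_w) / (w/M_w + (100-w)/M_il) * 100.  No display rounding is
    applied; use :func:`round_half_up` for reporting.
    """
    if not 0.0 <= wt_water <= 100.0:
        raise ValueError(f"wt_water must be in [0, 100], got {wt_water}")
    if m_il <= 0 or m_water <= 0:
        raise ValueError("molar masses must be positive")
    n_w = wt_water / m_water
    n_il = (100.0 - wt_water) / m_il
    return 100.0 * n_w / (n_w + n_il)


def mol_to_wt_percent(mol_water: float, m_il: float, m_water: float) -> float:
    """Exact inverse of :func:`wt_to_mol_percent`."""
    if not 0.0 <= mol_water <= 100.0:
        raise ValueError(f"mol_water must be in [0, 100], got {mol_water}")
    if m_il <= 0 or m_water <= 0:
        raise ValueError("molar masses must be positive")
    w_w = mol_water * m_water
    w_il = (100.0 - mol_water) * m_il
    return 100.0 * w_w / (w_w + w_il)


@dataclass(frozen=True)
class SystemComposition:
    """Counts of IL ion pairs and water molecules for one simulated system."""

    n_il: int
    n_water: int
    il_species: tuple[SpeciesFormula, SpeciesFormula] = (TBP_CATION, HYDROXIDE)
    water_species: SpeciesFormula = WATER
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_il < 0 or self.n_water < 0:
            raise ValueError("counts must be non-negative")
        if self.n_il + self.n_water == 0:
            raise ValueError("empty system")

    @property
    def n_molecules(self) -> int:
        # an IL pair counts as one "molecule", matching the manifest convention
        return self.n_il + self.n_water

    @property
    def mole_percent_water(self) -> float:
        return 100.0 * self.n_water / (self.n_il + self.n_water)


def total_atoms(comp: SystemComposition) -> int:
    """Total counted atomic sites in the system."""
    cation, anion = comp.il_species
    per_pair = cation.sites_per_molecule + anion.sites_per_molecule
    return comp.n_il * per_pair + comp.n_water * comp.water_species.sites_per_molecule


# (label, n_il, n_water) for every printed TBPH-water system.
_TBPH_ROWS: tuple[tuple[str, int, int], ...] = (
    ("0.55", 180, 1),
    ("5.26", 180, 10),
    ("10.0", 180, 20),
    ("20.0", 180, 45),
    ("30.0", 180, 77),
    ("40.0", 180, 120),
    ("50.0", 170, 170),
    ("60.0", 165, 248),
    ("70.0", 160, 374),
    ("80.0", 150, 600),
    ("85.0", 140, 794),
    ("90.0", 120, 1080),
    ("92.5", 110, 1357),
    ("94.0", 100, 1567),
    ("95.0", 90, 1710),
    ("99.0", 30, 2970),
    ("99.97", 1, 3000),
)


def table1_manifest() -> list[SystemComposition]:
    """All 17 simulated TBPH-water compositions (TBPH only; the chloride
    systems' atom totals are not tabulated)."""
    return [
        SystemComposition(n_il, n_water, (TBP_CATION, HYDROXIDE), WATER, label)
        for label, n_il, n_water in _TBPH_ROWS
    ]


def manifest_frame() -> pd.DataFrame:
    """Manifest as a tidy table (exportable as CSV)."""
    rows = []
    for comp in table1_manifest():
        rows.append(
            {
                "mol_pct_water": comp.label,
                "n_il": comp.n_il,
                "n_water": comp.n_water,
                "n_molecules": comp.n_molecules,
                "n_atoms": total_atoms(comp),
            }
        )
    return pd.DataFrame(rows)
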