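"""Lipid species registry: nomenclature, formulas and adduct rules.

A species is named at sum-composition level, e.g. ``"PC 34:1"`` — lipid
class, total acyl carbons and total double bonds across chains.  Elemental
formulas for each supported class follow the standard head-group + acyl
arithmetic (diacyl for PC/PE/PI, monoacyl for LysoPC, triacyl for TAG,
and so on), which reproduces the compositions curated in public lipid
databases for these classes.

The registry is a user-supplied TSV (one row per species) rather than an
embedded database; :func:`build_registry` constructs one programmatically
from (class, carbons, double bonds) tuples.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .chem import PROTON_MASS, formula_to_hill, monoisotopic_mass, parse_formula

__all__ = [
    "LipidSpecies",
    "AdductRule",
    "LIPID_CLASSES",
    "POSITIVE_ADDUCTS",
    "NEGATIVE_ADDUCTS",
    "DEFAULT_ADDUCTS",
    "formula_for_species",
    "make_species",
    "parse_species_id",
    "build_registry",
    "load_registry",
    "save_registry",
    "theoretical_mz",
]

_ID_RE = re.compile(r"^\s*(\S+)\s+(\d+):(\d+)\s*$")

# element-count rule per class: (c, d) -> formula, sum-composition level.
# H count decreases by 2 per double bond in every class.
_CLASS_RULES = {
    "PC": lambda c, d: {"C": c + 8, "H": 2 * c + 16 - 2 * d, "N": 1, "O": 8, "P": 1},
    "LysoPC": lambda c, d: {"C": c + 8, "H": 2 * c + 18 - 2 * d, "N": 1, "O": 7, "P": 1},
    "PE": lambda c, d: {"C": c + 5, "H": 2 * c + 10 - 2 * d, "N": 1, "O": 8, "P": 1},
    "PI": lambda c, d: {"C": c + 9, "H": 2 * c + 15 - 2 * d, "O": 13, "P": 1},
    "TAG": lambda c, d: {"C": c + 3, "H": 2 * c + 2 - 2 * d, "O": 6},
    "DAG": lambda c, d: {"C": c + 3, "H": 2 * c + 4 - 2 * d, "O": 5},
    "CE": lambda c, d: {"C": c + 27, "H": 2 * c + 44 - 2 * d, "O": 2},
    "SM": lambda c, d: {"C": c + 5, "H": 2 * c + 13 - 2 * d, "N": 2, "O": 6, "P": 1},
    "Cer": lambda c, d: {"C": c, "H": 2 * c + 1 - 2 * d, "N": 1, "O": 3},
    "FA": lambda c, d: {"C": c, "H": 2 * c - 2 * d, "O": 2},
}

LIPID_CLASSES = tuple(_CLASS_RULES)


@dataclass(frozen=True)
class LipidSpecies:
    """One sum-composition lipid species (the unit of annotation)."""

    id: str
    lipid_class: str
    total_carbons: int
    total_double_bonds: int
    formula: Mapping[str, int]
    neutral_mass: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.total_carbons < 1:
            raise ValueError(f"{self.id}: total_carbons must be >= 1")
        if self.total_double_bonds < 0:
            raise ValueError(f"{self.id}: total_double_bonds must be >= 0")
        if self.neutral_mass == 0.0:
            object.__setattr__(self, "neutral_mass", monoisotopic_mass(self.formula))
        if self.neutral_mass <= 0:
            raise ValueError(f"{self.id}: neutral_mass must be positive")


@dataclass(frozen=True)
class AdductRule:
    """Ionization adduct: name, polarity, total mass shift (Da) and charge."""

    name: str
    polarity: str  # "+" or "-"
    mass_shift: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.polarity not in {"+", "-"}:
            raise ValueError(f"polarity must be '+' or '-', got {self.polarity!r}")
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")


# Positive- and negative-mode adducts allowed in the annotation searches
# (protonation, ammonium, in-source water losses, doubly protonated; and
# deprotonation, formate, acetate, doubly deprotonated, sodiated/potassiated
# deprotonated forms).
_H2O = 18.010565
POSITIVE_ADDUCTS: tuple[AdductRule, ...] = (
    AdductRule("+H", "+", PROTON_MASS, 1),
    AdductRule("+NH4", "+", 18.033823, 1),
    AdductRule("+H-H2O", "+", PROTON_MASS - _H2O, 1),
    AdductRule("+H-2H2O", "+", PROTON_MASS - 2 * _H2O, 1),
    AdductRule("+2H", "+", 2 * PROTON_MASS, 2),
)
NEGATIVE_ADDUCTS: tuple[AdductRule, ...] = (
    AdductRule("-H", "-", -PROTON_MASS, 1),
    AdductRule("+HCOO", "-", 44.998201, 1),
    AdductRule("+CH3COO", "-", 59.013851, 1),
    AdductRule("-2H", "-", -2 * PROTON_MASS, 2),
    AdductRule("-2H+Na", "-", 22.989769 - 2 * 1.007825 + 0.000549, 1),
    AdductRule("-2H+K", "-", 38.963706 - 2 * 1.007825 + 0.000549, 1),
)
DEFAULT_ADDUCTS: tuple[AdductRule, ...] = POSITIVE_ADDUCTS + NEGATIVE_ADDUCTS


def formula_for_species(lipid_class: str, carbons: int, double_bonds: int) -> dict[str, int]:
    """Elemental formula of a sum-composition species of a supported class."""
    try:
        rule = _CLASS_RULES[lipid_class]
    except KeyError:
        raise ValueError(
            f"unsupported lipid class {lipid_class!r}; supported: {LIPID_CLASSES}"
        ) from None
    formula = rule(carbons, double_bonds)
    if any(v < 0 for v in formula.values()):
        raise ValueError(
            f"{lipid_class} {carbons}:{double_bonds} yields a negative element count"
        )
    return formula


def make_species(lipid_class: str, carbons: int, double_bonds: int) -> LipidSpecies:
    """Construct a :class:`LipidSpecies` with formula and mass from class rules."""
    return LipidSpecies(
        id=f"{lipid_class} {carbons}:{double_bonds}",
        lipid_class=lipid_class,
        total_carbons=carbons,
        total_double_bonds=double_bonds,
        formula=formula_for_species(lipid_class, carbons, double_bonds),
    )


def parse_species_id(species_id: str) -> tuple[str, int, int]:
    """Parse ``"PC 34:1"`` into ``("PC", 34, 1)``; inverse of id construction."""
    m = _ID_RE.match(species_id)
    if m is None:
        raise ValueError(f"cannot parse species id {species_id!r} (expected 'CLS C:D')")
    return m.group(1), int(m.group(2)), int(m.group(3))


def build_registry(entries: Iterable[tuple[str, int, int]]) -> list[LipidSpecies]:
    """Build a registry from (class, carbons, double_bonds) tuples."""
    return [make_species(cls, c, d) for cls, c, d in entries]


def theoretical_mz(species: LipidSpecies, adduct: AdductRule) -> float:
    """m/z of a species under an adduct: (M + shift) / z.

    Rejects combinations yielding a non-positive m/z (nonsensical adduct
    for this mass, e.g. a double water loss from a tiny molecule).
    """
    mz = (species.neutral_mass + adduct.mass_shift) / adduct.charge
    if mz <= 0:
        raise ValueError(
            f"adduct {adduct.name} applied to {species.id} "
            f"(M={species.neutral_mass:.4f}) gives non-positive m/z"
        )
    return mz


_REGISTRY_COLUMNS = ["id", "class", "carbons", "double_bonds", "formula"]


def load_registry(path: str | Path) -> list[LipidSpecies]:
    """Read a registry TSV (columns id, class, carbons, double_bonds, formula).

    The stored formula (Hill notation) is authoritative for the mass; the id
    must round-trip to (class, carbons, double_bonds).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"registry {path}: missing columns {missing}")
    dupes = df["id"][df["id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"registry {path}: duplicated species ids {sorted(set(dupes))}")
    species = []
    for _, row in df.iterrows():
        cls, c, d = parse_species_id(row["id"])
        if (cls, c, d) != (row["class"], int(row["carbons"]), int(row["double_bonds"])):
            raise ValueError(
                f"registry {path}: id {row['id']!r} does not round-trip to "
                f"({row['class']}, {row['carbons']}, {row['double_bonds']})"
            )
        species.append(
            LipidSpecies(
                id=row["id"],
                lipid_class=cls,
                total_carbons=c,
                total_double_bonds=d,
                formula=parse_formula(row["formula"]),
            )
        )
    return species


def save_registry(species: Sequence[LipidSpecies], path: str | Path) -> None:
    """Write a registry TSV readable by :func:`load_registry`."""
    df = pd.DataFrame(
        {
            "id": [s.id for s in species],
            "class": [s.lipid_class for s in species],
            "carbons": [s.total_carbons for s in species],
            "double_bonds": [s.total_double_bonds for s in species],
            "formula": [formula_to_hill(s.formula) for s in species],
        }
    )
    df.to_csv(path, sep="\t", index=False)
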