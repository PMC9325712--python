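"""Elemental composition arithmetic for lipid mass spectrometry.

Monoisotopic element masses are pinned to a versioned constant table so that
theoretical masses are reproducible across environments.  The supported
element set covers the lipid classes handled by this package plus the heavy
isotopes (2H, 13C) that appear in deuterated internal standards and
stable-isotope tracers.
"""

from __future__ import annotations

import re
from collections.abc import Mapping

__all__ = [
    "ELEMENT_MASSES",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "monoisotopic_mass",
    "parse_formula",
    "formula_to_hill",
]

# Monoisotopic atomic masses in Da (CODATA 2018 / AME2020 rounded to 1e-6).
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.007825,
    "C": 12.0,
    "N": 14.003074,
    "O": 15.994915,
    "P": 30.973762,
    "S": 31.972071,
    "Na": 22.989769,
    "K": 38.963706,
    "F": 18.998403,
    "Cl": 34.968853,
    # heavy-isotope labels (deuterium, carbon-13)
    "2H": 2.014102,
    "13C": 13.003355,
}

PROTON_MASS = 1.007276  # Da, mass of H+ (H minus one electron)
ELECTRON_MASS = 0.000549  # Da

_TOKEN = re.compile(r"\[(\d+)([A-Z][a-z]?)\](\d*)|([A-Z][a-z]?)(\d*)")


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of an elemental composition.

    Parameters
    ----------
    formula
        Mapping of element symbol (including isotope labels such as
        ``"2H"`` or ``"13C"``) to a non-negative integer count.

    Raises
    ------
    ValueError
        If the formula is empty after dropping zero counts, a count is
        negative, or an element symbol is not in the supported set.
    """
    total = 0.0
    n_atoms = 0
    for symbol, count in formula.items():
        if symbol not in ELEMENT_MASSES:
            raise ValueError(
                f"unknown element symbol {symbol!r}; supported: "
                f"{sorted(ELEMENT_MASSES)}"
            )
        if count < 0:
            raise ValueError(f"negative count for element {symbol!r}: {count}")
        total += ELEMENT_MASSES[symbol] * count
        n_atoms += count
    if n_atoms == 0:
        raise ValueError("empty formula: no atoms with positive count")
    return total


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-notation formula string into an element-count mapping.

    Isotope labels are written in brackets, e.g. ``"C16H29[2H]3O2"`` for a
    d3-palmitate.  Counts default to 1 when omitted.
    """
    text = text.strip()
    if not text:
        raise ValueError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        if m.group(2):  # isotope token like [2H]31
            symbol = m.group(1) + m.group(2)
            count = int(m.group(3) or 1)
        else:
            symbol = m.group(4)
            count = int(m.group(5) or 1)
        if symbol not in ELEMENT_MASSES:
            raise ValueError(f"unknown element symbol {symbol!r} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + count
        pos = m.end()
    return counts


def formula_to_hill(formula: Mapping[str, int]) -> str:
    """Render an element-count mapping in Hill order (C, H, then alphabetic)."""

    def sort_key(symbol: str) -> tuple[int, str]:
        order = {"C": 0, "H": 1}.get(symbol, 2)
        return order, symbol

    parts = []
    for symbol in sorted((s for s, c in formula.items() if c > 0), key=sort_key):
        count = formula[symbol]
        label = f"[{symbol}]" if symbol[0].isdigit() else symbol
        parts.append(label if count == 1 else f"{label}{count}")
    if not parts:
        raise ValueError("empty formula: no atoms with positive count")
    return "".join(parts)
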