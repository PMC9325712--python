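"""Peak-to-species annotation with explicit tolerance and mass-error rules.

MS1 annotation matches observed m/z values against every (species, adduct)
candidate within a tolerance window and keeps a single best candidate per
peak.  The tolerance is either absolute (Da; imaging mode, default 0.5) or
relative (ppm; LC mode, default 5).  The reported mass error follows the
convention with the *observed* m/z in the denominator:

    ppm = (observed - theoretical) / observed * 1e6

MS/MS confirmation operates on unit-mass product-ion scans: a precursor
candidate is confirmed when a class-diagnostic fragment (product ion or
neutral loss) is present above a relative-intensity floor; otherwise the
annotation is kept but flagged as MS1-only.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import AdductRule, LipidSpecies, theoretical_mz

__all__ = [
    "PeakList",
    "MsmsAllScan",
    "FragmentRule",
    "Annotation",
    "Tolerance",
    "DEFAULT_FRAGMENT_RULES",
    "mass_error_ppm",
    "annotate_peaks",
    "identify_msms_all",
    "annotations_to_frame",
]

PHOSPHOCHOLINE_MZ = 184.0733  # C5H15NO4P+, head-group fragment of PC/LysoPC/SM
PE_NEUTRAL_LOSS = 141.0191  # phosphoethanolamine head group


@dataclass(frozen=True)
class PeakList:
    """Observed m/z-intensity pairs of one polarity, sorted by m/z."""

    polarity: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and np.any(np.diff(mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        if self.polarity not in {"+", "-"}:
            raise ValueError(f"polarity must be '+' or '-', got {self.polarity!r}")


@dataclass(frozen=True)
class MsmsAllScan:
    """Product-ion spectrum collected at one unit precursor mass."""

    precursor_center: float
    products: PeakList
    precursor_range: tuple[float, float] = (200.0, 1200.0)

    def __post_init__(self) -> None:
        lo, hi = self.precursor_range
        if not lo <= self.precursor_center <= hi:
            raise ValueError(
                f"precursor center {self.precursor_center} outside configured "
                f"range {self.precursor_range}"
            )


@dataclass(frozen=True)
class FragmentRule:
    """Class-diagnostic fragment: product ion or neutral loss from precursor."""

    lipid_class: str
    polarity: str
    diagnostic_mz: float
    rule_kind: str = "product-ion"  # or "neutral-loss"
    tolerance: float = 0.01

    def __post_init__(self) -> None:
        if self.diagnostic_mz <= 0:
            raise ValueError("diagnostic_mz must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.rule_kind not in {"product-ion", "neutral-loss"}:
            raise ValueError(f"unknown rule_kind {self.rule_kind!r}")


# Default class-diagnostic set; identification logic of vendor pipelines is
# unpublished, so the set is deliberately small and configurable.
DEFAULT_FRAGMENT_RULES: tuple[FragmentRule, ...] = (
    FragmentRule("PC", "+", PHOSPHOCHOLINE_MZ, "product-ion"),
    FragmentRule("LysoPC", "+", PHOSPHOCHOLINE_MZ, "product-ion"),
    FragmentRule("SM", "+", PHOSPHOCHOLINE_MZ, "product-ion"),
    FragmentRule("PE", "+", PE_NEUTRAL_LOSS, "neutral-loss"),
    # TAG: loss of an acyl chain as RCOOH + NH3 from the ammonium adduct;
    # palmitate loss used as representative diagnostic.
    FragmentRule("TAG", "+", 273.2668, "neutral-loss", tolerance=0.02),
)


@dataclass(frozen=True)
class Annotation:
    """One peak-to-species match within tolerance."""

    observed_mz: float
    species_id: str
    adduct: str
    theoretical_mz: float
    delta_mda: float = field(default=float("nan"))
    ppm: float = field(default=float("nan"))
    confirmed: bool | None = None  # None: MS1-only annotation, not evaluated

    def __post_init__(self) -> None:
        delta = (self.observed_mz - self.theoretical_mz) * 1000.0
        object.__setattr__(self, "delta_mda", delta)
        object.__setattr__(
            self, "ppm", mass_error_ppm(self.observed_mz, self.theoretical_mz)
        )


@dataclass(frozen=True)
class Tolerance:
    """Annotation tolerance: absolute ("Da") or relative ("ppm")."""

    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in {"Da", "ppm"}:
            raise ValueError(
                f"tolerance unit must be 'Da' or 'ppm', got {self.unit!r}"
            )
        if self.value <= 0:
            raise ValueError("tolerance must be positive")

    @classmethod
    def imaging(cls) -> "Tolerance":
        return cls(0.5, "Da")

    @classmethod
    def lc(cls) -> "Tolerance":
        return cls(5.0, "ppm")

    def window(self, mz: float) -> float:
        """Half-width of the acceptance window (Da) at a given m/z."""
        return self.value if self.unit == "Da" else self.value * mz * 1e-6


def mass_error_ppm(observed: float, theoretical: float) -> float:
    """Mass error in ppm, with the observed m/z in the denominator."""
    if observed <= 0:
        raise ValueError(f"observed m/z must be positive, got {observed}")
    return (observed - theoretical) / observed * 1e6


def _candidate_table(
    registry: Sequence[LipidSpecies],
    adducts: Sequence[AdductRule],
    polarity: str,
) -> tuple[np.ndarray, list[tuple[LipidSpecies, AdductRule]]]:
    pairs = []
    for sp in registry:
        for ad in adducts:
            if ad.polarity != polarity:
                continue
            try:
                mz = theoretical_mz(sp, ad)
            except ValueError:
                continue
            pairs.append((mz, sp, ad))
    pairs.sort(key=lambda t: t[0])
    mzs = np.array([t[0] for t in pairs])
    meta = [(t[1], t[2]) for t in pairs]
    return mzs, meta


def annotate_peaks(
    peaks: PeakList,
    registry: Sequence[LipidSpecies],
    adducts: Sequence[AdductRule],
    tolerance: Tolerance,
) -> list[Annotation | None]:
    """Annotate each peak with at most one species (single-candidate rule).

    Among all (species, adduct) candidates inside the tolerance window the
    one with minimal |observed - theoretical| wins; ties (within 1e-6 Da)
    are broken toward fewer double bonds, then lexicographic species id.
    Unmatched peaks yield ``None`` at their position.
    """
    if not registry:
        raise ValueError("registry must be non-empty")
    if not isinstance(tolerance, Tolerance):
        raise TypeError("tolerance must be a Tolerance (unit must be declared)")
    cand_mz, cand_meta = _candidate_table(registry, adducts, peaks.polarity)
    out: list[Annotation | None] = []
    for mz in peaks.mz:
        half = tolerance.window(mz)
        if cand_mz.size == 0:
            out.append(None)
            continue
        lo = np.searchsorted(cand_mz, mz - half, side="left")
        hi = np.searchsorted(cand_mz, mz + half, side="right")
        if lo == hi:
            out.append(None)
            continue
        window = range(lo, hi)
        best = min(
            window,
            key=lambda i: (
                round(abs(cand_mz[i] - mz), 6),
                cand_meta[i][0].total_double_bonds,
                cand_meta[i][0].id,
            ),
        )
        sp, ad = cand_meta[best]
        out.append(
            Annotation(
                observed_mz=float(mz),
                species_id=sp.id,
                adduct=ad.name,
                theoretical_mz=float(cand_mz[best]),
            )
        )
    return out


def identify_msms_all(
    scans: Sequence[MsmsAllScan],
    registry: Sequence[LipidSpecies],
    adducts: Sequence[AdductRule],
    fragment_rules: Sequence[FragmentRule] = DEFAULT_FRAGMENT_RULES,
    precursor_tol: Tolerance = Tolerance(0.5, "Da"),
    product_tol: float = 0.01,
    intensity_floor: float = 0.01,
) -> list[Annotation | None]:
    """Annotate unit-mass product-ion scans with class-diagnostic confirmation.

    Each scan's precursor center is annotated at MS1 level; the candidate is
    confirmed when its class's diagnostic fragment (or neutral loss from the
    precursor) is present within ``product_tol`` Da at relative intensity
    >= ``intensity_floor`` of the base peak.  Unconfirmed candidates are kept,
    flagged ``confirmed=False`` (MS1-only).  Fragment rules whose polarity
    does not match a scan are skipped with a warning.
    """
    classes = {sp.lipid_class for sp in registry}
    out: list[Annotation | None] = []
    for scan in scans:
        polarity = scan.products.polarity
        prec = PeakList(polarity, np.array([scan.precursor_center]), np.array([1.0]))
        ann = annotate_peaks(prec, registry, adducts, precursor_tol)[0]
        if ann is None:
            out.append(None)
            continue
        cls = next(sp.lipid_class for sp in registry if sp.id == ann.species_id)
        rules = []
        for rule in fragment_rules:
            if rule.lipid_class != cls or rule.lipid_class not in classes:
                continue
            if rule.polarity != polarity:
                warnings.warn(
                    f"fragment rule for {rule.lipid_class} has polarity "
                    f"{rule.polarity!r} but scan is {polarity!r}; rule skipped",
                    stacklevel=2,
                )
                continue
            rules.append(rule)
        confirmed = False
        prod = scan.products
        base = prod.intensity.max() if prod.intensity.size else 0.0
        for rule in rules:
            target = (
                rule.diagnostic_mz
                if rule.rule_kind == "product-ion"
                else scan.precursor_center - rule.diagnostic_mz
            )
            tol = max(rule.tolerance, product_tol)
            sel = np.abs(prod.mz - target) <= tol
            if base > 0 and np.any(prod.intensity[sel] >= intensity_floor * base):
                confirmed = True
                break
        out.append(
            Annotation(
                observed_mz=ann.observed_mz,
                species_id=ann.species_id,
                adduct=ann.adduct,
                theoretical_mz=ann.theoretical_mz,
                confirmed=confirmed,
            )
        )
    return out


def annotations_to_frame(
    peaks: PeakList, annotations: Sequence[Annotation | None]
) -> pd.DataFrame:
    """Tabulate annotations (one row per peak, unmatched rows blank)."""
    rows = []
    for mz, ann in zip(peaks.mz, annotations):
        if ann is None:
            rows.append(
                {
                    "peak_mz": mz,
                    "species_id": "",
                    "adduct": "",
                    "theoretical_mz": np.nan,
                    "delta_mDa": np.nan,
                    "ppm": np.nan,
                    "confirmed_flag": "",
                }
            )
        else:
            rows.append(
                {
                    "peak_mz": mz,
                    "species_id": ann.species_id,
                    "adduct": ann.adduct,
                    "theoretical_mz": ann.theoretical_mz,
                    "delta_mDa": ann.delta_mda,
                    "ppm": ann.ppm,
                    "confirmed_flag": "" if ann.confirmed is None else str(ann.confirmed),
                }
            )
    return pd.DataFrame(rows)
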