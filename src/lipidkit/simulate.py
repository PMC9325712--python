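"""Synthetic lipidomics data with machine-readable ground truth.

Every generator plants a known structure so the downstream stage it feeds
can be verified exactly:

* lipidome tables — log-normal species abundances with multiplicative
  class- or saturation-bin-level effects per experimental condition
  (genotype group x treatment), emulating the oncogene-specific lipidome
  signatures (mutant-KRAS tumors: PC/TAG/SM/PE up, LysoPC down; mutant-EGFR:
  PI up, TAG down; both: CE up, DAG down) and the FASN-inhibitor response of
  KRAS-mutant cells (LysoPC up, DAG up, SFA/MUFA-TAG down, PUFA-PC up,
  SFA/MUFA-PC down, PUFA-TAG unchanged);
* isotopologue envelopes — forward natural-abundance convolution of planted
  tracer-label fractions (supported at even M+n, two-carbon acetate units);
* ion images — a tumor ellipse over stroma with opposite SFA/MUFA-PC vs
  PUFA-PC contrast;
* peak lists — theoretical adduct m/z values with Gaussian jitter plus
  decoys placed beyond the annotation tolerance.

All randomness flows from the single seed in :class:`SimConfig`; identical
configurations produce byte-identical outputs.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd

from .imaging import ROIMask, SpectrumGrid
from .isotope import IsotopologueVector, build_correction_matrix
from .profiles import LipidTable, saturation_bin
from .registry import (
    AdductRule,
    LipidSpecies,
    POSITIVE_ADDUCTS,
    build_registry,
    parse_species_id,
    theoretical_mz,
)

__all__ = [
    "EffectSpec",
    "SimConfig",
    "GroundTruth",
    "EFFECT_PRESETS",
    "default_species_entries",
    "default_registry",
    "simulate_lipid_table",
    "simulate_isotopologues",
    "simulate_ion_image",
    "simulate_peaklist",
]


@dataclass(frozen=True)
class EffectSpec:
    """Multiplicative effect on mean abundance for a class (or class, bin)
    under a condition; ``group``/``treatment`` of ``None`` match any level."""

    lipid_class: str
    effect: float
    saturation: str | None = None  # SFA | MUFA | PUFA, None = whole class
    group: str | None = None
    treatment: str | None = None

    def __post_init__(self) -> None:
        if self.effect <= 0:
            raise ValueError("effect must be > 0")
        if self.saturation not in {None, "SFA", "MUFA", "PUFA"}:
            raise ValueError(f"unknown saturation bin {self.saturation!r}")

    def condition_matches(self, group: str, treatment: str) -> bool:
        return (self.group is None or self.group == group) and (
            self.treatment is None or self.treatment == treatment
        )

    def species_matches(self, lipid_class: str, double_bonds: int) -> bool:
        if self.lipid_class != lipid_class:
            return False
        return self.saturation is None or saturation_bin(double_bonds) == self.saturation


# Named, versioned effect presets (v1).  Magnitudes are round defaults
# (2x up, 0.5x down); the underlying study reports effect directions in
# figures only, so magnitudes are not claimed to match measured ones.
EFFECT_PRESETS: dict[str, tuple[EffectSpec, ...]] = {
    "fig1_km": (
        EffectSpec("PC", 2.0, group="KM"),
        EffectSpec("TAG", 2.0, group="KM"),
        EffectSpec("SM", 2.0, group="KM"),
        EffectSpec("PE", 2.0, group="KM"),
        EffectSpec("LysoPC", 0.5, group="KM"),
        EffectSpec("CE", 2.0, group="KM"),
        EffectSpec("DAG", 0.5, group="KM"),
    ),
    "fig1_egfr": (
        EffectSpec("PI", 2.0, group="EGFR"),
        EffectSpec("TAG", 0.5, group="EGFR"),
        EffectSpec("CE", 2.0, group="EGFR"),
        EffectSpec("DAG", 0.5, group="EGFR"),
    ),
    "fig4_fasni_km": (
        EffectSpec("LysoPC", 2.0, group="KM", treatment="FASNi"),
        EffectSpec("DAG", 2.0, group="KM", treatment="FASNi"),
        EffectSpec("PC", 2.0, saturation="PUFA", group="KM", treatment="FASNi"),
        EffectSpec("PC", 0.5, saturation="SFA", group="KM", treatment="FASNi"),
        EffectSpec("PC", 0.5, saturation="MUFA", group="KM", treatment="FASNi"),
        EffectSpec("TAG", 0.5, saturation="SFA", group="KM", treatment="FASNi"),
        EffectSpec("TAG", 0.5, saturation="MUFA", group="KM", treatment="FASNi"),
        EffectSpec("TAG", 1.0, saturation="PUFA", group="KM", treatment="FASNi"),
    ),
}

# canonical per-class sum compositions for synthetic registries: one SFA,
# one MUFA and two PUFA species per glycerophospholipid/glycerolipid class
_DEFAULT_SPECIES: dict[str, tuple[tuple[int, int], ...]] = {
    "PC": ((32, 0), (34, 1), (36, 2), (38, 4)),
    "LysoPC": ((16, 0), (18, 1), (18, 2), (20, 4)),
    "PE": ((32, 0), (34, 1), (36, 2), (38, 4)),
    "PI": ((32, 0), (34, 1), (36, 2), (38, 4)),
    "TAG": ((48, 0), (50, 1), (52, 2), (54, 4)),
    "DAG": ((32, 0), (34, 1), (36, 2), (38, 4)),
    "CE": ((16, 0), (18, 1), (18, 2), (20, 4)),
    "SM": ((34, 1), (36, 1), (36, 2), (42, 2)),
    "Cer": ((34, 1), (36, 1), (42, 1), (42, 2)),
}


def default_species_entries(species_per_class: int = 4) -> list[tuple[str, int, int]]:
    """(class, carbons, double_bonds) entries of the default synthetic registry."""
    if not 1 <= species_per_class <= 4:
        raise ValueError("species_per_class must be in [1, 4]")
    return [
        (cls, c, d)
        for cls, combos in _DEFAULT_SPECIES.items()
        for c, d in combos[:species_per_class]
    ]


def default_registry(species_per_class: int = 4) -> list[LipidSpecies]:
    """The default ~36-species synthetic registry."""
    return build_registry(default_species_entries(species_per_class))


@dataclass(frozen=True)
class SimConfig:
    """All generator knobs, with one seed driving every source of randomness."""

    seed: int = 0
    # lipidome tables
    groups: tuple[str, ...] = ("healthy", "KM")
    treatments: tuple[str, ...] = ("vehicle",)
    samples_per_condition: int = 5
    species_per_class: int = 4
    baseline_mean: float = 1e5
    baseline_log_sd: float = 0.5  # species-to-species spread of baselines
    cv: float = 0.20  # within-condition biological coefficient of variation
    effects: tuple[EffectSpec, ...] = ()
    # isotopologue envelopes
    tracer_fractions: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {"FA 16:0": (0.60, 0.0, 0.25, 0.0, 0.15)}
    )
    isotopologue_noise_cv: float = 0.05
    isotopologue_replicates: int = 1
    p13c: float = 0.0107
    # ion images
    image_width: int = 40
    image_height: int = 30
    pixel_size_um: float = 60.0
    ellipse_axes: tuple[float, float] = (10.0, 7.0)
    image_contrast: float = 3.0
    image_baseline: float = 100.0
    image_noise_cv: float = 0.0
    image_noise_model: str = "lognormal"  # or "poisson"
    tic_variation_cv: float = 0.0
    # peak lists
    n_peaks: int | None = None  # default: one peak per registry species
    mz_jitter_sd: float = 0.0
    n_decoys: int = 0
    peak_tolerance_da: float = 0.5

    def __post_init__(self) -> None:
        if self.samples_per_condition < 1:
            raise ValueError("samples_per_condition must be >= 1")
        for bad in ("cv", "baseline_log_sd", "isotopologue_noise_cv",
                    "image_noise_cv", "tic_variation_cv", "mz_jitter_sd"):
            if getattr(self, bad) < 0:
                raise ValueError(f"{bad} must be >= 0")

    def with_effects(self, preset: str) -> "SimConfig":
        """Copy of this config with a named effect preset installed."""
        if preset not in EFFECT_PRESETS:
            raise ValueError(
                f"unknown preset {preset!r}; available: {sorted(EFFECT_PRESETS)}"
            )
        return replace(self, effects=EFFECT_PRESETS[preset])


@dataclass
class GroundTruth:
    """Planted truth aligned one-to-one with generated features."""

    # species x condition multiplicative effects ("group|treatment" columns)
    effects: pd.DataFrame | None = None
    # analyte -> planted label-fraction vector
    labeled_fractions: dict[str, tuple[float, ...]] | None = None
    # marker name -> {"kind": tumor|stroma, "contrast": float, "mz": float}
    marker_contrast: dict[str, dict] | None = None
    # per generated peak: species id, or None for decoys
    peak_identities: list[str | None] | None = None

    def planted_log2fc(self, species_id: str, condition: str, reference: str) -> float:
        if self.effects is None:
            raise ValueError("no table ground truth present")
        e = self.effects
        return float(np.log2(e.at[species_id, condition] / e.at[species_id, reference]))


def _condition_label(group: str, treatment: str) -> str:
    return f"{group}|{treatment}"


def simulate_lipid_table(config: SimConfig) -> tuple[LipidTable, GroundTruth]:
    """Group-structured lipidome table with planted class/saturation effects.

    Species abundances are log-normal around class baselines; each effect
    multiplies the mean of its target in matching conditions.  A bin-level
    effect (class, saturation) overrides any whole-class effect for species
    in that bin.
    """
    rng = np.random.default_rng(config.seed)
    entries = default_species_entries(config.species_per_class)
    species_ids = [f"{cls} {c}:{d}" for cls, c, d in entries]
    for spec in config.effects:
        if not any(spec.lipid_class == cls for cls, _, _ in entries):
            raise ValueError(
                f"effect target class {spec.lipid_class!r} not in the registry"
            )
    conditions = list(product(config.groups, config.treatments))
    sigma = float(np.sqrt(np.log1p(config.cv**2)))
    baselines = config.baseline_mean * np.exp(
        rng.normal(0.0, config.baseline_log_sd, size=len(species_ids))
    )

    def effect_multiplier(cls: str, d: int, group: str, treatment: str) -> float:
        bin_specs = [
            s for s in config.effects
            if s.saturation is not None
            and s.species_matches(cls, d)
            and s.condition_matches(group, treatment)
        ]
        class_specs = [
            s for s in config.effects
            if s.saturation is None
            and s.species_matches(cls, d)
            and s.condition_matches(group, treatment)
        ]
        chosen = bin_specs if bin_specs else class_specs
        mult = 1.0
        for s in chosen:
            mult *= s.effect
        return mult

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    effect_table = pd.DataFrame(
        1.0, index=species_ids,
        columns=[_condition_label(g, t) for g, t in conditions],
    )
    for (cls, c, d), sid in zip(entries, species_ids):
        for g, t in conditions:
            effect_table.at[sid, _condition_label(g, t)] = effect_multiplier(cls, d, g, t)
    for g, t in conditions:
        mult = effect_table[_condition_label(g, t)].to_numpy()
        for rep in range(1, config.samples_per_condition + 1):
            sample_id = f"{g}-{t}-{rep}"
            noise = np.exp(rng.normal(0.0, sigma, size=len(species_ids)))
            columns[sample_id] = baselines * mult * noise
            meta_rows.append(
                {"sample_id": sample_id, "group": g, "treatment": t, "replicate": rep}
            )
    abundances = pd.DataFrame(columns, index=species_ids)
    table = LipidTable(abundances, pd.DataFrame(meta_rows), normalized=True)
    return table, GroundTruth(effects=effect_table)


def simulate_isotopologues(
    config: SimConfig,
) -> tuple[list[tuple[str, IsotopologueVector]], GroundTruth]:
    """Measured envelopes = natural-abundance convolution of planted fractions.

    Multiplicative log-normal noise (``isotopologue_noise_cv``) acts per
    channel.  Fraction vectors must sum to 1.
    """
    rng = np.random.default_rng(config.seed)
    sigma = float(np.sqrt(np.log1p(config.isotopologue_noise_cv**2)))
    out = []
    truth: dict[str, tuple[float, ...]] = {}
    for analyte_id, fractions in config.tracer_fractions.items():
        f = np.asarray(fractions, dtype=float)
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"{analyte_id}: planted fractions sum to {f.sum()}, expected 1"
            )
        if np.any(f < 0):
            raise ValueError(f"{analyte_id}: planted fractions must be >= 0")
        _, n_carbons, _ = parse_species_id(analyte_id)
        m = build_correction_matrix(n_carbons, config.p13c, size=f.size)
        envelope = m @ f
        truth[analyte_id] = tuple(f.tolist())
        for rep in range(1, config.isotopologue_replicates + 1):
            noise = (
                np.exp(rng.normal(0.0, sigma, size=f.size)) if sigma > 0 else 1.0
            )
            measured = envelope * 1e6 * noise
            out.append(
                (f"rep{rep}", IsotopologueVector(analyte_id, n_carbons, measured))
            )
    return out, GroundTruth(labeled_fractions=truth)


# marker panel for synthetic ion images: saturated and monounsaturated PC
# concentrate in the tumor ellipse, polyunsaturated PC in the stroma
_IMAGE_MARKERS: tuple[tuple[str, str, int, int, str], ...] = (
    ("SFA-PC", "PC", 32, 0, "tumor"),
    ("MUFA-PC", "PC", 34, 1, "tumor"),
    ("PUFA-PC", "PC", 36, 4, "stroma"),
)


def simulate_ion_image(
    config: SimConfig,
) -> tuple[SpectrumGrid, list[ROIMask], GroundTruth]:
    """Tumor-ellipse ion image with opposite SFA/MUFA-PC vs PUFA-PC contrast.

    Marker peaks sit at the theoretical protonated m/z of PC 32:0, PC 34:1
    and PC 36:4 on a 0.1 Da axis.  Tumor markers are ``image_contrast``-fold
    elevated inside the ellipse (T); the stroma marker is elevated outside
    (S).  Optional per-pixel multiplicative noise and TIC variation.
    """
    a, b = config.ellipse_axes
    if a <= 0 or b <= 0:
        raise ValueError("degenerate ellipse: both axes must be positive")
    w, h = config.image_width, config.image_height
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    if cx - a < 0 or cx + a > w - 1 or cy - b < 0 or cy + b > h - 1:
        raise ValueError("ellipse does not fit inside the grid")
    rng = np.random.default_rng(config.seed)
    proton = POSITIVE_ADDUCTS[0]
    markers = {}
    for name, cls, c, d, kind in _IMAGE_MARKERS:
        sp = build_registry([(cls, c, d)])[0]
        markers[name] = {"mz": theoretical_mz(sp, proton), "kind": kind,
                         "contrast": config.image_contrast}
    lo = min(m["mz"] for m in markers.values()) - 5.0
    hi = max(m["mz"] for m in markers.values()) + 5.0
    mz_axis = np.round(np.arange(lo, hi + 0.1, 0.1), 4)
    yy, xx = np.mgrid[0:h, 0:w]
    tumor = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    cube = np.zeros((h, w, mz_axis.size))
    sigma = float(np.sqrt(np.log1p(config.image_noise_cv**2)))
    for name, info in markers.items():
        bin_idx = int(np.argmin(np.abs(mz_axis - info["mz"])))
        base = np.full((h, w), config.image_baseline)
        if info["kind"] == "tumor":
            base[tumor] *= config.image_contrast
        else:
            base[~tumor] *= config.image_contrast
        if config.image_noise_cv > 0:
            if config.image_noise_model == "lognormal":
                base = base * np.exp(rng.normal(0.0, sigma, size=base.shape))
            elif config.image_noise_model == "poisson":
                base = rng.poisson(base).astype(float)
            else:
                raise ValueError(
                    f"unknown image_noise_model {config.image_noise_model!r}"
                )
        cube[:, :, bin_idx] = base
    if config.tic_variation_cv > 0:
        tic_sigma = float(np.sqrt(np.log1p(config.tic_variation_cv**2)))
        cube *= np.exp(rng.normal(0.0, tic_sigma, size=(h, w)))[..., None]
    grid = SpectrumGrid(mz_axis, cube, config.pixel_size_um)
    masks = [ROIMask("T", tumor), ROIMask("S", ~tumor)]
    return grid, masks, GroundTruth(marker_contrast=markers)


def simulate_peaklist(
    config: SimConfig,
    registry: Sequence[LipidSpecies] | None = None,
    adducts: Sequence[AdductRule] | None = None,
) -> tuple["PeakList", GroundTruth]:
    """Peaks at theoretical adduct m/z with Gaussian jitter, plus decoys.

    Decoys are rejected-sampled until they lie further than the annotation
    tolerance (plus a jitter margin) from every theoretical candidate m/z.
    """
    from .annotate import PeakList  # local import to avoid cycle

    registry = list(registry) if registry is not None else default_registry()
    if not registry:
        raise ValueError("registry must be non-empty")
    adducts = list(adducts) if adducts is not None else [POSITIVE_ADDUCTS[0]]
    if config.mz_jitter_sd >= config.peak_tolerance_da / 3.0:
        warnings.warn(
            "m/z jitter SD >= tolerance/3: annotation recovery is no longer "
            "guaranteed",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    theo = []
    for sp in registry:
        for ad in adducts:
            theo.append((theoretical_mz(sp, ad), sp.id))
    theo_mz = np.array([t[0] for t in theo])
    n_peaks = config.n_peaks if config.n_peaks is not None else len(theo)
    mzs = []
    ids: list[str | None] = []
    for i in range(n_peaks):
        mz0, sid = theo[i % len(theo)]
        mzs.append(mz0 + (rng.normal(0.0, config.mz_jitter_sd)
                          if config.mz_jitter_sd > 0 else 0.0))
        ids.append(sid)
    margin = config.peak_tolerance_da + 3.0 * config.mz_jitter_sd + 0.05
    lo, hi = theo_mz.min() - 30.0, theo_mz.max() + 30.0
    for _ in range(config.n_decoys):
        for _attempt in range(1000):
            cand = rng.uniform(lo, hi)
            if np.min(np.abs(theo_mz - cand)) > margin:
                mzs.append(cand)
                ids.append(None)
                break
        else:  # pragma: no cover - essentially impossible for sane configs
            raise RuntimeError("could not place a decoy outside the tolerance")
    order = np.argsort(mzs, kind="stable")
    mz_sorted = np.asarray(mzs)[order]
    ids_sorted = [ids[i] for i in order]
    keep = np.concatenate([[True], np.diff(mz_sorted) > 0])
    mz_final = mz_sorted[keep]
    ids_final = [sid for sid, k in zip(ids_sorted, keep) if k]
    peaks = PeakList("+", mz_final, np.ones_like(mz_final))
    return peaks, GroundTruth(peak_identities=ids_final)
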