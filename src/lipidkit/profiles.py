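"""Class totals, double-bond distributions and saturation binning.

Operates on a species-by-sample abundance table whose row ids parse to
(class, carbons, double bonds).  Double-bond counts are sum-composition
level (total over acyl chains); "relative" double-bond quantification is
the within-class fraction per sample.  Saturation bins follow the usual
definition: 0 double bonds saturated (SFA), 1 monounsaturated (MUFA),
>= 2 polyunsaturated (PUFA).
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import parse_species_id

__all__ = [
    "LipidTable",
    "saturation_bin",
    "normalize_to_class_standard",
    "class_totals",
    "double_bond_distribution",
    "log_fold_change",
]

_META_COLUMNS = ["sample_id", "group", "treatment", "replicate"]


@dataclass
class LipidTable:
    """Species x sample abundance matrix with per-sample design metadata.

    ``abundances``: DataFrame indexed by species id, one column per sample.
    ``meta``: DataFrame with columns sample_id, group, treatment, replicate;
    (group, treatment, replicate) must be unique.
    """

    abundances: pd.DataFrame
    meta: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        ab = self.abundances
        if (ab.values < 0).any():
            bad = np.argwhere(ab.values < 0)[0]
            raise ValueError(
                f"negative abundance at species {ab.index[bad[0]]!r}, "
                f"sample {ab.columns[bad[1]]!r}"
            )
        if ab.index.duplicated().any():
            dupes = sorted(set(ab.index[ab.index.duplicated()]))
            raise ValueError(f"duplicated species ids: {dupes}")
        for sid in ab.index:
            parse_species_id(sid)  # raises on malformed ids
        missing = [c for c in _META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns {missing}")
        meta = self.meta.set_index("sample_id", drop=False)
        absent = [c for c in ab.columns if c not in meta.index]
        if absent:
            raise ValueError(f"samples without metadata: {absent}")
        key = self.meta[["group", "treatment", "replicate"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise ValueError("(group, treatment, replicate) must be unique per sample")
        object.__setattr__(self, "meta", meta.loc[list(ab.columns)])
        object.__setattr__(self, "abundances", ab.rename_axis("species_id"))

    @property
    def species_classes(self) -> pd.Series:
        return pd.Series(
            {sid: parse_species_id(sid)[0] for sid in self.abundances.index},
            name="class",
        )

    @property
    def species_double_bonds(self) -> pd.Series:
        return pd.Series(
            {sid: parse_species_id(sid)[2] for sid in self.abundances.index},
            name="double_bonds",
        )

    def samples_where(self, group: str | None = None,
                      treatment: str | None = None) -> list[str]:
        meta = self.meta
        sel = pd.Series(True, index=meta.index)
        if group is not None:
            sel &= meta["group"] == group
        if treatment is not None:
            sel &= meta["treatment"] == treatment
        return list(meta.index[sel])

    def to_tsv(self, table_path: str | Path, meta_path: str | Path) -> None:
        self.abundances.rename_axis("species_id").to_csv(table_path, sep="\t")
        self.meta.to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, table_path: str | Path, meta_path: str | Path,
                 normalized: bool = False) -> "LipidTable":
        ab = pd.read_csv(table_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t")
        return cls(ab, meta, normalized=normalized)


def saturation_bin(double_bonds: int) -> str:
    """SFA (0), MUFA (1) or PUFA (>= 2) from a total double-bond count."""
    if double_bonds < 0:
        raise ValueError(f"double_bonds must be >= 0, got {double_bonds}")
    if double_bonds == 0:
        return "SFA"
    if double_bonds == 1:
        return "MUFA"
    return "PUFA"


def normalize_to_class_standard(
    table: LipidTable,
    class_standards: Mapping[str, Mapping[str, float] | pd.Series],
) -> LipidTable:
    """Divide each species by its class's internal-standard intensity per sample.

    Emulates class-wise normalization against one spiked deuterated standard
    per lipid class.  Classes with no standard are passed through unchanged
    with a warning.
    """
    classes = table.species_classes
    ab = table.abundances.copy().astype(float)
    for cls in classes.unique():
        if cls not in class_standards:
            warnings.warn(
                f"no class standard for {cls!r}; class left unnormalized",
                stacklevel=2,
            )
            continue
        std = pd.Series(class_standards[cls], dtype=float).reindex(ab.columns)
        if std.isna().any() or (std <= 0).any():
            raise ValueError(
                f"class standard for {cls!r} must be positive in every sample"
            )
        members = classes.index[classes == cls]
        ab.loc[members] = ab.loc[members].div(std, axis=1)
    return LipidTable(ab, table.meta.reset_index(drop=True), normalized=True)


def class_totals(table: LipidTable, allow_raw: bool = False) -> pd.DataFrame:
    """Per-class total abundance (class x sample).

    Classes with zero member species are absent from the result rather
    than zero-filled.  Expects a normalized table unless ``allow_raw``.
    """
    if not table.normalized and not allow_raw:
        raise ValueError(
            "table is not normalized; pass allow_raw=True to total raw abundances"
        )
    return table.abundances.groupby(table.species_classes).sum()


def double_bond_distribution(table: LipidTable, lipid_class: str) -> pd.DataFrame:
    """Within-class double-bond fractions (double_bonds x sample).

    For each sample, the fraction at double-bond count d is the summed
    abundance of class members with d double bonds divided by the class
    total.  An absent class yields an empty frame, not an error.
    """
    classes = table.species_classes
    members = classes.index[classes == lipid_class]
    if len(members) == 0:
        return pd.DataFrame()
    sub = table.abundances.loc[members]
    by_d = sub.groupby(table.species_double_bonds.loc[members]).sum()
    totals = by_d.sum(axis=0)
    frac = by_d.div(totals.where(totals > 0), axis=1)
    frac.index.name = "double_bonds"
    return frac


def log_fold_change(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: tuple[str, str],
    on: str = "treatment",
    pseudo: float | None = None,
    base: float = 2.0,
) -> pd.Series:
    """Per-feature log fold-change of a treatment level over a reference level.

    log_base((mean_treatment + pseudo) / (mean_reference + pseudo)); pseudo
    defaults to half the smallest nonzero value in the table so that
    dropout features stay defined.  Features absent (all-NaN) in both
    groups are returned as NaN.
    """
    level, reference = contrast
    for lv in (level, reference):
        if not (meta[on] == lv).any():
            raise ValueError(f"contrast level {lv!r} has no samples in column {on!r}")
    if pseudo is None:
        vals = values.values
        nz = vals[vals > 0]
        pseudo = float(nz.min()) / 2.0 if nz.size else 1e-12
    cols_t = meta.index[meta[on] == level]
    cols_r = meta.index[meta[on] == reference]
    mean_t = values[cols_t].mean(axis=1)
    mean_r = values[cols_r].mean(axis=1)
    return np.log(mean_t.add(pseudo) / mean_r.add(pseudo)) / np.log(base)


def double_bond_profile_tidy(table: LipidTable) -> pd.DataFrame:
    """Tidy (class, double_bonds, sample_id, fraction) profile for all classes."""
    frames = []
    for cls in sorted(table.species_classes.unique()):
        frac = double_bond_distribution(table, cls)
        if frac.empty:
            continue
        tidy = frac.reset_index().melt(
            id_vars="double_bonds", var_name="sample_id", value_name="fraction"
        )
        tidy.insert(0, "class", cls)
        frames.append(tidy)
    return pd.concat(frames, ignore_index=True)
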