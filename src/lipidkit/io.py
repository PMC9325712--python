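"""Schema-validated table I/O for the pipeline's plain-text formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SchemaError", "read_table", "SCHEMAS"]


class SchemaError(ValueError):
    """Raised with the full list of violations, not just the first."""

    def __init__(self, path, violations: list[str]):
        self.violations = violations
        super().__init__(
            f"{path}: {len(violations)} schema violation(s):\n  "
            + "\n  ".join(violations)
        )


def _check_numeric(df: pd.DataFrame, columns, violations: list[str],
                   non_negative: bool = False) -> None:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for row in bad:
            violations.append(f"malformed numeric cell at row {row}, column {col!r}")
        if non_negative:
            neg = df.index[coerced < 0]
            for row in neg:
                violations.append(f"negative value at row {row}, column {col!r}")


SCHEMAS = {
    "peaks": {"required": ["mz", "intensity", "polarity"]},
    "isotopologues": {
        "required": ["analyte_id", "n_carbons", "m_plus", "intensity", "sample_id"]
    },
    "lipid_table": {"required": None},  # species_id index + >=1 sample column
    "sample_meta": {"required": ["sample_id", "group", "treatment", "replicate"]},
    "registry": {"required": ["id", "class", "carbons", "double_bonds", "formula"]},
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a TSV/CSV against a named schema, collecting all violations.

    Schemas: ``peaks`` (CSV), ``isotopologues`` (CSV), ``lipid_table``
    (TSV, species_id first column), ``sample_meta`` (TSV), ``registry``
    (TSV).
    """
    path = Path(path)
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if schema in {"peaks", "isotopologues"} else "\t"
    df = pd.read_csv(path, sep=sep)
    violations: list[str] = []
    required = SCHEMAS[schema]["required"]
    if required is not None:
        for col in required:
            if col not in df.columns:
                violations.append(f"missing required column {col!r}")
        if violations:
            raise SchemaError(path, violations)
    if schema == "peaks":
        _check_numeric(df, ["mz", "intensity"], violations, non_negative=True)
    elif schema == "isotopologues":
        _check_numeric(df, ["n_carbons", "m_plus", "intensity"], violations,
                       non_negative=True)
    elif schema == "lipid_table":
        if df.shape[1] < 2:
            violations.append("need a species_id column plus >= 1 sample column")
        else:
            first = df.columns[0]
            dupes = df[first][df[first].duplicated()].tolist()
            if dupes:
                violations.append(f"duplicated species ids: {sorted(set(dupes))}")
            _check_numeric(df, df.columns[1:], violations, non_negative=True)
    elif schema == "sample_meta":
        key = df[["group", "treatment", "replicate"]].apply(tuple, axis=1)
        if key.duplicated().any():
            violations.append("(group, treatment, replicate) not unique")
    elif schema == "registry":
        dupes = df["id"][df["id"].duplicated()].tolist()
        if dupes:
            violations.append(f"duplicated species ids: {sorted(set(dupes))}")
        _check_numeric(df, ["carbons", "double_bonds"], violations,
                       non_negative=True)
    if violations:
        raise SchemaError(path, violations)
    if schema == "lipid_table":
        df = df.set_index(df.columns[0])
        df.index.name = "species_id"
        return df.astype(float)
    return df


def load_label_grid(path: str | Path) -> np.ndarray:
    """Read an integer label image stored as a CSV grid."""
    return np.loadtxt(path, delimiter=",", dtype=int)
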