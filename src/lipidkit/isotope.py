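"""Natural-abundance correction and de novo lipogenesis flux ratios.

Measured fatty-acid isotopologue envelopes (M+0 ... M+K) mix tracer-derived
labels with naturally occurring 13C.  The correction model is carbon-only
binomial: given j tracer-derived labels on an n-carbon analyte, the
probability of observing isotopologue M+i is the binomial probability of
i - j natural 13C among the remaining n - j carbons.  Contributions of
2H/17O/18O/15N are ignored (sub-0.1% at M+2 resolution for fatty-acid
pentafluorobenzyl derivatives) — a documented simplification.

Corrected fractional enrichments feed the lipogenesis readouts M+2/M+0 and
M+4/M+0, reflecting two-carbon acetate incorporation.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import linalg, optimize
from scipy.stats import binom

__all__ = [
    "P13C_NATURAL",
    "IsotopologueVector",
    "FluxResult",
    "InternalStandardRule",
    "GCMS_STANDARD_RULES",
    "SOLVENT_STANDARD_RULES",
    "build_correction_matrix",
    "correct_natural_abundance",
    "labeling_ratio",
    "normalize_to_internal_standard",
]

P13C_NATURAL = 0.0107  # natural 13C abundance


@dataclass(frozen=True)
class IsotopologueVector:
    """M+0 ... M+K intensities for one fatty-acid analyte."""

    analyte_id: str
    n_carbons: int
    intensities: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", v)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("intensities must be a non-empty 1-D array")
        if v.size - 1 > self.n_carbons:
            raise ValueError(
                f"{self.analyte_id}: K={v.size - 1} exceeds n_carbons={self.n_carbons}"
            )
        if np.any(v < 0):
            raise ValueError(f"{self.analyte_id}: intensities must be non-negative")

    @property
    def k(self) -> int:
        return self.intensities.size - 1


class LabelingRatios(NamedTuple):
    m2_over_m0: float | None
    m4_over_m0: float | None
    reason: str | None = None


@dataclass(frozen=True)
class FluxResult:
    """Corrected fractional enrichments and lipogenesis ratios."""

    analyte_id: str
    fractions: np.ndarray
    ratios: LabelingRatios


def build_correction_matrix(n_carbons: int, p13c: float = P13C_NATURAL,
                            size: int | None = None) -> np.ndarray:
    """Lower-triangular natural-abundance convolution matrix.

    Entry (i, j) is the probability of observing M+i given j tracer labels:
    binomial(i - j successes among n_carbons - j carbons at rate p13c).
    With ``p13c = 0`` the matrix is the identity.

    Parameters
    ----------
    n_carbons
        Carbon count of the analyte (>= 1).
    p13c
        Per-carbon heavy-isotope probability, ``0 <= p13c < 1``.
    size
        Matrix dimension K+1; defaults to ``n_carbons + 1``.
    """
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    if not 0 <= p13c < 1:
        raise ValueError("p13c must be in [0, 1)")
    dim = n_carbons + 1 if size is None else size
    if dim < 1 or dim > n_carbons + 1:
        raise ValueError(f"size must be in [1, n_carbons + 1], got {dim}")
    if p13c == 0.0:
        return np.eye(dim)
    i = np.arange(dim)[:, None]
    j = np.arange(dim)[None, :]
    m = binom.pmf(i - j, n_carbons - j, p13c)
    return np.where(i >= j, m, 0.0)


def correct_natural_abundance(v: IsotopologueVector, m: np.ndarray) -> np.ndarray:
    """Invert the natural-abundance convolution into label fractions.

    Normalizes the measured envelope to unit sum, then solves m @ f = v.
    The exact triangular solve is used when it returns no negative entry;
    otherwise non-negative least squares.  The result is clipped at zero
    and renormalized to sum 1.
    """
    raw = v.intensities
    total = raw.sum()
    if total <= 0:
        raise ValueError(f"{v.analyte_id}: all-zero intensity vector")
    if m.shape != (raw.size, raw.size):
        raise ValueError(
            f"correction matrix shape {m.shape} does not match vector length {raw.size}"
        )
    meas = raw / total
    f = linalg.solve_triangular(m, meas, lower=True)
    if np.any(f < 0):
        f, _ = optimize.nnls(m, meas)
    f = np.clip(f, 0.0, None)
    s = f.sum()
    if s <= 0:
        raise ValueError(f"{v.analyte_id}: correction produced a zero vector")
    return f / s


def labeling_ratio(fractions: Sequence[float]) -> LabelingRatios:
    """M+2/M+0 and (when K >= 4) M+4/M+0 from corrected fractions.

    A zero M+0 fraction makes the ratios undefined; they are reported as
    missing with a reason, never as infinity.
    """
    f = np.asarray(fractions, dtype=float)
    if f.size < 1:
        raise ValueError("fractions must be non-empty")
    if f[0] <= 0:
        return LabelingRatios(None, None, reason="M+0 fraction is zero")
    m2 = float(f[2] / f[0]) if f.size > 2 else None
    m4 = float(f[4] / f[0]) if f.size > 4 else None
    reason = None
    if m2 is None:
        reason = "fewer than 3 isotopologues: M+2/M+0 unavailable"
    elif m4 is None:
        reason = "fewer than 5 isotopologues: M+4/M+0 unavailable"
    return LabelingRatios(m2, m4, reason)


def correct_and_ratio(v: IsotopologueVector, p13c: float = P13C_NATURAL) -> FluxResult:
    """Convenience: build matrix, correct, and compute ratios for one analyte."""
    m = build_correction_matrix(v.n_carbons, p13c, size=v.k + 1)
    f = correct_natural_abundance(v, m)
    return FluxResult(v.analyte_id, f, labeling_ratio(f))


@dataclass(frozen=True)
class InternalStandardRule:
    """Maps a carbon-length range [min_carbons, max_carbons] to a standard."""

    min_carbons: int
    max_carbons: int
    standard_id: str

    def matches(self, carbons: int) -> bool:
        return self.min_carbons <= carbons <= self.max_carbons


# Default rule set (the GC-MS triple): C<=18 to palmitate-d31,
# C=20 to arachidonate-d8, C=22 to docosahexaenoate-d5.
GCMS_STANDARD_RULES: tuple[InternalStandardRule, ...] = (
    InternalStandardRule(0, 18, "FA(16:0 d31)"),
    InternalStandardRule(20, 20, "FA(20:4 d8)"),
    InternalStandardRule(22, 22, "FA(22:6 d5)"),
)

# Alternative triple (palmitate-d31, oleate-d5, arachidonate-d8) with
# length ranges assigned by proximity; selectable via configuration.
SOLVENT_STANDARD_RULES: tuple[InternalStandardRule, ...] = (
    InternalStandardRule(0, 16, "FA(16:0 d31)"),
    InternalStandardRule(17, 18, "FA(18:1 d5)"),
    InternalStandardRule(19, 22, "FA(20:4 d8)"),
)


def _validate_rules(rules: Sequence[InternalStandardRule]) -> None:
    for a in range(len(rules)):
        for b in range(a + 1, len(rules)):
            if rules[a].min_carbons <= rules[b].max_carbons and \
               rules[b].min_carbons <= rules[a].max_carbons:
                raise ValueError(
                    f"overlapping internal-standard rules: {rules[a]} and {rules[b]}"
                )


def normalize_to_internal_standard(
    rows: Sequence[tuple[str, int, float]],
    standards: Mapping[str, float],
    rules: Sequence[InternalStandardRule] = GCMS_STANDARD_RULES,
) -> list[tuple[str, float, bool]]:
    """Divide each analyte intensity by its carbon-length-matched standard.

    Parameters
    ----------
    rows
        (analyte_id, carbons, intensity) triples.
    standards
        Measured intensity per standard id; must be positive for every
        matched standard (zero rejects the sample).
    rules
        Disjoint carbon-length ranges mapping to standard ids.

    Returns
    -------
    list of (analyte_id, value, normalized_flag); analytes matched by no
    rule are passed through unnormalized with the flag False and a warning.
    """
    _validate_rules(rules)
    out = []
    for analyte_id, carbons, intensity in rows:
        rule = next((r for r in rules if r.matches(carbons)), None)
        if rule is None:
            warnings.warn(
                f"{analyte_id} (C{carbons}): no internal-standard rule; "
                "reported unnormalized",
                stacklevel=2,
            )
            out.append((analyte_id, float(intensity), False))
            continue
        std = standards.get(rule.standard_id)
        if std is None:
            raise ValueError(
                f"{analyte_id}: standard {rule.standard_id!r} not measured"
            )
        if std <= 0:
            raise ValueError(
                f"sample rejected: standard {rule.standard_id!r} intensity is "
                f"{std} (must be > 0)"
            )
        out.append((analyte_id, float(intensity) / float(std), True))
    return out
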