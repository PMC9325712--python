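"""Two-sample testing, two-stage adaptive FDR, volcano tables, H-score.

Per-feature differential testing follows the "multiple t-tests followed by
FDR" convention: an unpaired two-tailed t-test per feature (pooled-variance
Student's t by default, Welch selectable), then the Benjamini-Krieger-
Yekutieli two-stage adaptive linear step-up procedure.

The two-stage procedure at level q:

1. stage 1: Benjamini-Hochberg step-up at q' = q / (1 + q), giving r1
   rejections;
2. if r1 = 0 reject nothing; if r1 = m reject everything;
3. stage 2: Benjamini-Hochberg step-up at level q' * m / (m - r1).

Adjusted values invert the step-up rule monotonically, so that a feature is
rejected iff its adjusted value is <= q; note they therefore depend on q
(the procedure is adaptive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "two_sample_t",
    "two_sample_t_matrix",
    "bky_two_stage_fdr",
    "BkyResult",
    "volcano_table",
    "differential_table",
    "h_score",
]


def two_sample_t(x, y, variant: str = "pooled") -> tuple[float, float]:
    """Unpaired two-tailed t-test; returns (t, p).

    ``variant="pooled"`` is the classic equal-variance Student's t;
    ``"welch"`` uses the Welch-Satterthwaite correction.  Both groups need
    n >= 2.  If both groups have zero variance and equal means the result
    is (0, 1) by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError(f"each group needs n >= 2 (got {x.size}, {y.size})")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if variant not in {"pooled", "welch"}:
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        t = np.inf if x.mean() > y.mean() else -np.inf
        return float(t), 0.0
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.pvalue)


def two_sample_t_matrix(x: np.ndarray, y: np.ndarray,
                        variant: str = "pooled") -> tuple[np.ndarray, np.ndarray]:
    """Row-wise t-tests for feature x sample matrices; returns (t, p) arrays.

    Degenerate rows (zero variance in both groups) get t = 0, p = 1 when the
    means agree and p = 0 otherwise.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[1] < 2 or y.shape[1] < 2:
        raise ValueError("each group needs n >= 2")
    res = sps.ttest_ind(x, y, axis=1, equal_var=(variant == "pooled"))
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    flat = (x.var(axis=1, ddof=1) == 0) & (y.var(axis=1, ddof=1) == 0)
    equal = flat & (x.mean(axis=1) == y.mean(axis=1))
    t[equal] = 0.0
    p[equal] = 1.0
    unequal = flat & ~equal
    t[unequal] = np.where(x.mean(axis=1)[unequal] > y.mean(axis=1)[unequal],
                          np.inf, -np.inf)
    p[unequal] = 0.0
    return t, p


def _bh_rejections(p_sorted: np.ndarray, level: float) -> int:
    """Number of rejections of the linear step-up rule at a given level."""
    m = p_sorted.size
    thresh = level * np.arange(1, m + 1) / m
    passing = np.nonzero(p_sorted <= thresh)[0]
    return int(passing[-1] + 1) if passing.size else 0


@dataclass(frozen=True)
class BkyResult:
    adjusted: np.ndarray  # adjusted values, original order
    rejected: np.ndarray  # boolean mask, original order
    r1: int  # stage-1 rejection count
    stage2_level: float  # effective BH level used in stage 2


def bky_two_stage_fdr(p, q: float = 0.05) -> BkyResult:
    """Two-stage adaptive linear step-up FDR procedure at level q.

    Returns adjusted values (monotone in p; rejected iff adjusted <= q),
    the rejection mask, and the stage bookkeeping.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    m = p.size
    q1 = q / (1.0 + q)
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    r1 = _bh_rejections(p_sorted, q1)
    m0 = m - r1  # estimated number of true nulls
    stage2_level = q1 * m / m0 if m0 > 0 else np.inf
    # adjusted value construction: stage-2 threshold is
    #   p_(i) <= i * q / ((1 + q) * m0)
    # so adj_(i) = min over j >= i of p_(j) * (1 + q) * m0 / j, clipped to 1.
    # r1 = 0 and r1 = m reduce to "reject nothing" / "reject everything"
    # consistently (m0 = m reproduces stage 1; m0 = 0 gives adj = 0).
    ranks = np.arange(1, m + 1)
    raw = p_sorted * (1.0 + q) * m0 / ranks
    adj_sorted = np.minimum(np.minimum.accumulate(raw[::-1])[::-1], 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    rejected = adjusted <= q
    return BkyResult(adjusted, rejected, r1, float(stage2_level))


def volcano_table(
    logfc: pd.Series,
    qvals: pd.Series,
    cutoff: float = 0.05,
    rejected: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble a volcano table (logFC, -log10 q, significance flag).

    Feature sets must match exactly; a mismatch is rejected with the
    symmetric difference listed.  q = 0 is clamped to the smallest positive
    normal float for the -log10 display and flagged in the ``q_clamped``
    column.  By default significance is the strict cutoff ``q < cutoff``;
    passing the procedure's rejection mask overrides it.
    """
    a, b = set(logfc.index), set(qvals.index)
    if a != b:
        raise ValueError(
            f"feature sets differ; symmetric difference: {sorted(a ^ b)}"
        )
    features = sorted(a)
    q = qvals.loc[features].astype(float)
    tiny = np.finfo(float).tiny
    clamped = q <= 0
    q_disp = q.where(~clamped, tiny)
    if rejected is not None:
        significant = rejected.loc[features].astype(bool)
    else:
        significant = q < cutoff
    return pd.DataFrame(
        {
            "feature": features,
            "logFC": logfc.loc[features].astype(float).values,
            "q": q.values,
            "neg_log10_q": -np.log10(q_disp.values),
            "q_clamped": clamped.values,
            "significant": significant.values,
        }
    ).set_index("feature")


def differential_table(
    values: pd.DataFrame,
    group_a_cols: list[str],
    group_b_cols: list[str],
    q: float = 0.05,
    variant: str = "pooled",
    log_transform: bool = True,
    pseudo: float | None = None,
) -> pd.DataFrame:
    """Feature-wise t-tests (A vs B) with two-stage FDR and log2 fold-changes.

    ``log_transform`` tests log2(value + pseudo) (species-level default);
    pass False to test on the provided scale (e.g. class fractions).
    """
    x = values[group_a_cols].to_numpy(dtype=float)
    y = values[group_b_cols].to_numpy(dtype=float)
    if pseudo is None:
        nz = np.concatenate([x[x > 0], y[y > 0]])
        pseudo = float(nz.min()) / 2.0 if nz.size else 1e-12
    lfc = np.log2((x.mean(axis=1) + pseudo) / (y.mean(axis=1) + pseudo))
    if log_transform:
        x = np.log2(x + pseudo)
        y = np.log2(y + pseudo)
    t, p = two_sample_t_matrix(x, y, variant=variant)
    res = bky_two_stage_fdr(p, q=q)
    return pd.DataFrame(
        {
            "logFC": lfc,
            "t": t,
            "p": p,
            "q": res.adjusted,
            "significant": res.rejected,
        },
        index=values.index,
    )


def h_score(grade: int, percent_positive: float) -> float:
    """Immunoreactivity score: staining grade (0-3) x percent positive (0-100).

    Grade 0 is no staining, 1 weak, 2 moderate, 3 strong; the score spans
    0-300 and is exactly bilinear in its arguments.
    """
    if int(grade) != grade or grade not in (0, 1, 2, 3):
        raise ValueError(f"grade must be an integer in {{0,1,2,3}}, got {grade!r}")
    if not 0 <= percent_positive <= 100:
        raise ValueError(
            f"percent_positive must be in [0, 100], got {percent_positive!r}"
        )
    return float(grade) * float(percent_positive)
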