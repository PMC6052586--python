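"""Outcome measures and hypothesis tests for refractive prediction error.

The refractive prediction error is the postoperative spherical
equivalent minus the formula-predicted refraction (positive = hyperopic
surprise). Summaries follow the clinical reporting convention: MAE and
MedAE of the absolute errors, interquartile range, and the percentage of
eyes within ±0.25/±0.50/±0.75/±1.00 D. Group comparisons use the
Mann–Whitney U test on absolute errors, the 2x2 chi-square on threshold
splits, Student's two-sample t-test, and the squared Pearson correlation
for interocular agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import stats

DEFAULT_THRESHOLDS = (0.25, 0.50, 0.75, 1.00)


@dataclass(frozen=True)
class ErrorSummary:
    """Summary statistics of one set of refractive prediction errors."""

    n: int
    mean_error: float
    mae: float
    medae: float
    iqr: Tuple[float, float]          # 25th/75th percentile of |error|
    range: Tuple[float, float]        # min/max of signed error
    pct_within: Dict[float, float]    # threshold (D) -> percentage
    counts_within: Dict[float, int]   # threshold (D) -> eye count


def prediction_error(postop_se: float, predicted: float) -> float:
    """Signed refractive prediction error, D (postop SE - predicted)."""
    return postop_se - predicted


def summarize(
    errors: Sequence[float], thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> ErrorSummary:
    """Summarize signed errors: MAE, MedAE, IQR, threshold percentages.

    The median uses the midpoint-of-middle-two convention for even n and
    quartiles use linear interpolation. ``|error| <= threshold`` counts
    as within.
    """
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("cannot summarize an empty error set")
    if not np.all(np.isfinite(e)):
        raise ValueError("errors must be finite")
    a = np.abs(e)
    q25, q75 = np.percentile(a, [25.0, 75.0])
    counts = {float(t): int(np.sum(a <= t)) for t in thresholds}
    pct = {t: 100.0 * c / e.size for t, c in counts.items()}
    return ErrorSummary(
        n=int(e.size),
        mean_error=float(e.mean()),
        mae=float(a.mean()),
        medae=float(np.median(a)),
        iqr=(float(q25), float(q75)),
        range=(float(e.min()), float(e.max())),
        pct_within=pct,
        counts_within=counts,
    )


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U of x, p).

    Uses exact enumeration of the U null distribution when
    n1*n2 <= 400 and there are no ties, otherwise the tie-corrected
    normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(
    a: int, b: int, c: int, d: int, yates: bool = False
) -> Tuple[float, float]:
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]], 1 df.

    Without continuity correction by default; ``yates=True`` applies the
    Yates correction. Raises on a zero row or column marginal.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    if n < 1:
        raise ValueError("table total must be at least 1")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero marginal: chi-square undefined")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    stat = n * diff * diff / (r1 * r2 * c1 * c2)
    return float(stat), float(stats.chi2.sf(stat, df=1))


def student_t(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Student's two-sample t-test (pooled variance), two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per sample")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        return 0.0, 1.0  # degenerate identical constants
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation of paired samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need paired samples of equal length >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate variance: correlation undefined")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)
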