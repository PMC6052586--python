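"""Data-adjusted lens-constant optimization.

Both procedures target the standard clinical criterion: after
adjustment, the cohort's mean signed refractive prediction error is
zero.

SRK/T: the A-constant is a single scalar, so the criterion defines a
one-dimensional root problem — mean error is monotone in A — solved by
a bracketed search.

Haigis: for each eye the effective lens position (ELP) that exactly
reproduces the observed postoperative refraction is back-solved from the
vergence equation; ordinary least squares of those ELPs on (ACD, AL)
gives the slopes a1, a2 and intercept a0. The intercept is then shifted
so the mean prediction error is exactly zero (the regression minimizes
squared ELP residuals, which is not identical to zero mean dioptric
error; the raw intercept is kept in the diagnostics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy.optimize import brentq

from . import formula_engine as fe
from .types import BracketError, EyeBiometry, FormulaName, IOLModel

ELP_BOUNDS = (0.5, 9.0)      # physically plausible pseudophakic ELP, mm
A_CONSTANT_BRACKET = (100.0, 130.0)


@dataclass(frozen=True)
class OptimizationResult:
    """Fitted constants plus the diagnostics that justify them."""

    constants: Dict[str, float]
    mean_error_after: float
    per_eye_elp: Optional[np.ndarray] = None
    diagnostics: Dict[str, float] = field(default_factory=dict)


def _require_outcomes(cohort: Sequence[EyeBiometry]) -> None:
    missing = [
        f"{e.patient_id}/{e.laterality}"
        for e in cohort
        if e.implanted_power is None or e.postop_se is None
    ]
    if missing:
        raise ValueError(
            "implanted_power and postop_se required for every eye; missing "
            f"for: {', '.join(missing)}"
        )


def back_solve_elp(
    eye: EyeBiometry,
    implanted_power: Optional[float] = None,
    postop_se: Optional[float] = None,
    vertex: float = fe.DEFAULT_VERTEX_MM,
    corneal_index: float = fe.HAIGIS_CORNEAL_INDEX,
) -> float:
    """ELP (mm) at which the implanted power reproduces the observed SE.

    Solves the Haigis vergence equation for the lens position d given
    the labeled power and postoperative spherical equivalent. Refraction
    is strictly monotone in d on the physical range, so a Brent search
    on (0.5, 9.0) mm suffices; absence of a sign change is reported.
    """
    power = eye.implanted_power if implanted_power is None else implanted_power
    se = eye.postop_se if postop_se is None else postop_se
    if power is None or se is None:
        raise ValueError("implanted_power and postop_se are required")

    def f(d: float) -> float:
        return (
            fe.haigis_refraction_at_elp(
                eye.K, eye.AL, d, power, vertex=vertex, corneal_index=corneal_index
            )
            - se
        )

    lo, hi = ELP_BOUNDS
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise BracketError(
            f"no ELP in {ELP_BOUNDS} mm reproduces SE {se} D at power "
            f"{power} D (eye {eye.patient_id}/{eye.laterality})"
        )
    return float(brentq(f, lo, hi, xtol=1e-10, maxiter=200))


def _haigis_mean_error(
    cohort: Sequence[EyeBiometry],
    a0: float,
    a1: float,
    a2: float,
    vertex: float,
    corneal_index: float,
) -> float:
    errs = [
        e.postop_se
        - fe.haigis_refraction(
            e.K, e.ACD, e.AL, a0, a1, a2, e.implanted_power,
            vertex=vertex, corneal_index=corneal_index,
        )
        for e in cohort
    ]
    return float(np.mean(errs))


def optimize_haigis(
    cohort: Sequence[EyeBiometry],
    vertex: float = fe.DEFAULT_VERTEX_MM,
    corneal_index: float = fe.HAIGIS_CORNEAL_INDEX,
) -> OptimizationResult:
    """Fit data-adjusted Haigis (a0, a1, a2) on a cohort.

    Requires >= 3 eyes with implanted power and postoperative SE and a
    non-collinear (ACD, AL) design.
    """
    _require_outcomes(cohort)
    if len(cohort) < 3:
        raise ValueError("need at least 3 eyes to fit three constants")
    elp = np.array(
        [back_solve_elp(e, vertex=vertex, corneal_index=corneal_index) for e in cohort]
    )
    X = sm.add_constant(
        np.column_stack([[e.ACD for e in cohort], [e.AL for e in cohort]])
    )
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("singular design matrix: (ACD, AL) are collinear")
    fit = sm.OLS(elp, X).fit()
    a0_raw, a1, a2 = (float(v) for v in fit.params)

    # Shift the intercept so the cohort mean dioptric error is zero.
    def g(delta: float) -> float:
        return _haigis_mean_error(
            cohort, a0_raw + delta, a1, a2, vertex, corneal_index
        )

    lo, hi = -3.0, 3.0
    if g(lo) * g(hi) > 0:
        raise BracketError("zero-mean-error shift not bracketed in ±3 mm")
    delta = float(brentq(g, lo, hi, xtol=1e-12, maxiter=200))
    a0 = a0_raw + delta
    mean_after = _haigis_mean_error(cohort, a0, a1, a2, vertex, corneal_index)
    return OptimizationResult(
        constants={"a0": a0, "a1": a1, "a2": a2},
        mean_error_after=mean_after,
        per_eye_elp=elp,
        diagnostics={
            "a0_raw_intercept": a0_raw,
            "a0_shift": delta,
            "elp_residual_sd": float(np.std(fit.resid, ddof=3))
            if len(cohort) > 3
            else 0.0,
            "r_squared": float(fit.rsquared),
        },
    )


def optimize_a_constant(
    cohort: Sequence[EyeBiometry],
    initial_a: float = 118.0,
    vertex: float = fe.DEFAULT_VERTEX_MM,
) -> OptimizationResult:
    """SRK/T A-constant giving zero cohort mean prediction error.

    The mean error is strictly monotone in A (a larger A moves the ELP
    posteriorly, making every predicted refraction more hyperopic and
    thus the mean error smaller), so the root in [100, 130] is unique;
    ``initial_a`` is recorded for provenance.
    """
    _require_outcomes(cohort)
    if len(cohort) < 1:
        raise ValueError("need at least one eye")

    def mean_err(a: float) -> float:
        return float(
            np.mean(
                [
                    e.postop_se
                    - fe.srkt_refraction(e.K, e.AL, a, e.implanted_power, vertex)
                    for e in cohort
                ]
            )
        )

    lo, hi = A_CONSTANT_BRACKET
    flo, fhi = mean_err(lo), mean_err(hi)
    if flo * fhi > 0:
        raise BracketError(
            f"no zero-mean-error A-constant in [{lo}, {hi}]"
        )
    a_star = float(brentq(mean_err, lo, hi, xtol=1e-8, maxiter=200))
    return OptimizationResult(
        constants={"a_constant": a_star},
        mean_error_after=mean_err(a_star),
        diagnostics={"initial_a": float(initial_a)},
    )
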