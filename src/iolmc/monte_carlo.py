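"""Monte Carlo propagation of IOL manufacturing power error.

The study design isolates the manufacturing tolerance: IOL power is the
only random variable. For each eye the anchor is the continuous power
with zero refractive prediction error — back-solved from the eye's
biometry and observed postoperative spherical equivalent — so that,
before perturbation, every error is identically zero and no biometry,
ELP-estimation or measurement error leaks into the simulation. Each
replicate then draws one Gaussian power per eye (mean = zero-error
power, SD = the lens's tolerance) and records the induced refraction
shift at the spectacle plane:

    error_i = f(P_drawn_i) - f(P_zero_i)

where f is the formula's predicted refraction for eye i. Since
f(P_zero) equals the observed postoperative SE by construction, this is
the usual "postoperative SE minus predicted refraction" with the drawn
power playing the implanted lens.

Drawn powers are deliberately NOT re-rounded to the labeling grid:
manufacturing error is a continuous deviation from the label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import formula_engine as fe
from .outcome_statistics import DEFAULT_THRESHOLDS, ErrorSummary, summarize
from .types import EyeBiometry, FormulaName, IOLModel


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one Monte Carlo study (one formula, one lens group)."""

    formula: FormulaName
    tolerance_sd: float
    n_replicates: int = 10
    seed: int = 0
    thresholds: Tuple[float, ...] = DEFAULT_THRESHOLDS
    uniform_within_limits: bool = False  # sensitivity mode: U(-sd, +sd)

    def __post_init__(self) -> None:
        if self.tolerance_sd < 0:
            raise ValueError("tolerance_sd must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")


@dataclass(frozen=True)
class SimulationResult:
    """Per-replicate summaries and per-eye errors, plus aggregates."""

    config: SimulationConfig
    zero_powers: np.ndarray          # (n_eyes,)
    drawn_powers: np.ndarray         # (n_replicates, n_eyes)
    errors: np.ndarray               # (n_replicates, n_eyes), D
    replicates: List[ErrorSummary]
    aggregate: Dict[str, object] = field(default_factory=dict)


def zero_error_powers(
    cohort: Sequence[EyeBiometry], formula: FormulaName, lens: IOLModel
) -> np.ndarray:
    """Continuous zero-prediction-error power for every eye, D."""
    missing = [
        f"{e.patient_id}/{e.laterality}" for e in cohort if e.postop_se is None
    ]
    if missing:
        raise ValueError(f"postop_se required for: {', '.join(missing)}")
    return np.array(
        [fe.power_for_target(formula, e, lens, e.postop_se) for e in cohort]
    )


def draw_powers(
    mean_powers: Sequence[float],
    tolerance_sd: float,
    rng: np.random.Generator,
    uniform_within_limits: bool = False,
) -> np.ndarray:
    """One perturbed power per eye.

    Gaussian with SD ``tolerance_sd`` by default; the uniform mode draws
    U(-tolerance_sd, +tolerance_sd) for treating the figure as a hard
    tolerance limit instead of an SD.
    """
    mean_powers = np.asarray(mean_powers, dtype=float)
    if tolerance_sd < 0:
        raise ValueError("tolerance_sd must be non-negative")
    if uniform_within_limits:
        return mean_powers + rng.uniform(-tolerance_sd, tolerance_sd, mean_powers.size)
    return mean_powers + tolerance_sd * rng.standard_normal(mean_powers.size)


def replicate_errors(
    cohort: Sequence[EyeBiometry],
    formula: FormulaName,
    lens: IOLModel,
    tolerance_sd: float,
    rng: np.random.Generator,
    zero_powers: Optional[np.ndarray] = None,
    uniform_within_limits: bool = False,
) -> np.ndarray:
    """Refractive prediction errors (D) for one replicate, one per eye."""
    if zero_powers is None:
        zero_powers = zero_error_powers(cohort, formula, lens)
    drawn = draw_powers(zero_powers, tolerance_sd, rng, uniform_within_limits)
    return _errors_from_powers(cohort, formula, lens, zero_powers, drawn)


def _errors_from_powers(
    cohort: Sequence[EyeBiometry],
    formula: FormulaName,
    lens: IOLModel,
    zero_powers: np.ndarray,
    drawn_powers: np.ndarray,
) -> np.ndarray:
    return np.array(
        [
            fe.predict_refraction(formula, e, lens, pd)
            - fe.predict_refraction(formula, e, lens, pz)
            for e, pz, pd in zip(cohort, zero_powers, drawn_powers)
        ]
    )


def run_study(
    cohort: Sequence[EyeBiometry],
    config: SimulationConfig,
    lens: IOLModel,
) -> SimulationResult:
    """Run the full replicate study for one formula and lens group.

    One root seed sequence per study; each replicate draws from its own
    deterministically spawned substream, so replicate r is reproducible
    independently of how many replicates run.
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 eyes")
    zero = zero_error_powers(cohort, config.formula, lens)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    drawn_all = np.empty((config.n_replicates, len(cohort)))
    errors_all = np.empty_like(drawn_all)
    summaries: List[ErrorSummary] = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        drawn = draw_powers(
            zero, config.tolerance_sd, rng, config.uniform_within_limits
        )
        errs = _errors_from_powers(cohort, config.formula, lens, zero, drawn)
        drawn_all[i] = drawn
        errors_all[i] = errs
        summaries.append(summarize(errs, config.thresholds))

    medae = np.array([s.medae for s in summaries])
    pooled = summarize(errors_all.ravel(), config.thresholds)
    aggregate: Dict[str, object] = {
        "medae": {
            "min": float(medae.min()),
            "max": float(medae.max()),
            "grand_median": float(np.median(medae)),
        },
        "pct_within": {
            t: {
                "min": float(min(s.pct_within[t] for s in summaries)),
                "max": float(max(s.pct_within[t] for s in summaries)),
                "grand_median": float(
                    np.median([s.pct_within[t] for s in summaries])
                ),
                "pooled": pooled.pct_within[t],
            }
            for t in (float(t) for t in config.thresholds)
        },
        "seed": config.seed,
    }
    return SimulationResult(
        config=config,
        zero_powers=zero,
        drawn_powers=drawn_all,
        errors=errors_all,
        replicates=summaries,
        aggregate=aggregate,
    )
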