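"""SRK/T and Haigis vergence engines.

Both formulas model the pseudophakic eye as a two-lens system (cornea +
intraocular lens) in aqueous/vitreous of refractive index n = 1.336 and
return the predicted spectacle-plane spherical equivalent for a given
IOL power, or invert that relation to find the power that achieves a
target refraction.

SRK/T follows the published theoretic formula with its errata: the
corneal radius is recovered from keratometry via the 1.3375 keratometric
index (r = 337.5/K), the effective lens position (ELP) is the corneal
dome height plus an A-constant-derived offset, long eyes have their
axial length quadratically corrected, and a retinal-thickness term is
added to the optical axial length.

Haigis places the lens at ELP d = a0 + a1*ACD + a2*AL and runs a thin-
lens vergence chain spectacle -> cornea -> IOL -> retina. The corneal
power uses the corneal index 1.3315 on the 337.5/K radius (the original
publication's convention; the 1.3375 keratometric variant can be
selected via ``corneal_index``).

The refraction is strictly decreasing in IOL power for physical eyes,
so the inverse map is found by a bracketed Brent search.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

from scipy.optimize import brentq

from .types import (
    AL_BOUNDS,
    BracketError,
    DomainError,
    EyeBiometry,
    FormulaName,
    IOLModel,
    SrktIntermediates,
)

NA = 1.336                     # aqueous/vitreous refractive index
NC_SRKT = 1.333                # SRK/T corneal index
NCM1_SRKT = NC_SRKT - 1.0
HAIGIS_CORNEAL_INDEX = 1.3315  # original Haigis corneal index
DEFAULT_VERTEX_MM = 12.0
POWER_BRACKET = (-10.0, 40.0)  # D, search interval for inversions


def corneal_radius(K: float) -> float:
    """Corneal radius of curvature in mm from mean keratometry in D.

    Undoes the 1.3375 keratometric index: r = 337.5 / K.
    """
    if K <= 0:
        raise DomainError(f"keratometry must be positive, got {K}")
    return 337.5 / K


def srkt_intermediates(eye: EyeBiometry, a_constant: float) -> SrktIntermediates:
    """Compute the SRK/T intermediate quantities for one eye.

    Long eyes (AL > 24.2 mm) get the quadratic axial-length correction;
    a negative square-root argument in the corneal-height step (very
    steep, small cornea) is clamped to zero per the published errata.
    """
    if eye.K <= 0:
        raise DomainError("K must be positive")
    if not (AL_BOUNDS[0] <= eye.AL <= AL_BOUNDS[1]):
        raise DomainError(f"AL={eye.AL} outside {AL_BOUNDS}")
    r = corneal_radius(eye.K)
    al = eye.AL
    lcor = al if al <= 24.2 else -3.446 + 1.716 * al - 0.0237 * al * al
    cw = -5.41 + 0.58412 * lcor + 0.098 * eye.K
    h = r - math.sqrt(max(r * r - cw * cw / 4.0, 0.0))
    acd_const = 0.62467 * a_constant - 68.747
    offset = acd_const - 3.336
    acd_est = h + offset
    lopt = al + (0.65696 - 0.02029 * al)
    return SrktIntermediates(
        r=r, lcor=lcor, cw=cw, h=h, offset=offset, acd_est=acd_est, lopt=lopt
    )


def srkt_refraction(
    K: float,
    AL: float,
    a_constant: float,
    iol_power: float,
    vertex: float = DEFAULT_VERTEX_MM,
) -> float:
    """Predicted spectacle refraction (D) under SRK/T.

    Direct evaluation of the published refraction form with optical
    axial length L, estimated ELP C and corneal radius r (all mm).
    """
    # EyeBiometry is not required here so the optimizers can sweep
    # constants over raw numbers; domain checks mirror the dataclass.
    inter = srkt_intermediates(
        EyeBiometry("_", "OD", K=K, ACD=3.0, AL=AL), a_constant
    )
    r, L, C = inter.r, inter.lopt, inter.acd_est
    P = iol_power
    num = 1000.0 * NA * (NA * r - NCM1_SRKT * L) - P * (L - C) * (
        NA * r - NCM1_SRKT * C
    )
    den = NA * (vertex * (NA * r - NCM1_SRKT * L) + L * r) - 0.001 * P * (
        L - C
    ) * (vertex * (NA * r - NCM1_SRKT * C) + C * r)
    if abs(den) < 1e-9:
        raise DomainError("singular denominator in SRK/T refraction")
    return num / den


def haigis_elp(eye: EyeBiometry, lens: IOLModel) -> float:
    """Haigis effective lens position d = a0 + a1*ACD + a2*AL, mm."""
    return lens.haigis_a0 + lens.haigis_a1 * eye.ACD + lens.haigis_a2 * eye.AL


def haigis_refraction_at_elp(
    K: float,
    AL: float,
    elp: float,
    iol_power: float,
    vertex: float = DEFAULT_VERTEX_MM,
    corneal_index: float = HAIGIS_CORNEAL_INDEX,
) -> float:
    """Predicted spectacle refraction (D) for a lens at a given ELP.

    Thin-lens vergence chain run backwards from the retina: the vergence
    required just behind the IOL is n/(AL - d); subtracting the IOL
    power and back-propagating through d of aqueous and the cornea gives
    the corneal-plane refraction, translated to the spectacle plane at
    the stated vertex distance.
    """
    if elp >= AL:
        raise DomainError(f"ELP {elp} mm not anterior to retina (AL {AL} mm)")
    dc = (corneal_index - 1.0) * 1000.0 / corneal_radius(K)  # corneal power, D
    v3 = 1000.0 * NA / (AL - elp)          # vergence leaving the IOL
    v2 = v3 - iol_power                    # vergence arriving at the IOL
    den = 1.0 + (elp / 1000.0 / NA) * v2
    if abs(den) < 1e-12:
        raise DomainError("singular denominator in Haigis vergence chain")
    v1 = v2 / den                          # vergence leaving the cornea
    rc = v1 - dc                           # corneal-plane refraction
    den2 = 1.0 + (vertex / 1000.0) * rc
    if abs(den2) < 1e-12:
        raise DomainError("singular spectacle-plane translation")
    return rc / den2


def haigis_refraction(
    K: float,
    ACD: float,
    AL: float,
    a0: float,
    a1: float,
    a2: float,
    iol_power: float,
    vertex: float = DEFAULT_VERTEX_MM,
    corneal_index: float = HAIGIS_CORNEAL_INDEX,
) -> float:
    """Predicted spectacle refraction (D) under Haigis."""
    elp = a0 + a1 * ACD + a2 * AL
    return haigis_refraction_at_elp(
        K, AL, elp, iol_power, vertex=vertex, corneal_index=corneal_index
    )


def predict_refraction(
    formula: FormulaName,
    eye: EyeBiometry,
    lens: IOLModel,
    iol_power: float,
    vertex: float = DEFAULT_VERTEX_MM,
    corneal_index: float = HAIGIS_CORNEAL_INDEX,
) -> float:
    """Spectacle-plane spherical equivalent predicted for ``iol_power``."""
    if not math.isfinite(iol_power):
        raise DomainError("iol_power must be finite")
    formula = FormulaName(formula)
    if formula is FormulaName.SRKT:
        return srkt_refraction(eye.K, eye.AL, lens.a_constant, iol_power, vertex)
    return haigis_refraction(
        eye.K,
        eye.ACD,
        eye.AL,
        lens.haigis_a0,
        lens.haigis_a1,
        lens.haigis_a2,
        iol_power,
        vertex=vertex,
        corneal_index=corneal_index,
    )


def power_for_target(
    formula: FormulaName,
    eye: EyeBiometry,
    lens: IOLModel,
    target_refraction: float,
    vertex: float = DEFAULT_VERTEX_MM,
    corneal_index: float = HAIGIS_CORNEAL_INDEX,
    bracket: Tuple[float, float] = POWER_BRACKET,
) -> float:
    """Continuous IOL power achieving ``target_refraction`` exactly.

    With the target set to the observed postoperative spherical
    equivalent this is the zero-prediction-error power; with the planned
    refraction it is surgical power selection (before grid rounding).
    """

    def f(power: float) -> float:
        return (
            predict_refraction(
                formula, eye, lens, power, vertex=vertex, corneal_index=corneal_index
            )
            - target_refraction
        )

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        raise BracketError(
            f"no zero-error power in [{lo}, {hi}] D for target "
            f"{target_refraction} D (eye {eye.patient_id}/{eye.laterality})"
        )
    return float(brentq(f, lo, hi, xtol=1e-10, maxiter=200))


def emmetropia_power(
    formula: FormulaName, eye: EyeBiometry, lens: IOLModel, **kwargs
) -> float:
    """Continuous power producing a 0.00 D spectacle refraction."""
    return power_for_target(formula, eye, lens, 0.0, **kwargs)


def round_to_grid(power: float, lens: IOLModel) -> float:
    """Nearest labeled power on the lens grid, clamped to its range.

    Exact half-interval ties round toward the lower power (the myopia-
    favoring surgical convention).
    """
    if not math.isfinite(power):
        raise DomainError("power must be finite")
    step = lens.interval
    snapped = math.ceil(power / step - 0.5) * step
    snapped = min(max(snapped, lens.power_min), lens.power_max)
    # kill 20.750000000000004-style representation noise
    return round(snapped, 10)
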