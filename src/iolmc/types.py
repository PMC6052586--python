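"""Core domain types: per-eye biometry, lens models, formula names.

Units follow clinical convention throughout: dioptric powers and
refractions in diopters (D), distances (axial length, anterior chamber
depth, effective lens position, corneal radius, vertex) in millimeters.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional


class FormulaName(str, Enum):
    """The two vergence formulas implemented here."""

    SRKT = "srkt"
    HAIGIS = "haigis"


class DomainError(ValueError):
    """An input lies outside the physical/optical domain of a formula."""


class BracketError(RuntimeError):
    """A bracketed root search found no sign change on its interval."""


# Plausibility bounds for optical biometry of adult cataract eyes.
K_BOUNDS = (30.0, 60.0)    # mean keratometry, D
ACD_BOUNDS = (1.5, 5.0)    # anterior chamber depth, mm
AL_BOUNDS = (18.0, 32.0)   # axial length, mm

LATERALITIES = ("OD", "OS")


@dataclass(frozen=True)
class EyeBiometry:
    """One eye's preoperative biometry plus (optionally) surgical facts.

    Parameters
    ----------
    patient_id : opaque patient identifier.
    laterality : "OD" (right) or "OS" (left).
    K : mean keratometry, D.
    ACD : anterior chamber depth, epithelium to lens, mm.
    AL : axial length, mm.
    implanted_power : labeled power of the implanted lens, D (optional).
    postop_se : postoperative spherical equivalent, D (optional).
    preop_se : preoperative spherical equivalent, D (optional, descriptive).
    """

    patient_id: str
    laterality: str
    K: float
    ACD: float
    AL: float
    implanted_power: Optional[float] = None
    postop_se: Optional[float] = None
    preop_se: Optional[float] = None

    def __post_init__(self) -> None:
        if self.laterality not in LATERALITIES:
            raise DomainError(
                f"laterality must be one of {LATERALITIES}, got {self.laterality!r}"
            )
        for name, value, (lo, hi) in (
            ("K", self.K, K_BOUNDS),
            ("ACD", self.ACD, ACD_BOUNDS),
            ("AL", self.AL, AL_BOUNDS),
        ):
            if not (lo <= value <= hi):
                raise DomainError(
                    f"{name}={value} outside plausible range [{lo}, {hi}] "
                    f"for eye {self.patient_id}/{self.laterality}"
                )


@dataclass(frozen=True)
class IOLModel:
    """A lens product: diopter grid, manufacturing tolerance, constants.

    ``tolerance_sd`` is the standard deviation of the true-minus-labeled
    dioptric power, D. ``interval`` is the labeling grid step (0.25 or
    0.50 D in the products modeled here). ``a_constant`` feeds SRK/T;
    the ``haigis_a0/a1/a2`` triple parameterizes the Haigis effective
    lens position d = a0 + a1*ACD + a2*AL (mm).
    """

    name: str
    interval: float
    tolerance_sd: float
    a_constant: float
    haigis_a0: float
    haigis_a1: float
    haigis_a2: float
    power_min: float
    power_max: float

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        if self.tolerance_sd < 0:
            raise ValueError("tolerance_sd must be non-negative")
        if not self.power_min < self.power_max:
            raise ValueError("power_min must be below power_max")


@dataclass(frozen=True)
class SrktIntermediates:
    """Intermediate quantities of the SRK/T formula (all mm)."""

    r: float        # corneal radius, 337.5/K
    lcor: float     # corrected axial length for long eyes
    cw: float       # computed corneal width
    h: float        # corneal dome height
    offset: float   # A-constant-derived ELP offset
    acd_est: float  # estimated postoperative ELP (ACDest)
    lopt: float     # optical axial length (AL + retinal thickness term)
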