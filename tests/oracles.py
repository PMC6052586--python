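"""Independent line-by-line transcriptions of the published formulas.

These oracles are kept deliberately separate from the package: each
function is a flat, sequential transcription of the published equation
set, sharing no code with ``iolmc``, so that agreement between the two
routes is a meaningful check. A plain bisection root-finder provides
the brute-force inverse.
"""

import math


def srkt_refraction_oracle(K, AL, A, P, V=12.0):
    """Spectacle refraction under SRK/T, transcribed equation by equation."""
    na = 1.336
    ncm1 = 1.333 - 1.0
    r = 337.5 / K
    if AL > 24.2:
        LCOR = -3.446 + 1.716 * AL - 0.0237 * AL ** 2
    else:
        LCOR = AL
    Cw = -5.41 + 0.58412 * LCOR + 0.098 * K
    sq = r ** 2 - (Cw ** 2) / 4.0
    if sq < 0.0:
        sq = 0.0
    H = r - math.sqrt(sq)
    ACDconst = 0.62467 * A - 68.747
    offset = ACDconst - 3.336
    C = H + offset
    RETHICK = 0.65696 - 0.02029 * AL
    L = AL + RETHICK
    numerator = 1000.0 * na * (na * r - ncm1 * L) - P * (L - C) * (na * r - ncm1 * C)
    denominator = na * (V * (na * r - ncm1 * L) + L * r) - 0.001 * P * (L - C) * (
        V * (na * r - ncm1 * C) + C * r
    )
    return numerator / denominator


def srkt_intermediates_oracle(K, AL, A):
    """The SRK/T intermediate chain as a plain dict (all mm)."""
    r = 337.5 / K
    if AL > 24.2:
        LCOR = -3.446 + 1.716 * AL - 0.0237 * AL ** 2
    else:
        LCOR = AL
    Cw = -5.41 + 0.58412 * LCOR + 0.098 * K
    sq = r ** 2 - (Cw ** 2) / 4.0
    if sq < 0.0:
        sq = 0.0
    H = r - math.sqrt(sq)
    ACDconst = 0.62467 * A - 68.747
    offset = ACDconst - 3.336
    return {
        "r": r,
        "lcor": LCOR,
        "cw": Cw,
        "h": H,
        "offset": offset,
        "acd_est": H + offset,
        "lopt": AL + 0.65696 - 0.02029 * AL,
    }


def haigis_refraction_oracle(K, ACD, AL, a0, a1, a2, P, V=12.0, nC=1.3315):
    """Spectacle refraction under Haigis: thin-lens vergence chain."""
    n = 1.336
    RC = 337.5 / K                      # corneal radius, mm
    DC = (nC - 1.0) * 1000.0 / RC       # corneal power, D
    d = a0 + a1 * ACD + a2 * AL         # effective lens position, mm
    target_vergence = 1000.0 * n / (AL - d)
    before_iol = target_vergence - P
    after_cornea = before_iol / (1.0 + (d / 1000.0 / n) * before_iol)
    at_cornea = after_cornea - DC
    return at_cornea / (1.0 + (V / 1000.0) * at_cornea)


def bisect_power(refraction_fn, target, lo=-10.0, hi=40.0, iters=200, tol=1e-10):
    """Brute-force bisection for the power with refraction == target.

    Assumes refraction is decreasing in power (physical regime).
    """
    flo = refraction_fn(lo) - target
    fhi = refraction_fn(hi) - target
    assert flo * fhi <= 0, "target not bracketed"
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        fm = refraction_fn(mid) - target
        if abs(fm) == 0 or (hi - lo) / 2 < tol:
            return mid
        if flo * fm < 0:
            hi = mid
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


def bisect_elp(elp_refraction_fn, target, lo=0.5, hi=9.0, iters=200, tol=1e-10):
    """Bisection for the ELP reproducing the observed refraction."""
    flo = elp_refraction_fn(lo) - target
    fhi = elp_refraction_fn(hi) - target
    assert flo * fhi <= 0, "target not bracketed"
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        fm = elp_refraction_fn(mid) - target
        if abs(fm) == 0 or (hi - lo) / 2 < tol:
            return mid
        if flo * fm < 0:
            hi = mid
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)
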