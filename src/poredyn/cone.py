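"""Wobbling-in-a-cone interpretation of motional averaging factors.

If fast motions randomize a bond direction uniformly within a cone of
half-angle beta, the surviving fraction of the second-rank orientational
correlation is

    a1(beta) = cos^2(beta) (cos(beta) + 1)^2 / 4,

the square of the first-power coupling scaling factor

    s(beta) = cos(beta) (cos(beta) + 1) / 2.

``a1`` is the weight on the slow correlation time in the two-timescale
relaxation model; ``s`` is the factor by which residual dipole-dipole
couplings are scaled in echo experiments.  Angles are degrees at every
interface (radians internally).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "a1_from_cone",
    "cone_from_a1",
    "scaling_from_cone",
    "cone_from_scaling",
]


def _check_angle(beta_deg) -> np.ndarray:
    b = np.asarray(beta_deg, dtype=float)
    if np.any(b < 0) or np.any(b > 180):
        raise ValueError(f"cone half-angle must be in [0, 180] degrees, got {beta_deg}")
    return b


def a1_from_cone(beta_deg):
    """Slow-motion weight a1 for a cone half-angle in degrees."""
    b = np.deg2rad(_check_angle(beta_deg))
    c = np.cos(b)
    out = c * c * (c + 1.0) ** 2 / 4.0
    return float(out) if out.ndim == 0 else out


def scaling_from_cone(beta_deg):
    """Signed first-power coupling scaling factor s = cos(b)(cos(b)+1)/2.

    Returns ``(s, abs(s))``.
    """
    b = np.deg2rad(_check_angle(beta_deg))
    c = np.cos(b)
    s = c * (c + 1.0) / 2.0
    if s.ndim == 0:
        s = float(s)
        return s, abs(s)
    return s, np.abs(s)


def cone_from_a1(a1: float, tol_deg: float = 1e-6) -> float:
    """Invert a1(beta) on the monotone small-angle branch beta in [0, 90] degrees."""
    if not 0.0 <= a1 <= 1.0:
        raise ValueError(f"a1 must be in [0, 1], got {a1}")
    if a1 == 1.0:
        return 0.0
    if a1 == 0.0:
        return 90.0
    # a1 = s^2 with s = c(c+1)/2 monotone in c on [0, 1]; bisect on the angle
    f = lambda beta: a1_from_cone(beta) - a1
    return float(brentq(f, 0.0, 90.0, xtol=tol_deg))


_BRANCH_LO = 120.0  # |s| has its large-angle maximum 1/8 at cos(beta) = -1/2


def cone_from_scaling(s_max: float, tol_deg: float = 1e-8) -> float:
    """Minimal cone half-angle on the large-angle branch with |s| <= s_max.

    On beta in (120, 180] degrees, |s(beta)| decreases monotonically from
    1/8 to 0; the returned beta is the angle above which the coupling
    reduction is at least 1/s_max-fold.  A 50-fold reduction (s_max = 1/50)
    gives beta ~ 163 degrees.
    """
    if not 0.0 < s_max < 1.0:
        raise ValueError(f"s_max must be in (0, 1), got {s_max}")
    s_branch_max = abs(scaling_from_cone(_BRANCH_LO)[0])
    if s_max >= s_branch_max:
        raise ValueError(
            f"s_max={s_max} is not attainable on the large-angle branch; "
            f"|s| <= {s_branch_max} for beta >= {_BRANCH_LO} degrees")
    f = lambda beta: abs(scaling_from_cone(beta)[0]) - s_max
    return float(brentq(f, _BRANCH_LO, 180.0, xtol=tol_deg))
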