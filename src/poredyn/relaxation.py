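"""Dipolar relaxation-rate expressions for two-spin systems.

Implements the Solomon longitudinal and transverse rates and the
Jones/Bleich-Glasel rotating-frame rates for a dipole-coupled spin pair,
composed under a two-correlation-time orientational correlation function

    C(t)/C(0) = a1 exp(-t/tau_c1) + (1 - a1) exp(-t/tau_c2).

The net rate for each observable channel is the a1-weighted sum of the
single-correlation-time rate evaluated at tau_c1 and tau_c2.  Cross
correlations between distinct couplings and cross-relaxation are ignored
here (the cross-relaxation check lives in :mod:`poredyn.spinsim`).

All rates accept scalar or ndarray ``tau_c`` and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import PhysicalConstants, SpectrometerContext

__all__ = [
    "DipolarPair",
    "MotionModel",
    "SiteClass",
    "METHINE_CH",
    "METHYLENE_HH_HC",
    "dipolar_coupling",
    "rate_hetero",
    "rate_homo",
    "model_rate",
    "predicted_observables",
]

CHANNELS = ("R1", "R2", "R1rho")

#: observable channel -> (relaxing nucleus, rate channel)
H_CHANNELS = {"T1H": "R1", "T1rhoH": "R1rho", "T2H": "R2"}
C_CHANNELS = {"T1C": "R1", "T2C": "R2"}


def dipolar_coupling(constants: PhysicalConstants, nuclide_x: str, nuclide_y: str,
                     r: float) -> float:
    """Dipole-dipole coupling constant d = (mu0/4pi) hbar gammaX gammaY / r^3.

    Parameters
    ----------
    r : float
        Internuclear distance in meters.

    Returns
    -------
    float
        Coupling constant in rad/s.  For a 0.110 nm H-C bond this is
        1.426e5 rad/s; for a 0.176 nm geminal H-H pair, 1.384e5 rad/s.
    """
    if r <= 0:
        raise ValueError(f"internuclear distance must be positive, got {r}")
    gx = constants.gamma_of(nuclide_x)
    gy = constants.gamma_of(nuclide_y)
    return constants.mu0_over_4pi * constants.hbar * gx * gy / r**3


@dataclass(frozen=True)
class DipolarPair:
    """A dipole-coupled spin pair, heteronuclear (X-Y) or homonuclear (X-X)."""

    nuclide_x: str
    nuclide_y: str
    r: float  # meters
    constants: PhysicalConstants = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.constants is None:
            object.__setattr__(self, "constants", PhysicalConstants())
        if self.r <= 0:
            raise ValueError("internuclear distance must be positive")

    @property
    def kind(self) -> str:
        return "homo" if self.nuclide_x == self.nuclide_y else "hetero"

    @property
    def d(self) -> float:
        """Coupling constant, rad/s."""
        return dipolar_coupling(self.constants, self.nuclide_x, self.nuclide_y, self.r)


@dataclass(frozen=True)
class MotionModel:
    """Two-correlation-time motion: weight a1 on the slow time tau_c1 (s)."""

    a1: float
    tau_c1: float
    tau_c2: float

    def __post_init__(self):
        if not 0.0 <= self.a1 <= 1.0:
            raise ValueError(f"a1 must be in [0, 1], got {self.a1}")
        if not self.tau_c1 > self.tau_c2 > 0:
            raise ValueError(
                f"need tau_c1 > tau_c2 > 0, got tau_c1={self.tau_c1}, tau_c2={self.tau_c2}"
            )


def _lorentz(omega, tau_c):
    """1 / (1 + omega^2 tau_c^2)."""
    x = omega * tau_c
    return 1.0 / (1.0 + x * x)


def rate_hetero(channel: str, d: float, tau_c, ctx: SpectrometerContext,
                nuclide_x: str, nuclide_y: str):
    """Heteronuclear relaxation rate of spin X coupled to unlike spin Y.

    ``channel`` selects R1 (longitudinal), R2 (transverse) or R1rho
    (rotating frame, spin-lock amplitude ``ctx.omega1``).  Rates in 1/s.
    """
    tau_c = np.asarray(tau_c, dtype=float)
    if np.any(tau_c <= 0):
        raise ValueError("tau_c must be positive")
    wx = ctx.omega(nuclide_x)
    wy = ctx.omega(nuclide_y)
    w1 = ctx.omega1
    L = _lorentz
    if channel == "R1":
        s = L(wx - wy, tau_c) + 3 * L(wx, tau_c) + 6 * L(wx + wy, tau_c)
        return d * d * tau_c / 10.0 * s
    if channel == "R2":
        s = (4.0 + L(wx - wy, tau_c) + 3 * L(wx, tau_c)
             + 6 * L(wy, tau_c) + 6 * L(wx + wy, tau_c))
        return d * d * tau_c / 20.0 * s
    if channel == "R1rho":
        s = (8 * L(w1, tau_c)
             + L(wx - wy + w1, tau_c) + L(wx - wy - w1, tau_c)
             + 3 * L(wx + w1, tau_c) + 3 * L(wx - w1, tau_c)
             + 6 * L(wy + w1, tau_c) + 6 * L(wy - w1, tau_c)
             + 6 * L(wx + wy + w1, tau_c) + 6 * L(wx + wy - w1, tau_c))
        return d * d * tau_c / 40.0 * s
    raise ValueError(f"unknown channel {channel!r}; valid channels: {CHANNELS}")


def rate_homo(channel: str, d: float, tau_c, ctx: SpectrometerContext,
              nuclide_x: str):
    """Homonuclear relaxation rate of spin X coupled to a like spin."""
    tau_c = np.asarray(tau_c, dtype=float)
    if np.any(tau_c <= 0):
        raise ValueError("tau_c must be positive")
    wx = ctx.omega(nuclide_x)
    w1 = ctx.omega1
    L = _lorentz
    if channel == "R1":
        s = L(wx, tau_c) + 4 * L(2 * wx, tau_c)
        return 3.0 * d * d * tau_c / 10.0 * s
    if channel == "R2":
        s = 9.0 + 15 * L(wx, tau_c) + 6 * L(2 * wx, tau_c)
        return d * d * tau_c / 20.0 * s
    if channel == "R1rho":
        s = (18 * L(w1, tau_c)
             + 3 * L(wx + w1, tau_c) + 3 * L(wx - w1, tau_c)
             + 12 * L(wx + 2 * w1, tau_c) + 12 * L(wx - 2 * w1, tau_c)
             + 3 * L(2 * wx + w1, tau_c) + 3 * L(2 * wx - w1, tau_c)
             + 3 * L(2 * wx + 2 * w1, tau_c) + 3 * L(2 * wx - 2 * w1, tau_c))
        return d * d * tau_c / 40.0 * s
    raise ValueError(f"unknown channel {channel!r}; valid channels: {CHANNELS}")


def pair_rate(channel: str, pair: DipolarPair, tau_c, ctx: SpectrometerContext):
    """Single-correlation-time rate for a pair, dispatching on its kind."""
    if pair.kind == "homo":
        return rate_homo(channel, pair.d, tau_c, ctx, pair.nuclide_x)
    return rate_hetero(channel, pair.d, tau_c, ctx, pair.nuclide_x, pair.nuclide_y)


def model_rate(channel: str, pair: DipolarPair, motion: MotionModel,
               ctx: SpectrometerContext):
    """Net rate under the two-correlation-time model: a1 R(tau_c1) + (1-a1) R(tau_c2)."""
    r1 = pair_rate(channel, pair, motion.tau_c1, ctx)
    r2 = pair_rate(channel, pair, motion.tau_c2, ctx)
    return motion.a1 * r1 + (1.0 - motion.a1) * r2


@dataclass(frozen=True)
class SiteClass:
    """Which spin pairs relax the observed site.

    ``methine-CH``: a 13C relaxed by its one-bond 1H (observables T1C, T2C).
    ``methylene-HH+HC``: a methylene 1H relaxed by its geminal 1H partner plus
    a one-bond 13C (observables T1H, T1rhoH, T2H); rates add.
    """

    label: str
    r_hc: float = 0.110e-9  # one-bond H-C distance, m
    r_hh: float = 0.176e-9  # geminal H-H distance, m

    KNOWN = ("methine-CH", "methylene-HH+HC")

    def __post_init__(self):
        if self.label not in self.KNOWN:
            raise ValueError(
                f"unknown site class {self.label!r}; known: {self.KNOWN}")
        if self.r_hc <= 0 or self.r_hh <= 0:
            raise ValueError("internuclear distances must be positive")

    @property
    def channels(self) -> tuple:
        if self.label == "methine-CH":
            return tuple(C_CHANNELS)
        return tuple(H_CHANNELS)

    def pairs_for(self, constants: PhysicalConstants):
        """The dipolar pairs whose rates add for each observable channel."""
        if self.label == "methine-CH":
            return [DipolarPair("13C", "1H", self.r_hc, constants)]
        return [
            DipolarPair("1H", "1H", self.r_hh, constants),
            DipolarPair("1H", "13C", self.r_hc, constants),
        ]


METHINE_CH = SiteClass("methine-CH")
METHYLENE_HH_HC = SiteClass("methylene-HH+HC")

_CHANNEL_MAP = {**H_CHANNELS, **C_CHANNELS}


def observable_rate(observable: str, site: SiteClass, tau_c,
                    ctx: SpectrometerContext):
    """Single-tau_c total rate for one observable channel of a site class.

    For methylene 1H channels this is the homonuclear (H-H) plus
    heteronuclear (H-C) contribution; for methine 13C channels the one-bond
    H-C contribution alone.
    """
    if observable not in site.channels:
        raise ValueError(
            f"channel {observable!r} not defined for site class {site.label!r}; "
            f"valid: {site.channels}")
    rate_channel = _CHANNEL_MAP[observable]
    total = 0.0
    for pair in site.pairs_for(ctx.constants):
        total = total + pair_rate(rate_channel, pair, tau_c, ctx)
    return total


def predicted_observables(site: SiteClass, motion: MotionModel,
                          ctx: SpectrometerContext) -> dict:
    """Predicted relaxation times (s) for every channel of a site class.

    T = 1 / [a1 R_total(tau_c1) + (1-a1) R_total(tau_c2)].
    """
    out = {}
    for obs in site.channels:
        r = (motion.a1 * observable_rate(obs, site, motion.tau_c1, ctx)
             + (1.0 - motion.a1) * observable_rate(obs, site, motion.tau_c2, ctx))
        out[obs] = 1.0 / float(r)
    return out
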