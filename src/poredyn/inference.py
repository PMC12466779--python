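"""Two-correlation-time grid inference from relaxation rates.

For one site and temperature, the measured rates 1/T_mu with uncertainties
sigma_mu are compared with the model a1 R_mu(tau_c1) + (1-a1) R_mu(tau_c2)
on a 100x100 grid of (tau_c1, tau_c2), log-uniform over
[10, 500] ns x [0.1, 9] ns.  At each grid point the weight a1 minimizing
chi-squared is available in closed form (the model is linear in a1):

    a1* = sum_mu g_mu y_mu / sigma_mu^2  /  sum_mu g_mu^2 / sigma_mu^2,

with g_mu = R_mu(tau_c1) - R_mu(tau_c2) and y_mu = 1/T_mu - R_mu(tau_c2).
Because acceptable chi-squared values occupy broad regions of the grid,
the reported parameters are probability-weighted averages and standard
deviations with weights exp(-chi^2) delta1(j) delta2(k), where the deltas
are the local (linear-tau) grid spacings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import SpectrometerContext
from .relaxation import SiteClass, observable_rate

__all__ = [
    "Observation",
    "RelaxationObservationSet",
    "GridSpec",
    "GridPosterior",
    "chi2_given_taus",
    "run_grid",
    "weighted_summary",
]


@dataclass(frozen=True)
class Observation:
    """One measured relaxation rate 1/T (1/s) with its uncertainty (1/s)."""

    channel: str   # T1H | T1rhoH | T2H | T1C | T2C
    rate: float
    sigma: float

    def __post_init__(self):
        if self.rate <= 0 or self.sigma <= 0:
            raise ValueError("rate and sigma must be positive")


@dataclass
class RelaxationObservationSet:
    """All rates entering one grid fit (one site, one temperature)."""

    site: str
    site_class: SiteClass
    temperature_c: float
    observations: list

    def __post_init__(self):
        valid = self.site_class.channels
        for obs in self.observations:
            if obs.channel not in valid:
                raise ValueError(
                    f"channel {obs.channel!r} invalid for site class "
                    f"{self.site_class.label!r}; valid: {valid}")

    def rates(self) -> np.ndarray:
        return np.array([o.rate for o in self.observations])

    def sigmas(self) -> np.ndarray:
        return np.array([o.sigma for o in self.observations])

    def channels(self) -> list:
        return [o.channel for o in self.observations]


@dataclass(frozen=True)
class GridSpec:
    """Log-uniform (tau_c1, tau_c2) grid, endpoints inclusive."""

    n1: int = 100
    n2: int = 100
    tau1_min: float = 10e-9
    tau1_max: float = 500e-9
    tau2_min: float = 0.1e-9
    tau2_max: float = 9e-9

    def __post_init__(self):
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need at least 2 grid points per axis")
        if not (0 < self.tau1_min < self.tau1_max) or not (0 < self.tau2_min < self.tau2_max):
            raise ValueError("grid ranges must be positive and increasing")

    def tau1(self) -> np.ndarray:
        return np.geomspace(self.tau1_min, self.tau1_max, self.n1)

    def tau2(self) -> np.ndarray:
        return np.geomspace(self.tau2_min, self.tau2_max, self.n2)

    @staticmethod
    def _measure(tau: np.ndarray) -> np.ndarray:
        """Local grid spacing in linear tau units: centered differences,
        one-sided at the endpoints."""
        d = np.empty_like(tau)
        d[1:-1] = (tau[2:] - tau[:-2]) / 2.0
        d[0] = tau[1] - tau[0]
        d[-1] = tau[-1] - tau[-2]
        return d

    def delta1(self) -> np.ndarray:
        return self._measure(self.tau1())

    def delta2(self) -> np.ndarray:
        return self._measure(self.tau2())


@dataclass
class GridPosterior:
    """chi-squared surface, minimizing a1, and probability-weighted summaries."""

    spec: GridSpec
    chi2: np.ndarray          # (n1, n2)
    a1: np.ndarray            # (n1, n2), analytic minimizer (not clamped)
    min_index: tuple          # (j, k) of the chi-squared minimum
    n_degenerate: int
    summary: dict = field(default_factory=dict)

    @property
    def min_chi2(self) -> float:
        return float(self.chi2[self.min_index])

    @property
    def best(self) -> tuple:
        j, k = self.min_index
        return (self.spec.tau1()[j], self.spec.tau2()[k], float(self.a1[self.min_index]))

    def a1_out_of_range(self) -> bool:
        """True when the unconstrained minimizer leaves [0, 1] anywhere the
        posterior weight is non-negligible."""
        w = np.exp(-(self.chi2 - self.min_chi2))
        mask = w > 1e-6
        return bool(np.any((self.a1[mask] < 0) | (self.a1[mask] > 1)))


def _rate_matrix(obs: RelaxationObservationSet, tau: np.ndarray,
                 ctx: SpectrometerContext) -> np.ndarray:
    """Total model rate for each observation channel at each tau: shape (m, len(tau))."""
    return np.array([observable_rate(ch, obs.site_class, tau, ctx)
                     for ch in obs.channels()])


def chi2_given_taus(obs: RelaxationObservationSet, tau_c1: float, tau_c2: float,
                    ctx: SpectrometerContext) -> tuple[float, float]:
    """Closed-form minimization of chi-squared over a1 at fixed (tau_c1, tau_c2)."""
    if not tau_c1 > tau_c2:
        raise ValueError("tau_c1 must exceed tau_c2")
    if len(obs.observations) < 1:
        raise ValueError("need at least one observation")
    r1 = _rate_matrix(obs, np.atleast_1d(tau_c1), ctx)[:, 0]
    r2 = _rate_matrix(obs, np.atleast_1d(tau_c2), ctx)[:, 0]
    y = obs.rates() - r2
    g = r1 - r2
    w = 1.0 / obs.sigmas() ** 2
    denom = np.sum(g * g * w)
    if denom == 0.0:
        raise ZeroDivisionError(
            "degenerate grid point: tau_c1 and tau_c2 give identical rates")
    a1 = float(np.sum(g * y * w) / denom)
    chi2 = float(np.sum((y - a1 * g) ** 2 * w))
    return chi2, a1


def run_grid(obs: RelaxationObservationSet, spec: Optional[GridSpec] = None,
             ctx: Optional[SpectrometerContext] = None) -> GridPosterior:
    """Evaluate chi-squared (with analytic a1) over the full grid and summarize."""
    from .constants import default_context
    spec = spec or GridSpec()
    ctx = ctx or default_context()
    if len(obs.observations) < 1:
        raise ValueError("need at least one observation")

    tau1, tau2 = spec.tau1(), spec.tau2()
    R1 = _rate_matrix(obs, tau1, ctx)   # (m, n1)
    R2 = _rate_matrix(obs, tau2, ctx)   # (m, n2)
    w = 1.0 / obs.sigmas() ** 2         # (m,)
    rates = obs.rates()

    g = R1[:, :, None] - R2[:, None, :]          # (m, n1, n2)
    y = rates[:, None] - R2                      # (m, n2)
    num = np.einsum("mjk,mk,m->jk", g, y, w)
    den = np.einsum("mjk,mjk,m->jk", g, g, w)
    degenerate = den == 0.0
    n_deg = int(np.count_nonzero(degenerate))
    with np.errstate(invalid="ignore", divide="ignore"):
        a1 = num / den
    resid = y[:, None, :] - a1[None] * g         # (m, n1, n2)
    chi2 = np.einsum("mjk,mjk,m->jk", resid, resid, w)
    chi2[degenerate] = np.inf
    a1[degenerate] = np.nan

    min_index = np.unravel_index(np.argmin(chi2), chi2.shape)
    post = GridPosterior(spec=spec, chi2=chi2, a1=a1,
                         min_index=tuple(int(i) for i in min_index),
                         n_degenerate=n_deg)
    post.summary = weighted_summary(post)
    return post


def weighted_summary(posterior: GridPosterior) -> dict:
    """Probability-weighted means and SDs of tau_c1, tau_c2, a1.

    Weights are exp(-chi^2) delta1(j) delta2(k); chi^2 is shifted by its
    grid minimum before exponentiation, which cancels in the normalization
    and prevents underflow.
    """
    spec = posterior.spec
    chi2 = posterior.chi2
    finite = np.isfinite(chi2)
    if not np.any(finite):
        raise ValueError("all grid points degenerate; no finite chi-squared")
    shift = chi2[finite].min()
    w = np.where(finite, np.exp(-(chi2 - shift)), 0.0)
    w = w * np.outer(spec.delta1(), spec.delta2())
    norm = w.sum()

    tau1_grid = np.broadcast_to(spec.tau1()[:, None], chi2.shape)
    tau2_grid = np.broadcast_to(spec.tau2()[None, :], chi2.shape)
    a1 = np.where(finite, posterior.a1, 0.0)

    out = {}
    for name, vals in (("tau_c1", tau1_grid), ("tau_c2", tau2_grid), ("a1", a1)):
        mean = float((vals * w).sum() / norm)
        sd = float(np.sqrt(((vals - mean) ** 2 * w).sum() / norm))
        out[name] = mean
        out[name + "_sd"] = sd
    out["min_chi2"] = float(chi2[finite].min())
    return out
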