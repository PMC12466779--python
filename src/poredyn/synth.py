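"""Synthetic relaxation data with the statistical structure the analysis assumes.

Generates decay curves (amplitude vs t_rel with Gaussian noise whose RMS
matches the quoted per-point uncertainty, exactly as spectra-derived peak
heights behave), per-site observation sets of rates for the grid
inference, and temperature series with smooth Arrhenius-like truth maps
and optional injected discontinuities (the counterfactual a phase
transition would produce).  Everything is a pure function of
(plan, seed): a fixed seed regenerates identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import zlib

import numpy as np

from .constants import SpectrometerContext, default_context
from .decay import DecayCurve
from .inference import Observation, RelaxationObservationSet
from .relaxation import MotionModel, SiteClass, observable_rate, predicted_observables

__all__ = [
    "GenerationPlan",
    "make_decay_curve",
    "make_observation_set",
    "make_temperature_series",
]

KELVIN = 273.15


@dataclass
class GenerationPlan:
    """Truth and noise settings for one generated site.

    The defaults mirror the study conditions: a methylene/methine site with
    two-timescale motion, amplitude noise at a few percent of the initial
    amplitude (the spectral RMS-noise level), rate-level fractional noise of
    5% for observation sets, 8 log-spaced t_rel points spanning [T/8, 4T],
    and temperatures from -5 to 50 C.
    """

    site: str = "G28_CA"
    site_class: SiteClass = field(default_factory=lambda: SiteClass("methylene-HH+HC"))
    motion: MotionModel = field(default_factory=lambda: MotionModel(0.25, 100e-9, 1e-9))
    ctx: SpectrometerContext = field(default_factory=default_context)
    amplitude_noise: float = 0.02      # RMS, fraction of initial amplitude
    rate_noise: float = 0.05           # fractional sigma on rates
    beta_stretch: dict = field(default_factory=dict)  # channel -> truth beta
    n_trel: int = 8
    seed: int = 0

    def rng(self, *salt) -> np.random.Generator:
        return np.random.default_rng([self.seed, *salt])


def _trel_schedule(t_char: float, n: int) -> np.ndarray:
    """Log-spaced relaxation periods spanning [T/8, 4T]."""
    return np.geomspace(t_char / 8.0, 4.0 * t_char, n)


def _motion_at(plan: GenerationPlan, temperature_c: float,
               ea_kj_mol: float = 12.0, t_ref_c: float = 20.0) -> MotionModel:
    """Arrhenius-like tau_c2(T) with mild slope; tau_c1 and a1 constant."""
    r_gas = 8.314462618e-3  # kJ/mol/K
    t_k, t_ref_k = temperature_c + KELVIN, t_ref_c + KELVIN
    factor = np.exp(ea_kj_mol / r_gas * (1.0 / t_k - 1.0 / t_ref_k))
    tau2 = plan.motion.tau_c2 * factor
    tau2 = min(tau2, 0.5 * plan.motion.tau_c1)
    return MotionModel(plan.motion.a1, plan.motion.tau_c1, tau2)


def make_decay_curve(plan: GenerationPlan, channel: str,
                     temperature_c: float = 20.0,
                     motion: Optional[MotionModel] = None) -> DecayCurve:
    """Forward-model one decay/build-up curve with Gaussian amplitude noise.

    Inversion-recovery channels (T1H, T1C) are generated as
    a + b exp(-t/T) with a = 1, b = -2 (full inversion); decay channels as
    b exp(-(t/T)^beta) with b = 1.  The per-point sigma column is set to
    the noise RMS, matching the uncertainty convention for peak heights.
    """
    motion = motion or _motion_at(plan, temperature_c)
    times = predicted_observables(plan.site_class, motion, plan.ctx)
    if channel not in times:
        raise ValueError(
            f"channel {channel!r} undefined for site class "
            f"{plan.site_class.label!r}; valid: {tuple(times)}")
    t_char = times[channel]
    t_rel = _trel_schedule(t_char, plan.n_trel)
    beta = plan.beta_stretch.get(channel, 1.0)
    if channel in ("T1H", "T1C"):
        offset, b = 1.0, -2.0
        clean = offset + b * np.exp(-t_rel / t_char)
        scale = abs(b)
    else:
        offset, b = 0.0, 1.0
        clean = b * np.exp(-((t_rel / t_char) ** beta))
        scale = b
    sigma = plan.amplitude_noise * scale
    rng = plan.rng(zlib.crc32(channel.encode()), int(round(temperature_c * 100)) % 2**31)
    noise = rng.normal(0.0, sigma, size=t_rel.shape) if sigma > 0 else 0.0
    sig_col = np.full_like(t_rel, sigma if sigma > 0 else 1e-12)
    return DecayCurve(site=plan.site, channel=channel,
                      temperature_c=temperature_c, t_rel=t_rel,
                      amplitude=clean + noise, sigma=sig_col)


def make_observation_set(plan: GenerationPlan, temperature_c: float = 20.0,
                         motion: Optional[MotionModel] = None,
                         ) -> RelaxationObservationSet:
    """Rates from the truth model with Gaussian fractional noise."""
    motion = motion or _motion_at(plan, temperature_c)
    rng = plan.rng(int(round(temperature_c * 100)) % 2**31, 7)
    observations = []
    for ch in plan.site_class.channels:
        rate = (motion.a1 * float(observable_rate(ch, plan.site_class,
                                                  motion.tau_c1, plan.ctx))
                + (1 - motion.a1) * float(observable_rate(ch, plan.site_class,
                                                          motion.tau_c2, plan.ctx)))
        sigma = plan.rate_noise * rate
        noisy = rate + rng.normal(0.0, sigma) if sigma > 0 else rate
        while noisy <= 0:  # rates are physical; redraw the rare negative sample
            noisy = rate + rng.normal(0.0, sigma)
        observations.append(Observation(ch, noisy, sigma if sigma > 0 else rate * 1e-12))
    return RelaxationObservationSet(site=plan.site, site_class=plan.site_class,
                                    temperature_c=temperature_c,
                                    observations=observations)


def make_temperature_series(plan: GenerationPlan,
                            temperatures_c: Sequence[float] = tuple(range(-5, 51, 5)),
                            discontinuity: Optional[tuple] = None) -> dict:
    """Relaxation-time series vs temperature per channel.

    Smooth truth maps (constant a1 and tau_c1, Arrhenius-like tau_c2) yield
    smooth series.  ``discontinuity=(t_star_c, factor)`` multiplies all
    relaxation times by ``factor`` for temperatures >= t_star_c — the
    abrupt change long-lived cluster formation would cause.

    Returns {channel: {"temperature_c", "value", "sigma"}} arrays.
    """
    temps = np.asarray(temperatures_c, float)
    out = {ch: {"temperature_c": temps.copy(),
                "value": np.zeros_like(temps),
                "sigma": np.zeros_like(temps)}
           for ch in plan.site_class.channels}
    for i, t_c in enumerate(temps):
        motion = _motion_at(plan, t_c)
        times = predicted_observables(plan.site_class, motion, plan.ctx)
        for ch, t_val in times.items():
            if discontinuity is not None and t_c >= discontinuity[0]:
                t_val = t_val * discontinuity[1]
            rng = plan.rng(zlib.crc32(ch.encode()), i, 13)
            sigma = plan.rate_noise * t_val
            val = t_val + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
            out[ch]["value"][i] = val
            out[ch]["sigma"][i] = sigma if sigma > 0 else t_val * 1e-12
    return out
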