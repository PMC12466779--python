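"""YAML run configuration.

A config file collects the defaults a run needs — spectrometer context,
grid ranges, site-class distances, generation plan, simulator settings —
in the units practitioners use (field in T or ¹H MHz, ω₁ in Hz, distances
in nm, correlation times in ns, temperatures in °C).  Command-line flags
override config values; the effective config is hashed into the run log.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .constants import SpectrometerContext
from .inference import GridSpec
from .relaxation import MotionModel, SiteClass

DEFAULTS: dict = {
    "context": {"proton_mhz": 599.1, "omega1_hz": 1.0e4},
    "grid": {"n1": 100, "n2": 100, "tau1_ns": [10.0, 500.0],
             "tau2_ns": [0.1, 9.0]},
    "site": {"class": "methylene-HH+HC", "r_hc_nm": 0.110, "r_hh_nm": 0.176},
    "plan": {"a1": 0.25, "tau_c1_ns": 100.0, "tau_c2_ns": 1.0,
             "amplitude_noise": 0.02, "rate_noise": 0.05, "seed": 0},
    "echo": {"nu_r_khz": 1.2, "steps_per_period": 200, "orientations": 144},
}


def load_config(path: str | Path | None) -> dict:
    """Merge a YAML file over the shipped defaults (two-level merge)."""
    cfg = {k: dict(v) for k, v in DEFAULTS.items()}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        for section, values in loaded.items():
            if section not in cfg:
                raise ValueError(
                    f"{path}: unknown config section {section!r}; "
                    f"known: {sorted(cfg)}")
            cfg[section].update(values)
    return cfg


def context_from_config(cfg: dict) -> SpectrometerContext:
    c = cfg["context"]
    if "b0_tesla" in c:
        from .constants import TWO_PI
        return SpectrometerContext(b0=c["b0_tesla"],
                                   omega1=TWO_PI * c["omega1_hz"])
    return SpectrometerContext.from_proton_mhz(c["proton_mhz"], c["omega1_hz"])


def grid_from_config(cfg: dict) -> GridSpec:
    g = cfg["grid"]
    return GridSpec(n1=g["n1"], n2=g["n2"],
                    tau1_min=g["tau1_ns"][0] * 1e-9,
                    tau1_max=g["tau1_ns"][1] * 1e-9,
                    tau2_min=g["tau2_ns"][0] * 1e-9,
                    tau2_max=g["tau2_ns"][1] * 1e-9)


def site_from_config(cfg: dict) -> SiteClass:
    s = cfg["site"]
    return SiteClass(s["class"], r_hc=s["r_hc_nm"] * 1e-9,
                     r_hh=s["r_hh_nm"] * 1e-9)


def motion_from_config(cfg: dict) -> MotionModel:
    p = cfg["plan"]
    return MotionModel(p["a1"], p["tau_c1_ns"] * 1e-9, p["tau_c2_ns"] * 1e-9)
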