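"""Delimited-table I/O for decay curves, observation sets, and summaries.

All tables are comma-separated with a header row; units are part of the
column names (``t_rel_s``, ``rate_per_s``, ...).  Parsing is
locale-independent (pandas C parser, '.' decimal point) and numbers round
trip at full double precision.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .decay import DecayCurve, FitResult
from .inference import Observation, RelaxationObservationSet
from .relaxation import SiteClass

DECAY_COLUMNS = ["site", "channel", "temperature_C", "t_rel_s", "amplitude",
                 "sigma", "mode"]
OBS_COLUMNS = ["site", "site_class", "temperature_C", "channel", "rate_per_s",
               "sigma_per_s"]
SUMMARY_COLUMNS = ["site", "temperature_C", "tau_c1_ns", "tau_c1_sd_ns",
                   "tau_c2_ns", "tau_c2_sd_ns", "a1", "a1_sd", "min_chi2"]


class TableFormatError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing column(s) {', '.join(missing)}; "
            f"expected {list(required)}")


def write_decay_curves(curves: Sequence[DecayCurve], path) -> None:
    rows = []
    for c in curves:
        for t, a, s in zip(c.t_rel, c.amplitude, c.sigma):
            rows.append((c.site, c.channel, c.temperature_c, t, a, s, c.mode))
    pd.DataFrame(rows, columns=DECAY_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")


def read_decay_curves(path) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, DECAY_COLUMNS, path)
    curves = []
    for (site, channel, temp, mode), grp in df.groupby(
            ["site", "channel", "temperature_C", "mode"], sort=False):
        grp = grp.sort_values("t_rel_s")
        curves.append(DecayCurve(site=site, channel=channel,
                                 temperature_c=float(temp),
                                 t_rel=grp["t_rel_s"].to_numpy(),
                                 amplitude=grp["amplitude"].to_numpy(),
                                 sigma=grp["sigma"].to_numpy(), mode=mode))
    return curves


def write_observation_sets(obs_sets: Sequence[RelaxationObservationSet],
                           path) -> None:
    rows = []
    for s in obs_sets:
        for o in s.observations:
            rows.append((s.site, s.site_class.label, s.temperature_c,
                         o.channel, o.rate, o.sigma))
    pd.DataFrame(rows, columns=OBS_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")


def read_observation_sets(path) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, OBS_COLUMNS, path)
    out = []
    for (site, cls, temp), grp in df.groupby(
            ["site", "site_class", "temperature_C"], sort=False):
        observations = [Observation(r.channel, r.rate_per_s, r.sigma_per_s)
                        for r in grp.itertuples()]
        out.append(RelaxationObservationSet(
            site=site, site_class=SiteClass(cls), temperature_c=float(temp),
            observations=observations))
    return out


def fit_results_frame(keys: Sequence[tuple], fits: Sequence[FitResult]
                      ) -> pd.DataFrame:
    """Summary table keyed by (site, channel, temperature_C)."""
    rows = []
    for (site, channel, temp), f in zip(keys, fits):
        rows.append({
            "site": site, "channel": channel, "temperature_C": temp,
            "model": f.model, "a": f.a, "b": f.b, "T_s": f.T,
            "beta_stretch": f.beta_stretch if f.beta_stretch is not None else np.nan,
            "redchi": f.redchi,
            "T_stderr_s": f.stderr.get("T", np.nan),
        })
    return pd.DataFrame(rows)


def summary_frame(entries: Sequence[dict]) -> pd.DataFrame:
    """Per-site posterior table mirroring the parameter-table layout:
    site, temperature, mean +/- SD for tau_c1, tau_c2, a1, min chi^2."""
    rows = []
    for e in entries:
        s = e["summary"]
        rows.append({
            "site": e["site"], "temperature_C": e["temperature_C"],
            "tau_c1_ns": s["tau_c1"] * 1e9, "tau_c1_sd_ns": s["tau_c1_sd"] * 1e9,
            "tau_c2_ns": s["tau_c2"] * 1e9, "tau_c2_sd_ns": s["tau_c2_sd"] * 1e9,
            "a1": s["a1"], "a1_sd": s["a1_sd"], "min_chi2": s["min_chi2"],
        })
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
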