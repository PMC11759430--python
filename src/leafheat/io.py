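"""CSV/JSON/YAML readers and writers and the validated run configuration.

Trace files are plain CSV in field units — seconds, °C, % relative
humidity — and are converted to internal SI units (K, fractions) on read.
Two layouts are supported:

* narrow: ``time_s,value`` (one file per channel);
* wide: ``time_s,T_leaf_C,T_air_C,RH_pct,T_reflect_C`` (one file per run).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .simulate import EnvironmentTrace, LightProtocol, ThermalTrace

__all__ = [
    "read_trace_csv",
    "read_run_csv",
    "write_run_csv",
    "RunConfig",
    "load_config",
]

WIDE_COLUMNS = ("time_s", "T_leaf_C", "T_air_C", "RH_pct", "T_reflect_C")


def _check_times(t: np.ndarray, path: Path) -> None:
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        # +2: one for the header line, one for 0- vs 1-based indexing
        raise ValueError(
            f"{path}: non-increasing time_s at data line {int(bad[0]) + 2} "
            f"(t={t[bad[0] + 1]!r} after t={t[bad[0]]!r})"
        )


def read_trace_csv(
    path: str | Path,
    kind: Literal["thermal", "value"] = "thermal",
    sample_rate_hz: float | None = None,
) -> ThermalTrace:
    """Read a narrow ``time_s,value`` CSV into a trace.

    ``kind="thermal"`` treats values as °C and converts to K; ``"value"``
    leaves them untouched (e.g. RH fractions already converted upstream).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"time_s", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    _check_times(t, path)
    v = df["value"].to_numpy(dtype=float)
    if kind == "thermal":
        v = v + 273.15
    if sample_rate_hz is None:
        sample_rate_hz = 1.0 / float(np.median(np.diff(t)))
    return ThermalTrace(t, v, sample_rate_hz=sample_rate_hz)


def read_run_csv(
    path: str | Path,
) -> tuple[ThermalTrace, EnvironmentTrace]:
    """Read a wide run CSV into (object trace, environment trace).

    Temperatures are °C, relative humidity is %, pressure defaults to one
    standard atmosphere (override via the run config).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(WIDE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    _check_times(t, path)
    rate = 1.0 / float(np.median(np.diff(t)))
    thermal = ThermalTrace(
        t, df["T_leaf_C"].to_numpy(dtype=float) + 273.15, sample_rate_hz=rate
    )
    env = EnvironmentTrace(
        t,
        df["T_air_C"].to_numpy(dtype=float) + 273.15,
        df["RH_pct"].to_numpy(dtype=float) / 100.0,
        df["T_reflect_C"].to_numpy(dtype=float) + 273.15,
    )
    return thermal, env


def write_run_csv(
    path: str | Path, thermal: ThermalTrace, env: EnvironmentTrace
) -> None:
    """Write a wide run CSV (inverse of :func:`read_run_csv`)."""
    t = thermal.times
    df = pd.DataFrame({
        "time_s": t,
        "T_leaf_C": thermal.T - 273.15,
        "T_air_C": np.interp(t, env.times, env.T_air) - 273.15,
        "RH_pct": np.interp(t, env.times, env.RH_air) * 100.0,
        "T_reflect_C": np.interp(t, env.times, env.T_reflect) - 273.15,
    })
    df.to_csv(path, index=False, float_format="%.9g")


class ProtocolConfig(BaseModel):
    """Pulse-then-dark light protocol, seconds and W m⁻²."""

    pulse_duration_s: float = Field(10.0, gt=0)
    dark_duration_s: float = Field(110.0, gt=0)
    irradiance_w_m2: float = Field(270.0, ge=0)

    def build(self) -> LightProtocol:
        return LightProtocol.pulse(
            self.pulse_duration_s, self.dark_duration_s, self.irradiance_w_m2
        )


class SampleConfig(BaseModel):
    """Sample optics and geometry in bench units (g, cm²)."""

    alpha: float = Field(..., ge=0)
    epsilon: float = Field(..., ge=0)
    fresh_weight_g: float = Field(..., gt=0)
    area_cm2: float = Field(..., gt=0)
    dry_weight_g: float | None = Field(None, gt=0)
    thickness_m: float | None = Field(None, gt=0)
    density_kg_m3: float | None = Field(None, gt=0)


class MCMCSettings(BaseModel):
    chains: int = Field(4, ge=2)
    iterations: int = Field(1000, gt=0)
    warmup: int = Field(500, ge=0)
    walkers_per_chain: int = Field(8, ge=2)
    seed: int = 0
    solver_dt_s: float = Field(0.1, gt=0)

    @model_validator(mode="after")
    def _warmup_lt_iterations(self):
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be < iterations")
        return self


class RunConfig(BaseModel):
    """Validated configuration for a fit/simulate/sensitivity run.

    Every assumed constant is an explicit field so that the echoed config in
    the output report contains no silent defaults.
    """

    trace_csv: str | None = None
    sample: SampleConfig
    protocol: ProtocolConfig = ProtocolConfig()
    mcmc: MCMCSettings = MCMCSettings()
    P_atm_pa: float = Field(101325.0, gt=0)
    C_s_air: float = Field(1010.0, gt=0)
    latent_heat: float = Field(2.45e6, gt=0)
    noise_sd_K: float = Field(0.05, ge=0)
    decimate_to_hz: float | None = Field(5.0, gt=0)
    fix_g_sw: float | None = None
    prior_k_sd: float = Field(5000.0, gt=0)
    prior_g_bh_sd: float = Field(0.005, gt=0)
    prior_g_sw_sd: float = Field(0.005, gt=0)
    prior_sigma_sd: float = Field(0.5, gt=0)

    def echo(self) -> dict:
        return self.model_dump()


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON, a YAML subset) run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)
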