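"""Synthetic weather and field-water salinity scenarios.

Two salinity archetypes are provided, idealising the seasonal dynamics of
contrasting rice districts: an *early peak* (salinity builds quickly during
water-holding early in the cycle, then collapses when fresh water inflow
resumes — Californian pattern) and a *gradual ramp* (saline soils and
evapo-concentration raise field-water salinity steadily until mid-season,
constant afterwards — Greek pattern).  A seeded weather generator stands in
for multi-year reanalysis series.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: conventional dilute-NaCl approximation, mM Na+ per dS m-1
DEFAULT_MM_PER_DSM = 10.0

NA_MOLAR_MASS = 22.99  # mg mmol-1


@dataclass(frozen=True)
class DailyEnvironment:
    """One day of forcing: weather plus external-medium salinity.

    ``rh`` air relative humidity (%), ``na_ext`` Na+ concentration of the
    external medium (mM), ``tmean`` mean air temperature (deg C),
    ``radiation`` global solar radiation (MJ m-2 d-1), ``et0`` reference
    evapotranspiration (mm d-1).
    """

    rh: float
    na_ext: float
    tmean: float
    radiation: float
    et0: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rh <= 100.0):
            raise ValueError("rh must be in [0, 100]")
        if self.na_ext < 0.0:
            raise ValueError("na_ext must be non-negative")


@dataclass(frozen=True)
class SalinityScenario:
    """Parameterised seasonal salinity pattern, in field-water EC units.

    ``pattern`` is one of ``early_peak``, ``gradual_ramp``, ``constant`` or
    ``custom``.  ``peak_ec`` (dS m-1) is the maximum EC of the season.  The
    breakpoints are fractions of the season: for ``early_peak``, EC ramps
    from 0 to the peak at ``peak_day_frac``, holds until ``release_day_frac``
    (fresh-water inflow), then decays sharply to ``residual_frac`` of the
    peak; for ``gradual_ramp``, EC rises linearly to the plateau at
    ``plateau_day_frac`` and stays constant.  ``mm_per_dsm`` converts EC to
    Na+ molarity.
    """

    pattern: str = "constant"
    peak_ec: float = 3.5
    peak_day_frac: float = 0.15
    release_day_frac: float = 0.33
    decay_days: float = 7.0
    residual_frac: float = 0.05
    plateau_day_frac: float = 0.5
    mm_per_dsm: float = DEFAULT_MM_PER_DSM
    custom_ec: tuple[float, ...] = ()

    _PATTERNS = ("early_peak", "gradual_ramp", "constant", "custom")

    def __post_init__(self) -> None:
        if self.pattern not in self._PATTERNS:
            raise ValueError(f"pattern must be one of {self._PATTERNS}")
        if self.peak_ec < 0.0:
            raise ValueError("peak_ec must be non-negative")


def ec_to_molarity(ec, factor: float = DEFAULT_MM_PER_DSM):
    """Convert electrical conductivity (dS m-1) to Na+ molarity (mM).

    Linear with a configurable factor; the default 10 mM per dS m-1 is the
    standard approximation for dilute NaCl solutions.
    """
    ec = np.asarray(ec, dtype=float)
    if np.any(ec < 0):
        raise ValueError("ec must be non-negative")
    out = ec * factor
    return float(out) if out.ndim == 0 else out


def make_salinity_series(scenario: SalinityScenario, season_length: int) -> np.ndarray:
    """Daily external Na+ molarity series (mM) of length ``season_length``."""
    if season_length <= 0:
        raise ValueError("season_length must be positive")
    d = np.arange(season_length, dtype=float)
    L = float(season_length)
    p = scenario
    if p.pattern == "constant":
        ec = np.full(season_length, p.peak_ec)
    elif p.pattern == "early_peak":
        t_peak = max(p.peak_day_frac * L, 1.0)
        t_rel = max(p.release_day_frac * L, t_peak + 1.0)
        ec = np.empty(season_length)
        rising = d < t_peak
        ec[rising] = p.peak_ec * d[rising] / t_peak
        hold = (d >= t_peak) & (d < t_rel)
        ec[hold] = p.peak_ec
        after = d >= t_rel
        # sharp exponential decay toward a small residual once fresh water returns
        ec[after] = p.residual_frac * p.peak_ec + (1.0 - p.residual_frac) * p.peak_ec * np.exp(
            -(d[after] - t_rel) / max(p.decay_days, 1e-9)
        )
    elif p.pattern == "gradual_ramp":
        t_mid = max(p.plateau_day_frac * L, 1.0)
        ec = np.minimum(d / t_mid, 1.0) * p.peak_ec
    else:  # custom
        if len(p.custom_ec) != season_length:
            raise ValueError("custom_ec length must equal season_length")
        ec = np.asarray(p.custom_ec, dtype=float)
    return ec_to_molarity(ec, p.mm_per_dsm)


def make_weather(
    season_length: int,
    seed: int,
    *,
    t_mean_mid: float = 24.0,
    t_amplitude: float = 5.0,
    rad_mid: float = 20.0,
    rad_amplitude: float = 6.0,
    rh_band: tuple[float, float] = (58.0, 92.0),
    noise_sd_t: float = 1.5,
    noise_sd_rad: float = 2.0,
) -> list[DailyEnvironment]:
    """Seeded synthetic season of daily weather (no salinity; ``na_ext`` = 0).

    Temperature and radiation follow half-sine seasonal curves peaking at
    mid-season, plus bounded Gaussian noise; relative humidity is drawn
    uniformly within ``rh_band``; ET0 is a Hargreaves-flavoured bilinear
    function of temperature and radiation.  Fully reproducible from
    ``seed`` alone.
    """
    if season_length <= 0:
        raise ValueError("season_length must be positive")
    rng = np.random.default_rng(seed)
    d = np.arange(season_length)
    phase = np.sin(np.pi * d / max(season_length - 1, 1))
    tmean = t_mean_mid - t_amplitude + 2 * t_amplitude * phase
    tmean = tmean + np.clip(rng.normal(0.0, noise_sd_t, season_length), -3 * noise_sd_t, 3 * noise_sd_t)
    rad = rad_mid - rad_amplitude + 2 * rad_amplitude * phase
    rad = rad + np.clip(rng.normal(0.0, noise_sd_rad, season_length), -3 * noise_sd_rad, 3 * noise_sd_rad)
    rad = np.clip(rad, 1.0, None)
    rh = rng.uniform(rh_band[0], rh_band[1], season_length)
    et0 = np.clip(0.013 * (tmean + 17.8) * rad * 0.408, 0.5, None)
    return [
        DailyEnvironment(rh=float(rh[i]), na_ext=0.0, tmean=float(tmean[i]),
                         radiation=float(rad[i]), et0=float(et0[i]))
        for i in range(season_length)
    ]


def with_salinity(weather: Sequence[DailyEnvironment], na_ext: Sequence[float]) -> list[DailyEnvironment]:
    """Attach a daily Na+ series (mM) to a weather series."""
    if len(weather) != len(na_ext):
        raise ValueError("weather and salinity series must have equal length")
    return [
        DailyEnvironment(rh=w.rh, na_ext=float(s), tmean=w.tmean,
                         radiation=w.radiation, et0=w.et0)
        for w, s in zip(weather, na_ext)
    ]


# ---------------------------------------------------------------- file I/O

WEATHER_COLUMNS = ["day", "tmean", "radiation", "rh", "et0"]


def write_weather(path: str | Path, weather: Sequence[DailyEnvironment]) -> None:
    df = pd.DataFrame(
        {
            "day": np.arange(1, len(weather) + 1),
            "tmean": [w.tmean for w in weather],
            "radiation": [w.radiation for w in weather],
            "rh": [w.rh for w in weather],
            "et0": [w.et0 for w in weather],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_weather(path: str | Path) -> list[DailyEnvironment]:
    """Read a tab-delimited weather file.

    Requires ``radiation``, ``rh`` and ``et0`` columns plus either a
    ``tmean`` column or the ``tmin``/``tmax`` pair (averaged).
    """
    df = pd.read_csv(path, sep="\t")
    if "tmean" not in df.columns:
        if {"tmin", "tmax"} <= set(df.columns):
            df["tmean"] = 0.5 * (df["tmin"] + df["tmax"])
        else:
            raise ValueError("weather file needs 'tmean' or 'tmin'/'tmax' columns")
    missing = {"tmean", "radiation", "rh", "et0"} - set(df.columns)
    if missing:
        raise ValueError(f"weather file missing columns: {sorted(missing)}")
    return [
        DailyEnvironment(rh=float(r.rh), na_ext=0.0, tmean=float(r.tmean),
                         radiation=float(r.radiation), et0=float(r.et0))
        for r in df.itertuples()
    ]


def write_salinity(path: str | Path, na_ext_mm: Sequence[float]) -> None:
    pd.DataFrame(
        {"day": np.arange(1, len(na_ext_mm) + 1), "na_mm": np.asarray(na_ext_mm, dtype=float)}
    ).to_csv(path, sep="\t", index=False)


def read_salinity(path: str | Path, mm_per_dsm: float = DEFAULT_MM_PER_DSM) -> np.ndarray:
    """Read a salinity file with either an ``na_mm`` or an ``ec`` column."""
    df = pd.read_csv(path, sep="\t")
    if "na_mm" in df.columns:
        return df["na_mm"].to_numpy(dtype=float)
    if "ec" in df.columns:
        return ec_to_molarity(df["ec"].to_numpy(dtype=float), mm_per_dsm)
    raise ValueError("salinity file must have an 'na_mm' or 'ec' column")
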