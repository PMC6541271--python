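"""Synthetic daily weather for rice growing seasons.

Generates one 184-day series (May 01 – Oct 31, non-leap calendar) per
grid-cell-year, with a latitude-graded seasonal temperature cycle, AR(1)
day-to-day variability, clearness-modulated solar radiation, astronomical
day length, and constant CO2.  Scenario perturbations reproduce the three
stress regimes relevant to rice spikelet sterility: cool-summer spells,
heat waves around anthesis, and cold regions where the crop never matures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SEASON_DAYS = 184
#: day of year of May 01 in a non-leap calendar (day_of_year = 121)
PLANTING_DOY = 121
#: day index of October 05 counted from May 01 (day 0)
OCT05_INDEX = 157
DEFAULT_CO2_PPM = 350.0

SCENARIO_NAMES = ("baseline", "cool_summer", "heat_anthesis", "cold_region")

_MONTH_DAYS = ((5, 31), (6, 30), (7, 31), (8, 31), (9, 30), (10, 31))
SEASON_DATES = tuple(
    f"{m:02d}-{d:02d}" for m, nd in _MONTH_DAYS for d in range(1, nd + 1)
)
assert len(SEASON_DATES) == SEASON_DAYS


class WeatherError(ValueError):
    """Raised for invalid weather inputs or generator preconditions."""


@dataclass(frozen=True)
class ScenarioSpec:
    """A named weather perturbation applied on top of the baseline climate.

    ``delta_T`` is the perturbation magnitude in °C, applied inside
    ``window`` (inclusive day-index range from planting): ``cool_summer``
    subtracts it from Tmean, ``heat_anthesis`` adds it to Tmax, and
    ``cold_region`` subtracts it from both Tmean and Tmax (its window
    defaults to the whole season).  ``noise_sd`` is the innovation scale of
    the AR(1) daily temperature noise; ``seed`` feeds the per-series RNG.
    """

    name: str = "baseline"
    delta_T: float = 0.0
    window: tuple[int, int] = (0, SEASON_DAYS - 1)
    noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise WeatherError(f"unknown scenario {self.name!r}")
        if self.delta_T < 0:
            raise WeatherError("delta_T must be >= 0")
        lo, hi = self.window
        if not (0 <= lo <= hi <= SEASON_DAYS - 1):
            raise WeatherError(f"window {self.window} outside 0..{SEASON_DAYS - 1}")
        if self.noise_sd < 0:
            raise WeatherError("noise_sd must be >= 0")


def default_scenario(name: str, seed: int = 0) -> ScenarioSpec:
    """Scenario with the default magnitude and window for its stress regime."""
    defaults = {
        "baseline": dict(delta_T=0.0, window=(0, SEASON_DAYS - 1)),
        "cool_summer": dict(delta_T=5.0, window=(65, 120)),
        "heat_anthesis": dict(delta_T=6.0, window=(70, 120)),
        "cold_region": dict(delta_T=12.0, window=(0, SEASON_DAYS - 1)),
    }
    try:
        kw = defaults[name]
    except KeyError:
        raise WeatherError(f"unknown scenario {name!r}") from None
    return ScenarioSpec(name=name, seed=seed, **kw)


DEFAULT_SCENARIO_WEIGHTS: dict[str, float] = {
    "baseline": 0.55,
    "cool_summer": 0.20,
    "heat_anthesis": 0.20,
    "cold_region": 0.05,
}


@dataclass
class WeatherSeries:
    """One grid-cell-year of daily weather from planting (day 0 = May 01).

    Column arrays are aligned on day index 0..183.  ``tmean``/``tmax`` in
    °C, ``s_incident`` daily total global solar radiation in MJ m⁻² d⁻¹,
    ``day_len`` hours, ``co2`` ppm.
    """

    grid_id: str
    year_index: int
    latitude: float
    tmean: np.ndarray
    tmax: np.ndarray
    s_incident: np.ndarray
    day_len: np.ndarray
    co2: np.ndarray
    scenario: str = "baseline"

    def validate(self) -> None:
        arrays = (self.tmean, self.tmax, self.s_incident, self.day_len, self.co2)
        for a in arrays:
            if a.shape != (SEASON_DAYS,):
                raise WeatherError(
                    f"expected {SEASON_DAYS} daily records, got shape {a.shape}"
                )
            if not np.all(np.isfinite(a)):
                raise WeatherError("non-finite weather value")
        if np.any(self.tmax < self.tmean):
            raise WeatherError("Tmax < Tmean")
        if np.any((self.day_len <= 0) | (self.day_len >= 24)):
            raise WeatherError("day length outside (0, 24)")
        if np.any(self.s_incident < 0):
            raise WeatherError("negative solar radiation")
        if np.any(self.co2 <= 0):
            raise WeatherError("non-positive CO2")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day_index": np.arange(SEASON_DAYS),
                "date": SEASON_DATES,
                "Tmean": self.tmean,
                "Tmax": self.tmax,
                "S_incident": self.s_incident,
                "L": self.day_len,
                "P": self.co2,
            }
        )


def day_length(latitude: float, day_of_year: int) -> float:
    """Civil daylight duration in hours (sunrise-to-sunset hour angle).

    Uses the Cooper solar declination
    ``delta = 23.45° sin(2π (284 + N) / 365)`` and the daylight half-angle
    ``omega_s = arccos(-tan(phi) tan(delta))``; twilight and atmospheric
    refraction are ignored.  Latitudes within the polar circles only.
    """
    if not abs(latitude) < 66.5:
        raise WeatherError(f"latitude {latitude} outside supported band |lat| < 66.5")
    if not 1 <= day_of_year <= 366:
        raise WeatherError(f"day_of_year {day_of_year} outside 1..366")
    phi = math.radians(latitude)
    decl = math.radians(23.45) * math.sin(2.0 * math.pi * (284 + day_of_year) / 365.0)
    cos_omega = -math.tan(phi) * math.tan(decl)
    omega = math.acos(min(1.0, max(-1.0, cos_omega)))
    return 24.0 * omega / math.pi


def extraterrestrial_radiation(latitude: float, day_of_year: int) -> float:
    """Daily top-of-atmosphere solar radiation Ra in MJ m⁻² d⁻¹ (FAO-56)."""
    phi = math.radians(latitude)
    decl = math.radians(23.45) * math.sin(2.0 * math.pi * (284 + day_of_year) / 365.0)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * day_of_year / 365.0)
    cos_omega = -math.tan(phi) * math.tan(decl)
    omega = math.acos(min(1.0, max(-1.0, cos_omega)))
    gsc = 0.0820  # MJ m-2 min-1
    return (
        24.0 * 60.0 / math.pi
        * gsc
        * dr
        * (omega * math.sin(phi) * math.sin(decl)
           + math.cos(phi) * math.cos(decl) * math.sin(omega))
    )


def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float = 0.7) -> np.ndarray:
    z = rng.standard_normal(n)
    e = np.empty(n)
    e[0] = sd * z[0]
    innov = sd * math.sqrt(1.0 - rho * rho)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + innov * z[t]
    return e


def synth_weather(
    latitude: float,
    year_index: int,
    scenario: ScenarioSpec,
    seed: int,
    grid_id: str = "g000",
    co2_ppm: float = DEFAULT_CO2_PPM,
) -> WeatherSeries:
    """Generate one seeded grid-cell-year of daily weather.

    The baseline climate depends only on (latitude, year_index, seed,
    scenario.seed, scenario.noise_sd); the scenario perturbation is applied
    additively afterwards, so seed-matched series of different scenarios
    differ exactly by the perturbation.
    """
    rng = np.random.default_rng(
        [int(seed), int(year_index) & 0x7FFFFFFF, int(round(latitude * 1e4)),
         int(scenario.seed)]
    )
    doy = PLANTING_DOY + np.arange(SEASON_DAYS)  # 121..304, non-leap

    # seasonal cycle: warmer south, peak near end of July (doy 210)
    t_ann = 16.0 - 1.0 * (latitude - 35.7)
    t_amp = 10.5 + 0.2 * (latitude - 35.7)
    t_base = t_ann + t_amp * np.cos(2.0 * np.pi * (doy - 210) / 365.0)
    year_offset = 0.7 * rng.standard_normal()
    tmean = t_base + year_offset + _ar1(rng, SEASON_DAYS, scenario.noise_sd)

    # diurnal range: positive offset plus noise, never below Tmean
    dtr = 4.5 + 1.0 * rng.standard_normal(SEASON_DAYS)
    tmax = tmean + np.maximum(0.0, dtr)

    # radiation: clearness index applied to top-of-atmosphere radiation
    ra = np.array([extraterrestrial_radiation(latitude, int(d)) for d in doy])
    kt = np.clip(0.55 + 0.15 * _ar1(rng, SEASON_DAYS, 1.0, rho=0.5), 0.12, 0.78)
    s_inc = kt * ra

    day_len_h = np.array([day_length(latitude, int(d)) for d in doy])
    co2 = np.full(SEASON_DAYS, float(co2_ppm))

    lo, hi = scenario.window
    sl = slice(lo, hi + 1)
    if scenario.name == "cool_summer":
        tmean = tmean.copy()
        tmean[sl] -= scenario.delta_T
    elif scenario.name == "heat_anthesis":
        tmax = tmax.copy()
        tmax[sl] += scenario.delta_T
    elif scenario.name == "cold_region":
        tmean = tmean - scenario.delta_T
        tmax = tmax - scenario.delta_T
    tmax = np.maximum(tmax, tmean)

    series = WeatherSeries(
        grid_id=grid_id,
        year_index=int(year_index),
        latitude=float(latitude),
        tmean=tmean,
        tmax=tmax,
        s_incident=s_inc,
        day_len=day_len_h,
        co2=co2,
        scenario=scenario.name,
    )
    series.validate()
    return series


def synth_grid(
    n_grids: int,
    n_years: int,
    lat_range: tuple[float, float],
    scenario_weights: Mapping[str, float] | None = None,
    seed: int = 0,
    noise_sd: float = 1.5,
    co2_ppm: float = DEFAULT_CO2_PPM,
) -> list[WeatherSeries]:
    """Generate ``n_grids × n_years`` series with seeded scenario assignment.

    Latitudes are evenly spread across ``lat_range``; each grid-year draws
    its scenario from ``scenario_weights`` (default
    :data:`DEFAULT_SCENARIO_WEIGHTS`) with an RNG derived from ``seed``.
    """
    if n_grids < 1 or n_years < 1:
        raise WeatherError("n_grids and n_years must be >= 1")
    lat_lo, lat_hi = lat_range
    if not lat_hi > lat_lo:
        raise WeatherError(f"empty latitude range {lat_range}")
    weights = dict(scenario_weights or DEFAULT_SCENARIO_WEIGHTS)
    for name, w in weights.items():
        if name not in SCENARIO_NAMES:
            raise WeatherError(f"unknown scenario {name!r} in weights")
        if w < 0:
            raise WeatherError("scenario weights must be nonnegative")
    total = sum(weights.values())
    if total <= 0:
        raise WeatherError("scenario weights must not all be zero")

    names = sorted(weights)
    probs = np.array([weights[n] for n in names]) / total
    master = np.random.default_rng(seed)
    if n_grids == 1:
        lats = np.array([(lat_lo + lat_hi) / 2.0])
    else:
        lats = np.linspace(lat_lo, lat_hi, n_grids)

    out: list[WeatherSeries] = []
    for gi in range(n_grids):
        grid_id = f"g{gi:03d}"
        for yi in range(n_years):
            name = names[int(master.choice(len(names), p=probs))]
            scen = replace(default_scenario(name), noise_sd=noise_sd)
            series_seed = int(master.integers(0, 2**31 - 1))
            out.append(
                synth_weather(
                    lats[gi], yi, scen, series_seed,
                    grid_id=grid_id, co2_ppm=co2_ppm,
                )
            )
    return out


# --- CSV interchange ------------------------------------------------------

def write_weather_csv(series: WeatherSeries, path: str | Path) -> None:
    """One file per grid-year; metadata in '#'-prefixed lines, then header."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# grid_id: {series.grid_id}\n")
        fh.write(f"# year_index: {series.year_index}\n")
        fh.write(f"# latitude: {series.latitude!r}\n")
        fh.write(f"# scenario: {series.scenario}\n")
        series.to_frame().to_csv(fh, index=False)


def read_weather_csv(path: str | Path) -> WeatherSeries:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("# ").partition(":")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#")
    series = WeatherSeries(
        grid_id=meta.get("grid_id", path.stem),
        year_index=int(meta.get("year_index", 0)),
        latitude=float(meta.get("latitude", "nan")),
        tmean=df["Tmean"].to_numpy(float),
        tmax=df["Tmax"].to_numpy(float),
        s_incident=df["S_incident"].to_numpy(float),
        day_len=df["L"].to_numpy(float),
        co2=df["P"].to_numpy(float),
        scenario=meta.get("scenario", "baseline"),
    )
    series.validate()
    return series


def weather_filename(series: WeatherSeries) -> str:
    return f"{series.grid_id}_y{series.year_index:03d}.csv"


def write_weather_dir(series_list: Iterable[WeatherSeries], out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in series_list:
        p = out_dir / weather_filename(s)
        write_weather_csv(s, p)
        paths.append(p)
    return paths


def read_weather_dir(in_dir: str | Path) -> list[WeatherSeries]:
    paths = sorted(Path(in_dir).glob("*.csv"))
    if not paths:
        raise WeatherError(f"no weather CSV files in {in_dir}")
    return [read_weather_csv(p) for p in paths]
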