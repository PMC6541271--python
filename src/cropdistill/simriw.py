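"""Deterministic daily-step rice growth simulator (SIMRIW-style).

The model tracks a developmental index DVI (0 at emergence, 1 at heading,
2 at maturity) advanced daily by a developmental rate DVR driven by mean
temperature and day length, accumulates dry matter from canopy-absorbed
short-wave radiation, and forms grain yield as ``YG = h * Wt`` where the
harvest index ``h`` is reduced by spikelet sterility.  Sterility is the
maximum of a cool-summer component (cooling-degree sum below 22 °C while
0.75 < DVI < 1.2) and a heat-at-anthesis component (logistic in the mean
daily maximum temperature while 0.96 < DVI <= 1.22).

Canopy light interception is not part of the model's printed equations; a
documented surrogate is used: a developmental LAI curve peaking at DVI = 1
with Beer's-law absorption (see :func:`lai_and_absorption`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cultivar import CultivarParams
from .weather import OCT05_INDEX, SEASON_DAYS, WeatherSeries

# Heat-sterility logistic (cultivar-independent empirical constants):
# gammaH = 1 / (1 + exp(-HEAT_STERILITY_SLOPE * (TH - HEAT_STERILITY_T50)))
HEAT_STERILITY_SLOPE = 0.853
HEAT_STERILITY_T50 = 36.6  # degC
#: base temperature of the cooling-degree sum
COOL_BASE_T = 22.0  # degC
#: open DVI interval of panicle cool-temperature sensitivity
COOL_DVI_WINDOW = (0.75, 1.2)
#: half-open DVI interval (lo, hi] over which Tmax is averaged for heat sterility
HEAT_DVI_WINDOW = (0.96, 1.22)
#: DVI offset in the harvest-index development term
HARVEST_DVI_OFFSET = 1.22


class SimulationError(ValueError):
    pass


@dataclass
class SeasonResult:
    """Simulator output for one grid-cell-year.

    ``h_gammaH``/``h_gammaL`` are the harvest indices recomputed with only
    the heat (resp. cool) sterility component — the quantities whose lower
    tails define the stress-specific analysis cases.  ``excluded`` flags
    series whose DVI had not reached 2.0 by October 05 (day index 157).
    """

    grid_id: str
    year_index: int
    yg: float
    wt_final: float
    h: float
    h_gammaH: float
    h_gammaL: float
    gamma: float
    gammaH: float
    gammaL: float
    final_dvi: float
    dvi_by_day: np.ndarray
    wt_by_day: np.ndarray
    heading_day: int | None
    maturity_day: int | None
    excluded: bool


# --- developmental rate ---------------------------------------------------

def dvr_pre_heading(tmean: float, day_len: float, dvi: float,
                    params: CultivarParams) -> float:
    """Daily developmental rate before heading (0 <= DVI <= 1).

    A logistic temperature response with half rate at ``Th``; once DVI
    exceeds ``DVI_star`` the rate is additionally scaled by a short-day
    photoperiod factor and is zero for day lengths beyond the critical
    ``Lc`` (rice is a short-day plant).
    """
    if not 0.0 <= dvi <= 1.0:
        raise SimulationError(f"pre-heading DVR called at DVI={dvi}")
    denom = params.Gv * (1.0 + math.exp(-params.A * (tmean - params.Th)))
    if dvi <= params.DVI_star:
        return 1.0 / denom
    if day_len <= params.Lc:
        return (1.0 - math.exp(params.Bp * (day_len - params.Lc))) / denom
    return 0.0


def dvr_grain_filling(tmean: float, params: CultivarParams) -> float:
    """Daily developmental rate during grain filling (1 < DVI <= 2).

    Saturating temperature response above the base temperature ``Tcr``;
    floored at zero (development does not reverse below ``Tcr``).
    """
    return max(0.0, (1.0 - math.exp(-params.Kr * (tmean - params.Tcr)))) / params.Gr


# --- canopy and dry matter ------------------------------------------------

def lai_curve(dvi: float, params: CultivarParams) -> float:
    """Developmental LAI surrogate: rises to ``LAI_max`` at DVI = 1, then
    declines exponentially (senescence)."""
    if dvi <= 0.0:
        return 0.0
    if dvi <= 1.0:
        return params.LAI_max * dvi ** params.lai_rise_exp
    return params.LAI_max * math.exp(-params.lai_decline_rate * (dvi - 1.0))


def lai_and_absorption(s_incident: float, dvi: float,
                       params: CultivarParams) -> tuple[float, float]:
    """Beer's-law canopy absorption: ``Ss = S (1 - exp(-k LAI))``."""
    if s_incident < 0:
        raise SimulationError("negative incident radiation")
    lai = lai_curve(dvi, params)
    ss = s_incident * (1.0 - math.exp(-params.k_beer * lai))
    return lai, ss


def conversion_efficiency(dvi: float, co2_ppm: float,
                          params: CultivarParams) -> float:
    """Radiation conversion efficiency Cs (g DM MJ⁻¹).

    Constant at ``C0`` before heading, declining toward zero through the
    back half of grain filling, and scaled by a saturating CO2 response
    that equals 1 at 330 ppm and approaches ``1 + Rm`` at high CO2.
    """
    if co2_ppm <= 0:
        raise SimulationError("CO2 must be positive")
    if dvi < 1.0:
        c0_star = params.C0
    else:
        c0_star = (params.Cf * (1.0 + params.Bf)
                   / (1.0 + params.Bf * math.exp((dvi - 1.0) / params.tf)))
    co2_factor = 1.0 + params.Rm * (co2_ppm - 330.0) / ((co2_ppm - 330.0) + params.Kc)
    return max(0.0, c0_star * co2_factor)


def dry_matter_increment(cs: float, ss: float) -> float:
    """Daily dry matter gain ``dWt = Cs * Ss`` (g m⁻² d⁻¹)."""
    return cs * ss


# --- sterility and yield formation ---------------------------------------

def cooling_degree_sum(tmean_series: Sequence[float],
                       dvi_by_day: Sequence[float]) -> float:
    """Cooling-degree sum Qt = sum(max(0, 22 - Tmean)) over days with
    0.75 < DVI < 1.2 (days warmer than 22 °C contribute nothing)."""
    tmean = np.asarray(tmean_series, dtype=float)
    dvi = np.asarray(dvi_by_day, dtype=float)
    if tmean.shape != dvi.shape:
        raise SimulationError(
            f"misaligned series: {tmean.shape} vs {dvi.shape}")
    lo, hi = COOL_DVI_WINDOW
    mask = (dvi > lo) & (dvi < hi)
    return float(np.sum(np.maximum(0.0, COOL_BASE_T - tmean[mask])))


def sterility_cool(qt: float, params: CultivarParams) -> float:
    """Cool-summer sterility fraction, increasing in the cooling sum Qt."""
    if qt < 0:
        raise SimulationError("Qt must be >= 0")
    return float(min(1.0, max(0.0, params.gamma0 + params.Kq * qt ** params.aq)))


def sterility_heat(th: float) -> float:
    """Heat-at-anthesis sterility fraction: logistic in the mean daily
    maximum temperature over the anthesis window, midpoint 36.6 °C."""
    return 1.0 / (1.0 + math.exp(-HEAT_STERILITY_SLOPE * (th - HEAT_STERILITY_T50)))


def harvest_index(final_dvi: float, gamma: float, params: CultivarParams) -> float:
    """Harvest index: saturating in development past DVI = 1.22, scaled by
    the non-sterile fraction; zero when development stopped too early."""
    if not 0.0 <= gamma <= 1.0:
        raise SimulationError("gamma must be in [0, 1]")
    h = params.hm * (1.0 - gamma) * (
        1.0 - math.exp(-params.Kh * (final_dvi - HARVEST_DVI_OFFSET)))
    return max(0.0, h)


# --- season loop ----------------------------------------------------------

def simulate_season(weather: WeatherSeries, params: CultivarParams) -> SeasonResult:
    """Run the daily loop over one 184-day season.

    Per day: DVR from the day's weather and the current DVI, DVI update
    (capped at 2.0; heading/maturity flagged on first crossing of 1.0 and
    2.0), then canopy absorption and dry matter accumulation at the updated
    DVI.  Growth stops once matured.  Pure function of its inputs.
    """
    weather.validate()

    dvi = 0.0
    wt = 0.0
    heading_day: int | None = None
    maturity_day: int | None = None
    dvi_by_day = np.empty(SEASON_DAYS)
    wt_by_day = np.empty(SEASON_DAYS)

    for t in range(SEASON_DAYS):
        if dvi < 2.0:
            if dvi <= 1.0:
                dvr = dvr_pre_heading(weather.tmean[t], weather.day_len[t],
                                      dvi, params)
            else:
                dvr = dvr_grain_filling(weather.tmean[t], params)
            dvi = dvi + dvr
            if heading_day is None and dvi >= 1.0:
                heading_day = t
            if dvi >= 2.0:
                dvi = 2.0
                maturity_day = t
            _, ss = lai_and_absorption(weather.s_incident[t], dvi, params)
            cs = conversion_efficiency(dvi, weather.co2[t], params)
            wt += dry_matter_increment(cs, ss)
        dvi_by_day[t] = dvi
        wt_by_day[t] = wt

    qt = cooling_degree_sum(weather.tmean, dvi_by_day)
    gamma_l = sterility_cool(qt, params)

    lo, hi = HEAT_DVI_WINDOW
    heat_mask = (dvi_by_day > lo) & (dvi_by_day <= hi)
    if np.any(heat_mask):
        th = float(np.mean(weather.tmax[heat_mask]))
        gamma_h = sterility_heat(th)
    else:
        gamma_h = 0.0  # anthesis window never entered

    gamma = max(gamma_l, gamma_h)
    h = harvest_index(dvi, gamma, params)
    excluded = bool(dvi_by_day[OCT05_INDEX] < 2.0)

    return SeasonResult(
        grid_id=weather.grid_id,
        year_index=weather.year_index,
        yg=h * wt,
        wt_final=wt,
        h=h,
        h_gammaH=harvest_index(dvi, gamma_h, params),
        h_gammaL=harvest_index(dvi, gamma_l, params),
        gamma=gamma,
        gammaH=gamma_h,
        gammaL=gamma_l,
        final_dvi=dvi,
        dvi_by_day=dvi_by_day,
        wt_by_day=wt_by_day,
        heading_day=heading_day,
        maturity_day=maturity_day,
        excluded=excluded,
    )


def simulate_batch(series_list: Iterable[WeatherSeries],
                   params: CultivarParams) -> list[SeasonResult]:
    return [simulate_season(w, params) for w in series_list]


def results_to_frame(results: Sequence[SeasonResult]) -> pd.DataFrame:
    """One row per grid-year with all scalar result fields."""
    rows = []
    for r in results:
        rows.append({
            "grid_id": r.grid_id,
            "year_index": r.year_index,
            "YG": r.yg,
            "Wt_final": r.wt_final,
            "h": r.h,
            "h_gammaH": r.h_gammaH,
            "h_gammaL": r.h_gammaL,
            "gamma": r.gamma,
            "gammaH": r.gammaH,
            "gammaL": r.gammaL,
            "final_DVI": r.final_dvi,
            "heading_day": -1 if r.heading_day is None else r.heading_day,
            "maturity_day": -1 if r.maturity_day is None else r.maturity_day,
            "excluded": r.excluded,
        })
    return pd.DataFrame(rows)


def write_results(results: Sequence[SeasonResult], out_dir: str | Path) -> tuple[Path, Path]:
    """Scalar results CSV plus a companion CSV of DVI trajectories."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scalars = out_dir / "season_results.csv"
    results_to_frame(results).to_csv(scalars, index=False)
    traj = out_dir / "dvi_trajectories.csv"
    dvi = pd.DataFrame(
        np.stack([r.dvi_by_day for r in results]),
        columns=[f"d{t:03d}" for t in range(SEASON_DAYS)],
    )
    dvi.insert(0, "grid_id", [r.grid_id for r in results])
    dvi.insert(1, "year_index", [r.year_index for r in results])
    dvi.to_csv(traj, index=False)
    return scalars, traj
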