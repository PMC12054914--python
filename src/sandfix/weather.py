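"""Station weather series and monthly climate summaries.

A :class:`WeatherSeries` holds one station's daily records: 10-m wind speed,
mean temperature, precipitation, solar radiation and snow depth.  The wind
erosion climate factor consumes these through per-calendar-month, multi-year
summaries (:class:`MonthlyClimateSummary`): mean 2-m wind speed, count of
erosive days, precipitation totals, wet-day counts, potential
evapotranspiration and snow-cover probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .factors import air_density, convert_wind_height

__all__ = ["WeatherSeries", "MonthlyClimateSummary", "monthly_summaries"]

#: precipitation (mm) at or above which a day counts as a wet day
WET_DAY_MM = 0.1
#: snow depth (mm) above which a day counts as snow-covered
SNOW_COVER_MM = 25.4
#: wind speed (m/s, at 2 m) above which a day counts as erosive
EROSIVE_WIND_MS = 5.0

STATION_CSV_COLUMNS = ["date", "u10", "temp", "precip", "sr", "snow"]


@dataclass
class WeatherSeries:
    """Daily meteorology for one station.

    ``records`` columns: ``date`` (datetime), ``u10`` (m/s at 10 m), ``temp``
    (deg C), ``precip`` (mm), ``sr`` (solar radiation, cal/cm^2/day), ``snow``
    (snow depth, mm).  ``elevation_km`` is the station altitude in km, used
    for air density.
    """

    station_id: str
    lon: float
    lat: float
    elevation_km: float
    records: pd.DataFrame = field(repr=False)
    #: optional projected coordinates (m) on the working grid, used by IDW
    x: float | None = None
    y: float | None = None

    def __post_init__(self) -> None:
        missing = [c for c in STATION_CSV_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"station {self.station_id}: missing columns {missing}")
        rec = self.records
        dates = pd.to_datetime(rec["date"])
        if len(dates) == 0:
            raise ValueError(f"station {self.station_id}: empty record")
        gaps = dates.diff().dropna()
        if not (gaps == pd.Timedelta(days=1)).all():
            raise ValueError(f"station {self.station_id}: dates not contiguous daily")
        for col in ("u10", "precip", "snow"):
            if (rec[col] < 0).any():
                raise ValueError(f"station {self.station_id}: negative {col}")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.records.copy()
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
        out[STATION_CSV_COLUMNS].to_csv(path, index=False, float_format="%.6g")
        return path

    @classmethod
    def from_csv(
        cls, path: str | Path, station_id: str, lon: float, lat: float, elevation_km: float
    ) -> "WeatherSeries":
        rec = pd.read_csv(path, parse_dates=["date"])
        return cls(station_id, lon, lat, elevation_km, rec)


@dataclass(frozen=True)
class MonthlyClimateSummary:
    """Multi-year average climate for one calendar month at one station.

    ``u2_mean`` is the mean 2-m wind speed over all days (m/s); ``nd`` the
    average number of erosive days (2-m wind > 5 m/s) in the month; ``r_mm``
    the mean monthly precipitation; ``rd`` the mean number of wet days;
    ``etp_mm`` mean monthly potential evapotranspiration; ``p_snow`` the
    probability of snow cover deeper than 25.4 mm; ``rho`` air density
    (kg/m^3) at the station altitude and mean monthly temperature.
    """

    month: int
    u2_mean: float
    nd: float
    r_mm: float
    rd: float
    etp_mm: float
    p_snow: float
    rho: float
    days_in_month: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_snow <= 1.0:
            raise ValueError(f"month {self.month}: p_snow outside [0,1]")
        if self.nd < 0 or self.nd > self.days_in_month:
            raise ValueError(f"month {self.month}: nd outside [0, days in month]")
        if self.r_mm < 0 or self.etp_mm < 0:
            raise ValueError(f"month {self.month}: negative precipitation or ETp")


def potential_evapotranspiration(sr_total: float | np.ndarray, dt_mean: float | np.ndarray):
    """Monthly potential evapotranspiration (mm) from solar radiation and temperature.

    ETp = 0.0162 * (SR / 58.5) * (DT + 17.8), with SR the monthly total solar
    radiation in cal/cm^2 and DT the monthly mean temperature in deg C.  The
    result is floored at zero (very cold months).
    """
    etp = 0.0162 * (np.asarray(sr_total, dtype=float) / 58.5) * (np.asarray(dt_mean, dtype=float) + 17.8)
    return np.maximum(etp, 0.0)


def monthly_summaries(
    series: WeatherSeries,
    anemometer_height_m: float = 10.0,
    erosive_threshold: float = EROSIVE_WIND_MS,
    etp_monthly: dict[int, float] | None = None,
) -> list[MonthlyClimateSummary]:
    """Reduce a daily station series to 12 multi-year monthly climate summaries.

    Wind is converted from the anemometer height to 2 m before thresholding.
    When ``etp_monthly`` is given (month -> mm) it is used directly; otherwise
    ETp is computed from solar radiation and mean temperature.
    """
    rec = series.records.copy()
    rec["date"] = pd.to_datetime(rec["date"])
    rec["u2"] = convert_wind_height(rec["u10"].to_numpy(float), anemometer_height_m)
    rec["year"] = rec["date"].dt.year
    rec["month"] = rec["date"].dt.month

    out: list[MonthlyClimateSummary] = []
    for month, grp in rec.groupby("month"):
        n_years = grp["year"].nunique()
        days = len(grp) / n_years
        nd = float((grp["u2"] > erosive_threshold).sum()) / n_years
        u2_mean = float(grp["u2"].mean())
        r_mm = float(grp["precip"].sum()) / n_years
        rd = float((grp["precip"] >= WET_DAY_MM).sum()) / n_years
        p_snow = float((grp["snow"] > SNOW_COVER_MM).mean())
        dt_mean = float(grp["temp"].mean())
        if etp_monthly is not None and month in etp_monthly:
            etp = float(etp_monthly[month])
        else:
            sr_total = float(grp["sr"].sum()) / n_years
            etp = float(potential_evapotranspiration(sr_total, dt_mean))
        rho = air_density(series.elevation_km, dt_mean + 273.15)
        out.append(
            MonthlyClimateSummary(
                month=int(month),
                u2_mean=u2_mean,
                nd=nd,
                r_mm=r_mm,
                rd=rd,
                etp_mm=etp,
                p_snow=p_snow,
                rho=float(rho),
                days_in_month=days,
            )
        )
    return out
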