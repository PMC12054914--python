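"""The five RWEQ factor layers and their meteorological precursors.

The revised wind erosion equation expresses transport capacity as the product
of five factors: a climate/weather factor WF (kg/m), the soil erodible
fraction EF, the soil crust factor SCF, the surface roughness factor K' and
the vegetation factor C (all unitless multipliers in (0, 1] apart from K').
This module provides each factor as a scalar/array function plus the raster
builders that assemble a :class:`FactorStack` from station weather, soil
texture, a DEM and NDVI.

Scalar functions are vectorised: every formula accepts floats or numpy arrays
and returns the matching shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import GridSpec, mask_nodata

if TYPE_CHECKING:  # pragma: no cover
    from .weather import MonthlyClimateSummary

__all__ = [
    "FactorStack",
    "convert_wind_height",
    "air_density",
    "wind_intensity_factor",
    "soil_wetness_factor",
    "snow_factor",
    "weather_factor",
    "idw_interpolate",
    "erodibility_factor",
    "crust_factor",
    "fractional_cover",
    "vegetation_factor",
    "ridge_roughness",
    "roughness_factor",
]

GRAVITY = 9.8  # m/s^2
#: erosive wind threshold u1 (m/s at 2 m)
U1_THRESHOLD = 5.0
#: vegetation suppression coefficient per percent cover
AI_PER_PERCENT = -0.0438


@dataclass
class FactorStack:
    """The five aligned factor rasters feeding the erosion equations."""

    WF: np.ndarray
    EF: np.ndarray
    SCF: np.ndarray
    Kprime: np.ndarray
    C: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        for name in ("WF", "EF", "SCF", "Kprime", "C"):
            layer = getattr(self, name)
            if layer.shape != self.grid.shape:
                raise ValueError(f"{name} shape {layer.shape} != grid {self.grid.shape}")

    def valid_mask(self) -> np.ndarray:
        ok = np.ones(self.grid.shape, dtype=bool)
        for name in ("WF", "EF", "SCF", "Kprime", "C"):
            ok &= ~mask_nodata(getattr(self, name), self.grid)
        return ok


# ---------------------------------------------------------------------------
# wind & climate
# ---------------------------------------------------------------------------

def convert_wind_height(u_z, z: float = 10.0):
    """Convert wind speed measured at height ``z`` (m) to 2 m.

    Uses the FAO logarithmic-profile conversion
    ``u2 = u_z * 4.87 / ln(67.8 z - 5.42)``; standard anemometer height is
    10 m, for which the factor is ~0.748.
    """
    if 67.8 * z - 5.42 <= 0:
        raise ValueError(f"height z={z} m is below the valid profile range")
    u_z = np.asarray(u_z, dtype=float)
    if (u_z < 0).any():
        raise ValueError("wind speed must be non-negative")
    result = u_z * 4.87 / np.log(67.8 * z - 5.42)
    return result if result.ndim else float(result)


def air_density(el_km, t_kelvin):
    """Air density (kg/m^3) from altitude (km) and absolute temperature (K).

    rho = 348.0 * (1.013 - 0.1183 EL + 0.0048 EL^2) / T
    """
    t_kelvin = np.asarray(t_kelvin, dtype=float)
    if (t_kelvin <= 0).any():
        raise ValueError("absolute temperature must be positive")
    el_km = np.asarray(el_km, dtype=float)
    rho = 348.0 * (1.013 - 0.1183 * el_km + 0.0048 * el_km**2) / t_kelvin
    return rho if rho.ndim else float(rho)


def wind_intensity_factor(u2_mean, u1: float = U1_THRESHOLD, nd=0.0):
    """Wind field intensity Wf (m^3/s^3) for one month.

    ``Wf = u2 * (u2 - u1)^2 * Nd`` for mean 2-m wind ``u2`` above the erosive
    threshold ``u1`` (5 m/s), zero otherwise — sub-threshold wind moves no
    sand.  ``nd`` is the number of erosive days in the month.
    """
    nd = np.asarray(nd, dtype=float)
    if (nd < 0).any():
        raise ValueError("day count nd must be non-negative")
    u2 = np.asarray(u2_mean, dtype=float)
    wf = np.where(u2 > u1, u2 * (u2 - u1) ** 2 * nd, 0.0)
    return wf if wf.ndim else float(wf)


def soil_wetness_factor(etp_mm, r_mm, i_mm=0.0, rd=0.0, nd_period=30.0):
    """Soil moisture suppression SW in [0, 1].

    ``SW = (ETp - (R + I) * Rd / Nd) / ETp`` clamped to [0, 1]: the wetter the
    month relative to its evaporative demand, the smaller the factor.  ``I``
    is irrigation (mm), zero where unrecorded.
    """
    etp = np.asarray(etp_mm, dtype=float)
    if (etp <= 0).any():
        raise ValueError("ETp must be positive")
    sw = (etp - (np.asarray(r_mm, float) + np.asarray(i_mm, float)) * np.asarray(rd, float) / float(nd_period)) / etp
    sw = np.clip(sw, 0.0, 1.0)
    return sw if sw.ndim else float(sw)


def snow_factor(snow_depth_mm: Sequence[float] | np.ndarray, threshold_mm: float = 25.4) -> float:
    """Snow cover factor SD = 1 - P(snow depth > 25.4 mm) over a daily series."""
    depths = np.asarray(snow_depth_mm, dtype=float)
    if depths.size == 0:
        raise ValueError("snow depth series is empty")
    return float(1.0 - np.mean(depths > threshold_mm))


def weather_factor(monthlies: "Sequence[MonthlyClimateSummary]", g: float = GRAVITY) -> float:
    """Annual climate factor WF (kg/m): sum of monthly ``Wf * rho/g * SW * SD``.

    Months whose mean 2-m wind never clears the erosive threshold contribute
    zero, so WF is additive over any partition of the period into months.
    """
    if not monthlies:
        raise ValueError("no monthly summaries supplied")
    total = 0.0
    for m in monthlies:
        wf = wind_intensity_factor(m.u2_mean, nd=m.nd)
        sw = soil_wetness_factor(m.etp_mm, m.r_mm, 0.0, m.rd, m.days_in_month)
        sd = 1.0 - m.p_snow
        total += wf * (m.rho / g) * sw * sd
    return float(total)


def idw_interpolate(
    stations: Sequence[tuple[float, float, float]],
    grid: GridSpec,
    power: float = 2.0,
    k: int | None = None,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation of station values onto a grid.

    ``stations`` is a sequence of ``(x, y, value)`` in the grid's projected
    coordinates.  Each cell takes the d^(-power)-weighted mean of its ``k``
    nearest stations (all stations by default); a cell whose center coincides
    with a station returns that station's value exactly.
    """
    if len(stations) == 0:
        raise ValueError("IDW needs at least one station")
    pts = np.array([(s[0], s[1]) for s in stations], dtype=float)
    vals = np.array([s[2] for s in stations], dtype=float)
    if k is None or k > len(stations):
        k = len(stations)
    xs, ys = grid.cell_centers()
    query = np.column_stack([xs.ravel(), ys.ravel()])
    tree = cKDTree(pts)
    dist, idx = tree.query(query, k=k)
    dist = np.atleast_2d(dist.reshape(len(query), -1))
    idx = np.atleast_2d(idx.reshape(len(query), -1))
    out = np.empty(len(query), dtype=float)
    exact = dist[:, 0] < 1e-9
    out[exact] = vals[idx[exact, 0]]
    rest = ~exact
    w = dist[rest] ** (-power)
    out[rest] = np.sum(w * vals[idx[rest]], axis=1) / np.sum(w, axis=1)
    return out.reshape(grid.shape)


# ---------------------------------------------------------------------------
# soil
# ---------------------------------------------------------------------------

def erodibility_factor(sa, si, cl, om, caco3, constant: float = 29.9):
    """Soil erodible fraction EF from texture and chemistry percentages.

    ``EF = (const + 0.31 Sa + 0.17 Si + 0.33 Sa/Cl - 2.59 OM - 0.95 CaCO3)/100``
    with Sa/Si/Cl the sand/silt/clay contents (%), OM organic matter (%) and
    CaCO3 (%).  ``constant`` defaults to 29.9; pass 29.09 for the
    canonical RWEQ coefficient.  Zero clay makes the ratio term singular and
    yields NaN (raster callers map it to nodata).
    """
    sa, si, cl = (np.asarray(v, dtype=float) for v in (sa, si, cl))
    om, caco3 = np.asarray(om, dtype=float), np.asarray(caco3, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(cl > 0, sa / np.where(cl > 0, cl, 1.0), np.nan)
    ef = (constant + 0.31 * sa + 0.17 * si + 0.33 * ratio - 2.59 * om - 0.95 * caco3) / 100.0
    if ef.ndim == 0:
        ef = float(ef)
        if np.isnan(ef):
            raise ZeroDivisionError("clay content is zero; Sa/Cl undefined")
        return ef
    return ef


def crust_factor(cl, om):
    """Soil crust factor ``SCF = 1 / (1 + 0.0066 Cl^2 + 0.021 OM^2)`` in (0, 1]."""
    cl = np.asarray(cl, dtype=float)
    om = np.asarray(om, dtype=float)
    if (cl < 0).any() or (om < 0).any():
        raise ValueError("clay and organic matter contents must be non-negative")
    scf = 1.0 / (1.0 + 0.0066 * cl**2 + 0.021 * om**2)
    return scf if scf.ndim else float(scf)


# ---------------------------------------------------------------------------
# vegetation
# ---------------------------------------------------------------------------

def fractional_cover(ndvi, ndvi_soil: float | None = None, ndvi_veg: float | None = None):
    """Fractional vegetation cover by the NDVI pixel-dichotomy model.

    ``SC = (NDVI - NDVI_soil) / (NDVI_veg - NDVI_soil)`` clipped to [0, 1].
    When the bare-soil / full-vegetation endpoints are not supplied they are
    taken as the 5th and 95th percentiles of the scene's NDVI distribution.
    """
    ndvi = np.asarray(ndvi, dtype=float)
    if ndvi_soil is None:
        ndvi_soil = float(np.nanpercentile(ndvi, 5))
    if ndvi_veg is None:
        ndvi_veg = float(np.nanpercentile(ndvi, 95))
    if not ndvi_veg > ndvi_soil:
        raise ValueError(f"need ndvi_veg > ndvi_soil, got {ndvi_veg} <= {ndvi_soil}")
    sc = np.clip((ndvi - ndvi_soil) / (ndvi_veg - ndvi_soil), 0.0, 1.0)
    return sc if sc.ndim else float(sc)


def vegetation_factor(sc, ai: float = AI_PER_PERCENT, cover_scale: str = "percent"):
    """Vegetation factor ``C = exp(ai * cover)`` in (0, 1].

    ``sc`` is fractional cover in [0, 1]; with the default
    ``cover_scale='percent'`` it is multiplied by 100 before applying
    ``ai = -0.0438`` (per percent cover), so full cover suppresses erosion to
    ``e^-4.38 ~ 0.0125``.  ``cover_scale='fraction'`` applies ai to the raw
    fraction instead.
    """
    sc = np.asarray(sc, dtype=float)
    finite = sc[~np.isnan(sc)]
    if ((finite < 0) | (finite > 1)).any():
        raise ValueError("fractional cover must lie in [0, 1]")
    if cover_scale == "percent":
        c = np.exp(ai * sc * 100.0)
    elif cover_scale == "fraction":
        c = np.exp(ai * sc)
    else:
        raise ValueError(f"unknown cover_scale {cover_scale!r}")
    return c if c.ndim else float(c)


# ---------------------------------------------------------------------------
# terrain
# ---------------------------------------------------------------------------

def ridge_roughness(dem: np.ndarray, grid: GridSpec, length_m: float = 1000.0) -> np.ndarray:
    """Smith–Carson ridge roughness Kr (cm) from a DEM.

    Per cell, ``dH`` is the elevation range (max - min, m) within a square
    focal window of radius ``length_m``; ``Kr = 0.2 * dH^2 / L`` in meters,
    reported in cm.  Nodata DEM cells yield NaN.
    """
    if length_m <= 0:
        raise ValueError("window length must be positive")
    half_cells = int(round(length_m / grid.cellsize))
    if half_cells < 1:
        raise ValueError(
            f"window radius {length_m} m is smaller than one cell ({grid.cellsize} m)"
        )
    size = 2 * half_cells + 1
    arr = np.asarray(dem, dtype=float)
    bad = mask_nodata(arr, grid)
    work = arr.copy()
    work[bad] = np.nan
    # max/min filters ignore NaN by substituting +/- inf, then restore
    hi = ndimage.maximum_filter(np.where(np.isnan(work), -np.inf, work), size=size, mode="nearest")
    lo = ndimage.minimum_filter(np.where(np.isnan(work), np.inf, work), size=size, mode="nearest")
    dh = hi - lo
    kr_m = 0.2 * dh**2 / length_m
    kr_cm = kr_m * 100.0
    kr_cm[bad] = np.nan
    return kr_cm


def roughness_factor(kr_cm, crr_cm: float = 0.0, exponent: float = 0.94):
    """Surface roughness factor ``K' = exp(1.86 Kr - 2.41 Kr^e - 0.127 Crr)``.

    ``kr_cm`` is the ridge roughness in cm; ``crr_cm`` the random roughness
    (0 where unmeasured).  ``exponent`` defaults to 0.94; pass 0.934 for the
    canonical RWEQ value.
    """
    kr = np.asarray(kr_cm, dtype=float)
    finite = kr[~np.isnan(kr)]
    if (finite < 0).any():
        raise ValueError("ridge roughness must be non-negative")
    kp = np.exp(1.86 * kr - 2.41 * kr**exponent - 0.127 * crr_cm)
    return kp if kp.ndim else float(kp)
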