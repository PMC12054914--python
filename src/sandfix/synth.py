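"""Self-contained synthetic scenes for exercising the erosion pipeline.

A :class:`SyntheticScene` bundles everything the pipeline consumes — DEM,
monthly NDVI, soil texture/chemistry with a derived soil-type map, two-epoch
land cover, socio-economic surfaces and multi-station daily weather — on one
shared grid, with the planted ground truth recorded so detector tests can
check recovery.

The scene emulates the structure of a mid-latitude sandy desert study area:
a west-to-east greening gradient (dry mobile dunes in the west, vegetated
margins in the east), a springtime high-wind season (so the count of erosive
days is nonzero but far from saturated), sparse convective rainfall, and
spatially smooth soil texture closing to 100%.  No attempt is made to
reproduce any real region's climatology or taxonomy.

All randomness flows from one integer seed through a single
``numpy.random.Generator``; identical seeds give bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GridSpec, write_raster
from .weather import STATION_CSV_COLUMNS, WeatherSeries

__all__ = ["SyntheticScene", "generate_scene", "plant_driver_response"]

LANDCOVER_CLASSES = {1: "desert", 2: "grassland", 3: "cropland", 4: "forest", 5: "water"}


@dataclass
class SyntheticScene:
    """All input layers of one synthetic study area, on a shared grid."""

    grid: GridSpec
    dem: np.ndarray
    ndvi_monthly: np.ndarray  # (12, nrows, ncols)
    sand_pct: np.ndarray
    silt_pct: np.ndarray
    clay_pct: np.ndarray
    om_pct: np.ndarray
    caco3_pct: np.ndarray
    soil_type: np.ndarray
    landcover_t0: np.ndarray
    landcover_t1: np.ndarray
    pop_density: np.ndarray
    gdp_density: np.ndarray
    stations: list[WeatherSeries]
    truth: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Assert the scene invariants (texture closure, NDVI range, shapes)."""
        shape = self.grid.shape
        layers = {
            "dem": self.dem, "sand_pct": self.sand_pct, "silt_pct": self.silt_pct,
            "clay_pct": self.clay_pct, "om_pct": self.om_pct, "caco3_pct": self.caco3_pct,
            "soil_type": self.soil_type, "landcover_t0": self.landcover_t0,
            "landcover_t1": self.landcover_t1, "pop_density": self.pop_density,
            "gdp_density": self.gdp_density,
        }
        for name, layer in layers.items():
            if layer.shape != shape:
                raise ValueError(f"{name} shape {layer.shape} != grid {shape}")
        if self.ndvi_monthly.shape != (12, *shape):
            raise ValueError("ndvi_monthly must be (12, nrows, ncols)")
        closure = self.sand_pct + self.silt_pct + self.clay_pct
        if not np.allclose(closure, 100.0, atol=0.01):
            raise ValueError("sand+silt+clay does not close to 100%")
        if self.ndvi_monthly.min() < -1 or self.ndvi_monthly.max() > 1:
            raise ValueError("NDVI outside [-1, 1]")
        for name in ("landcover_t0", "landcover_t1"):
            codes = np.unique(layers[name])
            if not np.isin(codes, list(LANDCOVER_CLASSES)).all():
                raise ValueError(f"{name} contains undeclared class codes {codes}")

    def write(self, directory: str | Path) -> Path:
        """Write every layer as a text raster and every station as a CSV,
        plus a manifest CSV tying them together."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        entries = []
        rasters = {
            "dem": (self.dem, "m"), "sand_pct": (self.sand_pct, "%"),
            "silt_pct": (self.silt_pct, "%"), "clay_pct": (self.clay_pct, "%"),
            "om_pct": (self.om_pct, "%"), "caco3_pct": (self.caco3_pct, "%"),
            "soil_type": (self.soil_type, "class"),
            "landcover_t0": (self.landcover_t0, "class"),
            "landcover_t1": (self.landcover_t1, "class"),
            "pop_density": (self.pop_density, "persons/km2"),
            "gdp_density": (self.gdp_density, "currency/km2"),
        }
        for m in range(12):
            rasters[f"ndvi_{m + 1:02d}"] = (self.ndvi_monthly[m], "ndvi")
        for name, (layer, units) in rasters.items():
            path = directory / f"{name}.asc"
            write_raster(np.asarray(layer, dtype=float), self.grid, path, units=units)
            entries.append({"kind": "raster", "name": name, "path": path.name,
                            "units": units, "lon": "", "lat": "",
                            "elevation_km": "", "x": "", "y": ""})
        for st in self.stations:
            path = directory / f"station_{st.station_id}.csv"
            st.to_csv(path)
            entries.append({"kind": "station", "name": st.station_id, "path": path.name,
                            "units": "", "lon": st.lon, "lat": st.lat,
                            "elevation_km": st.elevation_km,
                            "x": st.x if st.x is not None else "",
                            "y": st.y if st.y is not None else ""})
        pd.DataFrame(entries).to_csv(directory / "manifest.csv", index=False)
        return directory


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field with spatial correlation."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate_scene(
    nrows: int = 60,
    ncols: int = 60,
    cellsize_m: float = 1000.0,
    n_stations: int = 5,
    years: int = 1,
    seed: int = 0,
    n_soil_classes: int = 5,
) -> SyntheticScene:
    """Generate a complete synthetic scene.

    Deterministic for a fixed ``seed``.  NDVI rises on average from west to
    east, so downstream erosion fields reproduce the qualitative pattern of
    strong erosion in the bare west and strong prevention service in the
    vegetated east.
    """
    if nrows < 4 or ncols < 4:
        raise ValueError("grid must be at least 4x4")
    if n_stations < 1:
        raise ValueError("need at least one station")
    if years < 1:
        raise ValueError("need at least one year")
    rng = np.random.default_rng(seed)
    grid = GridSpec(nrows=nrows, ncols=ncols, cellsize=cellsize_m,
                    origin_x=400_000.0, origin_y=4_400_000.0, crs="EPSG:32649")
    shape = grid.shape
    sigma = max(2.0, min(nrows, ncols) / 8.0)
    west_east = np.tile(np.linspace(0.0, 1.0, ncols), (nrows, 1))

    # terrain: gentle basin with modest local relief (the ridge-roughness
    # factor is extremely sensitive to relief above ~60 m per km)
    dem = 1100.0 + 15.0 * _smooth_field(rng, shape, sigma) + 120.0 * west_east
    dem = np.clip(dem, 900.0, 1600.0)

    # soil texture: sandy everywhere, sandier in the west; closes to 100
    sand = np.clip(82.0 - 18.0 * west_east + 6.0 * _smooth_field(rng, shape, sigma), 40.0, 95.0)
    remainder = 100.0 - sand
    clay_share = np.clip(0.35 + 0.10 * _smooth_field(rng, shape, sigma), 0.05, 0.8)
    clay = remainder * clay_share
    silt = remainder - clay
    om = np.clip(0.6 + 0.8 * west_east + 0.3 * _smooth_field(rng, shape, sigma), 0.05, 3.0)
    caco3 = np.clip(2.0 + 1.5 * _smooth_field(rng, shape, sigma), 0.0, 8.0)

    # soil type: quantile classes of a texture index (sand corrected by OM)
    texture_index = sand - 2.0 * om
    edges = np.quantile(texture_index, np.linspace(0, 1, n_soil_classes + 1)[1:-1])
    soil_type = (np.searchsorted(edges, texture_index) + 1).astype(int)

    # NDVI: west-east greening gradient x summer-peaking seasonal cycle
    base = 0.05 + 0.45 * west_east + 0.06 * _smooth_field(rng, shape, sigma)
    months = np.arange(12)
    season = 0.55 + 0.45 * np.cos((months - 6) / 12.0 * 2.0 * np.pi)  # peak in July
    ndvi = np.clip(base[None] * season[:, None, None]
                   + 0.015 * rng.standard_normal((12, *shape)), -1.0, 1.0)

    # land cover from mean NDVI; epoch 1 perturbs the class boundaries
    mean_ndvi = ndvi.mean(axis=0)
    lc_breaks = np.array([0.08, 0.16, 0.26, 0.38])

    def classify(surface: np.ndarray) -> np.ndarray:
        return (np.searchsorted(lc_breaks, surface) + 1).astype(int)

    landcover_t0 = classify(mean_ndvi)
    landcover_t1 = classify(mean_ndvi + 0.03 * _smooth_field(rng, shape, sigma) + 0.01)

    # socio-economic surfaces: sparse log-normal hotspots in the greener east
    pop = np.exp(1.5 * _smooth_field(rng, shape, sigma) + 2.0 * west_east)
    gdp = pop * np.exp(0.5 * _smooth_field(rng, shape, sigma))

    stations = _generate_stations(rng, grid, n_stations, years)

    scene = SyntheticScene(
        grid=grid, dem=dem, ndvi_monthly=ndvi,
        sand_pct=sand, silt_pct=silt, clay_pct=clay, om_pct=om, caco3_pct=caco3,
        soil_type=soil_type, landcover_t0=landcover_t0, landcover_t1=landcover_t1,
        pop_density=pop, gdp_density=gdp, stations=stations,
        truth={"seed": seed, "n_soil_classes": n_soil_classes,
               "landcover_classes": dict(LANDCOVER_CLASSES)},
    )
    scene.validate()
    return scene


def _generate_stations(
    rng: np.random.Generator, grid: GridSpec, n_stations: int, years: int
) -> list[WeatherSeries]:
    """Daily weather per station: Weibull wind with a spring windy season,
    sinusoidal temperature, sparse rain, winter snow events."""
    dates = pd.date_range("2001-01-01", periods=365 * years, freq="D")
    doy = dates.dayofyear.to_numpy()
    month = dates.month.to_numpy()
    stations = []
    for i in range(n_stations):
        # projected position inside the grid; lon/lat only for bookkeeping
        fx = rng.uniform(0.1, 0.9)
        fy = rng.uniform(0.1, 0.9)
        x = grid.origin_x + fx * grid.ncols * grid.cellsize
        y = grid.origin_y + fy * grid.nrows * grid.cellsize
        lon = 107.0 + 4.0 * fx
        lat = 39.3 + 1.4 * fy
        elev_km = 1.0 + 0.4 * rng.uniform()

        # 2-m erosive threshold is 5 m/s <-> ~6.7 m/s at 10 m; spring scale
        # pushes the monthly mean above it, the rest of the year stays below
        windy = np.isin(month, (3, 4, 5))
        scale = np.where(windy, 8.5, 5.5) * (1.0 + 0.05 * rng.standard_normal())
        u10 = scale * rng.weibull(3.0, size=len(dates))

        temp = 8.0 + 18.0 * np.sin((doy - 100) / 365.0 * 2 * np.pi) + 2.5 * rng.standard_normal(len(dates))
        wet = rng.random(len(dates)) < np.where(np.isin(month, (6, 7, 8)), 0.18, 0.05)
        precip = np.where(wet, rng.gamma(1.5, 4.0, size=len(dates)), 0.0)
        sr = np.clip(450.0 + 250.0 * np.sin((doy - 100) / 365.0 * 2 * np.pi)
                     + 40.0 * rng.standard_normal(len(dates)), 50.0, None)
        cold = temp < -2.0
        snow_event = cold & (rng.random(len(dates)) < 0.25)
        snow = np.where(snow_event, rng.gamma(2.0, 18.0, size=len(dates)), 0.0)

        rec = pd.DataFrame({
            "date": dates, "u10": u10, "temp": temp,
            "precip": precip, "sr": sr, "snow": snow,
        })[STATION_CSV_COLUMNS]
        stations.append(
            WeatherSeries(station_id=f"S{i + 1:02d}", lon=lon, lat=lat,
                          elevation_km=elev_km, records=rec, x=x, y=y)
        )
    return stations


def plant_driver_response(
    strata: np.ndarray,
    between_var: float,
    noise_var: float,
    seed: int = 0,
) -> np.ndarray:
    """Plant a response whose variance splits into a known between/within ratio.

    Each stratum receives a mean drawn from a normal distribution and rescaled
    so the class-level variance is exactly ``between_var``; iid cell noise with
    variance ``noise_var`` is added.  In the large-sample, balanced limit the
    q statistic of the response on these strata is
    ``between_var / (between_var + noise_var)``.
    """
    if between_var < 0 or noise_var < 0:
        raise ValueError("variances must be non-negative")
    labels = np.asarray(strata)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("strata must contain at least 2 classes")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"stratum {c} has fewer than 2 cells")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal(classes.size)
    raw = raw - raw.mean()
    sd = raw.std()
    means = raw / sd * np.sqrt(between_var) if sd > 0 and between_var > 0 else np.zeros_like(raw)
    lookup = dict(zip(classes.tolist(), means.tolist()))
    response = np.vectorize(lookup.get)(labels).astype(float)
    response += np.sqrt(noise_var) * rng.standard_normal(labels.shape)
    return response
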