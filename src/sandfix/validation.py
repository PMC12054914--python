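"""Field validation of modelled soil loss against measured sand fluxes.

Pairs of measured and model-predicted soil loss (kg/m^2) from short field
campaigns are classified with a +/-50% accuracy criterion, and per-site-type
calibration lines (predicted regressed on measured) are fit with R^2 and
RMSE.  A ten-site observation table from a spring campaign in the Kubuqi
Desert (four mobile-dune sites, six farmland sites) ships with the package as
``sandfix.validation.load_observations()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ObservationPair",
    "ValidationSummary",
    "load_observations",
    "accuracy_classify",
    "ols_fit",
    "r_squared",
    "rmse",
    "validation_report",
]


@dataclass(frozen=True)
class ObservationPair:
    """One site's measured vs predicted soil loss (kg/m^2)."""

    site_id: str
    site_type: str
    lon: float
    lat: float
    measured: float
    predicted: float

    def __post_init__(self) -> None:
        if self.measured < 0 or self.predicted < 0:
            raise ValueError(f"{self.site_id}: negative soil loss")


@dataclass
class ValidationSummary:
    """Counts from the accuracy criterion plus per-group calibration fits."""

    n_accurate: int
    n_over: int
    n_under: int
    groups: pd.DataFrame  # index: site_type; columns: n, slope, intercept, r2, rmse


def load_observations(path: str | Path | None = None) -> list[ObservationPair]:
    """Load an observation table (CSV: site_id,site_type,lon,lat,measured,predicted).

    With no path, returns the packaged ten-site field campaign table.
    """
    if path is None:
        src = resources.files("sandfix.data").joinpath("field_observations.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return [
        ObservationPair(
            site_id=str(r.site_id), site_type=str(r.site_type),
            lon=float(r.lon), lat=float(r.lat),
            measured=float(r.measured), predicted=float(r.predicted),
        )
        for r in df.itertuples()
    ]


def accuracy_classify(
    pairs: list[ObservationPair], tol: float = 0.5
) -> tuple[int, int, int]:
    """Classify pairs by the +/-``tol`` relative accuracy criterion.

    A prediction inside the closed interval ``[measured*(1-tol),
    measured*(1+tol)]`` is accurate; above it, overestimated; below,
    underestimated.  A zero measurement collapses the interval to {0} and is
    flagged with a warning.
    """
    n_acc = n_over = n_under = 0
    for p in pairs:
        if p.measured == 0:
            warnings.warn(f"{p.site_id}: measured=0; classified by absolute 0 tolerance", stacklevel=2)
        lo = p.measured * (1.0 - tol)
        hi = p.measured * (1.0 + tol)
        if p.predicted > hi:
            n_over += 1
        elif p.predicted < lo:
            n_under += 1
        else:
            n_acc += 1
    return n_acc, n_over, n_under


def ols_fit(x, y) -> tuple[float, float]:
    """Ordinary least squares line ``y = slope*x + intercept``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired points")
    if np.allclose(x, x[0]):
        raise ValueError("x is constant; OLS fit is singular")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def r_squared(x, y) -> float:
    """Squared Pearson correlation of x and y (OLS coefficient of determination)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired points")
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero variance; correlation undefined")
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return r * r


def rmse(a, b) -> float:
    """Root mean square difference of two equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size == 0:
        raise ValueError("vectors must be nonempty and of equal length")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def validation_report(pairs: list[ObservationPair], tol: float = 0.5) -> ValidationSummary:
    """Pooled accuracy counts plus per-site-type calibration fits.

    Fits regress predicted on measured within each site type; groups whose
    fit is undefined (fewer than 2 points or constant measured values) keep
    their count but carry NaN fit columns, with a warning.
    """
    if not pairs:
        raise ValueError("no observation pairs")
    n_acc, n_over, n_under = accuracy_classify(pairs, tol=tol)
    rows = {}
    df = pd.DataFrame(
        {
            "site_type": [p.site_type for p in pairs],
            "measured": [p.measured for p in pairs],
            "predicted": [p.predicted for p in pairs],
        }
    )
    for site_type, grp in df.groupby("site_type"):
        x = grp["measured"].to_numpy()
        y = grp["predicted"].to_numpy()
        row = {"n": len(grp), "slope": np.nan, "intercept": np.nan, "r2": np.nan, "rmse": np.nan}
        try:
            row["slope"], row["intercept"] = ols_fit(x, y)
            row["r2"] = r_squared(x, y)
        except ValueError as exc:
            warnings.warn(f"{site_type}: fit skipped ({exc})", stacklevel=2)
        row["rmse"] = rmse(x, y) if len(grp) else np.nan
        rows[site_type] = row
    groups = pd.DataFrame(rows).T
    groups.index.name = "site_type"
    return ValidationSummary(n_accurate=n_acc, n_over=n_over, n_under=n_under, groups=groups)
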