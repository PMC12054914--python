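"""Potential/actual wind erosion, the prevention service and change accounting.

The transport model: the five factors multiply into a transport-capacity
term; maximum transport ``Qmax = 109.8 * product`` (kg/m) and critical field
length ``s = 150.71 * product^-0.3711`` (m) shape a saturating flux curve,
and the soil loss at downwind distance ``z`` is

    SL = (2 z / s^2) * Qmax * exp(-(z/s)^2)      [kg/m^2]

Potential erosion SLR uses the same chain with the vegetation factor C set to
1 (bare surface); the wind-erosion prevention service is WEPS = SLR - SL and
the retention rate F = WEPS/SLR * 100 (%).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .factors import FactorStack
from .grid import GridSpec, mask_nodata

__all__ = [
    "TransportParams",
    "ErosionFields",
    "critical_field_length",
    "max_transport",
    "erosion_flux",
    "weps",
    "retention_rate",
    "erosion_fields",
    "regional_total",
    "temporal_change",
    "landcover_transition_matrix",
]

log = logging.getLogger(__name__)

#: default downwind distance of maximum erosion (m)
DEFAULT_Z_M = 50.0


@dataclass(frozen=True)
class TransportParams:
    """Scalar transport geometry for one cell: ``z`` (m), critical length
    ``s`` (m) and transport capacity ``q_max`` (kg/m)."""

    z: float
    s_critical: float
    q_max: float

    def __post_init__(self) -> None:
        if self.z <= 0 or self.s_critical <= 0:
            raise ValueError("z and s_critical must be positive")
        if self.q_max < 0:
            raise ValueError("q_max must be non-negative")


@dataclass
class ErosionFields:
    """SLR/SL/WEPS/F rasters for one year on a shared grid."""

    SLR: np.ndarray
    SL: np.ndarray
    WEPS: np.ndarray
    F: np.ndarray
    grid: GridSpec
    year: str = ""

    def totals_tonnes(self) -> dict[str, float]:
        return {
            "SLR_t": regional_total(self.SLR, self.grid),
            "SL_t": regional_total(self.SL, self.grid),
            "WEPS_t": regional_total(self.WEPS, self.grid),
        }


def critical_field_length(wf, ef, scf, kprime, c=1.0):
    """Critical field length ``s = 150.71 * (WF*EF*SCF*K'*C)^-0.3711`` (m).

    With C omitted (=1) this is the potential-case length ``sr``.  A zero or
    negative factor product has no defined length; scalar calls raise and
    raster callers map those cells to NaN/nodata.
    """
    product = np.asarray(wf, float) * np.asarray(ef, float) * np.asarray(scf, float) \
        * np.asarray(kprime, float) * np.asarray(c, float)
    if product.ndim == 0:
        if not product > 0:
            raise ValueError(f"factor product must be positive, got {float(product)}")
        return float(150.71 * product ** (-0.3711))
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(product > 0, 150.71 * np.maximum(product, 1e-300) ** (-0.3711), np.nan)
    return s


def max_transport(wf, ef, scf, kprime, c=1.0):
    """Maximum sand transport capacity ``Qmax = 109.8 * WF*EF*SCF*K'*C`` (kg/m)."""
    arrs = [np.asarray(v, float) for v in (wf, ef, scf, kprime, c)]
    for a in arrs:
        if (a[~np.isnan(a)] < 0).any() if a.ndim else (not np.isnan(a) and a < 0):
            raise ValueError("all factor inputs must be non-negative")
    q = 109.8 * arrs[0] * arrs[1] * arrs[2] * arrs[3] * arrs[4]
    return q if q.ndim else float(q)


def erosion_flux(q_max, s, z: float = DEFAULT_Z_M):
    """Soil loss per unit area ``(2z/s^2) * Qmax * exp(-(z/s)^2)`` (kg/m^2)."""
    s = np.asarray(s, dtype=float)
    if s.ndim == 0:
        if not float(s) > 0:
            raise ValueError(f"critical length must be positive, got {float(s)}")
        if z <= 0:
            raise ValueError(f"z must be positive, got {z}")
        return float((2.0 * z / float(s) ** 2) * float(q_max) * np.exp(-((z / float(s)) ** 2)))
    if z <= 0:
        raise ValueError(f"z must be positive, got {z}")
    with np.errstate(divide="ignore", invalid="ignore"):
        flux = np.where(s > 0, (2.0 * z / s**2) * np.asarray(q_max, float) * np.exp(-((z / s) ** 2)), np.nan)
    return flux


def weps(slr: np.ndarray, sl: np.ndarray) -> np.ndarray:
    """Wind-erosion prevention service per cell: ``SLR - SL`` (kg/m^2).

    NaN in either operand propagates.
    """
    slr = np.asarray(slr, dtype=float)
    sl = np.asarray(sl, dtype=float)
    if slr.shape != sl.shape:
        raise ValueError(f"shape mismatch {slr.shape} vs {sl.shape}")
    return slr - sl


def retention_rate(weps_field: np.ndarray, slr: np.ndarray) -> np.ndarray:
    """Retention rate ``F = WEPS/SLR * 100`` (%); NaN where SLR is zero."""
    weps_field = np.asarray(weps_field, dtype=float)
    slr = np.asarray(slr, dtype=float)
    if weps_field.shape != slr.shape:
        raise ValueError(f"shape mismatch {weps_field.shape} vs {slr.shape}")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(slr > 0, weps_field / np.where(slr > 0, slr, 1.0) * 100.0, np.nan)
    return f


def erosion_fields(stack: FactorStack, z: float = DEFAULT_Z_M, year: str = "") -> ErosionFields:
    """Run the full transport chain on a factor stack.

    Potential erosion uses C = 1; actual erosion uses the stack's C layer.
    Cells with a non-positive factor product (no wind, missing soil) are NaN
    in all four outputs.
    """
    ones = np.ones_like(stack.C)
    valid = stack.valid_mask()

    def chain(c_layer: np.ndarray) -> np.ndarray:
        s = critical_field_length(stack.WF, stack.EF, stack.SCF, stack.Kprime, c_layer)
        q = 109.8 * stack.WF * stack.EF * stack.SCF * stack.Kprime * c_layer
        out = erosion_flux(q, s, z)
        out[~valid] = np.nan
        return out

    slr = chain(ones)
    sl = chain(stack.C)
    service = weps(slr, sl)
    f = retention_rate(service, slr)
    return ErosionFields(SLR=slr, SL=sl, WEPS=service, F=f, grid=stack.grid, year=year)


def regional_total(field: np.ndarray, grid: GridSpec) -> float:
    """Regional total mass in tonnes: ``sum(cell kg/m^2 * cell area m^2) / 1000``.

    Nodata/NaN cells are excluded; an all-nodata raster totals 0 with a warning.
    """
    arr = np.asarray(field, dtype=float)
    bad = mask_nodata(arr, grid)
    if bad.all():
        warnings.warn("regional_total: all cells are nodata; total is 0 t", stacklevel=2)
        return 0.0
    return float(np.nansum(np.where(bad, 0.0, arr)) * grid.cell_area_m2 / 1000.0)


def temporal_change(field_t0: np.ndarray, field_t1: np.ndarray) -> tuple[np.ndarray, dict[str, float]]:
    """Per-cell change ``t1 - t0`` plus a summary of mean change and the
    percentage of valid area increasing / decreasing."""
    a = np.asarray(field_t0, dtype=float)
    b = np.asarray(field_t1, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    delta = b - a
    valid = ~np.isnan(delta)
    n = int(valid.sum())
    summary = {
        "mean_change": float(np.nanmean(delta)) if n else float("nan"),
        "pct_increasing": float(100.0 * np.sum(delta[valid] > 0) / n) if n else float("nan"),
        "pct_decreasing": float(100.0 * np.sum(delta[valid] < 0) / n) if n else float("nan"),
    }
    return delta, summary


def landcover_transition_matrix(
    lc_t0: np.ndarray,
    lc_t1: np.ndarray,
    grid: GridSpec,
    class_codes: list[int] | None = None,
) -> pd.DataFrame:
    """Area transition matrix (km^2) between two categorical land-cover maps.

    Rows are t0 classes, columns t1 classes; row sums equal class areas at t0
    and the grand total equals the valid domain area.  Codes present in the
    rasters but absent from ``class_codes`` (when given) raise a validation
    error listing the offenders.
    """
    a = np.asarray(lc_t0)
    b = np.asarray(lc_t1)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    valid = ~(mask_nodata(a, grid) | mask_nodata(b, grid))
    a_codes = np.unique(a[valid]).astype(int)
    b_codes = np.unique(b[valid]).astype(int)
    observed = sorted(set(a_codes) | set(b_codes))
    if class_codes is not None:
        unknown = sorted(int(c) for c in set(observed) - set(class_codes))
        if unknown:
            raise ValueError(f"unknown land-cover class codes: {unknown}")
        codes = sorted(class_codes)
    else:
        codes = observed
    cell_km2 = grid.cell_area_m2 / 1e6
    index = {c: i for i, c in enumerate(codes)}
    counts = np.zeros((len(codes), len(codes)), dtype=float)
    if valid.any():
        ai = np.vectorize(index.get)(a[valid].astype(int))
        bi = np.vectorize(index.get)(b[valid].astype(int))
        np.add.at(counts, (ai, bi), 1.0)
    return pd.DataFrame(counts * cell_km2, index=pd.Index(codes, name="from"), columns=pd.Index(codes, name="to"))
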