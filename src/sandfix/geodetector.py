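"""Geographical detector: factor, interaction, risk and ecological detectors.

The q statistic measures how much of a response's spatial variance a
categorical stratification explains:

    q = 1 - SSW / SST,   SSW = sum_h N_h * var_h(Y),   SST = N * var(Y)

with population variances, so q telescopes exactly into [0, 1].  The
interaction detector evaluates q on the cross-classification of two
stratifications and labels how the pair combines (enhancement, independence,
weakening); the risk detector compares stratum means with Welch t tests; the
ecological detector compares two factors' within-strata variance sums with an
F ratio.

Continuous drivers are discretised first (quantile, equal-interval or
Fisher-Jenks natural breaks); categorical drivers pass through unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StrataMap",
    "DetectorReport",
    "discretize",
    "q_statistic",
    "interaction_detector",
    "risk_detector",
    "ecological_detector",
    "rank_factors",
    "detector_report",
]

INTERACTION_CATEGORIES = (
    "nonlinear-weaken",
    "univariate-weaken",
    "bivariate-enhance",
    "independent",
    "nonlinear-enhance",
)


class DegenerateStrataError(ValueError):
    """A stratification with fewer than two usable classes."""


@dataclass
class StrataMap:
    """A stratification of the sample: dense integer class labels 1..k.

    ``labels`` is an integer array (any shape); ``breaks`` records the class
    boundaries when the map came from discretising a continuous layer.
    """

    labels: np.ndarray
    k: int
    source: str = ""
    breaks: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = np.unique(self.labels)
        if not np.isin(present, np.arange(1, self.k + 1)).all():
            raise ValueError(f"labels outside 1..{self.k}: {present}")

    @classmethod
    def from_categorical(cls, layer: np.ndarray, source: str = "") -> "StrataMap":
        """Wrap an already-categorical layer, relabelling codes densely to 1..k."""
        arr = np.asarray(layer)
        codes = np.unique(arr)
        remap = {c: i + 1 for i, c in enumerate(codes)}
        labels = np.vectorize(remap.get)(arr)
        return cls(labels=labels, k=len(codes), source=source)


def discretize(layer: np.ndarray, method: str = "quantile", k: int = 10, source: str = "") -> StrataMap:
    """Discretise a continuous layer into ``k`` classes.

    Methods: ``quantile`` (equal-frequency), ``equal_interval`` (equal-width)
    or ``natural_breaks`` (1-D k-means, a Fisher–Jenks analogue).  A constant
    layer cannot be stratified; if fewer than ``k`` distinct values exist the
    class count is reduced with a warning.
    """
    if k < 2:
        raise ValueError("need at least k=2 classes")
    arr = np.asarray(layer, dtype=float)
    flat = arr.ravel()
    finite = flat[~np.isnan(flat)]
    distinct = np.unique(finite)
    if distinct.size < 2:
        raise DegenerateStrataError("constant layer cannot be discretised")
    if distinct.size < k:
        warnings.warn(f"only {distinct.size} distinct values; reducing k from {k}", stacklevel=2)
        k = distinct.size

    if method == "quantile":
        qs = np.quantile(finite, np.linspace(0, 1, k + 1)[1:-1])
        breaks = np.unique(qs)
    elif method == "equal_interval":
        breaks = np.linspace(finite.min(), finite.max(), k + 1)[1:-1]
    elif method == "natural_breaks":
        breaks = _kmeans_breaks(finite, k)
    else:
        raise ValueError(f"unknown discretisation method {method!r}")

    labels = np.searchsorted(breaks, flat, side="right") + 1
    labels = labels.reshape(arr.shape)
    k_eff = len(breaks) + 1
    return StrataMap(labels=labels.astype(int), k=k_eff, source=source, breaks=np.asarray(breaks))


def _kmeans_breaks(values: np.ndarray, k: int) -> np.ndarray:
    """1-D k-means break points (midpoints between sorted cluster edges)."""
    from scipy.cluster.vq import kmeans2

    v = np.sort(values.astype(float))
    init = np.quantile(v, (np.arange(k) + 0.5) / k)[:, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        centroids, labels = kmeans2(v[:, None], init, minit="matrix", seed=0)
    order = np.argsort(centroids.ravel())
    edges = []
    for a, b in zip(order[:-1], order[1:]):
        va = v[labels == a]
        vb = v[labels == b]
        if len(va) and len(vb):
            edges.append((va.max() + vb.min()) / 2.0)
    return np.unique(edges)


def _prepare(y: np.ndarray, strata: StrataMap) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    labels = np.asarray(strata.labels).ravel()
    if y.shape != labels.shape:
        raise ValueError(f"Y has {y.size} samples but strata has {labels.size}")
    ok = ~np.isnan(y)
    return y[ok], labels[ok]


def q_statistic(y: np.ndarray, strata: StrataMap) -> float:
    """Share of Y's spatial variance explained by the stratification.

    ``q = 1 - sum_h N_h var_h / (N var)`` with population variances; strata
    left with fewer than one sample are simply absent from the sum.  A
    constant Y has no variance to decompose and raises.
    """
    yv, labels = _prepare(y, strata)
    if yv.size < 2:
        raise ValueError("need at least 2 samples")
    sst = float(yv.size * yv.var())
    if sst == 0:
        raise ValueError("total variance is zero; q undefined")
    ssw = 0.0
    for h in np.unique(labels):
        yh = yv[labels == h]
        ssw += yh.size * yh.var()
    return float(1.0 - ssw / sst)


def _cross_strata(a: StrataMap, b: StrataMap) -> StrataMap:
    la = np.asarray(a.labels).ravel()
    lb = np.asarray(b.labels).ravel()
    if la.shape != lb.shape:
        raise ValueError("stratifications cover different samples")
    pair = la.astype(np.int64) * (b.k + 1) + lb.astype(np.int64)
    codes, dense = np.unique(pair, return_inverse=True)
    return StrataMap(labels=(dense + 1).reshape(np.asarray(a.labels).shape), k=len(codes),
                     source=f"{a.source}*{b.source}")


def interaction_detector(
    y: np.ndarray, strata_a: StrataMap, strata_b: StrataMap, tol: float = 1e-9
) -> tuple[float, str]:
    """q of the cross-classification of two factors, with the joint-effect label.

    Categories: ``nonlinear-weaken`` (q12 < min), ``univariate-weaken``
    (min <= q12 < max), ``bivariate-enhance`` (max < q12 < q1+q2),
    ``independent`` (q12 = q1+q2 within ``tol``), ``nonlinear-enhance``
    (q12 > q1+q2).
    """
    q1 = q_statistic(y, strata_a)
    q2 = q_statistic(y, strata_b)
    q12 = q_statistic(y, _cross_strata(strata_a, strata_b))
    lo, hi = min(q1, q2), max(q1, q2)
    if abs(q12 - (q1 + q2)) < tol:
        cat = "independent"
    elif q12 > q1 + q2:
        cat = "nonlinear-enhance"
    elif q12 > hi:
        cat = "bivariate-enhance"
    elif q12 >= lo:
        cat = "univariate-weaken"
    else:
        cat = "nonlinear-weaken"
    return q12, cat


def risk_detector(y: np.ndarray, strata: StrataMap, alpha: float = 0.05) -> dict:
    """Stratum means with pairwise Welch t tests.

    Returns ``{"means": Series (stratum -> mean), "significant": DataFrame of
    booleans, "t": DataFrame of t statistics}``.  Strata with fewer than two
    samples are excluded with a warning.
    """
    yv, labels = _prepare(y, strata)
    groups: dict[int, np.ndarray] = {}
    for h in np.unique(labels):
        yh = yv[labels == h]
        if yh.size < 2:
            warnings.warn(f"stratum {h} has <2 samples; excluded from risk detector", stacklevel=2)
            continue
        groups[int(h)] = yh
    ids = sorted(groups)
    means = pd.Series({h: float(groups[h].mean()) for h in ids}, name="mean")
    tmat = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    sig = pd.DataFrame(False, index=ids, columns=ids, dtype=bool)
    for i, h1 in enumerate(ids):
        for h2 in ids[i + 1:]:
            t, p = stats.ttest_ind(groups[h1], groups[h2], equal_var=False)
            tmat.loc[h1, h2] = tmat.loc[h2, h1] = float(t)
            s = bool(p < alpha)
            sig.loc[h1, h2] = sig.loc[h2, h1] = s
    return {"means": means, "significant": sig, "t": tmat}


def _ssw(y: np.ndarray, strata: StrataMap) -> tuple[float, int]:
    yv, labels = _prepare(y, strata)
    ssw = 0.0
    for h in np.unique(labels):
        yh = yv[labels == h]
        ssw += yh.size * yh.var()
    return float(ssw), int(yv.size)


def ecological_detector(
    y: np.ndarray, strata_a: StrataMap, strata_b: StrataMap, alpha: float = 0.05
) -> bool:
    """Do two factors differ significantly in how they stratify Y's variance?

    ``F = [N_A (N_B - 1) SSW_A] / [N_B (N_A - 1) SSW_B]`` compared two-sided
    to the F distribution with ``(N_A - 1, N_B - 1)`` degrees of freedom at
    level ``alpha``.  Returns True (rendered as "Y" in report tables) when
    the within-strata variance sums differ significantly.
    """
    ssw_a, n_a = _ssw(y, strata_a)
    ssw_b, n_b = _ssw(y, strata_b)
    if ssw_b == 0 and ssw_a == 0:
        raise ValueError("both SSW are zero; F undefined")
    if ssw_b == 0:
        return True  # infinite F: A leaves variance B removes entirely
    f = (n_a * (n_b - 1) * ssw_a) / (n_b * (n_a - 1) * ssw_b)
    dist = stats.f(n_a - 1, n_b - 1)
    return bool(f < dist.ppf(alpha / 2) or f > dist.ppf(1 - alpha / 2))


def rank_factors(q_by_factor: dict[str, float]) -> pd.DataFrame:
    """Rank factors by q, descending; ties share a rank (dense ranking)."""
    if not q_by_factor:
        raise ValueError("no factors to rank")
    ser = pd.Series(q_by_factor, name="q").sort_values(ascending=False)
    rank = ser.rank(method="dense", ascending=False).astype(int)
    return pd.DataFrame({"q": ser, "rank": rank})


@dataclass
class DetectorReport:
    """All four detector outputs for one response and a set of drivers."""

    q_table: pd.DataFrame
    interaction_q: pd.DataFrame
    interaction_category: pd.DataFrame
    ecological: pd.DataFrame
    risk: dict[str, dict]


def detector_report(
    y: np.ndarray, drivers: dict[str, StrataMap], alpha: float = 0.05
) -> DetectorReport:
    """Run factor ranking, pairwise interactions, ecological tests and risk
    tables for a response against named driver stratifications."""
    names = list(drivers)
    q = {name: q_statistic(y, drivers[name]) for name in names}
    q_table = rank_factors(q)

    iq = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    icat = pd.DataFrame("", index=names, columns=names, dtype=object)
    eco = pd.DataFrame("", index=names, columns=names, dtype=object)
    for i, a in enumerate(names):
        iq.loc[a, a] = q[a]
        for b in names[i + 1:]:
            q12, cat = interaction_detector(y, drivers[a], drivers[b])
            iq.loc[a, b] = iq.loc[b, a] = q12
            icat.loc[a, b] = icat.loc[b, a] = cat
            sig = ecological_detector(y, drivers[a], drivers[b], alpha=alpha)
            eco.loc[a, b] = eco.loc[b, a] = "Y" if sig else "N"
    risk = {name: risk_detector(y, drivers[name], alpha=alpha) for name in names}
    return DetectorReport(q_table=q_table, interaction_q=iq,
                          interaction_category=icat, ecological=eco, risk=risk)
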