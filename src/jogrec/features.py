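"""Per-window feature families for the original time series.

From each series and window the extractor computes 14 basic statistics,
``h`` equal-width histogram counts (Sturges: ``h = ceil(log2 n + 1)``),
14 percentile features, 8 autocorrelation features (classical and Pearson
at four lags) and 5 curve-fit coefficients — 48 features per series for
60 s windows, 50 for 180 s windows — plus one hip/ankle cross-sensor
magnitude correlation and three gender features (two indicators and a
Weight-of-Evidence encoding fitted on the training split).

Every function accepts a single window (1-d array) or a stack of windows
(2-d, windows x samples) and is finite on all valid inputs: zero-variance
windows yield 0 for snr and all correlation-family features, and windows
containing non-positive values yield 0 for the geometric and harmonic mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import JOGGING, NONJOGGING, FeatureMatrix, ValidationError
from .names import all_series
from .segmentation import SegmentedDataset

__all__ = [
    "BinSpec",
    "WoETable",
    "basic_stats",
    "make_bins",
    "fit_bins",
    "histogram_features",
    "percentile_features",
    "pearson",
    "cross_sensor_correlation",
    "autocorr_features",
    "power_lag_domain",
    "lag_set",
    "curvefit_features",
    "gender_features",
    "extract_original_features",
    "sturges_bins",
]

#: lag sets for the two stock window lengths
_TAUS: Dict[int, Tuple[int, ...]] = {60: (1, 2, 4, 30), 180: (1, 2, 4, 90)}

PERCENTILE_LEVELS = (5, 10, 20, 30, 40, 60, 70, 80, 90, 95)


def _as2d(x: np.ndarray) -> Tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    return x, False


def _out(d: Dict[str, np.ndarray], squeeze: bool) -> Dict[str, float | np.ndarray]:
    if squeeze:
        return {k: float(v[0]) for k, v in d.items()}
    return d


# ---------------------------------------------------------------------------
# basic statistics


def basic_stats(x: np.ndarray, energy: str = "squared") -> Dict[str, float | np.ndarray]:
    """The 14 basic statistics of a window (or stack of windows).

    ``energy`` selects the energy definition: ``"squared"`` (sum of squared
    values, the signal-processing convention; the default) or ``"printed"``
    (plain sum of values).
    """
    X, squeeze = _as2d(x)
    n = X.shape[1]
    if n < 2:
        raise ValidationError("basic statistics need at least 2 samples")
    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    var = sd**2
    centered = X - mean[:, None]
    m3 = (centered**3).mean(axis=1)
    m4 = (centered**4).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(sd > 0, m3 / np.where(sd > 0, sd, 1) ** 3, 0.0)
        kurt = np.where(sd > 0, m4 / np.where(sd > 0, sd, 1) ** 4, 0.0)
        snr = np.where(sd > 0, mean / np.where(sd > 0, sd, 1), 0.0)
    positive = np.all(X > 0, axis=1)
    geo = np.zeros(X.shape[0])
    har = np.zeros(X.shape[0])
    if positive.any():
        P = X[positive]
        geo[positive] = np.exp(np.log(P).mean(axis=1))
        har[positive] = n / (1.0 / P).sum(axis=1)
    mode = sps.mode(X, axis=1, keepdims=False).mode.astype(float)
    e = (X**2).sum(axis=1) if energy == "squared" else X.sum(axis=1)
    return _out(
        {
            "min": X.min(axis=1),
            "max": X.max(axis=1),
            "range": X.max(axis=1) - X.min(axis=1),
            "mean": mean,
            "harmonic mean": har,
            "geometric mean": geo,
            "mode": mode,
            "std": sd,
            "variance": var,
            "skewness": skew,
            "kurtosis": kurt,
            "snr": snr,
            "energy": e,
            "energy/n": e / n,
        },
        squeeze,
    )


# ---------------------------------------------------------------------------
# histograms


def sturges_bins(n: int) -> int:
    """Sturges rule: ``h = ceil(log2 n + 1)`` intervals for window length n."""
    return math.ceil(math.log2(n) + 1)


def _fmt_bound(x: float) -> str:
    if x == 0:
        return "0"
    if abs(x) >= 10:
        return str(int(round(x)))
    return f"{x:.2g}"


@dataclass(frozen=True)
class BinSpec:
    """Global equal-width histogram bins of one series (fit on training data)."""

    series: str
    h: int
    edges: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.edges) != self.h + 1:
            raise ValidationError("edges must have h + 1 bounds")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValidationError("edges must be strictly increasing")

    def labels(self) -> List[str]:
        raw = [
            f"hist [{_fmt_bound(a)}, {_fmt_bound(b)})"
            for a, b in zip(self.edges, self.edges[1:])
        ]
        # formatting can collide for very narrow ranges; disambiguate by index
        if len(set(raw)) != len(raw):
            raw = [f"{lab} #{i}" for i, lab in enumerate(raw)]
        return raw


def make_bins(series_values: np.ndarray, n: int, series: str = "") -> BinSpec:
    """Equal-width bins over the global [min, max] of a series.

    The bin count follows the Sturges rule for the window length ``n``; a
    degenerate (constant) series gets its range widened by +/- 0.5 so the
    edges stay strictly increasing.
    """
    vals = np.asarray(series_values, dtype=float).ravel()
    if vals.size == 0:
        raise ValidationError("cannot build bins from an empty series")
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    h = sturges_bins(n)
    return BinSpec(series, h, tuple(np.linspace(lo, hi, h + 1)))


def histogram_features(x: np.ndarray, bins: BinSpec) -> Dict[str, float | np.ndarray]:
    """Counts per interval; values outside the global range fall in terminal bins."""
    X, squeeze = _as2d(x)
    W, n = X.shape
    inner = np.asarray(bins.edges[1:-1])
    idx = np.searchsorted(inner, X.ravel(), side="right").reshape(W, n)
    flat = idx + bins.h * np.arange(W)[:, None]
    counts = np.bincount(flat.ravel(), minlength=W * bins.h).reshape(W, bins.h)
    return _out(
        {lab: counts[:, j].astype(float) for j, lab in enumerate(bins.labels())},
        squeeze,
    )


# ---------------------------------------------------------------------------
# percentiles


def percentile_features(x: np.ndarray) -> Dict[str, float | np.ndarray]:
    """Quartiles, IQR and ten extra percentiles (linear interpolation)."""
    X, squeeze = _as2d(x)
    q1, med, q3 = (np.percentile(X, q, axis=1) for q in (25, 50, 75))
    out = {"perc. 25": q1, "median": med, "perc. 75": q3, "IQR": q3 - q1}
    for q in PERCENTILE_LEVELS:
        out[f"perc. {q}"] = np.percentile(X, q, axis=1)
    return _out(out, squeeze)


# ---------------------------------------------------------------------------
# correlations


def pearson(x: np.ndarray, y: np.ndarray) -> float | np.ndarray:
    """Pearson correlation of paired windows; 0 if either side has zero variance."""
    X, sq_x = _as2d(x)
    Y, sq_y = _as2d(y)
    if X.shape != Y.shape:
        raise ValidationError("pearson requires equal-length inputs")
    if X.shape[1] < 2:
        raise ValidationError("pearson needs at least 2 samples")
    xc = X - X.mean(axis=1, keepdims=True)
    yc = Y - Y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)
    r = np.clip(r, -1.0, 1.0)
    if sq_x and sq_y:
        return float(r[0])
    return r


def cross_sensor_correlation(
    hip_magnitude: np.ndarray, ankle_magnitude: np.ndarray
) -> float | np.ndarray:
    """Correlation between the hip and ankle vector-magnitude slices."""
    return pearson(hip_magnitude, ankle_magnitude)


# ---------------------------------------------------------------------------
# autocorrelation


def power_lag_domain(n: int) -> Tuple[int, ...]:
    """Lag set ``{floor(n/2)} U {2^i : 2^i <= n/2}`` (alternative generator)."""
    lags = {n // 2}
    i = 1
    while 2**i <= n // 2:
        lags.add(2**i)
        i += 1
    return tuple(sorted(lags))


def lag_set(n: int) -> Tuple[int, ...]:
    """The four stock lags per window length: {1,2,4,30} at n=60, {1,2,4,90} at n=180."""
    try:
        return _TAUS[n]
    except KeyError:
        raise ValidationError(
            f"no stock lag set for window length {n}; pass taus explicitly"
        ) from None


def autocorr_features(
    x: np.ndarray, n: int | None = None, taus: Sequence[int] | None = None
) -> Dict[str, float | np.ndarray]:
    """Classical autocorrelation and lagged Pearson correlation at four lags.

    The classical statistic is ``sum((x_i - mean)(x_{i+tau} - mean)) /
    ((n - tau) * var)`` with the unbiased variance; a zero-variance window
    yields 0 for all eight features.
    """
    X, squeeze = _as2d(x)
    length = X.shape[1]
    if n is None:
        n = length
    if taus is None:
        taus = lag_set(n)
    out: Dict[str, np.ndarray] = {}
    mean = X.mean(axis=1)
    var = X.var(axis=1, ddof=1)
    centered = X - mean[:, None]
    for tau in taus:
        if tau >= length:
            raise ValidationError(f"lag {tau} >= window length {length}")
        prod = (centered[:, : length - tau] * centered[:, tau:]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            classical = np.where(var > 0, prod / ((length - tau) * np.where(var > 0, var, 1)), 0.0)
        out[f"auto-corr t = {tau}"] = classical
        out[f"auto-pearson t = {tau}"] = np.atleast_1d(
            pearson(X[:, : length - tau], X[:, tau:])
        )
    return _out(out, squeeze)


# ---------------------------------------------------------------------------
# curve fitting


def curvefit_features(x: np.ndarray) -> Dict[str, float | np.ndarray]:
    """Least-squares linear and quadratic fit coefficients over abscissa 0..n-1."""
    X, squeeze = _as2d(x)
    n = X.shape[1]
    if n < 3:
        raise ValidationError("curve fitting needs at least 3 samples")
    t = np.arange(n, dtype=float)
    lin = np.linalg.pinv(np.column_stack([t, np.ones(n)])) @ X.T
    quad = np.linalg.pinv(np.column_stack([t**2, t, np.ones(n)])) @ X.T
    return _out(
        {
            "lin fit c1": lin[0],
            "lin fit c0": lin[1],
            "quad fit c2": quad[0],
            "quad fit c1": quad[1],
            "quad fit c0": quad[2],
        },
        squeeze,
    )


# ---------------------------------------------------------------------------
# gender encoding


class WoETable:
    """Weight-of-Evidence encoding of a categorical variable, fit on training data.

    ``WoE(g) = ln( (jogging count in g / total jogging) /
    (non-jogging count in g / total non-jogging) )`` with additive smoothing
    of 0.5 per cell.  Unseen categories map to 0.
    """

    def __init__(self) -> None:
        self.table: Dict[str, float] = {}

    def fit(self, categories: Sequence[str], labels: Sequence[int]) -> "WoETable":
        cats = np.asarray(categories)
        y = np.asarray(labels)
        values = sorted(set(cats.tolist()))
        k = len(values)
        tot_pos = float(np.sum(y == JOGGING)) + 0.5 * k
        tot_neg = float(np.sum(y == NONJOGGING)) + 0.5 * k
        self.table = {}
        for g in values:
            pos = float(np.sum((cats == g) & (y == JOGGING))) + 0.5
            neg = float(np.sum((cats == g) & (y == NONJOGGING))) + 0.5
            self.table[g] = math.log((pos / tot_pos) / (neg / tot_neg))
        return self

    def transform(self, categories: Sequence[str]) -> np.ndarray:
        return np.array([self.table.get(g, 0.0) for g in categories])


def gender_features(gender: Sequence[str], woe: WoETable) -> Dict[str, np.ndarray]:
    """Two binary indicators plus the WoE value of each instance's gender."""
    g = np.asarray(gender)
    return {
        "gender is_male": (g == "male").astype(float),
        "gender is_female": (g == "female").astype(float),
        "gender WoE": woe.transform(g),
    }


# ---------------------------------------------------------------------------
# assembly


def fit_bins(train: SegmentedDataset) -> Dict[str, BinSpec]:
    """Global histogram bins per original series from the training windows."""
    return {
        name: make_bins(values, train.spec.length_s, name)
        for name, values in train.series.items()
    }


def extract_original_features(
    dataset: SegmentedDataset,
    bins: Dict[str, BinSpec],
    woe: WoETable,
    energy: str = "squared",
) -> FeatureMatrix:
    """Features of all 12 original series, plus cross-sensor and gender columns.

    For 60 s windows this yields 12 x 48 + 1 + 3 = 580 columns; for 180 s
    windows 12 x 50 + 1 + 3 = 604.
    """
    n = dataset.spec.length_s
    columns: Dict[str, np.ndarray] = {}
    for series in all_series():
        X = dataset.series[series]
        for fam in (
            basic_stats(X, energy=energy),
            histogram_features(X, bins[series]),
            percentile_features(X),
            autocorr_features(X, n),
            curvefit_features(X),
        ):
            for suffix, vals in fam.items():
                columns[f"{series} {suffix}"] = vals
    columns["cross-corr HipMag AnkleMag"] = np.asarray(
        cross_sensor_correlation(dataset.series["HipMag"], dataset.series["AnkleMag"])
    )
    columns.update(gender_features(dataset.gender, woe))
    df = pd.DataFrame(columns, index=dataset.index)
    return FeatureMatrix(df, dataset.labels)
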