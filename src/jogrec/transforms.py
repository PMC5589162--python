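"""Derived time series and their feature families.

Three kinds of series are derived per retained original series:

* **delta**: window mean minus each value (a per-window centering, so only
  histogram and percentile features are informative on it);
* **first derivative**: differences of consecutive values (length n - 1);
* **FFT-derived**: the per-component frequencies, amplitudes and magnitudes
  of the real-input DFT of the window with the DC component excluded,
  plus the amplitude-weighted spectral centroid.

Amplitude is the normalized modulus ``2 |X_k| / n`` and magnitude the power
``|X_k|**2``; component ``k`` has frequency ``k / n`` Hz at the 1 Hz
sampling rate.  The baseline feature set uses the first five power-spectrum
coefficients (k = 1..5) of each retained series.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import FeatureMatrix, ValidationError
from .features import (
    BinSpec,
    WoETable,
    basic_stats,
    curvefit_features,
    extract_original_features,
    histogram_features,
    make_bins,
    percentile_features,
)
from .segmentation import SegmentedDataset

__all__ = [
    "delta_series",
    "delta_features",
    "first_derivative",
    "derivative_features",
    "fft_derive",
    "fft_stats",
    "merge_feature_blocks",
    "baseline_fft_features",
    "fit_delta_bins",
    "fit_derivative_bins",
    "extract_derived_features",
    "extract_full_features",
    "extract_baseline_features",
]


def _as2d(x: np.ndarray) -> Tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    return x, False


def delta_series(x: np.ndarray) -> np.ndarray:
    """Window mean minus each value; the output has mean zero by construction."""
    X, squeeze = _as2d(x)
    d = X.mean(axis=1, keepdims=True) - X
    return d[0] if squeeze else d


def first_derivative(x: np.ndarray) -> np.ndarray:
    """Differences of consecutive values within the window (length n - 1)."""
    X, squeeze = _as2d(x)
    if X.shape[1] < 2:
        raise ValidationError("first derivative needs at least 2 samples")
    d = np.diff(X, axis=1)
    return d[0] if squeeze else d


def delta_features(delta: np.ndarray, bins: BinSpec) -> Dict[str, np.ndarray]:
    """Histogram + percentile families only (h + 14 features).

    Basic statistics, autocorrelation and curve fits on a per-window
    centering are redundant with the original-series features.
    """
    out: Dict[str, np.ndarray] = {}
    out.update(histogram_features(delta, bins))
    out.update(percentile_features(delta))
    return out


def derivative_features(dx: np.ndarray, bins: BinSpec) -> Dict[str, np.ndarray]:
    """Basic statistics, histogram, percentile and curve-fit families (14+h+14+5)."""
    out: Dict[str, np.ndarray] = {}
    out.update(basic_stats(dx))
    out.update(histogram_features(dx, bins))
    out.update(percentile_features(dx))
    out.update(curvefit_features(dx))
    return out


def fft_derive(
    x: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, float | np.ndarray]:
    """(frequencies, amplitudes, magnitudes, spectral centroid) of each window.

    Components k = 1..floor(n/2) (DC excluded; the Nyquist component is
    included for even n).  The centroid is the amplitude-weighted mean
    frequency, 0 for an all-zero spectrum.
    """
    X, squeeze = _as2d(x)
    n = X.shape[1]
    if n < 2:
        raise ValidationError("FFT needs at least 2 samples")
    spectrum = np.fft.rfft(X, axis=1)[:, 1:]  # drop DC
    k = np.arange(1, spectrum.shape[1] + 1)
    freqs = k / n  # Hz at 1 Hz sampling
    modulus = np.abs(spectrum)
    amplitudes = 2.0 * modulus / n
    magnitudes = modulus**2
    total = amplitudes.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        centroid = np.where(
            total > 0, (amplitudes * freqs).sum(axis=1) / np.where(total > 0, total, 1), 0.0
        )
    freqs2 = np.broadcast_to(freqs, amplitudes.shape)
    if squeeze:
        return freqs, amplitudes[0], magnitudes[0], float(centroid[0])
    return freqs2, amplitudes, magnitudes, centroid


_FFT_STAT_NAMES = (
    "min",
    "max",
    "mean",
    "std",
    "range",
    "perc. 25",
    "perc. 75",
    "IQR",
    "median",
    "perc. 10",
    "perc. 40",
    "perc. 60",
    "perc. 90",
)


def fft_stats(series: np.ndarray) -> Dict[str, float | np.ndarray]:
    """The 13 distribution statistics of one FFT-derived series."""
    X, squeeze = _as2d(series)
    q = {p: np.percentile(X, p, axis=1) for p in (10, 25, 40, 50, 60, 75, 90)}
    out = {
        "min": X.min(axis=1),
        "max": X.max(axis=1),
        "mean": X.mean(axis=1),
        "std": X.std(axis=1, ddof=1),
        "range": X.max(axis=1) - X.min(axis=1),
        "perc. 25": q[25],
        "perc. 75": q[75],
        "IQR": q[75] - q[25],
        "median": q[50],
        "perc. 10": q[10],
        "perc. 40": q[40],
        "perc. 60": q[60],
        "perc. 90": q[90],
    }
    if squeeze:
        return {k: float(v[0]) for k, v in out.items()}
    return out


def baseline_fft_features(x: np.ndarray, include_dc: bool = False) -> np.ndarray:
    """First five FFT power-spectrum coefficients of each window.

    By default the DC component is excluded (it duplicates the window sum),
    so the coefficients are ``|X_k|**2`` for k = 1..5.
    """
    X, squeeze = _as2d(x)
    if X.shape[1] < 12:
        raise ValidationError("baseline features need at least 12 samples")
    spectrum = np.fft.rfft(X, axis=1)
    k0 = 0 if include_dc else 1
    power = np.abs(spectrum[:, k0 : k0 + 5]) ** 2
    return power[0] if squeeze else power


def merge_feature_blocks(blocks: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation of feature blocks over identical instances."""
    if not blocks:
        raise ValidationError("no blocks to merge")
    first = blocks[0]
    for b in blocks[1:]:
        if not b.features.index.equals(first.features.index):
            raise ValidationError("feature blocks have mismatched instance indices")
        if not np.array_equal(b.labels, first.labels):
            raise ValidationError("feature blocks have mismatched labels")
    merged = pd.concat([b.features for b in blocks], axis=1)
    if merged.columns.duplicated().any():
        dupes = merged.columns[merged.columns.duplicated()].tolist()
        raise ValidationError(f"duplicate feature names when merging: {dupes[:5]}")
    return FeatureMatrix(merged, first.labels)


# ---------------------------------------------------------------------------
# bin fitting for derived series (training split only, no leakage)


def fit_delta_bins(train: SegmentedDataset, retained: Sequence[str]) -> Dict[str, BinSpec]:
    return {
        s: make_bins(delta_series(train.series[s]), train.spec.length_s, f"delta({s})")
        for s in retained
    }


def fit_derivative_bins(
    train: SegmentedDataset, retained: Sequence[str]
) -> Dict[str, BinSpec]:
    return {
        s: make_bins(first_derivative(train.series[s]), train.spec.length_s, f"1st_deriv({s})")
        for s in retained
    }


def extract_derived_features(
    dataset: SegmentedDataset,
    retained: Sequence[str],
    delta_bins: Dict[str, BinSpec],
    derivative_bins: Dict[str, BinSpec],
) -> FeatureMatrix:
    """Delta, first-derivative and frequency-domain features of retained series.

    For 60 s windows and 10 retained series: 10 x 21 + 10 x 40 + (30 x 13 +
    10) = 210 + 400 + 400 = 1010 columns.
    """
    columns: Dict[str, np.ndarray] = {}
    for s in retained:
        X = dataset.series[s]
        for suffix, vals in delta_features(delta_series(X), delta_bins[s]).items():
            columns[f"delta({s}) {suffix}"] = vals
        for suffix, vals in derivative_features(
            first_derivative(X), derivative_bins[s]
        ).items():
            columns[f"1st_deriv({s}) {suffix}"] = vals
    for s in retained:
        X = dataset.series[s]
        freqs, amps, mags, centroid = fft_derive(X)
        for kind, series_vals in (("FFT_freq", freqs), ("FFT_amp", amps), ("FFT_mag", mags)):
            for suffix, vals in fft_stats(series_vals).items():
                columns[f"{kind}({s}) {suffix}"] = vals
        columns[f"{s} spectral centroid"] = np.atleast_1d(centroid)
    df = pd.DataFrame(columns, index=dataset.index)
    return FeatureMatrix(df, dataset.labels)


def extract_full_features(
    dataset: SegmentedDataset,
    retained: Sequence[str],
    bins: Dict[str, BinSpec],
    delta_bins: Dict[str, BinSpec],
    derivative_bins: Dict[str, BinSpec],
    woe: WoETable,
    energy: str = "squared",
) -> FeatureMatrix:
    """The merged feature set of one split.

    Original-series features restricted to the retained series (48 each for
    60 s windows) plus cross-sensor and gender columns, then the derived
    blocks: 10 x 48 + 4 + 210 + 400 + 400 = 1494 columns at 60 s (1554 at
    180 s) with 10 retained series.
    """
    original = extract_original_features(dataset, bins, woe, energy=energy)
    keep = [
        c
        for c in original.feature_names
        if not c.split(" ")[0].startswith(("Hip", "Ankle"))
        or c.split(" ")[0] in retained
        or c.startswith("cross-corr")
    ]
    # gender and cross-sensor columns survive the series screen
    original = original.select(keep)
    derived = extract_derived_features(dataset, retained, delta_bins, derivative_bins)
    return merge_feature_blocks([original, derived])


def extract_baseline_features(
    dataset: SegmentedDataset, retained: Sequence[str], include_dc: bool = False
) -> FeatureMatrix:
    """Baseline set: five power-spectrum coefficients per retained series."""
    columns: Dict[str, np.ndarray] = {}
    for s in retained:
        power = baseline_fft_features(dataset.series[s], include_dc=include_dc)
        for j in range(power.shape[1]):
            columns[f"{s} fft-power {j + 1}"] = power[:, j]
    df = pd.DataFrame(columns, index=dataset.index)
    return FeatureMatrix(df, dataset.labels)
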