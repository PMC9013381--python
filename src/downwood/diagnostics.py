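"""Model assessment: fit metrics, per-class accuracy, Moran's I, correlograms.

Residuals are observed minus predicted values on the response scale.
Global Moran's I is computed with an arbitrary non-negative spatial
weight matrix; its Z-value uses the randomization (permutation) variance.
Residual correlograms use binary distance-band weights on contiguous
half-open lag bins (default width 300 m), the headline statistic being
the first-lag [0, 300 m) band.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_core import cross_distances

#: two-sided 5% critical value for the Moran Z-test
Z_CRITICAL = 1.96

#: default correlogram lag-bin width in meters
DEFAULT_LAG_WIDTH = 300.0


@dataclass(frozen=True)
class MetricSet:
    """Coefficient of determination, RMSE and MAE on the response scale;
    per-class accuracies (binary models only)."""

    r2: float
    rmse: float
    mae: float
    acc0: float | None = None
    acc1: float | None = None


def regression_metrics(y: np.ndarray, yhat: np.ndarray) -> MetricSet:
    """R^2 = 1 - SS_res/SS_tot, RMSE, and MAE of yhat against y."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("y and yhat must be equal-length vectors with n >= 2")
    resid = y - yhat
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        raise ValueError("R^2 undefined: observed vector has zero variance")
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    mae = float(np.mean(np.abs(resid)))
    return MetricSet(r2=r2, rmse=rmse, mae=mae)


def class_accuracy(y: np.ndarray, p: np.ndarray, threshold: float = 0.5) -> tuple[float, float]:
    """Per-class accuracies of thresholded probabilities.

    acc0 is the fraction of true-0 units with p < threshold; acc1 the
    fraction of true-1 units with p >= threshold. An absent class yields
    NaN (undefined), never 0.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    y = np.asarray(y)
    p = np.asarray(p, dtype=float)
    is0, is1 = y == 0, y == 1
    acc0 = float(np.mean(p[is0] < threshold)) if is0.any() else math.nan
    acc1 = float(np.mean(p[is1] >= threshold)) if is1.any() else math.nan
    return acc0, acc1


@dataclass(frozen=True)
class MoranResult:
    """Global Moran's I with its randomization-assumption Z-test."""

    I: float
    expected_I: float
    variance: float
    z_value: float
    n: int
    weights: str = ""

    @property
    def significant(self) -> bool:
        """Two-sided test at the 5% level."""
        return abs(self.z_value) > Z_CRITICAL


def morans_i(x: np.ndarray, W: np.ndarray, weights_label: str = "") -> MoranResult:
    """Global Moran's I of ``x`` under spatial weights ``W``.

        I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2,   z = x - mean(x)

    The variance is computed under the randomization assumption, so the
    Z-value is (I - E[I]) / sd with E[I] = -1/(n-1).
    """
    x = np.asarray(x, dtype=float)
    W = np.asarray(W, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("randomization variance requires at least 4 observations")
    if W.shape != (n, n):
        raise ValueError(f"W must be {n}x{n}")
    if np.any(W < 0) or np.any(np.diag(W) != 0):
        raise ValueError("W must be non-negative with zero diagonal")
    z = x - x.mean()
    m2 = float(np.sum(z ** 2))
    if m2 <= 0:
        raise ValueError("Moran's I undefined for a constant vector")
    s0 = float(W.sum())
    if s0 <= 0:
        raise ValueError("spatial weight matrix has zero total weight")

    I = (n / s0) * float(z @ W @ z) / m2
    e_i = -1.0 / (n - 1)

    s1 = 0.5 * float(np.sum((W + W.T) ** 2))
    rs, cs = W.sum(axis=1), W.sum(axis=0)
    s2 = float(np.sum((rs + cs) ** 2))
    m4 = float(np.sum(z ** 4)) / n
    b2 = m4 / (m2 / n) ** 2
    num = n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0) \
        - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0)
    den = (n - 1) * (n - 2) * (n - 3) * s0 * s0
    var = num / den - e_i ** 2
    if var <= 0:
        raise ValueError("degenerate inputs: non-positive randomization variance")
    return MoranResult(I=I, expected_I=e_i, variance=var,
                       z_value=(I - e_i) / math.sqrt(var), n=n, weights=weights_label)


def distance_band_weights(coords: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Binary weights: w_ij = 1 iff the pair distance lies in [lo, hi)."""
    D = cross_distances(coords, coords)
    W = ((D >= lo) & (D < hi)).astype(float)
    np.fill_diagonal(W, 0.0)
    return W


@dataclass(frozen=True)
class Correlogram:
    """Per-lag-bin Moran's I series with neighbor-pair counts."""

    bin_edges: np.ndarray  # length n_bins + 1
    results: list[MoranResult | None]  # None where the bin is empty/degenerate
    pair_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, res in enumerate(self.results):
            rows.append({
                "bin_lo": self.bin_edges[i],
                "bin_hi": self.bin_edges[i + 1],
                "pairs": int(self.pair_counts[i]),
                "moran_i": res.I if res is not None else math.nan,
                "z": res.z_value if res is not None else math.nan,
            })
        return pd.DataFrame(rows)


def residual_correlogram(
    residuals: np.ndarray,
    coords: np.ndarray,
    lag_width: float = DEFAULT_LAG_WIDTH,
    n_bins: int | None = None,
) -> Correlogram:
    """Moran's I of residuals per distance band [m*lag, (m+1)*lag).

    ``n_bins`` defaults to the number of bands needed to cover the maximum
    pairwise distance. Empty (or degenerate) bins are reported with pair
    count 0 and an undefined statistic.
    """
    if lag_width <= 0:
        raise ValueError("lag_width must be positive")
    residuals = np.asarray(residuals, dtype=float)
    coords = np.asarray(coords, dtype=float)
    D = cross_distances(coords, coords)
    if n_bins is None:
        n_bins = int(np.ceil(D.max() / lag_width)) or 1
    edges = np.arange(n_bins + 1) * lag_width

    results: list[MoranResult | None] = []
    counts = np.zeros(n_bins, dtype=int)
    for m in range(n_bins):
        W = distance_band_weights(coords, edges[m], edges[m + 1])
        counts[m] = int(W.sum()) // 2  # unordered pairs
        if counts[m] == 0:
            results.append(None)
            continue
        try:
            results.append(morans_i(residuals, W,
                                    weights_label=f"band[{edges[m]:g},{edges[m+1]:g})"))
        except ValueError:
            results.append(None)
    return Correlogram(bin_edges=edges, results=results, pair_counts=counts)


def first_lag_moran(residuals: np.ndarray, coords: np.ndarray,
                    lag_width: float = DEFAULT_LAG_WIDTH) -> MoranResult:
    """Headline residual statistic: Moran's I on the first distance band."""
    W = distance_band_weights(np.asarray(coords, dtype=float), 0.0, lag_width)
    return morans_i(residuals, W, weights_label=f"band[0,{lag_width:g})")


def coefficient_summary(B, covariate_names: list[str] | None = None) -> pd.DataFrame:
    """Per-coefficient distribution summary: Mean, Min, Q1, Median, Q3, Max.

    Accepts a LocalFit-like object (with ``B`` and ``covariate_names``) or
    a plain matrix. Quantiles use linear interpolation.
    """
    if hasattr(B, "B"):
        covariate_names = B.covariate_names
        B = B.B
    B = np.asarray(B, dtype=float)
    if B.size == 0:
        raise ValueError("empty coefficient matrix")
    names = ["Intercept"] + (covariate_names or [f"x{i}" for i in range(1, B.shape[1])])
    rows = []
    for j, name in enumerate(names[: B.shape[1]]):
        col = B[:, j]
        col = col[np.isfinite(col)]
        rows.append({
            "Coefficient": name,
            "Mean": float(np.mean(col)),
            "Min": float(np.min(col)),
            "Q1": float(np.quantile(col, 0.25)),
            "Median": float(np.quantile(col, 0.5)),
            "Q3": float(np.quantile(col, 0.75)),
            "Max": float(np.max(col)),
        })
    return pd.DataFrame(rows).set_index("Coefficient")
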