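"""Geographically weighted logistic (GWLR) and Poisson (GWPR) regression.

At every target location a local GLM is fitted by kernel-weighted maximum
likelihood: observation j enters the fit at location i with weight
``K(d_ij / b)`` where K is a Gaussian or bisquare kernel and b the
bandwidth (a fixed metric distance, or adaptive — the distance to the
b-th nearest training point). The effective number of parameters is the
trace of the Fisher-scoring hat matrix, and the bandwidth is chosen by
minimizing the small-sample-corrected AIC,

    AICc = deviance + 2*enp + 2*enp*(enp + 1) / (n - enp - 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data_core import SpatialDataset, cross_distances
from .glm import (
    FAMILY_RESPONSE,
    GlobalFit,
    _check_family,
    _design,
    fit_glm,
    inverse_link,
    irls,
    log_likelihood,
    mean_derivative,
)

logger = logging.getLogger(__name__)

KERNEL_SHAPES = ("gaussian", "bisquare")
KERNEL_MODES = ("fixed", "adaptive")


@dataclass(frozen=True)
class KernelSpec:
    """Distance-decay kernel: shape, fixed/adaptive mode, and bandwidth.

    In fixed mode the bandwidth is a metric distance in meters; in
    adaptive mode it is the neighbor rank whose distance becomes the
    per-location bandwidth.
    """

    shape: str = "gaussian"
    mode: str = "fixed"
    bandwidth: float = 1000.0

    def __post_init__(self) -> None:
        if self.shape not in KERNEL_SHAPES:
            raise ValueError(f"shape must be one of {KERNEL_SHAPES}")
        if self.mode not in KERNEL_MODES:
            raise ValueError(f"mode must be one of {KERNEL_MODES}")
        if not self.bandwidth > 0:
            raise ValueError("bandwidth must be positive")


def kernel_weight(d: np.ndarray, spec: KernelSpec, bandwidth: float | None = None) -> np.ndarray:
    """Kernel weight in [0, 1] for distances ``d``.

    ``bandwidth`` overrides ``spec.bandwidth`` (used by adaptive mode,
    where the metric bandwidth differs per location).
    """
    b = spec.bandwidth if bandwidth is None else bandwidth
    d = np.asarray(d, dtype=float)
    if spec.shape == "gaussian":
        return np.exp(-0.5 * (d / b) ** 2)
    w = (1.0 - (d / b) ** 2) ** 2
    return np.where(d < b, w, 0.0)


def _local_bandwidths(D: np.ndarray, spec: KernelSpec, n_train: int) -> np.ndarray:
    """Metric bandwidth per target row of the target-to-train distance matrix D."""
    if spec.mode == "fixed":
        return np.full(D.shape[0], float(spec.bandwidth))
    k = int(spec.bandwidth)
    if not 1 <= k <= n_train:
        raise ValueError(f"adaptive bandwidth must be in [1, {n_train}]")
    return np.sort(D, axis=1)[:, k - 1]


@dataclass
class LocalFit:
    """Per-location coefficients from a geographically weighted (or
    neural-network-weighted) model.

    ``B[i, k]`` is coefficient k evaluated at target location i (intercept
    in column 0). ``enp``, ``deviance`` and ``aicc`` are populated only
    when the targets are the training locations themselves.
    """

    family: str
    B: np.ndarray
    covariate_names: list[str]
    converged: np.ndarray
    enp: float | None = None
    deviance: float | None = None
    aicc: float | None = None
    spec: KernelSpec | None = None

    @property
    def n_targets(self) -> int:
        return self.B.shape[0]


def gwr_aicc(deviance: float, enp: float, n: int) -> float:
    """Small-sample-corrected AIC for a local fit."""
    if n - enp - 1 <= 0:
        warnings.warn("AICc undefined: n - enp - 1 <= 0; returning +inf", RuntimeWarning)
        return float("inf")
    return deviance + 2.0 * enp + 2.0 * enp * (enp + 1.0) / (n - enp - 1.0)


def fit_gwr_glm(
    train: SpatialDataset,
    family: str,
    spec: KernelSpec,
    targets: np.ndarray | None = None,
    response: str | None = None,
    global_fit: GlobalFit | None = None,
    max_fail_frac: float = 0.10,
) -> LocalFit:
    """Fit local kernel-weighted GLMs at each target location.

    ``targets`` defaults to the training coordinates, in which case the
    effective number of parameters (hat-matrix trace), deviance and AICc
    are computed; out-of-sample targets get coefficients only. Local IRLS
    is warm-started at the global fit for stability.
    """
    _check_family(family)
    response = FAMILY_RESPONSE[family] if response is None else response
    y = train.response(response)
    Xd, names = _design(train.X)
    n, p = Xd.shape

    in_sample = targets is None
    tcoords = train.coords if in_sample else np.asarray(targets, dtype=float)
    D = cross_distances(tcoords, train.coords)
    bws = _local_bandwidths(D, spec, n)

    if global_fit is None:
        global_fit = fit_glm(train, family, response)
    beta0 = global_fit.beta

    m = len(tcoords)
    B = np.empty((m, p))
    conv = np.zeros(m, dtype=bool)
    hat_diag = np.zeros(m)
    failures = []

    for i in range(m):
        w = kernel_weight(D[i], spec, bws[i])
        try:
            beta_i, _, ok, _, _ = irls(Xd, y, family, obs_weights=w, beta0=beta0, max_iter=50)
        except np.linalg.LinAlgError:
            failures.append(i)
            B[i] = np.nan
            continue
        B[i] = beta_i
        conv[i] = ok
        if in_sample:
            # Fisher-scoring hat matrix row at convergence:
            # S_i = x_i' (X' G_i X)^{-1} X' G_i, with G_i = kernel * IRLS weight
            g = w * np.maximum(mean_derivative(Xd @ beta_i, family), 1e-10)
            A = Xd.T @ (Xd * g[:, None])
            try:
                hat_diag[i] = float(Xd[i] @ np.linalg.solve(A, Xd[i] * g[i]))
            except np.linalg.LinAlgError:
                hat_diag[i] = np.nan

    if failures:
        frac = len(failures) / m
        logger.warning("local fit failed at %d/%d locations", len(failures), m)
        if frac > max_fail_frac:
            raise RuntimeError(
                f"{len(failures)}/{m} local fits failed (bandwidth too small?)"
            )

    fit = LocalFit(family=family, B=B, covariate_names=names, converged=conv, spec=spec)
    if in_sample:
        eta = np.einsum("ij,ij->i", Xd, B)
        mu = inverse_link(eta, family)
        fit.deviance = -2.0 * log_likelihood(y, mu, family)
        fit.enp = float(np.nansum(hat_diag))
        fit.aicc = gwr_aicc(fit.deviance, fit.enp, n)
    return fit


def predict_gwr(fit: LocalFit, X, family: str | None = None) -> np.ndarray:
    """Predictions using each row's location-specific coefficients."""
    family = fit.family if family is None else family
    Xd, _ = _design(X, fit.covariate_names if hasattr(X, "columns") else None)
    if Xd.shape[0] != fit.n_targets:
        raise ValueError("X must have one row per fitted target location")
    eta = np.einsum("ij,ij->i", Xd, fit.B)
    return inverse_link(eta, family)


def _aicc_at(train, family, shape, mode, bandwidth, response, global_fit) -> float:
    spec = KernelSpec(shape=shape, mode=mode,
                      bandwidth=int(round(bandwidth)) if mode == "adaptive" else bandwidth)
    try:
        fit = fit_gwr_glm(train, family, spec, response=response, global_fit=global_fit)
    except (RuntimeError, np.linalg.LinAlgError):
        return float("inf")
    return fit.aicc


def select_bandwidth(
    train: SpatialDataset,
    family: str,
    shape: str = "gaussian",
    mode: str = "fixed",
    grid: list[float] | None = None,
    response: str | None = None,
    tol: float = 0.02,
) -> KernelSpec:
    """Choose the bandwidth minimizing AICc.

    With an explicit ``grid``, every candidate is evaluated. Otherwise a
    golden-section search runs between the 1st percentile and the maximum
    of the pairwise training distances (fixed mode) or between k+2
    neighbors and n (adaptive mode), assuming an approximately unimodal
    AICc profile.
    """
    global_fit = fit_glm(train, family, response)

    def score(b: float) -> float:
        a = _aicc_at(train, family, shape, mode, b, response, global_fit)
        logger.info("bandwidth search: b=%.6g AICc=%.6g", b, a)
        return a

    if grid is not None:
        if not grid:
            raise ValueError("grid must be non-empty")
        scores = [score(b) for b in grid]
        if not np.isfinite(scores).any():
            raise RuntimeError("all bandwidth candidates failed to fit")
        best = grid[int(np.argmin(scores))]
    else:
        D = cross_distances(train.coords, train.coords)
        pair = D[np.triu_indices_from(D, k=1)]
        if mode == "fixed":
            lo, hi = float(np.percentile(pair, 1)), float(pair.max())
        else:
            lo, hi = train.X.shape[1] + 2, train.n
        phi = (np.sqrt(5.0) - 1.0) / 2.0
        a, b = lo, hi
        c, d = b - phi * (b - a), a + phi * (b - a)
        fc, fd = score(c), score(d)
        while (b - a) > tol * (hi - lo) and (mode == "fixed" or (b - a) > 1):
            if fc <= fd:
                b, d, fd = d, c, fc
                c = b - phi * (b - a)
                fc = score(c)
            else:
                a, c, fc = c, d, fd
                d = a + phi * (b - a)
                fd = score(d)
        best = c if fc <= fd else d
        if not np.isfinite(min(fc, fd)):
            raise RuntimeError("bandwidth search failed: no candidate produced a finite AICc")

    if mode == "adaptive":
        best = int(round(best))
    return KernelSpec(shape=shape, mode=mode, bandwidth=best)
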