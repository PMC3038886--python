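"""Local minimax kernel prediction with finite-sample error bounds.

For a query point the estimator searches over nested neighborhoods of
nearest training points.  For neighborhood size ``i`` it solves a kernel
ridge system whose ridge constant is tied to a smoothness bound ``M`` that
grows with the neighborhood radius, yielding a worst-case MSE bound ``L_i``;
the ``i`` minimizing the bound is kept.  The estimate is affine in the
training labels, ``F = w* + sum_j w_j Y_j`` with the contextual offset
``w* = alpha (1 - sum_j w_j)``, and the bound depends only on predictor
geometry, never on labels.  One-sided confidence intervals have half-width
``rho * sqrt(1 + z_beta^2)`` with ``rho = sqrt(L)``.

Two algebraically identical computation paths exist: the production kernel
ridge (Schur-complement) solve in :func:`tikhonov_fit`, and the direct
``(i+1) x (i+1)`` bordered-matrix inverse in :func:`tikhonov_fit_direct`,
kept as an independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import solve
from scipy.spatial.distance import cdist
from scipy.stats import norm


class MinimaxError(ValueError):
    """Raised on invalid estimator inputs (bad geometry, bad config)."""


@dataclass(frozen=True)
class MinimaxConfig:
    """All method knobs.

    sigma_fraction : bandwidth as a fraction of the query-to-furthest
        training distance (typical choices 0.5 and 0.7).
    alpha : prior constant of the probability model class, in (0, 1).
    beta : one-sided confidence-interval miss level, in (0, 0.5).
    p_threshold : confident-predictability level, in (0, 0.5].
    adjustment_e : resampling label adjustment, in [0, 0.5].
    k : number of gene pairs for feature selection.
    """

    sigma_fraction: float = 0.5
    alpha: float = 0.5
    beta: float = 0.10
    p_threshold: float = 0.35
    adjustment_e: float = 0.0
    k: int = 10

    def __post_init__(self) -> None:
        if not self.sigma_fraction > 0:
            raise MinimaxError("sigma_fraction must be positive")
        if not 0 < self.alpha < 1:
            raise MinimaxError("alpha must lie in (0, 1)")
        if not 0 < self.beta < 0.5:
            raise MinimaxError("beta must lie in (0, 0.5)")
        if not 0 < self.p_threshold <= 0.5:
            raise MinimaxError("p_threshold must lie in (0, 0.5]")
        if not 0 <= self.adjustment_e <= 0.5:
            raise MinimaxError("adjustment_e must lie in [0, 0.5]")
        if self.k < 1:
            raise MinimaxError("k must be at least 1")

    @property
    def z_beta(self) -> float:
        """Exact standard normal (1 - beta) quantile."""
        return float(norm.ppf(1.0 - self.beta))

    @property
    def ci_multiplier(self) -> float:
        return math.sqrt(1.0 + self.z_beta**2)

    def snapshot(self) -> dict:
        return {
            "sigma_fraction": self.sigma_fraction,
            "alpha": self.alpha,
            "beta": self.beta,
            "p_threshold": self.p_threshold,
            "adjustment_e": self.adjustment_e,
            "k": self.k,
        }


@dataclass(frozen=True)
class LocalNeighborhoodFit:
    """Label-free fit of the estimator at one query point.

    ``weights`` are aligned to ``neighbor_indices`` (original training-row
    indices of the i nearest points, closest first); weights of training
    points beyond the i-th are implicitly zero.
    """

    i: int
    radius: float
    sigma: float
    M: float
    gamma: float
    weights: np.ndarray
    w_star: float
    mse_bound: float
    neighbor_indices: np.ndarray
    all_bounds: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class Prediction:
    """Per-query output of the estimator."""

    f_raw: float
    f_adjusted: float
    f_reported: float
    rmse_bound: float
    ci_low: float
    ci_high: float
    class_call: int
    cp_flag: bool
    fit: LocalNeighborhoodFit


@dataclass(frozen=True)
class SigmaSweep:
    """Per-patient predictions over a grid of bandwidth fractions."""

    fractions: tuple[float, ...]
    predictions: tuple[Prediction, ...]
    suggested_lower_limit: float


def gaussian_kernel(u, v, sigma: float) -> float:
    """Gaussian kernel exp(-||u - v||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise MinimaxError("sigma must be positive")
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    d2 = float(np.sum((u - v) ** 2))
    return math.exp(-d2 / (2.0 * sigma**2))


def kernel_matrix(X, Y, sigma: float) -> np.ndarray:
    """Gaussian kernel matrix between the rows of X and the rows of Y."""
    if sigma <= 0:
        raise MinimaxError("sigma must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    d2 = cdist(X, Y, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


def bandwidth_from_query(query, train, sigma_fraction: float) -> float:
    """sigma = sigma_fraction x (distance from query to furthest training point)."""
    query = np.asarray(query, dtype=float)
    train = np.atleast_2d(np.asarray(train, dtype=float))
    if train.shape[0] < 1:
        raise MinimaxError("need at least one training point")
    dmax = float(np.linalg.norm(train - query, axis=1).max())
    if dmax == 0.0:
        raise MinimaxError("all training points coincide with the query; bandwidth undefined")
    return sigma_fraction * dmax


def m_bound(radius: float, sigma: float, alpha: float) -> float:
    """Smoothness bound for the ball of given radius about the query.

    ``M = sqrt(alpha^2 + (1-alpha)^2) * c^{-1/2}`` with
    ``c = max_x min_y K(y, x)`` over the ball; for the Gaussian kernel
    ``c = exp(-radius^2 / (2 sigma^2))`` (max at the center, min at the
    antipodal boundary point), so ``M`` grows like ``exp(radius^2 / (4 sigma^2))``.
    """
    if radius < 0:
        raise MinimaxError("radius must be non-negative")
    if sigma <= 0:
        raise MinimaxError("sigma must be positive")
    return math.sqrt(alpha**2 + (1.0 - alpha) ** 2) * math.exp(
        radius**2 / (4.0 * sigma**2)
    )


def _check_distinct(points: np.ndarray) -> None:
    if points.shape[0] > 1:
        d = cdist(points, points)
        np.fill_diagonal(d, np.inf)
        if d.min() == 0.0:
            raise MinimaxError(
                "coincident training points in the neighborhood; "
                "deduplicate the training set before fitting"
            )


def tikhonov_fit(query, neighbors, sigma: float, M: float) -> tuple[np.ndarray, float]:
    """Kernel-ridge form of the fit (production path).

    Solves ``(K + gamma I) w = kvec`` with ``gamma = (0.5 / M)^2`` and
    returns ``(w, L)`` where ``L = M^2 (1 - kvec . w)`` is the MSE bound.
    """
    if M <= 0:
        raise MinimaxError("M must be positive")
    query = np.asarray(query, dtype=float)
    neighbors = np.atleast_2d(np.asarray(neighbors, dtype=float))
    _check_distinct(neighbors)
    K = kernel_matrix(neighbors, neighbors, sigma)
    kvec = kernel_matrix(neighbors, query[None, :], sigma)[:, 0]
    gamma = 0.25 / M**2
    try:
        w = solve(K + gamma * np.eye(len(kvec)), kvec, assume_a="pos")
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise MinimaxError(
            "singular ridge system; deduplicate coincident neighbors"
        ) from exc
    L = M**2 * (1.0 - float(kvec @ w))
    return w, max(L, 0.0)


def tikhonov_fit_direct(query, neighbors, sigma: float, M: float) -> tuple[np.ndarray, float]:
    """Direct bordered-matrix form of the fit (cross-check path).

    Builds ``A = S + M^2 K*`` over the (query, neighbors) block, with
    ``S = diag(0, 0.25, ..., 0.25)``; then ``L = 1 / [A^{-1}]_{00}`` and the
    weight vector is ``-(first row of A^{-1}) * L`` restricted to the
    neighbor entries.
    """
    if M <= 0:
        raise MinimaxError("M must be positive")
    query = np.asarray(query, dtype=float)
    neighbors = np.atleast_2d(np.asarray(neighbors, dtype=float))
    _check_distinct(neighbors)
    pts = np.vstack([query[None, :], neighbors])
    Kstar = kernel_matrix(pts, pts, sigma)
    S = 0.25 * np.eye(len(pts))
    S[0, 0] = 0.0
    A = S + M**2 * Kstar
    Ainv = np.linalg.inv(A)
    L = 1.0 / Ainv[0, 0]
    w_full = -Ainv[0] * L
    return w_full[1:], max(L, 0.0)


def fit_at_query(
    query,
    train_features,
    config: MinimaxConfig,
    sigma: float | None = None,
) -> LocalNeighborhoodFit:
    """Search all neighborhood sizes i = 1..N and keep the bound-minimizing fit.

    The result depends only on predictor geometry; labels enter later in
    :func:`predict_from_fit`.  Ties in the bound go to the smallest i.
    """
    query = np.asarray(query, dtype=float)
    train = np.atleast_2d(np.asarray(train_features, dtype=float))
    N = train.shape[0]
    if N < 1:
        raise MinimaxError("need at least one training point")
    if sigma is None:
        sigma = bandwidth_from_query(query, train, config.sigma_fraction)
    dists = np.linalg.norm(train - query, axis=1)
    order = np.argsort(dists, kind="stable")
    sorted_train = train[order]
    sorted_d = dists[order]
    _check_distinct(sorted_train)

    Kfull = kernel_matrix(sorted_train, sorted_train, sigma)
    kvec = kernel_matrix(sorted_train, query[None, :], sigma)[:, 0]

    bounds = np.empty(N)
    best = None  # (L, i, w, M, gamma)
    for i in range(1, N + 1):
        M = m_bound(float(sorted_d[i - 1]), sigma, config.alpha)
        gamma = 0.25 / M**2
        w = solve(Kfull[:i, :i] + gamma * np.eye(i), kvec[:i], assume_a="pos")
        L = max(M**2 * (1.0 - float(kvec[:i] @ w)), 0.0)
        bounds[i - 1] = L
        if best is None or L < best[0]:
            best = (L, i, w, M, gamma)
    L, i_star, w, M, gamma = best
    return LocalNeighborhoodFit(
        i=i_star,
        radius=float(sorted_d[i_star - 1]),
        sigma=float(sigma),
        M=float(M),
        gamma=float(gamma),
        weights=w,
        w_star=float(config.alpha * (1.0 - w.sum())),
        mse_bound=float(L),
        neighbor_indices=order[:i_star],
        all_bounds=bounds,
    )


def predict_from_fit(
    fit: LocalNeighborhoodFit,
    train_labels,
    config: MinimaxConfig,
) -> Prediction:
    """Combine a label-free fit with training labels into a Prediction.

    The adjusted estimate replaces each label Y by ``e + (1 - 2e) Y``; the
    confidence interval is formed around the unclipped adjusted estimate and
    clipped to [0, 1] afterwards.  The class call uses the unadjusted
    estimate at threshold 0.5.
    """
    y = np.asarray(train_labels, dtype=float)[fit.neighbor_indices]
    w = fit.weights
    e = config.adjustment_e
    f_raw = float(fit.w_star + w @ y)
    f_adjusted = float(fit.w_star + w @ (e + (1.0 - 2.0 * e) * y))
    rho = math.sqrt(fit.mse_bound)
    ci_low, ci_high = confidence_interval(f_adjusted, rho, config.beta)
    return Prediction(
        f_raw=f_raw,
        f_adjusted=f_adjusted,
        f_reported=float(np.clip(f_adjusted, 0.0, 1.0)),
        rmse_bound=rho,
        ci_low=ci_low,
        ci_high=ci_high,
        class_call=int(f_raw >= 0.5),
        cp_flag=is_confidently_predictable((ci_low, ci_high), config.p_threshold),
        fit=fit,
    )


def estimate(
    query,
    train_features,
    train_labels,
    config: MinimaxConfig,
    sigma: float | None = None,
) -> Prediction:
    """Full per-query pipeline: neighborhood search plus label combination."""
    train_labels = np.asarray(train_labels)
    if not np.isin(train_labels, (0, 1)).all():
        raise MinimaxError("training labels must be 0 or 1")
    fit = fit_at_query(query, train_features, config, sigma=sigma)
    return predict_from_fit(fit, train_labels, config)


def confidence_interval(f: float, rho: float, beta: float) -> tuple[float, float]:
    """One-sided (1 - beta) interval endpoints, clipped to [0, 1].

    Half-width is ``rho * sqrt(1 + z_beta^2)`` with the exact normal
    quantile ``z_beta``.
    """
    if rho < 0:
        raise MinimaxError("rho must be non-negative")
    if not 0 < beta < 0.5:
        raise MinimaxError("beta must lie in (0, 0.5)")
    z = float(norm.ppf(1.0 - beta))
    half = rho * math.sqrt(1.0 + z**2)
    # clamp both endpoints into [0, 1]; monotone, so ordering is preserved
    return (
        float(np.clip(f - half, 0.0, 1.0)),
        float(np.clip(f + half, 0.0, 1.0)),
    )


def is_confidently_predictable(ci: tuple[float, float], p_threshold: float) -> bool:
    """True iff the interval sits inside [0, p] or inside [1 - p, 1]."""
    low, high = ci
    if not 0.0 <= low <= high <= 1.0:
        raise MinimaxError(f"invalid clipped interval ({low}, {high})")
    return high <= p_threshold or low >= 1.0 - p_threshold


def suggested_sigma_lower_limit(query, train) -> float:
    """Distance to the ceil(N/5)-th closest training point over the furthest."""
    query = np.asarray(query, dtype=float)
    train = np.atleast_2d(np.asarray(train, dtype=float))
    d = np.sort(np.linalg.norm(train - query, axis=1))
    if d[-1] == 0.0:
        raise MinimaxError("all training points coincide with the query")
    j = math.ceil(train.shape[0] / 5)
    return float(d[j - 1] / d[-1])


def sigma_sweep(
    query,
    train_features,
    train_labels,
    config: MinimaxConfig,
    fractions: Sequence[float] | None = None,
) -> SigmaSweep:
    """Predictions for one query over a grid of bandwidth fractions."""
    if fractions is None:
        fractions = [round(0.2 + 0.1 * i, 10) for i in range(13)]  # 0.2..1.4
    fractions = [float(f) for f in fractions]
    if not fractions:
        raise MinimaxError("fraction grid must be non-empty")
    if any(f <= 0 for f in fractions):
        raise MinimaxError("fractions must be positive")
    preds = []
    from dataclasses import replace

    for frac in fractions:
        cfg = replace(config, sigma_fraction=frac)
        preds.append(estimate(query, train_features, train_labels, cfg))
    return SigmaSweep(
        fractions=tuple(fractions),
        predictions=tuple(preds),
        suggested_lower_limit=suggested_sigma_lower_limit(query, train_features),
    )
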