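"""Bivariate Gaussian likelihood of regional GWAS Z-scores, in eigen-space.

Model
-----
Stacked Z-score vectors for two traits over M variants are zero-mean
multivariate normal with

    Sigma_ii = (N_i * h_i^2 / M) * L + R,
    Sigma_12 = (sqrt(N1 * N2) * h12 / M) * L,

where R is the LD correlation matrix, L = R @ R its matrix square, h_i^2
the local SNP heritabilities and h12 the local genetic covariance.  Since
R and L are simultaneously diagonalized by R's eigenvectors U, rotating
``w_i = U.T @ z_i`` turns the 2M-dimensional density into K independent
bivariate normals: for eigenvalue lam_k,

    Cov(w1_k, w2_k) = [[N1*h1^2*lam_k^2/M + lam_k,  sqrt(N1*N2)*h12*lam_k^2/M],
                       [  (sym)                  ,  N2*h2^2*lam_k^2/M + lam_k]].

Within the admissible domain (|h12| <= sqrt(h1^2 h2^2), eigenvalues > 0)
each 2x2 block is positive definite, so the likelihood is finite.

Fitting follows the two-stage scheme of the test: each trait's
heritability is maximized on its own marginal likelihood over [0, 1]
(Newton-Raphson, step tolerance 1e-6, safeguarded bounded-Brent
fallback), then the genetic covariance is profiled with heritabilities
held fixed at those estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize

from .ldmodel import LDBlock

__all__ = [
    "HDLCParams",
    "FitReport",
    "loglik_joint",
    "loglik_single",
    "fit_h2",
    "profile_loglik_h12",
    "fit_h12",
]

LOG_2PI = float(np.log(2.0 * np.pi))

STEP_TOL = 1e-6
MAX_ITER = 100

H2_MAX = 1.0  # regional heritability search range [0, 1]


@dataclass
class HDLCParams:
    """Local heritabilities and genetic covariance (all unitless).

    The derived local genetic correlation ``rG = h12 / sqrt(h1_sq * h2_sq)``
    is None when either heritability is zero.
    """

    h1_sq: float
    h2_sq: float
    h12: float

    def __post_init__(self) -> None:
        if self.h1_sq < 0 or self.h2_sq < 0:
            raise ValueError("heritabilities must be >= 0")
        bound = np.sqrt(self.h1_sq * self.h2_sq)
        if abs(self.h12) > bound + 1e-9 * max(bound, 1.0):
            raise ValueError(
                f"|h12| = {abs(self.h12):.6g} exceeds sqrt(h1_sq*h2_sq) = {bound:.6g}"
            )

    @property
    def rg(self) -> float | None:
        denom = np.sqrt(self.h1_sq * self.h2_sq)
        if denom == 0:
            return None
        return float(np.clip(self.h12 / denom, -1.0, 1.0))


@dataclass
class FitReport:
    """Diagnostics from one 1-D likelihood maximization."""

    loglik: float
    iterations: int
    converged: bool
    at_lower: bool = False
    at_upper: bool = False
    gradient: float = np.nan
    used_fallback: bool = False

    @property
    def at_boundary(self) -> bool:
        return self.at_lower or self.at_upper


def _eigen_moments(block: LDBlock, z: np.ndarray, N: float):
    """Rotated data and eigen-space coefficients for one trait.

    Returns (w, a, lam) with per-direction variance ``a*h2 + lam`` where
    ``a = N * lam**2 / M``.
    """
    w = block.project(z)
    lam = block.eigvals
    a = N * lam**2 / block.M
    return w, a, lam


def loglik_single(h_sq: float, block: LDBlock, z: np.ndarray, N: float) -> float:
    """Marginal log-likelihood of one trait's Z-scores at heritability h_sq."""
    if h_sq < 0:
        return -np.inf
    w, a, lam = _eigen_moments(block, z, N)
    sig = a * h_sq + lam
    if np.any(sig <= 0):
        return -np.inf
    return float(-0.5 * np.sum(LOG_2PI + np.log(sig) + w**2 / sig))


def loglik_joint(
    params: HDLCParams,
    block: LDBlock,
    z1: np.ndarray,
    z2: np.ndarray,
    N1: float,
    N2: float,
) -> float:
    """Joint log-likelihood of both traits' Z-scores.

    Computed as the sum of K bivariate normal log-densities in the
    retained eigen-basis; truncated directions do not contribute.
    Returns -inf if any 2x2 block fails positive definiteness (possible
    only at numerically extreme parameter values).
    """
    w1, a1, lam = _eigen_moments(block, z1, N1)
    w2, a2, _ = _eigen_moments(block, z2, N2)
    t = np.sqrt(N1 * N2) * lam**2 / block.M
    d1 = a1 * params.h1_sq + lam
    d2 = a2 * params.h2_sq + lam
    c = t * params.h12
    det = d1 * d2 - c**2
    if np.any(det <= 0) or np.any(d1 <= 0):
        return -np.inf
    quad = (d2 * w1**2 - 2.0 * c * w1 * w2 + d1 * w2**2) / det
    return float(-0.5 * np.sum(2.0 * LOG_2PI + np.log(det) + quad))


def _newton_box_max(
    f: Callable[[float], float],
    grad: Callable[[float], float],
    hess: Callable[[float], float],
    lo: float,
    hi: float,
    x0: float,
    tol: float = STEP_TOL,
    max_iter: int = MAX_ITER,
) -> tuple[float, FitReport]:
    """Maximize a smooth scalar function on [lo, hi].

    Safeguarded Newton-Raphson on the parameter step: steps that leave
    the box or face a non-negative second derivative trigger a bounded
    Brent fallback; candidate optima are compared against both endpoints
    so boundary solutions are always found.  Convergence is declared when
    the Newton step falls below ``tol`` (scaled by the box width).
    """
    if hi < lo:
        raise ValueError("empty interval")
    scale = max(hi - lo, 1e-12)
    if hi == lo:
        return lo, FitReport(
            loglik=f(lo), iterations=0, converged=True,
            at_lower=True, at_upper=True, gradient=0.0,
        )

    x = float(np.clip(x0, lo, hi))
    converged = False
    used_fallback = False
    it = 0
    for it in range(1, max_iter + 1):
        g, h = grad(x), hess(x)
        if not np.isfinite(g) or not np.isfinite(h) or h >= 0:
            used_fallback = True
            break
        step = -g / h
        x_new = x + step
        if x_new < lo or x_new > hi:
            x_new = float(np.clip(x_new, lo, hi))
            if abs(x_new - x) <= tol * scale:
                x = x_new
                converged = True
                break
        if abs(x_new - x) <= tol * scale:
            x = x_new
            converged = True
            break
        x = x_new
    else:
        used_fallback = True

    if used_fallback:
        res = optimize.minimize_scalar(
            lambda v: -f(v), bounds=(lo, hi), method="bounded",
            options={"xatol": tol * scale},
        )
        x = float(res.x)
        it = max(it, int(res.nfev))
        converged = bool(res.success)

    # interior optimum can still lose to an endpoint (monotone likelihoods)
    candidates = [(f(lo), lo), (f(hi), hi), (f(x), x)]
    best_val, best_x = max(candidates, key=lambda p: p[0])
    edge = tol * scale
    report = FitReport(
        loglik=best_val,
        iterations=it,
        converged=converged or best_x in (lo, hi),
        at_lower=best_x - lo <= edge,
        at_upper=hi - best_x <= edge,
        gradient=float(grad(best_x)),
        used_fallback=used_fallback,
    )
    return best_x, report


def fit_h2(
    block: LDBlock, z: np.ndarray, N: float, tol: float = STEP_TOL
) -> tuple[float, FitReport]:
    """Maximum-likelihood local heritability of one trait on [0, 1].

    Analytic first and second derivatives in eigen-space drive the
    Newton iteration; boundary solutions (h2 = 0 in null regions) are
    legitimate and flagged in the report.
    """
    w, a, lam = _eigen_moments(block, z, N)
    w2 = w**2

    def f(h: float) -> float:
        sig = a * h + lam
        return float(-0.5 * np.sum(LOG_2PI + np.log(sig) + w2 / sig))

    def grad(h: float) -> float:
        sig = a * h + lam
        return float(-0.5 * np.sum(a / sig - a * w2 / sig**2))

    def hess(h: float) -> float:
        sig = a * h + lam
        return float(0.5 * np.sum(a**2 / sig**2 - 2.0 * a**2 * w2 / sig**3))

    # moment-matched start: E[w^2] = a*h2 + lam
    denom = float(np.sum(a**2))
    x0 = float(np.clip(np.sum((w2 - lam) * a) / denom, 0.0, H2_MAX)) if denom > 0 else 0.0
    h_hat, report = _newton_box_max(f, grad, hess, 0.0, H2_MAX, x0, tol=tol)
    if not report.converged and not report.at_boundary:
        raise RuntimeError(f"heritability fit failed to converge: {report}")
    return h_hat, report


def profile_loglik_h12(
    h12: float,
    h1_hat: float,
    h2_hat: float,
    block: LDBlock,
    z1: np.ndarray,
    z2: np.ndarray,
    N1: float,
    N2: float,
) -> float:
    """Profile log-likelihood of the genetic covariance.

    Heritabilities are held fixed at their single-trait MLEs — the
    practical profiling scheme of the test.
    """
    bound = np.sqrt(h1_hat * h2_hat)
    if abs(h12) > bound + 1e-9 * max(bound, 1.0):
        raise ValueError("h12 outside the admissible interval")
    params = HDLCParams(h1_hat, h2_hat, float(np.clip(h12, -bound, bound)))
    return loglik_joint(params, block, z1, z2, N1, N2)


def fit_h12(
    h1_hat: float,
    h2_hat: float,
    block: LDBlock,
    z1: np.ndarray,
    z2: np.ndarray,
    N1: float,
    N2: float,
    bound: float,
    tol: float = STEP_TOL,
) -> tuple[float, FitReport]:
    """Maximize the profile likelihood of h12 over |h12| <= bound.

    Analytic gradient with a finite-difference second derivative feeds
    the safeguarded Newton iteration; a zero-width bound short-circuits
    to h12 = 0.
    """
    if bound < 0:
        raise ValueError("bound must be >= 0")
    w1, a1, lam = _eigen_moments(block, z1, N1)
    w2, a2, _ = _eigen_moments(block, z2, N2)
    t = np.sqrt(N1 * N2) * lam**2 / block.M
    d1 = a1 * h1_hat + lam
    d2 = a2 * h2_hat + lam
    w1sq, w2sq, w12 = w1**2, w2**2, w1 * w2

    if bound == 0.0:
        val = float(
            -0.5 * np.sum(2.0 * LOG_2PI + np.log(d1 * d2) + w1sq / d1 + w2sq / d2)
        )
        return 0.0, FitReport(
            loglik=val, iterations=0, converged=True,
            at_lower=True, at_upper=True, gradient=0.0,
        )

    def f(h: float) -> float:
        c = t * h
        det = d1 * d2 - c**2
        if np.any(det <= 0):
            return -np.inf
        quad = (d2 * w1sq - 2.0 * c * w12 + d1 * w2sq) / det
        return float(-0.5 * np.sum(2.0 * LOG_2PI + np.log(det) + quad))

    def grad(h: float) -> float:
        c = t * h
        det = d1 * d2 - c**2
        num = d2 * w1sq - 2.0 * c * w12 + d1 * w2sq
        return float(
            np.sum(t * c / det + t * w12 / det - num * t * c / det**2)
        )

    eps = max(1e-7 * bound, 1e-12)

    def hess(h: float) -> float:
        return (grad(h + eps) - grad(h - eps)) / (2.0 * eps)

    # moment start: E[w1*w2] = t*h12
    denom = float(np.sum(t**2))
    x0 = float(np.clip(np.sum(w12 * t) / denom, -bound, bound)) if denom > 0 else 0.0
    h12_hat, report = _newton_box_max(f, grad, hess, -bound, bound, x0, tol=tol)
    if not report.converged and not report.at_boundary:
        raise RuntimeError(f"covariance fit failed to converge: {report}")
    return h12_hat, report
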