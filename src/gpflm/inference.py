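"""Asymptotic inference for fitted coefficient functions.

Centers on the generalized auto-covariance structure: the per-predictor
matrix ``Lambda_j`` with entries ``E[g'(eta)^2 / sigma^2(mu) * xi_k1 xi_k2]``
and the kernel ``G(s, t) = E[g'(eta)^2 / sigma^2(mu) * X(s) X(t)]``.  Both
are estimated by plug-in sample means at the fitted ``(eta_hat, mu_hat)``.
The metric ``d_G^2`` between coefficient functions can be evaluated either
as a quadratic form in score coordinates or as a double integral against the
kernel; the two agree whenever the curves involved lie in the span of the
estimated eigenfunctions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateCovariateError,
    ShapeError,
    SingularCovarianceError,
)
from .model import MU_EPS, VAR_FLOOR, LinkFamily

__all__ = [
    "GeneralizedCovariance",
    "BandResult",
    "lambda_tilde",
    "g_kernel",
    "dG2_coeff",
    "dG2_integral",
    "theorem1_standardize",
    "nu_and_gamma_se",
    "simultaneous_band",
    "band_constant",
    "default_multiplier",
]

#: eigenvalues of Lambda below this trigger a singularity error in bands
LAMBDA_FLOOR = 1e-12


def _weights(eta_hat, mu_hat, family: LinkFamily) -> np.ndarray:
    """Per-subject information weights g'(eta)^2 / sigma^2(mu), floored."""
    gprime = family.mean_deriv(np.asarray(eta_hat, dtype=float))
    mu = np.asarray(mu_hat, dtype=float)
    if family.name == "logit":
        mu = np.clip(mu, MU_EPS, 1.0 - MU_EPS)
    var = np.maximum(family.variance_fn(mu), VAR_FLOOR)
    return gprime**2 / var


@dataclass(frozen=True)
class GeneralizedCovariance:
    """Eigenstructure of the estimated generalized covariance matrix."""

    lambda_tilde: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns, matching eigenvalues (non-increasing)


@dataclass(frozen=True)
class BandResult:
    """Simultaneous confidence band around a coefficient curve."""

    grid: np.ndarray
    beta_hat: np.ndarray
    half_width: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    alpha: float
    multiplier: float
    c_alpha: float


def lambda_tilde(
    scores_j: np.ndarray,
    eta_hat: np.ndarray,
    mu_hat: np.ndarray,
    family: LinkFamily,
) -> np.ndarray:
    """Plug-in estimate ``(1/n) D_j' D_j`` of the generalized covariance.

    ``D_j`` has rows ``g'(eta_i) xi_ij / sigma(mu_i)``, so the result is the
    sample mean of ``w_i xi_i xi_i'`` with information weights ``w_i``.
    """
    scores_j = np.atleast_2d(np.asarray(scores_j, dtype=float))
    w = _weights(eta_hat, mu_hat, family)
    if w.size != scores_j.shape[0]:
        raise ShapeError("scores and fitted values have different n")
    n = scores_j.shape[0]
    lam = (scores_j.T * w) @ scores_j / n
    return (lam + lam.T) / 2.0


def g_kernel(
    centered_values: np.ndarray,
    eta_hat: np.ndarray,
    mu_hat: np.ndarray,
    family: LinkFamily,
    quad_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Plug-in kernel ``G(s,t) = (1/n) sum_i w_i X_i(s) X_i(t)`` on the grid.

    ``quad_weights`` is accepted for grid validation only; quadrature enters
    when the kernel is integrated (see :func:`dG2_integral`).
    """
    Xc = np.atleast_2d(np.asarray(centered_values, dtype=float))
    if quad_weights is not None and np.asarray(quad_weights).size != Xc.shape[1]:
        raise ShapeError("quadrature weights do not match the curve grid")
    w = _weights(eta_hat, mu_hat, family)
    if w.size != Xc.shape[0]:
        raise ShapeError("curves and fitted values have different n")
    n = Xc.shape[0]
    G = (Xc.T * w) @ Xc / n
    return (G + G.T) / 2.0


def dG2_coeff(b_hat: np.ndarray, b_true: np.ndarray, lam: np.ndarray) -> float:
    """Quadratic form ``(b_hat - b)' Lambda (b_hat - b)``."""
    b_hat = np.asarray(b_hat, dtype=float)
    b_true = np.asarray(b_true, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if b_hat.shape != b_true.shape or lam.shape != (b_hat.size, b_hat.size):
        raise ShapeError("coefficient vectors and Lambda dimensions must agree")
    d = b_hat - b_true
    return float(d @ lam @ d)


def dG2_integral(
    beta_hat: np.ndarray,
    beta_true: np.ndarray,
    kernel: np.ndarray,
    quad_weights: np.ndarray,
) -> float:
    """Double quadrature of ``(bh-b)(s)(bh-b)(t) G(s,t)`` over the grid."""
    beta_hat = np.asarray(beta_hat, dtype=float)
    beta_true = np.asarray(beta_true, dtype=float)
    w = np.asarray(quad_weights, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    m = beta_hat.size
    if beta_true.size != m or w.size != m or kernel.shape != (m, m):
        raise ShapeError("band inputs must share one grid")
    d = (beta_hat - beta_true) * w
    return float(d @ kernel @ d)


def theorem1_standardize(dg2: float, n: int, p: int) -> float:
    """Standardized statistic ``(n dG2 - p) / sqrt(2p)``."""
    return (n * dg2 - p) / np.sqrt(2.0 * p)


def nu_and_gamma_se(
    z_columns: np.ndarray,
    eta_hat: np.ndarray,
    mu_hat: np.ndarray,
    family: LinkFamily,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-covariate information ``nu_l`` and asymptotic standard errors.

    ``nu_hat_l`` is the sample mean of ``w_i z_il^2``; the asymptotic
    variance of ``sqrt(n)(gamma_l - gamma_hat_l)`` is ``1/nu_l``, so the
    standard error of ``gamma_hat_l`` is ``1 / sqrt(n nu_hat_l)``.
    """
    Z = np.atleast_2d(np.asarray(z_columns, dtype=float))
    if Z.shape[0] != np.asarray(eta_hat).size:
        Z = Z.T
    w = _weights(eta_hat, mu_hat, family)
    if Z.shape[0] != w.size:
        raise ShapeError("covariate rows do not match fitted values")
    nu_hat = (w[:, None] * Z**2).mean(axis=0)
    if np.any(nu_hat <= 0.0):
        bad = np.flatnonzero(nu_hat <= 0.0).tolist()
        raise DegenerateCovariateError(f"zero information for column(s) {bad}")
    se = 1.0 / np.sqrt(n * nu_hat)
    return nu_hat, se


def default_multiplier(alpha: float, convention: str = "two-sided") -> float:
    """Standard-normal multiplier entering the band constant ``c(alpha)``.

    At ``alpha = 0.05`` under the default two-sided convention the value is
    the conventional 1.96 exactly; other alphas use the corresponding normal
    quantile (upper alpha/2 for "two-sided", upper alpha for "one-sided").
    """
    from scipy.stats import norm

    if convention == "two-sided":
        if abs(alpha - 0.05) < 1e-12:
            return 1.96
        return float(norm.ppf(1.0 - alpha / 2.0))
    if convention == "one-sided":
        return float(norm.ppf(1.0 - alpha))
    raise ValueError(f"unknown quantile convention {convention!r}")


def band_constant(p: int, n: int, alpha: float = 0.05, multiplier: float | None = None) -> float:
    """Closed-form ``c(alpha) = [p + sqrt(2p) * multiplier] / n``."""
    if multiplier is None:
        multiplier = default_multiplier(alpha)
    return (p + np.sqrt(2.0 * p) * multiplier) / n


def eigen_decompose_lambda(lam: np.ndarray) -> GeneralizedCovariance:
    """Symmetric eigendecomposition of Lambda, sorted non-increasing."""
    lam = np.asarray(lam, dtype=float)
    sym = (lam + lam.T) / 2.0
    evals, evecs = np.linalg.eigh(sym)
    order = np.argsort(evals)[::-1]
    return GeneralizedCovariance(
        lambda_tilde=sym, eigenvalues=evals[order], eigenvectors=evecs[:, order]
    )


def simultaneous_band(
    beta_hat: np.ndarray,
    lam: np.ndarray,
    eigenfunctions: np.ndarray,
    n: int,
    alpha: float = 0.05,
    multiplier: float | None = None,
    grid: np.ndarray | None = None,
) -> BandResult:
    """Approximate simultaneous confidence band for a coefficient curve.

    With eigenpairs ``(e_k, l_k)`` of Lambda and basis curves ``phi_l`` the
    half-width is ``sqrt(c(alpha) sum_k omega_k(t)^2 / l_k)`` where
    ``omega_k(t) = sum_l phi_l(t) e_{k,l}``.

    Raises
    ------
    SingularCovarianceError
        If any eigenvalue of Lambda is below 1e-12 (no pseudo-inversion).
    """
    beta_hat = np.asarray(beta_hat, dtype=float)
    phi = np.atleast_2d(np.asarray(eigenfunctions, dtype=float))
    lam = np.asarray(lam, dtype=float)
    p = lam.shape[0]
    if phi.shape[0] < p:
        raise ShapeError(f"need {p} basis curves, got {phi.shape[0]}")
    if phi.shape[1] != beta_hat.size:
        raise ShapeError("beta_hat and eigenfunctions must share one grid")
    gc = eigen_decompose_lambda(lam)
    if np.any(gc.eigenvalues < LAMBDA_FLOOR):
        raise SingularCovarianceError(
            "Lambda has a (near-)zero eigenvalue; band is undefined"
        )
    if multiplier is None:
        multiplier = default_multiplier(alpha)
    c_alpha = band_constant(p, n, alpha, multiplier)
    # omega[k] curve = sum_l phi_l(t) * e_{k, l}
    omega = gc.eigenvectors.T @ phi[:p]
    var_curve = (omega**2 / gc.eigenvalues[:, None]).sum(axis=0)
    half = np.sqrt(c_alpha * var_curve)
    if grid is None:
        grid = np.arange(beta_hat.size, dtype=float)
    return BandResult(
        grid=np.asarray(grid, dtype=float),
        beta_hat=beta_hat,
        half_width=half,
        lower=beta_hat - half,
        upper=beta_hat + half,
        alpha=alpha,
        multiplier=float(multiplier),
        c_alpha=float(c_alpha),
    )
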