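"""Quasi-likelihood fitting of the truncated scalar-on-function model.

The linear predictor stacks functional principal component scores
(one block per functional predictor), an intercept column and scalar
covariates.  The mean model is ``mu = mean_fn(eta)`` — note the convention:
``mean_fn`` maps the linear predictor to the mean, i.e. it is the *inverse*
of the textbook GLM link.  Estimation solves the quasi-score equation

    U(theta) = sum_i (Y_i - mu_i) * mean_deriv(eta_i) / variance_fn(mu_i) * w_i = 0

by Fisher scoring / iteratively reweighted least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import linalg
from scipy.special import expit

from .exceptions import (
    InputError,
    ShapeError,
    SingularDesignError,
    UndefinedMetricError,
)

__all__ = [
    "LinkFamily",
    "DesignMatrix",
    "FitResult",
    "logit_family",
    "build_design",
    "score_function",
    "fit_quasi_likelihood",
    "reconstruct_coefficient_function",
    "predict_mean",
    "pseudo_r2",
    "gcv",
]

#: mean clipping bound for near-degenerate probabilities
MU_EPS = 1e-10
#: floor applied to the variance function before division
VAR_FLOOR = 1e-10
#: fitted means this close to {0, 1} count as pinned at the boundary
PIN_EPS = 1e-6
#: parameter magnitude beyond which the iteration is declared divergent
THETA_MAX = 1e8


@dataclass(frozen=True)
class LinkFamily:
    """Mean function, its derivative and the variance function.

    ``mean_fn`` maps the linear predictor eta to the conditional mean mu
    (the inverse of the textbook link), ``mean_deriv`` is its derivative in
    eta, and ``variance_fn`` maps mu to the conditional variance.
    ``loglik`` is optional: when provided it enables likelihood-based
    diagnostics (pseudo-R2) and step-halving line search during fitting.
    """

    name: str
    mean_fn: Callable[[np.ndarray], np.ndarray]
    mean_deriv: Callable[[np.ndarray], np.ndarray]
    variance_fn: Callable[[np.ndarray], np.ndarray]
    loglik: Optional[Callable[[np.ndarray, np.ndarray], float]] = None


def _bernoulli_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, MU_EPS, 1.0 - MU_EPS)
    return float(np.sum(y * np.log(mu) + (1.0 - y) * np.log1p(-mu)))


def logit_family() -> LinkFamily:
    """Binary-response family with ``mu = exp(eta)/(1+exp(eta))``.

    Overflow-safe for ``|eta|`` well beyond 1e4; ``mean_deriv(eta)`` and
    ``variance_fn(mu)`` both equal ``mu (1 - mu)``.
    """

    def mean_deriv(eta: np.ndarray) -> np.ndarray:
        mu = expit(eta)
        return mu * (1.0 - mu)

    return LinkFamily(
        name="logit",
        mean_fn=expit,
        mean_deriv=mean_deriv,
        variance_fn=lambda mu: mu * (1.0 - mu),
        loglik=_bernoulli_loglik,
    )


@dataclass(frozen=True)
class DesignMatrix:
    """Stacked design: score blocks, intercept column, scalar covariates.

    ``block_index`` maps each functional predictor label to its column
    slice, plus ``"intercept"`` and (when present) ``"scalar"``.
    """

    X: np.ndarray
    block_index: dict[str, slice]
    functional_labels: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


def build_design(
    score_blocks: list[np.ndarray],
    Z: Optional[np.ndarray] = None,
    intercept: bool = True,
    labels: Optional[list[str]] = None,
) -> DesignMatrix:
    """Concatenate score blocks, an intercept and scalar covariates.

    Column order is: functional blocks in the given order, then the constant
    intercept column, then the scalar columns — matching the parameter vector
    ``(b_11..b_1p1, ..., b_d1..b_dpd, gamma_0, gamma_1..gamma_q)``.
    """
    blocks = [np.atleast_2d(np.asarray(b, dtype=float)) for b in score_blocks]
    if labels is None:
        labels = [f"X{j + 1}" for j in range(len(blocks))]
    if len(labels) != len(blocks):
        raise ShapeError("labels must match the number of score blocks")
    ns = {b.shape[0] for b in blocks}
    if Z is not None:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.ndim != 2:
            raise ShapeError("Z must be a 2-D matrix")
        ns.add(Z.shape[0])
    if len(ns) > 1:
        raise ShapeError(f"row counts differ across blocks: {sorted(ns)}")
    if not ns:
        raise ShapeError("at least one block (or Z) is required")
    n = ns.pop()

    cols: list[np.ndarray] = []
    index: dict[str, slice] = {}
    start = 0
    for label, b in zip(labels, blocks):
        index[label] = slice(start, start + b.shape[1])
        cols.append(b)
        start += b.shape[1]
    if intercept:
        index["intercept"] = slice(start, start + 1)
        cols.append(np.ones((n, 1)))
        start += 1
    if Z is not None and Z.shape[1] > 0:
        index["scalar"] = slice(start, start + Z.shape[1])
        cols.append(Z)
        start += Z.shape[1]
    X = np.hstack(cols) if cols else np.empty((n, 0))
    return DesignMatrix(X=X, block_index=index, functional_labels=tuple(labels))


def _link_state(theta, X, family):
    """eta, clipped mu, mean derivative and floored variance at theta."""
    eta = X @ theta
    mu = family.mean_fn(eta)
    if family.name == "logit":
        mu = np.clip(mu, MU_EPS, 1.0 - MU_EPS)
    gprime = family.mean_deriv(eta)
    var = family.variance_fn(mu)
    small = var < VAR_FLOOR
    if np.any(small):
        var = np.where(small, VAR_FLOOR, var)
    return eta, mu, gprime, var


def score_function(
    theta: np.ndarray,
    design: DesignMatrix,
    Y: np.ndarray,
    family: LinkFamily,
) -> np.ndarray:
    """Quasi-score ``U(theta) = X' [(Y - mu) g'(eta) / sigma^2(mu)]``."""
    theta = np.asarray(theta, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if theta.size != design.n_columns or Y.size != design.n:
        raise ShapeError("theta / Y dimensions do not match the design")
    _, mu, gprime, var = _link_state(theta, design.X, family)
    return design.X.T @ ((Y - mu) * gprime / var)


@dataclass
class FitResult:
    """Converged (or honestly non-converged) quasi-likelihood fit."""

    theta_hat: np.ndarray
    b_blocks: dict[str, np.ndarray]
    alpha_hat: float
    gamma_hat: np.ndarray
    eta_hat: np.ndarray
    mu_hat: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    score_norm: float
    block_index: dict[str, slice] = field(default_factory=dict)
    family_name: str = ""
    ridge: float = 0.0
    tol: float = 1e-8


def _partition(theta: np.ndarray, design: DesignMatrix):
    b_blocks = {lab: theta[design.block_index[lab]] for lab in design.functional_labels}
    alpha = float(theta[design.block_index["intercept"]][0]) if "intercept" in design.block_index else 0.0
    gamma = theta[design.block_index["scalar"]] if "scalar" in design.block_index else np.empty(0)
    return b_blocks, alpha, gamma


def fit_quasi_likelihood(
    design: DesignMatrix,
    Y: np.ndarray,
    family: LinkFamily,
    tol: float = 1e-8,
    max_iter: int = 100,
    ridge: float = 0.0,
) -> FitResult:
    """Solve the quasi-score equation by Fisher scoring / IWLS.

    Convergence is declared when ``max|U(theta)| <= tol * n`` or the relative
    parameter step falls below ``tol``; otherwise the result is returned with
    ``converged=False`` (no silent clamping).  A positive ``ridge`` adds
    ``ridge * I`` to the weighted normal equations, which regularizes
    separation-prone binary data.

    Raises
    ------
    SingularDesignError
        If the weighted cross-product is singular and ``ridge == 0``.
    InputError
        If ``Y`` contains non-finite values, or ``n <= n_columns`` with
        ``ridge == 0``.
    """
    Y = np.asarray(Y, dtype=float)
    if not np.all(np.isfinite(Y)):
        raise InputError("response contains non-finite values")
    if Y.size != design.n:
        raise ShapeError("response length does not match the design")
    n, p = design.n, design.n_columns
    if ridge < 0:
        raise InputError("ridge must be >= 0")
    if ridge == 0.0 and n <= p:
        raise InputError(
            f"n={n} <= {p} columns: the unpenalized fit is ill-posed; use ridge > 0"
        )

    X = design.X
    theta = np.zeros(p)
    use_ll = family.loglik is not None

    def penalized_ll(th, mu):
        return family.loglik(Y, mu) - 0.5 * ridge * float(th @ th)

    eta, mu, gprime, var = _link_state(theta, X, family)
    ll = penalized_ll(theta, mu) if use_ll else None

    def all_pinned(mu_vec):
        # a "converged" score with every fitted mean at the boundary means
        # the optimum is at infinity (separation), not a finite solution
        if family.name != "logit":
            return False
        return bool(np.all((mu_vec <= PIN_EPS) | (mu_vec >= 1.0 - PIN_EPS)))

    converged = False
    n_iter = 0
    score_norm = np.inf
    for n_iter in range(1, max_iter + 1):
        resid = (Y - mu) * gprime / var
        U = X.T @ resid - ridge * theta
        score_norm = float(np.max(np.abs(U))) if U.size else 0.0
        if score_norm <= tol * n:
            converged = not all_pinned(mu)
            break
        W = gprime**2 / var
        A = X.T @ (W[:, None] * X)
        if ridge > 0:
            A = A + ridge * np.eye(p)
        try:
            step = linalg.solve(A, U, assume_a="pos")
        except linalg.LinAlgError as err:
            if ridge == 0.0:
                raise SingularDesignError(
                    "weighted normal equations are singular; retry with ridge > 0"
                ) from err
            step = linalg.lstsq(A, U)[0]
        if not np.all(np.isfinite(step)):
            if ridge == 0.0:
                raise SingularDesignError(
                    "weighted normal equations are numerically singular; "
                    "retry with ridge > 0"
                )
            break

        # step-halving line search on the penalized log-likelihood
        scale = 1.0
        for _ in range(30):
            cand = theta + scale * step
            eta_c, mu_c, gp_c, var_c = _link_state(cand, X, family)
            if use_ll:
                ll_c = penalized_ll(cand, mu_c)
                if np.isfinite(ll_c) and (ll_c >= ll - 1e-12):
                    break
            else:
                if np.all(np.isfinite(mu_c)):
                    break
            scale /= 2.0
        step_size = float(np.linalg.norm(scale * step))
        theta = theta + scale * step
        if not np.all(np.isfinite(theta)) or np.max(np.abs(theta)) > THETA_MAX:
            converged = False  # divergence (separation): report, don't raise
            eta, mu, gprime, var = _link_state(theta, X, family)
            break
        eta, mu, gprime, var = _link_state(theta, X, family)
        if use_ll:
            ll = penalized_ll(theta, mu)
        if step_size < tol * max(1.0, float(np.linalg.norm(theta))):
            U = X.T @ ((Y - mu) * gprime / var) - ridge * theta
            score_norm = float(np.max(np.abs(U))) if U.size else 0.0
            converged = not all_pinned(mu)
            break

    if not converged:
        U = X.T @ ((Y - mu) * gprime / var) - ridge * theta
        score_norm = float(np.max(np.abs(U))) if U.size else 0.0

    b_blocks, alpha, gamma = _partition(theta, design)
    final_ll = family.loglik(Y, mu) if use_ll else float(-np.sum((Y - mu) ** 2))
    return FitResult(
        theta_hat=theta,
        b_blocks=b_blocks,
        alpha_hat=alpha,
        gamma_hat=gamma,
        eta_hat=eta,
        mu_hat=mu,
        loglik=final_ll,
        n_iter=n_iter,
        converged=converged,
        score_norm=score_norm,
        block_index=dict(design.block_index),
        family_name=family.name,
        ridge=ridge,
        tol=tol,
    )


def reconstruct_coefficient_function(
    b_block: np.ndarray,
    eigenfunctions: np.ndarray,
    grid: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Coefficient curve ``beta(t_g) = sum_k b_k phi_k(t_g)`` on the grid."""
    b_block = np.asarray(b_block, dtype=float)
    eigenfunctions = np.atleast_2d(np.asarray(eigenfunctions, dtype=float))
    if b_block.size > eigenfunctions.shape[0]:
        raise ShapeError(
            f"{b_block.size} coefficients but only "
            f"{eigenfunctions.shape[0]} eigenfunctions"
        )
    if grid is not None and len(grid) != eigenfunctions.shape[1]:
        raise ShapeError("grid length does not match the eigenfunctions")
    return b_block @ eigenfunctions[: b_block.size]


def predict_mean(
    fit_or_theta: FitResult | np.ndarray,
    design: DesignMatrix,
    family: Optional[LinkFamily] = None,
) -> np.ndarray:
    """Componentwise ``mean_fn(X theta)`` for a fit or raw parameter vector."""
    if isinstance(fit_or_theta, FitResult):
        theta = fit_or_theta.theta_hat
        if family is None:
            if fit_or_theta.family_name != "logit":
                raise InputError("pass the family explicitly for non-logit fits")
            family = logit_family()
    else:
        theta = np.asarray(fit_or_theta, dtype=float)
        if family is None:
            raise InputError("family is required when passing a raw theta")
    if theta.size != design.n_columns:
        raise ShapeError("theta does not match the design")
    return family.mean_fn(design.X @ theta)


def pseudo_r2(fit: FitResult, null_fit: FitResult, n: int) -> tuple[float, float]:
    """McFadden and maximum-likelihood (Cox–Snell) pseudo-R2.

    ``mcfadden = 1 - ll_full / ll_null`` and
    ``r2ml = 1 - exp(2 (ll_null - ll_full) / n)``.
    """
    ll_full, ll_null = fit.loglik, null_fit.loglik
    if ll_null == 0.0:
        raise UndefinedMetricError("null log-likelihood is 0; McFadden undefined")
    mcfadden = 1.0 - ll_full / ll_null
    r2ml = 1.0 - float(np.exp(2.0 * (ll_null - ll_full) / n))
    return mcfadden, r2ml


def gcv(fit: FitResult, design: DesignMatrix, Y: np.ndarray) -> float:
    """Generalized cross-validation score of a fitted model.

    ``GCV = (RSS/n) / (1 - tr(H)/n)^2`` where ``H`` is the hat matrix of the
    converged IWLS weighted least-squares step.  Requires ``tr(H) < n``.
    """
    Y = np.asarray(Y, dtype=float)
    if not fit.converged:
        warnings.warn("GCV computed from a non-converged fit", stacklevel=2)
    if fit.family_name != "logit":
        raise InputError("gcv currently requires the logit family")
    X = design.X
    n = design.n
    mu = fit.mu_hat
    fam = logit_family()
    gprime = fam.mean_deriv(fit.eta_hat)
    var = np.maximum(fam.variance_fn(np.clip(mu, MU_EPS, 1 - MU_EPS)), VAR_FLOOR)
    W = gprime**2 / var
    XtWX = X.T @ (W[:, None] * X)
    A = XtWX + fit.ridge * np.eye(design.n_columns) if fit.ridge > 0 else XtWX
    try:
        trace_h = float(np.trace(linalg.solve(A, XtWX, assume_a="pos")))
    except linalg.LinAlgError as err:
        raise SingularDesignError("hat matrix is not computable") from err
    if trace_h >= n - 1e-9:
        raise UndefinedMetricError(f"tr(H)={trace_h:.3f} >= n={n}; GCV undefined")
    rss = float(np.sum((Y - mu) ** 2))
    return (rss / n) / (1.0 - trace_h / n) ** 2
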