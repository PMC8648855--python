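"""Functional principal component analysis on a shared observation grid.

Curves are stored as a dense ``n_subjects x n_grid`` matrix over one strictly
increasing grid.  Integrals over the domain are discretized with trapezoidal
quadrature, and eigenfunctions are orthonormal with respect to the resulting
weighted inner product ``<f, g> = sum_g w_g f(t_g) g(t_g)``.

The empirical covariance operator is estimated with a 1/n normalization so
that moment formulas of the form ``(1/n) E[D' D]`` used downstream are
consistent with the eigenvalues reported here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    InputError,
    InsufficientSampleError,
    InvalidGridError,
    NoVariationError,
    ShapeError,
)

__all__ = [
    "CurveSet",
    "FPCAResult",
    "quadrature_weights",
    "center_curves",
    "fpca_decompose",
    "select_truncation",
    "compute_scores",
]

#: tolerance below which eigenvalues are treated as round-off and clipped
EIGENVALUE_TOL = 1e-12


def quadrature_weights(grid: np.ndarray) -> np.ndarray:
    """Trapezoidal quadrature weights for a strictly increasing grid.

    The weights are positive and sum to the grid range, so
    ``sum_g w_g f(t_g)`` approximates ``int f(t) dt`` exactly for piecewise
    linear ``f``.

    Parameters
    ----------
    grid:
        1-D strictly increasing array with at least two points.

    Returns
    -------
    numpy.ndarray
        Weight vector of the same length as ``grid``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise InvalidGridError("grid must be 1-D with at least 2 points")
    steps = np.diff(grid)
    if np.any(steps <= 0):
        raise InvalidGridError("grid must be strictly increasing")
    w = np.zeros_like(grid)
    w[:-1] += steps / 2.0
    w[1:] += steps / 2.0
    return w


@dataclass(frozen=True)
class CurveSet:
    """A sample of discretized curves sharing one grid.

    Parameters
    ----------
    grid:
        Strictly increasing argument values, at least 3 points.
    values:
        ``n_subjects x n_grid`` matrix of curve evaluations; finite entries.
    domain:
        Closed interval containing the grid.  Defaults to the grid range.
    """

    grid: np.ndarray
    values: np.ndarray
    domain: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if grid.ndim != 1 or grid.size < 3:
            raise InvalidGridError("grid must be 1-D with at least 3 points")
        if np.any(np.diff(grid) <= 0):
            raise InvalidGridError("grid must be strictly increasing")
        if values.ndim != 2 or values.shape[1] != grid.size:
            raise ShapeError(
                f"values shape {values.shape} incompatible with grid of "
                f"length {grid.size}"
            )
        if not np.all(np.isfinite(values)):
            raise InputError(
                "curve values must be finite (missing values are not supported)"
            )
        domain = self.domain
        if domain is None:
            domain = (float(grid[0]), float(grid[-1]))
        a, b = float(domain[0]), float(domain[1])
        if grid[0] < a - 1e-12 or grid[-1] > b + 1e-12:
            raise InvalidGridError(f"grid not contained in domain [{a}, {b}]")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "domain", (a, b))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_grid(self) -> int:
        return self.grid.size

    def quad_weights(self) -> np.ndarray:
        """Trapezoidal weights on this grid."""
        return quadrature_weights(self.grid)


@dataclass(frozen=True)
class FPCAResult:
    """Output of :func:`fpca_decompose`.

    Attributes
    ----------
    mean_curve:
        Sample mean curve on the grid.
    eigenfunctions:
        ``p_max x n_grid`` matrix; row ``k`` is the k-th eigenfunction,
        orthonormal in the weighted inner product.
    eigenvalues:
        Non-increasing, non-negative (round-off clipped to 0).
    scores:
        ``n_subjects x p_max`` matrix of principal component scores of the
        centered curves.
    quad_weights:
        Trapezoidal weights used for all inner products.
    grid:
        The shared observation grid.
    """

    mean_curve: np.ndarray
    eigenfunctions: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    quad_weights: np.ndarray
    grid: np.ndarray


def center_curves(curves: CurveSet) -> tuple[CurveSet, np.ndarray]:
    """Subtract the cross-sectional sample mean curve.

    Returns the centered curve set and the mean curve; adding the mean back
    to the centered values reproduces the input exactly.
    """
    if curves.n_subjects < 2:
        raise InsufficientSampleError("centering requires at least 2 subjects")
    mean_curve = curves.values.mean(axis=0)
    centered = CurveSet(curves.grid, curves.values - mean_curve, curves.domain)
    return centered, mean_curve


def compute_scores(
    centered: CurveSet | np.ndarray,
    eigenfunctions: np.ndarray,
    quad_weights: np.ndarray,
) -> np.ndarray:
    """Project centered curves on eigenfunctions by weighted inner product.

    ``scores[i, k] = sum_g w_g X_i(t_g) phi_k(t_g)``.
    """
    values = centered.values if isinstance(centered, CurveSet) else np.atleast_2d(centered)
    eigenfunctions = np.atleast_2d(np.asarray(eigenfunctions, dtype=float))
    quad_weights = np.asarray(quad_weights, dtype=float)
    if values.shape[1] != eigenfunctions.shape[1] or values.shape[1] != quad_weights.size:
        raise ShapeError(
            "curves, eigenfunctions and quadrature weights must share one grid"
        )
    return (values * quad_weights) @ eigenfunctions.T


def fpca_decompose(curves: CurveSet, p_max: int | str = "all") -> FPCAResult:
    """Eigendecompose the weighted empirical covariance operator.

    The covariance matrix of the sample-centered values (1/n normalization)
    is symmetrized into ``W^{1/2} C W^{1/2}`` so that its orthonormal
    eigenvectors map to eigenfunctions orthonormal under the weighted inner
    product.  Sign convention: each eigenfunction is flipped so its weighted
    integral is >= 0; if that integral is ~0 the first grid value decides.

    Parameters
    ----------
    curves:
        Input sample, at least 2 subjects.
    p_max:
        Number of leading components to retain, or ``"all"``.
    """
    if curves.n_subjects < 2:
        raise InsufficientSampleError("FPCA requires at least 2 subjects")
    centered, mean_curve = center_curves(curves)
    w = curves.quad_weights()
    sqrt_w = np.sqrt(w)
    n = curves.n_subjects
    cov = (centered.values.T @ centered.values) / n
    sym = sqrt_w[:, None] * cov * sqrt_w[None, :]
    sym = (sym + sym.T) / 2.0
    evals, evecs = np.linalg.eigh(sym)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    evals = np.where(evals < EIGENVALUE_TOL, 0.0, evals)

    if p_max == "all":
        p = evals.size
    else:
        p = int(p_max)
        if p < 1:
            raise ShapeError("p_max must be a positive integer or 'all'")
        p = min(p, evals.size)

    phi = (evecs[:, :p] / sqrt_w[:, None]).T  # rows orthonormal under w
    # sign convention
    integrals = phi @ w
    for k in range(phi.shape[0]):
        s = integrals[k]
        if abs(s) < 1e-10:
            s = phi[k, 0]
        if s < 0:
            phi[k] = -phi[k]
    scores = compute_scores(centered, phi, w)
    return FPCAResult(
        mean_curve=mean_curve,
        eigenfunctions=phi,
        eigenvalues=evals[:p],
        scores=scores,
        quad_weights=w,
        grid=curves.grid,
    )


def select_truncation(eigenvalues: np.ndarray, threshold: float) -> int:
    """Smallest p whose leading eigenvalues explain ``threshold`` of variance.

    Parameters
    ----------
    eigenvalues:
        Non-increasing, non-negative values (negatives are clipped to 0).
    threshold:
        Target cumulative share in ``(0, 1]``.
    """
    if not 0.0 < threshold <= 1.0:
        raise InputError(f"threshold must be in (0, 1], got {threshold!r}")
    ev = np.clip(np.asarray(eigenvalues, dtype=float), 0.0, None)
    total = ev.sum()
    if total <= 0.0:
        raise NoVariationError("all eigenvalues are zero; truncation undefined")
    shares = np.cumsum(ev) / total
    # small slack so exact-arithmetic thresholds like 1.0 are not missed
    p = int(np.searchsorted(shares, threshold - 1e-12) + 1)
    return min(p, ev.size)
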