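"""Penalized B-spline smoothing of 5-point OGTT series.

Each participant's five timed measurements (0, 30, 60, 90, 120 min) are
represented as a smooth curve sum_k c_k phi_k(t) in a cubic B-spline basis
with knots at the measurement times (3 interior knots + order 4 = 7 basis
functions).  Coefficients are estimated by penalized least squares,

    c = argmin ||y - Phi c||^2 + lambda * c' R c,

where R is the integrated squared-second-derivative (curvature) penalty.
A single lambda per analyte is chosen by leave-one-point-out
cross-validation pooled across the cohort.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

logger = logging.getLogger(__name__)

DEFAULT_TIMES = np.array([0.0, 30.0, 60.0, 90.0, 120.0])

#: default log-spaced penalty grid searched by cross-validation
DEFAULT_LAMBDA_GRID = np.logspace(-4, 4, 25)


class BasisConfigError(ValueError):
    """Requested basis size is inconsistent with knots and spline order."""


@dataclass(frozen=True)
class BasisSystem:
    """Cubic B-spline basis on [t_min, t_max] with knots at the sample times.

    Attributes
    ----------
    times : measurement times (the knots), strictly increasing.
    order : spline order (4 = cubic).
    knots : full clamped knot vector.
    design : (len(times), n_basis) evaluation matrix Phi at the sample times.
    penalty : (n_basis, n_basis) matrix R of integrated products of second
        derivatives, computed by composite-trapezoid quadrature.
    gram : (n_basis, n_basis) Gram matrix J of integrated basis products,
        on the same quadrature grid (used as the L2 metric by FPCA).
    quad_step : quadrature resolution in minutes.
    """

    times: np.ndarray
    order: int
    knots: np.ndarray
    design: np.ndarray
    penalty: np.ndarray
    gram: np.ndarray
    quad_step: float = 1.0

    @property
    def n_basis(self) -> int:
        return self.design.shape[1]

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def quad_grid(self) -> np.ndarray:
        lo, hi = self.domain
        return np.arange(lo, hi + self.quad_step / 2, self.quad_step)

    def quad_weights(self) -> np.ndarray:
        g = self.quad_grid()
        w = np.full(g.shape, self.quad_step)
        w[0] = w[-1] = self.quad_step / 2
        return w

    def evaluate(self, grid: np.ndarray, derivative: int = 0) -> np.ndarray:
        """Evaluate every basis function (or a derivative) at ``grid``.

        Returns an array of shape (len(grid), n_basis).  Points outside the
        domain raise ``ValueError``; the basis is not defined there.
        """
        grid = np.asarray(grid, dtype=float)
        lo, hi = self.domain
        if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
            raise ValueError(
                f"evaluation grid outside basis domain [{lo}, {hi}]"
            )
        grid = np.clip(grid, lo, hi)
        k = self.order - 1
        out = np.empty((grid.size, self.n_basis))
        for j in range(self.n_basis):
            coef = np.zeros(self.n_basis)
            coef[j] = 1.0
            sp = BSpline(self.knots, coef, k)
            if derivative:
                sp = sp.derivative(derivative)
            out[:, j] = sp(grid)
        return out


def build_basis(
    times: np.ndarray | list[float] = DEFAULT_TIMES,
    n_basis: int = 7,
    order: int = 4,
    quad_step: float = 1.0,
) -> BasisSystem:
    """Construct the spline basis, design matrix and curvature penalty.

    The clamped knot vector repeats the boundary times ``order`` times and
    places one knot at each interior measurement time, so the number of
    basis functions is ``len(times) - 2 + order`` (7 for five timepoints and
    cubic splines).  A mismatching ``n_basis`` raises ``BasisConfigError``.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise BasisConfigError("times must be strictly increasing")
    expected = times.size - 2 + order
    if n_basis != expected:
        raise BasisConfigError(
            f"n_basis={n_basis} inconsistent with {times.size} knots and "
            f"order {order} (expected {expected})"
        )
    knots = np.concatenate(
        [np.repeat(times[0], order), times[1:-1], np.repeat(times[-1], order)]
    )
    k = order - 1
    design = BSpline.design_matrix(times, knots, k, extrapolate=False).toarray()

    grid = np.arange(times[0], times[-1] + quad_step / 2, quad_step)
    w = np.full(grid.shape, quad_step)
    w[0] = w[-1] = quad_step / 2
    d0 = np.empty((grid.size, n_basis))
    d2 = np.empty((grid.size, n_basis))
    for j in range(n_basis):
        coef = np.zeros(n_basis)
        coef[j] = 1.0
        sp = BSpline(knots, coef, k)
        d0[:, j] = sp(grid)
        d2[:, j] = sp.derivative(2)(grid)
    penalty = d2.T @ (w[:, None] * d2)
    gram = d0.T @ (w[:, None] * d0)
    # enforce exact symmetry against quadrature round-off
    penalty = (penalty + penalty.T) / 2
    gram = (gram + gram.T) / 2
    return BasisSystem(
        times=times,
        order=order,
        knots=knots,
        design=design,
        penalty=penalty,
        gram=gram,
        quad_step=quad_step,
    )


@dataclass
class SmoothCurve:
    """A fitted curve: basis coefficients plus fit diagnostics."""

    coefficients: np.ndarray
    analyte: str
    lam: float
    residuals: np.ndarray
    basis: BasisSystem = field(repr=False)

    @property
    def rss(self) -> float:
        return float(np.sum(self.residuals**2))

    @property
    def roughness(self) -> float:
        """Penalty quadratic form c' R c (integrated squared 2nd derivative)."""
        c = self.coefficients
        return float(c @ self.basis.penalty @ c)

    def __call__(self, grid: np.ndarray) -> np.ndarray:
        return evaluate_curve(self, grid)


def fit_coefficients(
    Y: np.ndarray, basis: BasisSystem, lam: float
) -> np.ndarray:
    """Penalized least-squares coefficients for one or many series.

    ``Y`` has shape (n, 5) (or (5,) for a single series); returns
    coefficients of shape (n, n_basis) (or (n_basis,)).  With ``lam = 0``
    the normal equations are singular (5 equations, 7 unknowns) and the
    minimum-norm solution is returned with a warning.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[1] != basis.times.size:
        raise ValueError(
            f"expected {basis.times.size} measurements per series, "
            f"got {Y.shape[1]}"
        )
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite measurement values")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    Phi = basis.design
    if lam == 0:
        warnings.warn(
            "lambda=0 leaves the system underdetermined; "
            "returning the minimum-norm interpolant",
            RuntimeWarning,
            stacklevel=2,
        )
        C = np.linalg.pinv(Phi) @ Y.T
    else:
        # augmented least-squares form of the penalized normal equations:
        # better conditioned than (Phi'Phi + lam R) when lam is tiny
        ev, E = np.linalg.eigh(basis.penalty)
        L = np.sqrt(np.clip(ev, 0, None))[:, None] * E.T
        aug = np.vstack([Phi, np.sqrt(lam) * L])
        rhs = np.vstack([Y.T, np.zeros((L.shape[0], Y.shape[0]))])
        C = np.linalg.lstsq(aug, rhs, rcond=None)[0]
    return C.T


def fit_curve(
    y: np.ndarray, basis: BasisSystem, lam: float, analyte: str = "glucose"
) -> SmoothCurve:
    """Fit a single 5-point series; see :func:`fit_coefficients`."""
    y = np.asarray(y, dtype=float).ravel()
    c = fit_coefficients(y, basis, lam)[0]
    residuals = y - basis.design @ c
    return SmoothCurve(
        coefficients=c, analyte=analyte, lam=float(lam),
        residuals=residuals, basis=basis,
    )


def evaluate_curve(curve: SmoothCurve, grid: np.ndarray) -> np.ndarray:
    """Evaluate sum_k c_k phi_k(t) at the requested time points."""
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    return curve.basis.evaluate(grid) @ curve.coefficients


@dataclass(frozen=True)
class LambdaSelection:
    """Outcome of the cross-validation search for the penalty weight."""

    lam: float
    grid: np.ndarray
    cv_error: np.ndarray
    flat: bool  # CV profile indistinguishable from constant


def select_lambda(
    Y: np.ndarray,
    basis: BasisSystem,
    lambda_grid: np.ndarray | list[float] = DEFAULT_LAMBDA_GRID,
) -> LambdaSelection:
    """Choose one penalty weight per analyte by pooled leave-one-point-out CV.

    For each candidate lambda, each of the five timepoints is deleted in
    turn, the curve refitted from the remaining four, and the deleted value
    predicted; the mean squared prediction error is pooled over all
    participants.  The same design applies to every participant so each
    deletion requires a single linear solve for the whole cohort.

    A flat CV profile (data reproducible at any lambda, e.g. straight
    lines) is flagged and resolved to the largest grid value — maximal
    smoothing is free when the data carry no curvature signal.  Exact
    non-flat ties resolve to the smallest lambda.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    grid = np.sort(np.asarray(lambda_grid, dtype=float))
    if grid.size == 0:
        raise ValueError("lambda grid must be non-empty")
    if np.any(grid <= 0):
        raise ValueError("lambda grid values must be positive")
    Phi = basis.design
    m = Phi.shape[0]
    cv = np.empty(grid.size)
    for gi, lam in enumerate(grid):
        sse = 0.0
        for j in range(m):
            keep = np.delete(np.arange(m), j)
            Pj = Phi[keep]
            A = Pj.T @ Pj + lam * basis.penalty
            C = np.linalg.solve(A, Pj.T @ Y[:, keep].T)
            pred = Phi[j] @ C
            sse += float(np.sum((Y[:, j] - pred) ** 2))
        cv[gi] = sse / (m * Y.shape[0])
    spread = cv.max() - cv.min()
    scale = max(cv.max(), np.mean(Y**2), 1.0)
    flat = spread <= 1e-10 * scale
    if flat:
        lam = float(grid[-1])
        logger.info(
            "flat CV profile (spread %.3g); defaulting to largest lambda %g",
            spread, lam,
        )
    else:
        lam = float(grid[int(np.argmin(cv))])
    return LambdaSelection(lam=lam, grid=grid, cv_error=cv, flat=flat)
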