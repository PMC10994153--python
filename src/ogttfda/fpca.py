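"""Functional principal component analysis of smoothed OGTT curves.

The fitted curves live in the span of the spline basis, so the covariance
operator of the cohort reduces to the coefficient covariance matrix seen
through the basis Gram matrix J = integral phi phi'.  Writing an
eigenfunction as xi(t) = phi(t)' b, the eigenproblem of the covariance
operator becomes the symmetric matrix problem

    J^{1/2} Cov(c) J^{1/2} u = lambda u,     b = J^{-1/2} u,

whose eigenvalues are exactly the variances of the FPC scores
z_k = integral xi_k(t) (x(t) - mean(t)) dt.  Eigenfunctions satisfy
integral xi_k^2 dt = 1 and are mutually orthogonal.  Scores are reported
raw (analyte-units x min) and standardized to cohort mean 0, SD 1.

All integrals use the composite trapezoid rule on the basis quadrature
grid (1-minute resolution by default), so coefficient-space score
computation and direct quadrature of xi_k x (curve - mean) agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .smoothing import BasisSystem, SmoothCurve


class DegenerateCohortError(ValueError):
    """Cohort has no usable curve variation (or too few curves)."""


@dataclass
class FPCModel:
    """Fitted FPC decomposition for one analyte.

    Eigenfunctions are stored both as basis coefficients (rows of
    ``eigen_coefs``) and evaluated on the quadrature grid (rows of
    ``eigenfunctions``).  ``variance_explained`` fractions are relative to
    the total variance across *all* (at most n_basis) components.
    """

    analyte: str
    basis: BasisSystem = field(repr=False)
    mean_coefs: np.ndarray = field(repr=False)
    eigen_coefs: np.ndarray = field(repr=False)
    eigenvalues: np.ndarray = field(default=None)
    all_eigenvalues: np.ndarray = field(default=None, repr=False)
    n_components: int = 3
    n_curves: int = 0

    @property
    def grid(self) -> np.ndarray:
        return self.basis.quad_grid()

    @property
    def mean_values(self) -> np.ndarray:
        return self.basis.evaluate(self.grid) @ self.mean_coefs

    @property
    def eigenfunctions(self) -> np.ndarray:
        return (self.basis.evaluate(self.grid) @ self.eigen_coefs.T).T

    @property
    def variance_explained(self) -> np.ndarray:
        total = self.all_eigenvalues.sum()
        return self.eigenvalues / total


def _sign_convention(eigen_coefs: np.ndarray, basis: BasisSystem) -> np.ndarray:
    """Flip each eigenfunction so integral xi dt >= 0 (tie: xi(0) > 0)."""
    grid = basis.quad_grid()
    w = basis.quad_weights()
    vals = basis.evaluate(grid) @ eigen_coefs.T  # (G, k)
    integrals = w @ vals
    out = eigen_coefs.copy()
    for k, s in enumerate(integrals):
        if abs(s) < 1e-9:
            s = vals[0, k]
        if s < 0:
            out[k] = -out[k]
    return out


def fit_fpca(
    curves: list[SmoothCurve] | np.ndarray,
    basis: BasisSystem | None = None,
    n_components: int = 3,
    analyte: str | None = None,
) -> FPCModel:
    """Fit the FPC decomposition of a cohort of smoothed curves.

    Parameters
    ----------
    curves : list of ``SmoothCurve`` (all same analyte and basis), or an
        (n, n_basis) coefficient array with ``basis`` given explicitly.
    n_components : number of leading components retained (3 by default,
        which in practice captures essentially all smoothed-curve variance).
    """
    if isinstance(curves, np.ndarray):
        if basis is None:
            raise ValueError("basis required with a coefficient array")
        C = np.asarray(curves, dtype=float)
        analyte = analyte or "unknown"
    else:
        if not curves:
            raise DegenerateCohortError("no curves supplied")
        analytes = {c.analyte for c in curves}
        if len(analytes) > 1:
            raise ValueError(f"mixed analytes in one FPCA: {sorted(analytes)}")
        analyte = analyte or curves[0].analyte
        basis = basis or curves[0].basis
        C = np.vstack([c.coefficients for c in curves])
    n = C.shape[0]
    if n < n_components + 1:
        raise DegenerateCohortError(
            f"need at least {n_components + 1} curves, got {n}"
        )
    mean_coefs = C.mean(axis=0)
    Cc = C - mean_coefs
    cov = Cc.T @ Cc / (n - 1)

    J = basis.gram
    jw, jv = np.linalg.eigh(J)
    jw = np.clip(jw, 0, None)
    J_half = jv @ (np.sqrt(jw)[:, None] * jv.T)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(jw > 1e-12 * jw.max(), 1.0 / np.sqrt(jw), 0.0)
    J_inv_half = jv @ (inv_sqrt[:, None] * jv.T)

    S = J_half @ cov @ J_half
    S = (S + S.T) / 2
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    if evals.sum() <= 0 or evals[0] < 1e-12 * max(1.0, np.mean(C**2)):
        raise DegenerateCohortError(
            "zero covariance: all curves identical (degenerate cohort)"
        )
    eigen_coefs = (J_inv_half @ evecs[:, :n_components]).T
    eigen_coefs = _sign_convention(eigen_coefs, basis)
    return FPCModel(
        analyte=analyte,
        basis=basis,
        mean_coefs=mean_coefs,
        eigen_coefs=eigen_coefs,
        eigenvalues=evals[:n_components],
        all_eigenvalues=evals,
        n_components=n_components,
        n_curves=n,
    )


def score(model: FPCModel, curve: SmoothCurve | np.ndarray) -> np.ndarray:
    """Raw FPC scores z_k = integral xi_k(t) (x(t) - mean(t)) dt.

    Accepts a fitted curve or its coefficient vector/matrix.  Computed in
    coefficient space through the Gram matrix, which is identical to
    trapezoid quadrature on the model grid.
    """
    if isinstance(curve, SmoothCurve):
        if curve.analyte != model.analyte:
            raise ValueError(
                f"curve analyte {curve.analyte!r} does not match model "
                f"{model.analyte!r}"
            )
        coefs = curve.coefficients
    else:
        coefs = np.asarray(curve, dtype=float)
    single = coefs.ndim == 1
    coefs = np.atleast_2d(coefs)
    if coefs.shape[1] != model.mean_coefs.size:
        raise ValueError("coefficient length does not match model basis")
    z = (coefs - model.mean_coefs) @ model.basis.gram @ model.eigen_coefs.T
    return z[0] if single else z


def score_cohort(model: FPCModel, curves: list[SmoothCurve]) -> np.ndarray:
    """Raw scores for a cohort, shape (n, n_components)."""
    C = np.vstack([c.coefficients for c in curves])
    return score(model, C)


def standardize_scores(raw: np.ndarray) -> np.ndarray:
    """Standardize each score column to mean 0, SD 1 (n-1 denominator)."""
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if raw.shape[0] < 2:
        raise ValueError("standardization needs at least 2 participants")
    sd = raw.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.nonzero(sd == 0)[0].tolist()
        raise ValueError(f"zero-variance score component(s): {bad}")
    return (raw - raw.mean(axis=0)) / sd


def quartile_curves(
    model: FPCModel, raw_scores: np.ndarray, curves: list[SmoothCurve]
) -> dict[int, np.ndarray]:
    """Mean fitted curve per score quartile, for each retained component.

    Participants are binned by the empirical quartiles of each component's
    scores (values tied with a cut point fall in the lower bin).  Returns
    {component index: (4, G) array} of quartile-mean curves on the model
    grid.
    """
    raw_scores = np.atleast_2d(raw_scores)
    n = raw_scores.shape[0]
    if n < 4:
        raise ValueError("quartile curves need at least 4 participants")
    vals = np.vstack([c(model.grid) for c in curves])
    out: dict[int, np.ndarray] = {}
    for k in range(raw_scores.shape[1]):
        s = raw_scores[:, k]
        edges = np.quantile(s, [0.25, 0.5, 0.75])
        bins = (s[:, None] > edges[None, :]).sum(axis=1)
        out[k] = np.vstack([vals[bins == b].mean(axis=0) for b in range(4)])
    return out


def decile_curves(
    model: FPCModel, raw_scores: np.ndarray, curves: list[SmoothCurve]
) -> dict[int, dict[str, np.ndarray]]:
    """Mean fitted curve for the lowest and highest score decile."""
    raw_scores = np.atleast_2d(raw_scores)
    if raw_scores.shape[0] < 10:
        raise ValueError("decile curves need at least 10 participants")
    vals = np.vstack([c(model.grid) for c in curves])
    out: dict[int, dict[str, np.ndarray]] = {}
    for k in range(raw_scores.shape[1]):
        s = raw_scores[:, k]
        lo, hi = np.quantile(s, [0.10, 0.90])
        out[k] = {
            "low": vals[s <= lo].mean(axis=0),
            "high": vals[s > hi].mean(axis=0),
        }
    return out
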