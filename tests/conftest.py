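import numpy as np
import pytest

from ogttfda import build_basis, generate_cohort
from ogttfda.config import PipelineConfig
from ogttfda.pipeline import smooth_cohort


@pytest.fixture(scope="session")
def basis():
    return build_basis()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest default-parameter cohort shared across read-only tests."""
    return generate_cohort(n=120, seed=42)


@pytest.fixture(scope="session")
def smoothed(small_cohort):
    cfg = PipelineConfig(seed=42)
    basis, lam, coef_df, curves = smooth_cohort(small_cohort.records, cfg)
    return {"basis": basis, "lambdas": lam, "coefficients": coef_df,
            "curves": curves, "records": small_cohort.records}


def grid_fpca_oracle(C, basis, n_components=3):
    """Brute-force FPCA: eigen-decomposition of the sample covariance of
    curves evaluated on the quadrature grid with trapezoid weights.

    Independent of the coefficient-space route used by the package.
    """
    grid = basis.quad_grid()
    w = basis.quad_weights()
    X = C @ basis.evaluate(grid).T
    Xc = X - X.mean(axis=0)
    M = Xc * np.sqrt(w)
    K = M.T @ M / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(K)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    xi = (evecs[:, order] / np.sqrt(w)[:, None]).T  # rows: eigenfunctions
    scores = Xc @ (w[:, None] * xi.T)
    return evals, xi, scores, X.mean(axis=0)
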