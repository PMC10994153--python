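import numpy as np
import pytest

from conftest import grid_fpca_oracle
from ogttfda.fpca import (DegenerateCohortError, fit_fpca, quartile_curves,
                          decile_curves, score, standardize_scores)
from ogttfda.smoothing import SmoothCurve


def j_orthonormal_directions(basis, k, seed=0):
    """Random coefficient vectors orthonormalized in the L2 (Gram) metric,
    i.e. the corresponding functions satisfy integral u_i u_j dt = delta_ij."""
    rng = np.random.default_rng(seed)
    J = basis.gram
    vecs = []
    for _ in range(k):
        v = rng.normal(size=basis.n_basis)
        for u in vecs:
            v = v - (u @ J @ v) * u
        v = v / np.sqrt(v @ J @ v)
        vecs.append(v)
    return np.array(vecs)


def cosine(f, g, basis):
    J = basis.gram
    return (f @ J @ g) / np.sqrt((f @ J @ f) * (g @ J @ g))


class TestFitFPCA:
    def test_planted_single_component_recovered(self, basis):
        """Cohort mean + a*u(t), a ~ N(0,1): xi_1 = +/-u with near-perfect
        cosine and essentially all variance in the first component."""
        u = j_orthonormal_directions(basis, 1, seed=5)[0]
        mean = np.linalg.lstsq(basis.design, np.full(5, 100.0), rcond=None)[0]
        rng = np.random.default_rng(5)
        a = rng.normal(size=200)
        C = mean + a[:, None] * u
        model = fit_fpca(C, basis=basis, n_components=3, analyte="glucose")
        assert abs(cosine(model.eigen_coefs[0], u, basis)) >= 0.999
        assert model.variance_explained[0] >= 0.999

    def test_vertical_shift_cohort_gives_constant_eigenfunction(self, basis):
        base = np.linalg.lstsq(basis.design,
                               100 + 0.3 * basis.times, rcond=None)[0]
        shifts = np.linspace(-20, 20, 50)
        # by the partition of unity, all-ones coefficients are f(t) = 1
        C = base + shifts[:, None] * np.ones(basis.n_basis)
        model = fit_fpca(C, basis=basis, n_components=1, analyte="glucose")
        xi = model.eigenfunctions[0]
        expected = 1.0 / np.sqrt(120.0)
        assert np.allclose(xi, expected, atol=1e-6)

    def test_three_planted_components_recovered(self, basis):
        """Eigenvalue ratio 10:3:1, n=500: all three directions recovered."""
        U = j_orthonormal_directions(basis, 3, seed=9)
        rng = np.random.default_rng(9)
        sd = np.sqrt(np.array([10.0, 3.0, 1.0]))
        A = rng.normal(size=(500, 3)) * sd
        mean = np.linalg.lstsq(basis.design, np.full(5, 100.0), rcond=None)[0]
        C = mean + A @ U
        model = fit_fpca(C, basis=basis, n_components=3, analyte="glucose")
        for k in range(3):
            assert abs(cosine(model.eigen_coefs[k], U[k], basis)) >= 0.95

    def test_variance_fractions_sum_to_one_and_nonincreasing(self, basis):
        rng = np.random.default_rng(2)
        C = rng.normal(100, 10, size=(60, basis.n_basis))
        model = fit_fpca(C, basis=basis, n_components=7, analyte="glucose")
        total = model.all_eigenvalues / model.all_eigenvalues.sum()
        assert abs(total.sum() - 1.0) < 1e-8
        assert np.all(np.diff(model.variance_explained) <= 1e-12)
        assert np.all(model.variance_explained > 0)

    def test_orthonormality_constraints(self, smoothed):
        model = fit_fpca(smoothed["curves"]["glucose"])
        basis = smoothed["basis"]
        J = basis.gram
        G = model.eigen_coefs @ J @ model.eigen_coefs.T
        assert np.allclose(G, np.eye(model.n_components), atol=1e-6)

    def test_oracle_equivalence_grid_eigendecomposition(self, smoothed):
        """Coefficient-space FPCA equals brute-force eigen-decomposition of
        the grid-discretized covariance with trapezoid weights."""
        basis = smoothed["basis"]
        for analyte in ("glucose", "insulin"):
            curves = smoothed["curves"][analyte]
            C = np.vstack([c.coefficients for c in curves])
            model = fit_fpca(curves)
            evals, xi, _, _ = grid_fpca_oracle(C, basis)
            grid = basis.quad_grid()
            for k in range(3):
                num = np.trapezoid(model.eigenfunctions[k] * xi[k], grid)
                assert abs(num) >= 0.999
                assert abs(model.eigenvalues[k] - evals[k]) <= \
                    1e-4 * max(evals[k], 1e-12)

    def test_degenerate_inputs_rejected(self, basis):
        C = np.tile(np.linspace(1, 7, basis.n_basis), (30, 1))
        with pytest.raises(DegenerateCohortError, match="degenerate"):
            fit_fpca(C, basis=basis, analyte="glucose")
        with pytest.raises(DegenerateCohortError):
            fit_fpca(C[:3] + np.arange(3)[:, None], basis=basis,
                     analyte="glucose")


class TestScore:
    def test_mean_curve_scores_zero(self, smoothed):
        model = fit_fpca(smoothed["curves"]["glucose"])
        z = score(model, model.mean_coefs)
        assert np.max(np.abs(z)) < 1e-8

    def test_planted_eigen_direction_scores_its_coefficient(self, smoothed):
        model = fit_fpca(smoothed["curves"]["glucose"])
        c = model.mean_coefs + 5.0 * model.eigen_coefs[0]
        z = score(model, c)
        assert abs(z[0] - 5.0) < 1e-8
        assert np.max(np.abs(z[1:])) < 1e-8

    def test_training_scores_uncorrelated(self, smoothed):
        from ogttfda.fpca import score_cohort
        model = fit_fpca(smoothed["curves"]["glucose"])
        z = score_cohort(model, smoothed["curves"]["glucose"])
        cov = np.cov(z, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) <= 1e-6 * np.max(np.diag(cov))
        assert np.allclose(np.diag(cov), model.eigenvalues, rtol=1e-6)

    def test_analyte_mismatch_rejected(self, smoothed):
        model = fit_fpca(smoothed["curves"]["glucose"])
        with pytest.raises(ValueError, match="analyte"):
            score(model, smoothed["curves"]["insulin"][0])


class TestStandardize:
    def test_mean_zero_sd_one(self, smoothed):
        from ogttfda.fpca import score_cohort
        model = fit_fpca(smoothed["curves"]["insulin"])
        z = standardize_scores(score_cohort(model,
                                            smoothed["curves"]["insulin"]))
        assert np.max(np.abs(z.mean(axis=0))) < 1e-10
        assert np.max(np.abs(z.std(axis=0, ddof=1) - 1.0)) < 1e-10

    def test_two_point_closed_form(self):
        z = standardize_scores(np.array([[-1.0], [1.0]]))
        assert np.allclose(z.ravel(), [-0.7071, 0.7071], atol=1e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            standardize_scores(np.ones((5, 2)))


class TestQuartileCurves:
    def test_eight_participants_make_four_bins_of_two(self, basis):
        rng = np.random.default_rng(4)
        shifts = rng.permutation(np.linspace(-20, 20, 8))
        C = 100.0 + shifts[:, None] * np.ones(basis.n_basis)
        curves = [SmoothCurve(C[i], "glucose", 1.0, np.zeros(5), basis)
                  for i in range(8)]
        model = fit_fpca(curves, n_components=1)
        from ogttfda.fpca import score_cohort
        z = score_cohort(model, curves)
        out = quartile_curves(model, z, curves)
        s = z[:, 0]
        edges = np.quantile(s, [0.25, 0.5, 0.75])
        bins = (s[:, None] > edges[None, :]).sum(axis=1)
        assert np.bincount(bins, minlength=4).tolist() == [2, 2, 2, 2]
        assert out[0].shape == (4, model.grid.size)

    def test_fpc1_quartile_means_ordered_on_synthetic_cohort(self, smoothed):
        """FPC1 captures curve height, so its quartile-mean curves should
        be pointwise ordered at nearly all grid points."""
        from ogttfda.fpca import score_cohort
        curves = smoothed["curves"]["glucose"]
        model = fit_fpca(curves)
        z = score_cohort(model, curves)
        out = quartile_curves(model, z, curves)
        q = out[0]
        ordered = (q[1] >= q[0]) & (q[2] >= q[1]) & (q[3] >= q[2])
        assert ordered.mean() >= 0.9

    def test_decile_contract(self, smoothed):
        from ogttfda.fpca import score_cohort
        curves = smoothed["curves"]["glucose"]
        model = fit_fpca(curves)
        z = score_cohort(model, curves)
        out = decile_curves(model, z, curves)
        assert set(out) == {0, 1, 2}
        assert set(out[0]) == {"low", "high"}
        # highest-decile FPC1 curves sit above lowest-decile curves
        assert np.mean(out[0]["high"] - out[0]["low"]) > 0

    def test_fpc1_tracks_mean_curve_level(self, smoothed):
        from ogttfda.fpca import score_cohort
        curves = smoothed["curves"]["glucose"]
        model = fit_fpca(curves)
        z = standardize_scores(score_cohort(model, curves))
        levels = np.array([c(model.grid).mean() for c in curves])
        r = np.corrcoef(z[:, 0], levels)[0, 1]
        assert abs(r) > 0.9
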