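import numpy as np
import pytest

from eemcal.lar import LARModel, lar_fit, lar_predict, penalty_max, select_penalty
from eemcal.preprocessing import extract_contours
from eemcal.synthetic_data import default_design, generate_dataset


def _soft(x, t):
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


class TestLarFit:
    def test_penalty_above_max_gives_null_model(self, rng):
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        lam = penalty_max(X, y)
        m = lar_fit(X, y, lam * 1.001)
        assert m.coefficients == {}
        assert m.intercept == pytest.approx(y.mean())

    def test_zero_penalty_matches_normal_equations(self, rng):
        X = rng.normal(size=(50, 8))
        y = X @ rng.normal(size=8) + 0.1 * rng.normal(size=50)
        m = lar_fit(X, y, 0.0)
        Xc = X - X.mean(axis=0)
        b_ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - y.mean()))
        assert np.abs(m.coefficient_vector() - b_ols).max() <= 1e-6

    def test_orthonormal_design_matches_soft_thresholding(self, rng):
        n = 40
        A = rng.normal(size=(n, 10))
        Q, _ = np.linalg.qr(A - A.mean(axis=0))
        X = Q * np.sqrt(n)  # centered, X'X = n*I
        y = rng.normal(size=n)
        lam = 0.05
        m = lar_fit(X, y, lam, standardize=False)
        expected = _soft(X.T @ (y - y.mean()) / n, lam)
        np.testing.assert_allclose(m.coefficient_vector(), expected, atol=1e-10)

    def test_matches_reference_solver(self, rng):
        """Independent cross-check against scikit-learn's lasso on the same objective."""
        sklearn = pytest.importorskip("sklearn.linear_model")
        X = rng.normal(size=(30, 12))
        y = 2 * X[:, 0] - X[:, 3] + 0.2 * rng.normal(size=30)
        for alpha in (0.01, 0.1):
            ref = sklearn.Lasso(alpha=alpha, tol=1e-12, max_iter=200000).fit(X, y)
            m = lar_fit(X, y, alpha, standardize=False)
            np.testing.assert_allclose(m.coefficient_vector(), ref.coef_, atol=1e-7)
            assert m.intercept == pytest.approx(ref.intercept_, abs=1e-7)

    def test_subgradient_optimality_conditions(self, rng):
        X = rng.normal(size=(20, 15))
        y = rng.normal(size=20)
        lam = 0.08
        m = lar_fit(X, y, lam, standardize=False)
        beta = m.coefficient_vector()
        Xc = X - X.mean(axis=0)
        r = (y - y.mean()) - Xc @ beta
        g = Xc.T @ r / len(y)
        for j in range(X.shape[1]):
            if beta[j] != 0:
                assert g[j] == pytest.approx(lam * np.sign(beta[j]), abs=1e-6)
            else:
                assert abs(g[j]) <= lam + 1e-6

    def test_support_shrinks_along_the_penalty_path(self, rng):
        X = rng.normal(size=(25, 10))
        y = X @ np.array([3, -2, 1.5, 0, 0, 0, 0, 0, 0, 0]) + 0.1 * rng.normal(size=25)
        lams = np.logspace(np.log10(penalty_max(X, y)), -3, 15)
        sizes = [lar_fit(X, y, lam).n_active for lam in lams]
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_constant_y_gives_intercept_only(self, rng):
        X = rng.normal(size=(10, 4))
        m = lar_fit(X, np.full(10, 3.3), 0.01)
        assert m.coefficients == {}
        assert m.intercept == pytest.approx(3.3)

    def test_negative_penalty_rejected(self, rng):
        with pytest.raises(ValueError):
            lar_fit(rng.normal(size=(5, 2)), rng.normal(size=5), -1.0)


class TestLarPredict:
    def test_affine_sparse_formula(self):
        m = LARModel(
            intercept=1.0,
            coefficients={200.0: 2.0},
            penalty=0.1,
            wavelengths=np.array([200.0, 210.0]),
        )
        assert lar_predict(m, [3.0, 99.0])[0] == pytest.approx(7.0)

    def test_empty_model_predicts_intercept(self):
        m = LARModel(0.7, {}, 1.0, np.arange(5, dtype=float))
        np.testing.assert_allclose(lar_predict(m, np.ones((4, 5))), 0.7)

    def test_prediction_is_affine(self, rng):
        m = LARModel(0.3, {1.0: 2.0, 3.0: -0.5}, 0.0, np.arange(5, dtype=float))
        v1, v2 = rng.normal(size=5), rng.normal(size=5)
        a = 0.37
        mix = lar_predict(m, a * v1 + (1 - a) * v2)[0]
        assert mix == pytest.approx(a * lar_predict(m, v1)[0] + (1 - a) * lar_predict(m, v2)[0])

    def test_length_mismatch_rejected(self):
        m = LARModel(0.0, {}, 0.0, np.arange(5, dtype=float))
        with pytest.raises(ValueError):
            lar_predict(m, np.ones(4))

    def test_json_round_trip(self):
        m = LARModel(0.5, {210.0: 1.25}, 0.02, np.array([200.0, 210.0]), analyte="aesculin")
        back = LARModel.from_json(m.to_json())
        assert back.intercept == m.intercept
        assert back.coefficients == m.coefficients
        np.testing.assert_array_equal(back.wavelengths, m.wavelengths)


@pytest.fixture(scope="module")
def contours():
    # mild noise keeps the contour matrix full-rank, so the planted
    # support below is identifiable
    ds = generate_dataset(default_design(seed=7, n_samples=16, noise_sd=0.01, with_scatter=False))
    table, _ = extract_contours(ds)
    return table.to_numpy()


class TestSelectPenalty:

    def test_curve_shape_and_nonnegativity(self, contours, rng):
        y = 0.01 * contours[:, 10] + rng.normal(size=16) * 0.001
        lam, curve = select_penalty(contours, y, grid_size=12)
        assert len(curve) == 12
        assert (curve["rmsecv"] >= 0).all()
        assert lam in curve["penalty"].to_numpy()

    def test_recovers_planted_support(self, contours):
        y = 0.003 * contours[:, 10] + 0.001 * contours[:, 14]  # noiseless, 2 variables
        lam, _ = select_penalty(contours, y, grid_size=30)
        m = lar_fit(contours, y, lam, wavelengths=np.arange(200.0, 610.0, 10.0))
        assert {300.0, 340.0} <= set(m.coefficients)

    def test_one_se_rule_resists_pure_noise(self, contours):
        """With pure-noise y (n=16) the 1-SE rule lands at/near the null model
        in the large majority of noise draws (the CV curve is a random object,
        so occasional denser selections are expected)."""
        n_sparse = 0
        for seed in range(6):
            y = np.random.default_rng(100 + seed).normal(size=16)
            lam, _ = select_penalty(contours, y, grid_size=30, rule="1se")
            n_sparse += lar_fit(contours, y, lam).n_active <= 2
        assert n_sparse >= 5

    def test_noiseless_pipeline_recovers_held_out_concentrations(self):
        """Lasso on contours predicts held-out samples with R >= 0.999 (noiseless)."""
        from eemcal.preprocessing import split_calibration
        from eemcal.validation import correlation_r

        ds = generate_dataset(default_design(seed=13, noise_sd=0.0, with_scatter=False))
        cal, pred = split_calibration(ds)
        table, _ = extract_contours(ds, calibration_ids=cal.sample_ids)
        Xc = table.loc[cal.sample_ids].to_numpy()
        y = cal.concentrations["aesculin"].to_numpy()
        lam, _ = select_penalty(Xc, y, grid_size=20)
        m = lar_fit(Xc, y, lam)
        p = lar_predict(m, table.loc[pred.sample_ids].to_numpy())
        assert correlation_r(pred.concentrations["aesculin"], p) >= 0.999
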