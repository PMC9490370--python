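import numpy as np
import pytest

from eemcal.ipls import ipls_predict, ipls_select, make_intervals, pls1_fit, pls1_predict
from eemcal.model_selection import rmsecv
from eemcal.preprocessing import extract_contours, split_calibration
from eemcal.synthetic_data import default_design, generate_dataset
from eemcal.validation import correlation_r


class TestIntervals:
    @pytest.mark.parametrize(
        "n,k,sizes",
        [(41, 8, [5] * 7 + [6]), (40, 8, [5] * 8), (10, 3, [3, 3, 4])],
    )
    def test_near_equal_sizes_with_remainder_at_tail(self, n, k, sizes):
        scheme = make_intervals(n, k)
        assert scheme.widths() == sizes

    @pytest.mark.parametrize("n,k", [(41, 8), (17, 5), (100, 7), (6, 6)])
    def test_intervals_partition_all_variables(self, n, k):
        scheme = make_intervals(n, k)
        seen = sorted(i for s, e in scheme.bounds for i in range(s, e))
        assert seen == list(range(n))

    def test_too_many_intervals_rejected(self):
        with pytest.raises(ValueError):
            make_intervals(5, 6)


class TestPLS1:
    def test_rank_one_data_fits_exactly_with_one_component(self, rng):
        t = rng.normal(size=9)
        p = rng.normal(size=6)
        X = np.outer(t, p)
        y = 2.0 * t + 1.0
        m = pls1_fit(X, y, 1)
        np.testing.assert_allclose(pls1_predict(m, X), y, atol=1e-8)

    def test_full_components_match_least_squares(self, rng):
        X = rng.normal(size=(8, 4))
        y = rng.normal(size=8)
        m = pls1_fit(X, y, 4)
        Xc = X - X.mean(axis=0)
        b = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - y.mean()))
        np.testing.assert_allclose(m.coef, b, atol=1e-8)

    def test_matches_reference_pls(self, rng):
        """Independent cross-check against scikit-learn's NIPALS PLS."""
        PLSRegression = pytest.importorskip("sklearn.cross_decomposition").PLSRegression
        X = rng.normal(size=(15, 9))
        y = X[:, 0] - 0.5 * X[:, 4] + 0.05 * rng.normal(size=15)
        for a in (1, 2, 3):
            ours = pls1_predict(pls1_fit(X, y, a), X)
            ref = PLSRegression(n_components=a, scale=False).fit(X, y).predict(X).ravel()
            np.testing.assert_allclose(ours, ref, atol=1e-8)

    def test_mean_spectrum_predicts_mean_response(self, rng):
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        m = pls1_fit(X, y, 3)
        assert pls1_predict(m, X.mean(axis=0))[0] == pytest.approx(y.mean())

    def test_zero_variance_y_yields_intercept_only(self, rng):
        X = rng.normal(size=(6, 4))
        m = pls1_fit(X, np.full(6, 2.0), 2)
        assert m.n_components == 0
        np.testing.assert_allclose(pls1_predict(m, X), 2.0)


class TestIPLSSelect:
    def test_selects_the_informative_interval(self, rng):
        """y depends only on variables inside one interval; others are noise."""
        X = rng.normal(size=(16, 20))
        scheme = make_intervals(20, 4)
        s, e = scheme.bounds[2]
        y = X[:, s] + 0.5 * X[:, s + 1]  # noiseless function of interval 2
        model = ipls_select(X, y, n_intervals=4, max_components=3)
        assert model.selected_interval == 2

    def test_duplicate_intervals_tie_to_lower_index(self, rng):
        block = rng.normal(size=(12, 5))
        X = np.hstack([block, block])  # intervals 0 and 1 identical
        y = block @ rng.normal(size=5)
        model = ipls_select(X, y, n_intervals=2, max_components=2)
        assert model.selected_interval == 0

    def test_table_minimum_is_the_selected_pair(self, rng):
        X = rng.normal(size=(10, 12))
        y = rng.normal(size=10)
        model = ipls_select(X, y, n_intervals=3, max_components=3)
        table = model.rmsecv_table
        assert (table.stack() >= 0).all()
        assert table.loc[model.selected_interval, model.n_components] == pytest.approx(
            table.min().min()
        )

    def test_matches_brute_force_reference_table(self, rng):
        """Exhaustive recomputation of the RMSECV table with an independent PLS."""
        PLSRegression = pytest.importorskip("sklearn.cross_decomposition").PLSRegression
        ds = generate_dataset(default_design(seed=21, n_samples=16, noise_sd=0.01, with_scatter=False))
        table, _ = extract_contours(ds)
        X = table.to_numpy()
        y = ds.concentrations["aesculin"].to_numpy()
        model = ipls_select(X, y, n_intervals=8, max_components=3)
        for idx, (s, e) in enumerate(model.scheme.bounds):
            for a in range(1, 4):
                preds = np.empty(16)
                for i in range(16):
                    keep = np.arange(16) != i
                    ref = PLSRegression(n_components=a, scale=False).fit(X[keep, s:e], y[keep])
                    preds[i] = ref.predict(X[i : i + 1, s:e]).ravel()[0]
                assert model.rmsecv_table.loc[idx, a] == pytest.approx(
                    rmsecv(y, preds), rel=1e-8
                )

    def test_noiseless_contours_predict_held_out_samples(self):
        ds = generate_dataset(default_design(seed=23, noise_sd=0.0, with_scatter=False))
        cal, pred = split_calibration(ds)
        table, _ = extract_contours(ds, calibration_ids=cal.sample_ids)
        model = ipls_select(
            table.loc[cal.sample_ids].to_numpy(),
            cal.concentrations["aesculetin"].to_numpy(),
            wavelengths=[float(c) for c in table.columns],
        )
        p = ipls_predict(model, table.loc[pred.sample_ids].to_numpy())
        assert correlation_r(pred.concentrations["aesculetin"], p) >= 0.999
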