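import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eemcal.eem_io import EEMLandscape, WavelengthGrid
from eemcal.preprocessing import (
    build_scatter_mask,
    choose_max_energy_excitation,
    excise_and_interpolate,
    extract_contour,
    extract_contours,
    split_calibration,
)
from eemcal.synthetic_data import clean_signal, default_design, generate_dataset, simulate_eem


class TestScatterMask:
    def test_first_order_band_at_10nm_covers_three_diagonals(self, grid):
        m = build_scatter_mask(grid, w1=10, w2=0, wR=0)
        assert int(m.components["first_order"].sum()) == 121  # 41 + 2 * 40

    def test_zero_width_keeps_exact_ridge_cells(self, grid):
        m = build_scatter_mask(grid, w1=0, w2=0, wR=0)
        assert int(m.components["first_order"].sum()) == 41  # the main diagonal
        # second order: lambda_em = 2*lambda_ex forces excitation 200-300 nm
        assert int(m.components["second_order"].sum()) == 11

    def test_negative_width_rejected(self, grid):
        with pytest.raises(ValueError):
            build_scatter_mask(grid, w1=-1)

    @given(
        w=st.tuples(
            st.floats(0, 30), st.floats(0, 30), st.floats(0, 30), st.floats(0, 10)
        )
    )
    def test_mask_is_monotone_in_widths(self, w):
        grid = WavelengthGrid.default(step=20.0)
        w1, w2, wR, bump = w
        small = build_scatter_mask(grid, w1, w2, wR)
        large = build_scatter_mask(grid, w1 + bump, w2 + bump, wR + bump)
        assert not np.any(small.mask & ~large.mask)


class TestExciseAndInterpolate:
    def test_exact_on_affine_surfaces_for_interior_masks(self, grid, rng):
        """Interpolation reproduces any affine surface exactly on interior masks
        (end cells extrapolate as constants, so boundary runs are excluded)."""
        plane = 0.4 * grid.emission[:, None] - 0.7 * grid.excitation[None, :] + 11.0
        ls = EEMLandscape(grid, plane, "p")
        mask = build_scatter_mask(grid, 0, 0, 0)
        mask.mask[:] = False
        interior = rng.uniform(size=(31, 31)) < 0.3
        mask.mask[5:36, 5:36] = interior
        out = excise_and_interpolate(ls, mask, zero_below_diagonal=False)
        np.testing.assert_allclose(out.intensity, plane, atol=1e-9)

    def test_empty_mask_is_identity(self, grid, rng):
        ls = EEMLandscape(grid, rng.normal(size=grid.shape), "x")
        mask = build_scatter_mask(grid, 0, 0, 0)
        mask.mask[:] = False
        out = excise_and_interpolate(ls, mask, zero_below_diagonal=False)
        np.testing.assert_array_equal(out.intensity, ls.intensity)

    def test_idempotent(self, grid):
        d = default_design(seed=2, noise_sd=0.01, with_scatter=True)
        ls = simulate_eem({"aesculin": 0.4, "aesculetin": 1.5}, d)
        mask = build_scatter_mask(grid)
        once = excise_and_interpolate(ls, mask)
        twice = excise_and_interpolate(once, mask)
        np.testing.assert_array_equal(once.intensity, twice.intensity)

    def test_restores_clean_landscape_under_scatter(self, grid):
        """Mask + infill recovers the scatter-free trilinear signal within 5% of peak."""
        d = default_design(seed=5, noise_sd=0.0, with_scatter=True)
        mask = build_scatter_mask(grid)
        for conc in [
            {"aesculin": 0.5, "aesculetin": 2.0},
            {"aesculin": 1.02, "aesculetin": 0.009},
        ]:
            clean = clean_signal(conc, d)
            ls = simulate_eem(conc, d)
            out = excise_and_interpolate(ls, mask, zero_below_diagonal=False)
            assert np.abs(out.intensity - clean).max() <= 0.05 * clean.max()

    def test_fully_isolated_cells_zero_fill_with_warning(self):
        grid = WavelengthGrid(
            excitation=np.array([200.0, 210.0]), emission=np.array([200.0, 210.0])
        )
        ls = EEMLandscape(grid, np.ones((2, 2)), "tiny")
        mask = build_scatter_mask(grid, w1=20, w2=0, wR=0)  # masks everything
        with pytest.warns(UserWarning):
            out = excise_and_interpolate(ls, mask)
        assert np.all(out.intensity == 0.0)


class TestContours:
    def test_fixed_policy_returns_exact_column(self, grid, rng):
        ls = EEMLandscape(grid, rng.normal(size=grid.shape), "x")
        c = extract_contour(ls, 340.0)
        k = list(grid.excitation).index(340.0)
        np.testing.assert_array_equal(c.values, ls.intensity[:, k])
        assert c.excitation_used == 340.0
        assert len(c.values) == 41

    def test_off_grid_excitation_rejected(self, grid):
        ls = EEMLandscape(grid, np.zeros(grid.shape), "x")
        with pytest.raises(ValueError):
            extract_contour(ls, 305.0)

    def test_max_energy_contour_tracks_emission_profile(self, grid):
        """For one noiseless analyte the max-energy contour is its emission profile."""
        d = default_design(seed=1, noise_sd=0.0, with_scatter=False)
        ls = simulate_eem({"aesculin": 0.8, "aesculetin": 0.0}, d)
        lam = choose_max_energy_excitation([ls])
        c = extract_contour(ls, lam)
        em = d.analytes[0].emission_profile.values
        cos = c.values @ em / (np.linalg.norm(c.values) * np.linalg.norm(em))
        assert cos >= 0.999

    def test_dataset_policy_shared_across_samples(self, noiseless_dataset):
        table, lam = extract_contours(noiseless_dataset, policy="max_energy")
        assert table.shape == (21, 41)
        assert lam in noiseless_dataset.grid.excitation


class TestSplit:
    @pytest.mark.parametrize(
        "n,frac,expected",
        [(21, 0.75, (16, 5)), (20, 0.75, (15, 5)), (2, 0.99, (1, 1))],
    )
    def test_split_sizes(self, n, frac, expected, grid):
        d = default_design(seed=4, n_samples=n, noise_sd=0.0, with_scatter=False)
        ds = generate_dataset(d)
        cal, pred = split_calibration(ds, frac)
        assert (cal.n_samples, pred.n_samples) == expected

    def test_split_partitions_samples(self, noiseless_dataset):
        cal, pred = split_calibration(noiseless_dataset)
        assert set(cal.sample_ids) | set(pred.sample_ids) == set(noiseless_dataset.sample_ids)
        assert not set(cal.sample_ids) & set(pred.sample_ids)
        assert (cal.roles == "calibration").all() and (pred.roles == "prediction").all()

    def test_split_is_deterministic_and_stratified(self, noiseless_dataset):
        cal1, pred1 = split_calibration(noiseless_dataset)
        cal2, pred2 = split_calibration(noiseless_dataset)
        assert cal1.sample_ids == cal2.sample_ids
        # held-out samples span the concentration range, not one extreme
        c = noiseless_dataset.concentrations["aesculin"]
        ranks = c.rank().loc[pred1.sample_ids]
        assert ranks.min() <= 6 and ranks.max() >= 15
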