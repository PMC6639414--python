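"""Grid construction, error-aware smoothing weights, kernel cross-validation."""

import numpy as np
import pytest
from scipy.stats import norm
from sklearn.base import clone

from noisescape import landscape as land
from noisescape import synthetic as syn


class TestMakeGrid:
    def test_standard_grid_has_4941_points(self):
        grid = land.make_grid(4.0)
        assert grid.shape == (61, 81)
        assert grid.n_points == 4941
        assert grid.mu[grid.wt_index] == pytest.approx(4.0)
        assert grid.eta[0] == -3.0 and grid.eta[-1] == -1.0

    def test_minimal_grid_counts(self):
        grid = land.make_grid(4.0, mean_halfwidth=0.05,
                              noise_lo=-3.0, noise_hi=-2.975)
        assert grid.shape == (3, 2)
        assert grid.n_points == 6

    def test_non_divisible_extent_signalled(self):
        with pytest.raises(ValueError, match="divide"):
            land.make_grid(4.0, mean_step=0.07)


KERNEL = land.SmoothingKernel()   # 0.602 / 0.361


class TestPromoterWeight:
    def test_zero_errors_collapse_to_kernel_density(self):
        for method in ("closed_form", "auxiliary"):
            w = land.promoter_weight(4.1, -2.1, 0.0, 0.0, 2.0, (4.0, -2.0),
                                     KERNEL, method=method)
            expected = (norm.pdf(0.1, scale=0.602)
                        * norm.pdf(-0.1, scale=0.361) / 4.0)
            assert w == pytest.approx(expected, rel=1e-10)

    def test_coincident_point_matched_covariances(self):
        # product of two identical Gaussians integrates to the density of
        # zero offset under the summed covariance
        w = land.promoter_weight(4.0, -2.0, 0.602, 0.361, 1.0, (4.0, -2.0),
                                 KERNEL, method="closed_form")
        assert w == pytest.approx(1.0 / (2 * np.pi * 2 * 0.602 * 0.361),
                                  rel=1e-12)

    def test_auxiliary_matches_closed_form_on_operating_range(self):
        # offsets within Mahalanobis distance 2 of the grid point (kernel
        # metric), errors at the study scale
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            while True:
                dm = rng.uniform(-2, 2) * KERNEL.scale_mu
                de = rng.uniform(-2, 2) * KERNEL.scale_eta
                if dm ** 2 / KERNEL.var_mu + de ** 2 / KERNEL.var_eta < 4:
                    break
            emu = 0.2 * rng.uniform(0.7, 1.5)
            eeta = 0.15 * rng.uniform(0.7, 1.5)
            sf = 0.01 * rng.uniform(0.5, 2.0)
            args = (4.0 + dm, -2.0 + de, emu, eeta, sf, (4.0, -2.0), KERNEL)
            wc = land.promoter_weight(*args, method="closed_form")
            wa = land.promoter_weight(*args, method="auxiliary")
            worst = max(worst, abs(wa - wc) / wc)
        assert worst < 0.02

    def test_nonpositive_sigma_f_signalled(self):
        with pytest.raises(ValueError):
            land.promoter_weight(4.0, -2.0, 0.1, 0.1, 0.0, (4.0, -2.0),
                                 KERNEL)

    def test_unknown_method_signalled(self):
        with pytest.raises(ValueError):
            land.promoter_weight(4.0, -2.0, 0.1, 0.1, 1.0, (4.0, -2.0),
                                 KERNEL, method="fancy")


@pytest.fixture(scope="module")
def strain_sample():
    rng = np.random.default_rng(7)
    n = 40
    return dict(
        mu=rng.uniform(2.5, 5.5, n), eta=rng.uniform(-3, -1, n),
        err_mu=rng.uniform(0.15, 0.3, n), err_eta=rng.uniform(0.1, 0.25, n),
        sigma_f=rng.uniform(0.005, 0.02, n),
        fitness=rng.normal(0.0, 0.02, n))


class TestSmoothLandscape:
    def test_constant_fitness_gives_constant_landscape(self, strain_sample,
                                                       win_grid):
        for method in ("closed_form", "auxiliary"):
            ls = land.smooth_landscape(
                strain_sample["mu"], strain_sample["eta"],
                strain_sample["err_mu"], strain_sample["err_eta"],
                strain_sample["sigma_f"], np.full(40, 0.37), win_grid,
                method=method)
            assert np.max(np.abs(ls.f - 0.37)) < 1e-12

    def test_single_strain_gives_flat_landscape_at_its_fitness(self,
                                                               win_grid):
        ls = land.smooth_landscape([4.0], [-2.0], [0.2], [0.15], [0.01],
                                   [0.123], win_grid, method="closed_form")
        assert np.allclose(ls.f, 0.123)

    def test_landscape_is_convex_combination_of_strain_fitness(
            self, strain_sample, win_grid):
        ls = land.smooth_landscape(
            strain_sample["mu"], strain_sample["eta"],
            strain_sample["err_mu"], strain_sample["err_eta"],
            strain_sample["sigma_f"], strain_sample["fitness"], win_grid,
            method="closed_form")
        assert np.nanmin(ls.f) >= strain_sample["fitness"].min() - 1e-12
        assert np.nanmax(ls.f) <= strain_sample["fitness"].max() + 1e-12

    def test_equivariant_to_constant_fitness_shift(self, strain_sample,
                                                   win_grid):
        base = land.smooth_landscape(
            strain_sample["mu"], strain_sample["eta"],
            strain_sample["err_mu"], strain_sample["err_eta"],
            strain_sample["sigma_f"], strain_sample["fitness"], win_grid,
            method="closed_form")
        shifted = land.smooth_landscape(
            strain_sample["mu"], strain_sample["eta"],
            strain_sample["err_mu"], strain_sample["err_eta"],
            strain_sample["sigma_f"], strain_sample["fitness"] + 0.5,
            win_grid, method="closed_form")
        assert np.allclose(shifted.f, base.f + 0.5, atol=1e-10)

    def test_shrinking_kernel_interpolates_exact_positions(self, win_grid):
        # zero position errors, tiny kernel: landscape at a strain's grid
        # point converges to that strain's fitness
        mu = np.array([3.0, 4.0, 5.0])
        eta = np.array([-2.5, -2.0, -1.5])
        f = np.array([0.1, -0.2, 0.3])
        small = land.SmoothingKernel(0.02, 0.02)
        ls = land.smooth_landscape(mu, eta, np.zeros(3), np.zeros(3),
                                   np.ones(3) * 0.01, f, win_grid, small,
                                   method="closed_form")
        for m, e, v in zip(mu, eta, f):
            i = np.argmin(np.abs(win_grid.mu - m))
            j = np.argmin(np.abs(win_grid.eta - e))
            assert ls.f[i, j] == pytest.approx(v, abs=1e-6)

    def test_beats_nearest_neighbour_on_smooth_truth(self, win_grid,
                                                     ext_grid, basis):
        t1, _ = basis.evaluate(ext_grid)
        panel = syn.generate_promoter_panel(
            syn.SyntheticPanelConfig(n_promoters=80, seed=21,
                                     error_sds=(0.05, 0.05, 0.002)))
        strains = syn.sample_strains_from_surface(t1, ext_grid, panel, "G",
                                                  sigma_f=0.002, seed=3)
        truth_win, _ = basis.evaluate(win_grid)
        ls = land.smooth_landscape(
            panel["log2_mean"], panel["log2_cv"], panel["err_mean"],
            panel["err_cv"], strains["sigma_f"], strains["fitness"],
            win_grid, land.SmoothingKernel(0.2, 0.2), method="closed_form")
        # nearest-neighbour baseline
        nn = np.empty(win_grid.shape)
        mm, ee = np.meshgrid(win_grid.mu, win_grid.eta, indexing="ij")
        pts = np.column_stack([panel["log2_mean"], panel["log2_cv"]])
        for idx in np.ndindex(win_grid.shape):
            d = ((pts[:, 0] - mm[idx]) ** 2 / KERNEL.var_mu
                 + (pts[:, 1] - ee[idx]) ** 2 / KERNEL.var_eta)
            nn[idx] = strains["fitness"].to_numpy()[np.argmin(d)]
        rmse_smooth = np.sqrt(np.mean((ls.f - truth_win) ** 2))
        rmse_nn = np.sqrt(np.mean((nn - truth_win) ** 2))
        assert rmse_smooth < rmse_nn


class TestUncertainty:
    def test_single_strain_uncertainty_equals_its_error(self, win_grid):
        se = land.landscape_uncertainty([4.0], [-2.0], [0.2], [0.15], [0.03],
                                        win_grid, method="closed_form")
        assert np.allclose(se, 0.03)

    def test_duplicated_strains_shrink_uncertainty_sqrt_k(self, win_grid):
        k = 4
        se = land.landscape_uncertainty([4.0] * k, [-2.0] * k, [0.2] * k,
                                        [0.15] * k, [0.03] * k, win_grid,
                                        method="closed_form")
        assert np.allclose(se, 0.03 / np.sqrt(k))

    def test_mixed_errors_match_direct_formula(self, win_grid):
        rng = np.random.default_rng(11)
        n = 8
        mu = rng.uniform(3, 5, n)
        eta = rng.uniform(-2.5, -1.5, n)
        emu = rng.uniform(0.1, 0.3, n)
        eeta = rng.uniform(0.1, 0.2, n)
        sf = rng.uniform(0.01, 0.05, n)
        w = land.promoter_weights(mu, eta, emu, eeta, sf, win_grid, KERNEL,
                                  method="closed_form")
        expected = (np.sqrt(np.einsum("s,sxy->xy", sf ** 2, w ** 2))
                    / w.sum(axis=0))
        got = land.landscape_uncertainty(mu, eta, emu, eeta, sf, win_grid,
                                         KERNEL, method="closed_form")
        assert np.allclose(got, expected, atol=1e-12)


@pytest.fixture(scope="module")
def noiseless(ext_grid, win_grid, basis):
    t1, _ = basis.evaluate(ext_grid)
    panel = syn.generate_promoter_panel(
        syn.SyntheticPanelConfig(n_promoters=60, seed=30,
                                 error_sds=(0.0, 0.0, 0.0)))
    strains = syn.sample_strains_from_surface(t1, ext_grid, panel, "G",
                                              sigma_f=1e-6, seed=31)
    return dict(mu=panel["true_log2_mean"].to_numpy(),
                eta=panel["true_log2_cv"].to_numpy(),
                zeros=np.zeros(60),
                sigma_f=np.full(60, 1e-3),
                fitness=strains["true_fitness"].to_numpy())


class TestOptimizeKernel:
    def test_oversmoothing_penalised_on_noiseless_data(self, noiseless,
                                                       win_grid):
        kern, profile = land.optimize_kernel(
            noiseless["mu"], noiseless["eta"], noiseless["zeros"],
            noiseless["zeros"], noiseless["sigma_f"], noiseless["fitness"],
            win_grid, folds=10, seed=1)
        prof = profile.set_index(["scale_mu", "scale_eta"])["cv_rmse"]
        big = prof.loc[(1.6, 1.0)]
        assert big > prof.min()
        assert kern.scale_mu < 1.0

    def test_deterministic_given_seed(self, noiseless, win_grid):
        args = (noiseless["mu"], noiseless["eta"], noiseless["zeros"],
                noiseless["zeros"], noiseless["sigma_f"],
                noiseless["fitness"], win_grid)
        k1, _ = land.optimize_kernel(*args, folds=5, seed=7)
        k2, _ = land.optimize_kernel(*args, folds=5, seed=7)
        assert k1 == k2

    def test_constant_field_ties_break_to_smallest_kernel(self, win_grid):
        rng = np.random.default_rng(5)
        mu = rng.uniform(3, 5, 20)
        eta = rng.uniform(-2.5, -1.5, 20)
        kern, _ = land.optimize_kernel(
            mu, eta, np.zeros(20), np.zeros(20), np.full(20, 0.01),
            np.zeros(20), win_grid, folds=5, seed=2,
            scale_mu_grid=[0.1, 0.5], scale_eta_grid=[0.1, 0.5], refine=0)
        assert kern.scale_mu == pytest.approx(0.1)
        assert kern.scale_eta == pytest.approx(0.1)

    def test_too_few_strains_signalled(self, win_grid):
        with pytest.raises(ValueError):
            land.optimize_kernel([4.0], [-2.0], [0.1], [0.1], [0.01], [0.0],
                                 win_grid, folds=10)


class TestLandscapeSmootherEstimator:
    def make_xy(self):
        rng = np.random.default_rng(9)
        n = 30
        X = np.column_stack([rng.uniform(2.5, 5.5, n),
                             rng.uniform(-3, -1, n),
                             rng.uniform(0.15, 0.25, n),
                             rng.uniform(0.1, 0.2, n),
                             rng.uniform(0.005, 0.02, n)])
        y = rng.normal(0, 0.02, n)
        return X, y

    def test_predict_matches_functional_smoothing(self, win_grid):
        X, y = self.make_xy()
        est = land.LandscapeSmoother(scale_mu=0.3, scale_eta=0.2,
                                     method="closed_form").fit(X, y)
        ls = est.to_landscape(win_grid)
        queries = np.column_stack([win_grid.mu[[0, 30, 60]],
                                   win_grid.eta[[0, 40, 80]]])
        pred = est.predict(queries)
        for q, p in zip(queries, pred):
            i = np.argmin(np.abs(win_grid.mu - q[0]))
            j = np.argmin(np.abs(win_grid.eta - q[1]))
            assert p == pytest.approx(ls.f[i, j], rel=1e-10)

    def test_sklearn_protocol(self):
        X, y = self.make_xy()
        est = land.LandscapeSmoother(scale_mu=0.4)
        params = est.get_params()
        assert params["scale_mu"] == 0.4
        cloned = clone(est)
        assert cloned.get_params() == params
        with pytest.raises(ValueError):
            est.fit(X[:, :3], y)

    def test_landscape_round_trips_through_frame(self, win_grid):
        X, y = self.make_xy()
        ls = land.LandscapeSmoother(method="closed_form").fit(
            X, y).to_landscape(win_grid, gene="G1", with_uncertainty=True)
        back = land.FitnessLandscape.from_frame(ls.to_frame(), wt_mu=4.0)
        assert np.allclose(back.f, ls.f, equal_nan=True)
        assert back.gene == "G1"
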