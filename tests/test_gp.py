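import numpy as np
import pytest

from flowamide import GPConfig, default_space, fit_gp, from_unit_cube, loocv, predict
from flowamide.design_space import Conditions

from conftest import fast_gp


def _make_data(fn, n, seed, solvent="MeCN", space=None):
    space = space or default_space()
    rng = np.random.default_rng(seed)
    X = rng.random((n, space.n_continuous))
    return [(from_unit_cube(x, space, solvent), fn(x)) for x in X]


class TestFitGp:
    def test_ard_identifies_informative_dimension(self, space):
        data = _make_data(lambda x: x[0], 20, seed=0)
        fit = fit_gp(data, space, fast_gp(seed=1, n_restarts=5))
        ls = fit.lengthscales
        assert np.all(ls[0] < ls[1:])
        assert np.all(ls[1:] > 10.0)  # uninformative dims pushed out

    def test_interpolation_in_noise_free_limit(self, space):
        data = _make_data(lambda x: np.sin(3 * x[0]) + x[1] ** 2, 15, seed=2)
        fit = fit_gp(data, space, GPConfig(n_restarts=3, seed=0, fixed_noise=1e-10))
        mean, _ = predict(fit, [c for c, _ in data])
        assert np.allclose(mean, [t for _, t in data], atol=1e-5)

    def test_minimum_data_required(self, space):
        with pytest.raises(ValueError, match="at least 3"):
            fit_gp(_make_data(lambda x: x[0], 2, seed=0), space)

    def test_degenerate_targets_flat_fit(self, space):
        data = _make_data(lambda x: 0.7, 8, seed=3)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_gp(data, space, fast_gp())
        assert fit.degenerate
        assert np.all(fit.lengthscales == fit.lengthscales.max())
        mean, _ = predict(fit, [c for c, _ in data])
        assert np.allclose(mean, 0.7)

    def test_identical_solvents_collapse_in_latent_space(self, space):
        # two solvents share a response surface, two differ strongly
        rng = np.random.default_rng(4)

        def target(x, s):
            base = np.sin(3 * x[2]) + 0.5 * x[0]
            return base if s in ("MeCN", "anisole") else base + 2.0 * x[2]

        data = []
        for s in space.levels:
            for _ in range(8):
                x = rng.random(4)
                data.append((from_unit_cube(x, space, s), target(x, s)))
        fit = fit_gp(data, space, fast_gp(seed=0, n_restarts=8))
        z = {lvl: c for lvl, c in zip(fit.levels, fit.latent_coords)}
        d_same = np.linalg.norm(z["MeCN"] - z["anisole"])
        dists = [np.linalg.norm(z[a] - z[b]) for a in fit.levels
                 for b in fit.levels if a != b]
        assert d_same < 0.1 * max(dists)

    def test_identifiability_anchoring(self, space, params):
        from flowamide import observe, stratified_lhc
        conds = stratified_lhc(space, 12, seed=0)
        data = [(c, observe(c, params, seed=i).product_norm)
                for i, c in enumerate(conds)]
        fit = fit_gp(data, space, fast_gp(seed=0))
        assert tuple(fit.latent_coords[0]) == (0.0, 0.0)
        assert fit.latent_coords[1, 1] == 0.0

    def test_latent_geometry_stable_across_fit_seeds(self, space, params):
        from flowamide import observe, stratified_lhc
        conds = stratified_lhc(space, 24, seed=5)
        data = [(c, observe(c, params, seed=100 + i).product_norm)
                for i, c in enumerate(conds)]
        fits = [fit_gp(data, space, fast_gp(seed=s, n_restarts=8))
                for s in (0, 1)]
        dms = []
        for fit in fits:
            z = fit.latent_coords
            dms.append(np.linalg.norm(z[:, None] - z[None, :], axis=-1))
        assert np.allclose(dms[0], dms[1], atol=0.15)

    def test_restarts_only_improve_the_objective(self, space):
        data = _make_data(lambda x: x[0] + 0.3 * x[1], 12, seed=6)
        fit = fit_gp(data, space, fast_gp(seed=0, n_restarts=5))
        assert all(fit.lml >= l0 - 1e-6 for l0 in fit.restart_initial_lml)


class TestPredict:
    def test_prior_reversion_far_from_data(self, space):
        # all data in one corner; predict at the opposite corner
        data = [(from_unit_cube(np.full(4, v), space, "MeCN"), v)
                for v in np.linspace(0.0, 0.08, 8)]
        fit = fit_gp(data, space, fast_gp(seed=0))
        _, var = predict(fit, [from_unit_cube(np.ones(4), space, "MeCN")])
        prior_var = fit.signal_var * fit.y_scale**2
        assert var[0] > 0.5 * prior_var

    def test_mean_is_continuous(self, space, params):
        from flowamide import observe, stratified_lhc
        conds = stratified_lhc(space, 12, seed=1)
        data = [(c, observe(c, params, seed=i).product_norm)
                for i, c in enumerate(conds)]
        fit = fit_gp(data, space, fast_gp(seed=0))
        c0 = Conditions(250.0, 2.0, 5.0, 40.0, "MeCN")
        c1 = Conditions(250.0 + 1e-6 * 150, 2.0, 5.0, 40.0, "MeCN")
        m0, _ = predict(fit, [c0])
        m1, _ = predict(fit, [c1])
        assert abs(m1[0] - m0[0]) < 1e-4

    def test_variance_nonnegative(self, space):
        data = _make_data(lambda x: x[0], 10, seed=7)
        fit = fit_gp(data, space, fast_gp(seed=0))
        _, var = predict(fit, [c for c, _ in data])
        assert np.all(var >= 0.0)

    def test_unknown_solvent_rejected(self, space, params):
        from flowamide import observe, stratified_lhc
        conds = stratified_lhc(space, 8, seed=2)
        data = [(c, observe(c, params, seed=i).product_norm)
                for i, c in enumerate(conds)]
        fit = fit_gp(data, space, fast_gp(seed=0))
        with pytest.raises(ValueError, match="DMSO"):
            predict(fit, [Conditions(250.0, 2.0, 5.0, 40.0, "DMSO")])


class TestLoocv:
    def test_constant_targets_rejected(self, space):
        data = _make_data(lambda x: 1.0, 8, seed=0)
        with pytest.raises(ValueError, match="zero variance"):
            loocv(data, space)

    def test_minimum_points(self, space):
        with pytest.raises(ValueError, match="at least 5"):
            loocv(_make_data(lambda x: x[0], 4, seed=0), space)

    def test_pure_noise_gives_no_predictivity(self, space):
        r2s = []
        for s in range(3):
            rng = np.random.default_rng(s)
            data = _make_data(lambda x: rng.normal(), 20, seed=s)
            r2s.append(loocv(data, space, fast_gp(seed=s)).r2)
        assert np.median(r2s) <= 0.2

    def test_learnable_signal_gives_high_r2(self, space):
        data = _make_data(lambda x: np.sin(2 * x[0]) + x[3], 30, seed=9)
        rep = loocv(data, space, fast_gp(seed=0))
        assert rep.r2 > 0.9
        assert rep.r2 <= 1.0
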