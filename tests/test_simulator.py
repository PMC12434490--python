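import numpy as np
import pytest

from flowamide import (CalibrationError, Conditions, calibrate,
                       calibration_residuals, conversion, observe,
                       selectivity_ratio, stability_protocol, true_response)
from flowamide.simulator import (ETHER_SOLVENTS, SIGMOID_SOLVENTS,
                                 default_anchors, grid_response)


class TestTrueResponse:
    @pytest.mark.parametrize("solvent", ETHER_SOLVENTS)
    def test_ether_time_sweep_has_interior_maximum(self, params, solvent):
        taus = np.linspace(1.0, 10.0, 200)
        prod = np.array([
            true_response(Conditions(300.0, 1.5, t, 45.0, solvent), params).product_norm
            for t in taus])
        d = np.diff(prod)
        signs = np.sign(d[d != 0])
        assert np.sum(np.diff(signs) != 0) == 1
        assert 0 < np.argmax(prod) < len(taus) - 1

    @pytest.mark.parametrize("solvent", SIGMOID_SOLVENTS)
    def test_sigmoid_group_monotone_in_time_and_concentration(self, params, solvent):
        taus = np.linspace(1.0, 10.0, 50)
        prod_t = [true_response(Conditions(250.0, 2.0, t, 40.0, solvent),
                                params).product_norm for t in taus]
        assert np.all(np.diff(prod_t) >= -1e-12)
        concs = np.linspace(200.0, 350.0, 50)
        prod_c = [true_response(Conditions(c, 2.0, 5.0, 40.0, solvent),
                                params).product_norm for c in concs]
        assert np.all(np.diff(prod_c) <= 1e-12)

    @pytest.mark.parametrize("solvent", ["MeCN", "dioxane"])
    def test_impurity_linear_in_equivalents_only(self, params, solvent):
        eqs = np.linspace(1.0, 4.0, 7)
        imp = np.array([
            true_response(Conditions(250.0, e, 5.0, 40.0, solvent), params).impurity_norm
            for e in eqs])
        assert np.allclose(np.diff(imp, 2), 0.0, atol=1e-12)  # exactly linear
        assert imp[0] == pytest.approx(params.impurity_base[solvent])
        # invariant to time, concentration, temperature
        alt = true_response(Conditions(340.0, 2.5, 9.0, 58.0, solvent), params)
        ref = true_response(Conditions(205.0, 2.5, 1.5, 26.0, solvent), params)
        assert alt.impurity_norm == pytest.approx(ref.impurity_norm, abs=1e-15)

    def test_outputs_bounded_mass_balance(self, params, rng):
        lo = np.array([200.0, 1.0, 1.0, 25.0])
        hi = np.array([350.0, 4.0, 10.0, 60.0])
        for _ in range(2000):
            x = lo + rng.random(4) * (hi - lo)
            s = ["MeCN", "2-MeTHF", "anisole", "dioxane"][rng.integers(4)]
            obs = true_response(Conditions(*x, s), params)
            assert 0.0 <= obs.product_norm <= 1.0
            assert 0.0 <= obs.impurity_norm <= 1.0
            assert obs.product_norm + obs.impurity_norm <= 1.0 + 1e-12

    def test_out_of_bounds_condition_rejected(self, params):
        with pytest.raises(ValueError):
            true_response(Conditions(100.0, 2.0, 5.0, 40.0, "MeCN"), params)
        with pytest.raises(ValueError):
            true_response(Conditions(250.0, 2.0, 5.0, 40.0), params)


class TestObserve:
    def test_zero_noise_equals_truth(self, noiseless):
        cond = Conditions(250.0, 2.0, 5.0, 40.0, "MeCN")
        assert observe(cond, noiseless, seed=5) == true_response(cond, noiseless)

    def test_seed_determinism(self, params):
        cond = Conditions(250.0, 2.0, 5.0, 40.0, "dioxane")
        assert observe(cond, params, seed=11) == observe(cond, params, seed=11)

    def test_noise_is_unbiased(self, params):
        cond = Conditions(300.0, 2.0, 5.0, 40.0, "anisole")
        truth = true_response(cond, params).product_norm
        vals = [observe(cond, params, seed=k).product_norm for k in range(1000)]
        assert abs(np.mean(vals) - truth) < 3 * params.noise_sigma / np.sqrt(1000)

    def test_deactivation_scales_product(self, params):
        p = params.replace(deactivation=0.1, noise_sigma=0.0)
        cond = Conditions(250.0, 2.0, 5.0, 40.0, "MeCN")
        early = observe(cond, p, seed=0, t_elapsed_h=0.0).product_norm
        late = observe(cond, p, seed=0, t_elapsed_h=10.0).product_norm
        assert late == pytest.approx(early * np.exp(-1.0))


class TestCalibration:
    def test_direct_yield_anchors(self, params):
        a = default_anchors()
        p1 = true_response(a["A1"]["condition"], params).product_norm
        p2 = true_response(a["A2"]["condition"], params).product_norm
        assert p1 == pytest.approx(0.94, abs=0.005)
        assert p2 == pytest.approx(0.56, abs=0.005)

    def test_dioxane_conversion_argmax_selectivity(self, params):
        _, prod, imp = grid_response(params, "dioxane")
        k = int(np.argmax(prod + imp))
        assert prod[k] + imp[k] == pytest.approx(1.00, abs=0.005)
        assert prod[k] / imp[k] == pytest.approx(5.76, abs=0.05)

    def test_mecn_constrained_selectivity(self, params):
        _, prod, imp = grid_response(params, "MeCN")
        conv = prod + imp
        feasible = conv >= 0.90 - 1e-9
        ratio = np.where(feasible, prod / imp, -np.inf)
        k = int(np.argmax(ratio))
        assert ratio[k] == pytest.approx(16.0, abs=0.1)
        assert conv[k] == pytest.approx(0.90, abs=0.005)

    def test_restart_stability(self, params):
        worst0 = max(abs(v) for v in calibration_residuals(params).values())
        alt = calibrate(seed=99)
        worst1 = max(abs(v) for v in calibration_residuals(alt).values())
        assert abs(worst0 - worst1) < 1e-3

    def test_infeasible_anchor_reported(self):
        with pytest.raises(CalibrationError, match="slope"):
            calibrate(impurity_slope=0.08)


class TestConversionSelectivity:
    def test_definitions(self, params):
        obs = true_response(Conditions(250.0, 2.0, 5.0, 40.0, "MeCN"), params)
        assert conversion(obs) == obs.product_norm + obs.impurity_norm
        assert selectivity_ratio(obs) == obs.product_norm / obs.impurity_norm


class TestStabilityProtocol:
    def test_two_identical_rounds_without_deactivation(self, noiseless):
        rec = stability_protocol(noiseless, seed=0)
        assert len({s for _, s, _ in rec}) == 4
        segments = {}
        for t, s, obs in rec:
            segments.setdefault((s, t >= 12.0), []).append(obs.product_norm)
        for s in {"MeCN", "2-MeTHF", "anisole", "dioxane"}:
            assert segments[(s, False)] == segments[(s, True)]

    def test_eight_segments_over_24_hours(self, noiseless):
        rec = stability_protocol(noiseless, samples_per_hour=1, seed=0)
        seen, prev = [], None
        for _, s, _ in rec:
            if s != prev:
                seen.append(s)
                prev = s
        assert len(seen) == 8  # 4 solvents x 2 rounds

    def test_deactivation_lowers_second_round(self, params):
        p = params.replace(deactivation=0.1, noise_sigma=0.0)
        rec = stability_protocol(p, seed=0)
        for s in {"MeCN", "2-MeTHF", "anisole", "dioxane"}:
            r1 = np.mean([o.product_norm for t, sv, o in rec if sv == s and t < 12])
            r2 = np.mean([o.product_norm for t, sv, o in rec if sv == s and t >= 12])
            assert r2 < r1

    def test_incompatible_duration_rejected(self, params):
        with pytest.raises(ValueError, match="multiple"):
            stability_protocol(params, total_hours=20.0)
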