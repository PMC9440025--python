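import numpy as np
import pytest

from oholidar import (
    LidarGeometry,
    MSCModel,
    correct_kd,
    fit_msc_model,
    fit_msc_single,
    lee_kd,
    retrieve_klidar,
    simulate_molecular_signal,
    update_lidar_ratio,
)
from oholidar.iop_model import PhaseFunction, SeawaterConstants, make_profile
from oholidar.msc import MSCFitError, modeled_klidar

Z = np.linspace(0.0, 25.0, 90)


class TestFitSingle:
    def test_exact_model_recovered_to_four_sig_figs(self):
        k = 0.05 * np.exp(-0.5 * Z) + 0.02 + 0.06
        m1, m2, m3, rmsrd = fit_msc_single(k, a=0.06, z=Z)
        assert m1 == pytest.approx(0.05, rel=1e-4)
        assert m2 == pytest.approx(0.5, rel=1e-4)
        assert m3 == pytest.approx(0.02, rel=1e-4)
        assert rmsrd < 1e-6

    def test_increasing_profile_needs_negative_m1(self):
        # multiple scattering produces depth-increasing attenuation, which the
        # exponential model can only represent with a negative amplitude
        k = -0.04 * np.exp(-0.3 * Z) + 0.05 + 0.1
        m1, m2, m3, _ = fit_msc_single(k, a=0.1, z=Z)
        assert m1 == pytest.approx(-0.04, rel=1e-4)
        assert m2 == pytest.approx(0.3, rel=1e-4)

    def test_constant_profile_degenerate(self):
        k = np.full_like(Z, 0.06)
        m1, m2, m3, rmsrd = fit_msc_single(k, a=0.06, z=Z)
        assert abs(m1) < 1e-6 and abs(m3) < 1e-6 and rmsrd < 1e-6

    def test_robust_to_one_percent_noise(self, rng):
        k_clean = 0.05 * np.exp(-0.5 * Z) + 0.02 + 0.06
        k = k_clean * (1 + 0.01 * rng.standard_normal(Z.size))
        m1, m2, m3, _ = fit_msc_single(k, a=0.06, z=Z)
        assert m1 == pytest.approx(0.05, rel=0.10)
        assert m2 == pytest.approx(0.5, rel=0.10)
        assert m3 == pytest.approx(0.02, rel=0.10)

    def test_too_few_bins(self):
        with pytest.raises(MSCFitError):
            fit_msc_single(np.array([0.1, 0.1]), a=0.05, z=np.array([0.0, 1.0]))


class TestFitModel:
    def test_constant_bb_gives_constant_regressions(self, geom40):
        conds = [(a, 0.004) for a in (0.05, 0.1, 0.2, 0.3, 0.4, 0.5)]
        model = fit_msc_model(conds, geom=geom40)
        for name in ("m1", "m2", "m3"):
            fit = model.m_fits[name]
            vals = model.m(name, np.array([0.001, 0.004, 0.01]))
            np.testing.assert_allclose(vals, vals[0], rtol=1e-6, atol=1e-9)

    def test_deterministic(self, geom40):
        m1 = fit_msc_model(geom=geom40)
        m2 = fit_msc_model(geom=geom40)
        assert m1.to_json() == m2.to_json()

    def test_held_out_grid_consistency(self, geom40, msc_model40):
        # the attenuation model transferred through the m(b_b) regressions
        # must reproduce fresh simulations at intermediate IOPs
        sim_all, mod_all = [], []
        for a in (0.075, 0.275):
            for bb in (0.0015, 0.0085):
                p = make_profile([(0.0, 25.0, a, bb / 0.02, bb)],
                                 phase_fn=PhaseFunction(backscatter_fraction=0.02))
                bm = simulate_molecular_signal(p, geom40)
                k, valid = retrieve_klidar(bm, geom40)
                sim_all.append(k[valid])
                mod_all.append(modeled_klidar(msc_model40, a, bb, p.depth_grid)[valid])
        sim, mod = np.concatenate(sim_all), np.concatenate(mod_all)
        assert 100 * np.sqrt(np.mean((mod / sim - 1) ** 2)) <= 5.0

    def test_needs_six_conditions(self, geom40):
        with pytest.raises(ValueError):
            fit_msc_model([(0.1, 0.004)] * 3, geom=geom40)

    def test_per_condition_quality_gate(self, geom40):
        with pytest.raises(MSCFitError):
            fit_msc_model(geom=geom40, max_condition_rmsrd=1e-9)

    def test_json_round_trip(self, msc_model40, tmp_path):
        path = tmp_path / "msc.json"
        msc_model40.to_json(path)
        loaded = MSCModel.from_json(path)
        assert loaded.geometry == msc_model40.geometry
        bb = np.array([0.002, 0.006])
        for name in ("m1", "m2", "m3"):
            np.testing.assert_allclose(loaded.m(name, bb), msc_model40.m(name, bb))

    def test_geometry_tags_differ(self, geom40, geom60):
        m40 = fit_msc_model(geom=geom40)
        m60 = fit_msc_model(geom=geom60)
        bb = 0.004
        assert not np.allclose(
            [m40.m("m1", bb), m40.m("m3", bb)], [m60.m("m1", bb), m60.m("m3", bb)]
        )

    def test_refuses_foreign_geometry(self, msc_model40, geom60):
        k = np.full(Z.size, 0.1)
        with pytest.raises(ValueError, match="geometry"):
            correct_kd(k, 0.004, msc_model40, Z, geom=geom60)
        with pytest.warns(UserWarning):
            correct_kd(k, 0.004, msc_model40, Z, geom=geom60, force_geometry=True)


class TestCorrectKd:
    @staticmethod
    def _null_model(geom):
        fits = {name: {"family": "linear", "coeffs": [0.0, 0.0], "r2": 1.0}
                for name in ("m1", "m2", "m3")}
        return MSCModel(fits, geom)

    def test_reduces_to_lee_relation_with_null_model(self, geom40):
        model = self._null_model(geom40)
        kd, flagged = correct_kd(np.array([0.1]), 0.01, model, np.array([5.0]))
        assert kd[0] == pytest.approx(0.13442, abs=1e-5)
        assert not flagged.any()

    def test_pure_offset_removal(self, geom40):
        fits = {
            "m1": {"family": "linear", "coeffs": [0.0, 0.0], "r2": 1.0},
            "m2": {"family": "linear", "coeffs": [1.0, 0.0], "r2": 1.0},
            "m3": {"family": "linear", "coeffs": [0.02, 0.0], "r2": 1.0},
        }
        model = MSCModel(fits, geom40)
        kd, _ = correct_kd(np.array([0.1]), 0.0, model, np.array([5.0]))
        assert kd[0] == pytest.approx(0.08)

    def test_negative_residual_masked(self, geom40):
        fits = {
            "m1": {"family": "linear", "coeffs": [0.0, 0.0], "r2": 1.0},
            "m2": {"family": "linear", "coeffs": [1.0, 0.0], "r2": 1.0},
            "m3": {"family": "linear", "coeffs": [0.5, 0.0], "r2": 1.0},
        }
        model = MSCModel(fits, geom40)
        kd, flagged = correct_kd(np.array([0.1]), 0.004, model, np.array([5.0]))
        assert flagged[0] and np.isnan(kd[0])

    def test_end_to_end_recovery(self, geom40, msc_model40):
        a, bb = 0.08, 0.004
        p = make_profile([(0.0, 25.0, a, bb / 0.02, bb)],
                         phase_fn=PhaseFunction(backscatter_fraction=0.02))
        bm = simulate_molecular_signal(p, geom40)
        k, valid = retrieve_klidar(bm, geom40)
        kd, flagged = correct_kd(k, bb, msc_model40, p.depth_grid)
        sel = valid & ~flagged & (p.depth_grid >= 3)
        truth = lee_kd(a, bb)
        assert np.nanmax(np.abs(kd[sel] / truth - 1)) <= 0.05
        # uncorrected attenuation at depth overshoots the corrected product
        deep = sel & (p.depth_grid > 15)
        assert np.all(k[deep] > kd[deep])


class TestUpdateLidarRatio:
    def test_unchanged_when_kd_unchanged(self):
        const = SeawaterConstants()
        beta = np.array([1e-3, 2e-3])
        kd = np.array([0.15, 0.15])
        r1 = update_lidar_ratio(kd, beta, const)
        r2 = update_lidar_ratio(kd.copy(), beta, const)
        np.testing.assert_array_equal(r1, r2)

    def test_smaller_kd_smaller_ratio(self):
        const = SeawaterConstants()
        beta = np.array([1e-3])
        assert update_lidar_ratio(np.array([0.12]), beta, const)[0] < update_lidar_ratio(
            np.array([0.15]), beta, const)[0]

    def test_simulated_scene_ratio_recovery(self, geom40, msc_model40):
        const = SeawaterConstants()
        a, bb = 0.1, 0.005
        p = make_profile([(0.0, 25.0, a, bb / 0.02, bb)],
                         phase_fn=PhaseFunction(backscatter_fraction=0.02))
        bm = simulate_molecular_signal(p, geom40, const)
        k, valid = retrieve_klidar(bm, geom40)
        kd, flagged = correct_kd(k, bb, msc_model40, p.depth_grid)
        beta_truth = (bb - const.b_bw) / (2 * np.pi * const.chi)
        r = update_lidar_ratio(kd, beta_truth, const)
        r_truth = (lee_kd(a, bb) - const.K_dw) / beta_truth
        sel = valid & ~flagged & (p.depth_grid >= 3)
        assert np.nanmax(np.abs(r[sel] / r_truth - 1)) <= 0.05
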