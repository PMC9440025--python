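import numpy as np
import pytest

from oholidar import (
    ChannelCalibration,
    LidarGeometry,
    SeawaterConstants,
    add_noise,
    generate_scene,
    lee_kd,
    mc_oracle,
    retrieve_beta_p_pi,
    retrieve_bbp,
    retrieve_klidar,
    simulate_combined_signal,
    simulate_molecular_signal,
)
from oholidar.forward_sim import SignalProfile, beta_p_pi_true
from oholidar.iop_model import PhaseFunction, make_profile

PF = PhaseFunction(backscatter_fraction=0.02)


class TestGeometry:
    def test_snell(self):
        g = LidarGeometry(theta_i_deg=60.0, n=1.34)
        assert np.sin(g.theta_r) == pytest.approx(np.sin(g.theta_i) / 1.34)

    def test_validation(self):
        with pytest.raises(ValueError):
            LidarGeometry(H=-1.0)
        with pytest.raises(ValueError):
            LidarGeometry(fov=0.0)


class TestMolecularSignal:
    def test_vacuum_water_pure_geometric_decay(self):
        p = make_profile([(0.0, 30.0, 0.0, 0.0, 0.0)], phase_fn=PF)
        g = LidarGeometry()
        bm = simulate_molecular_signal(p, g)
        rc = bm.values * g.range_factor(p.depth_grid) ** 2
        np.testing.assert_allclose(rc, rc[0], rtol=1e-12)

    def test_vanishing_fov_recovers_beam_attenuation(self):
        # single-scattering limit: the slope of the range-corrected signal is
        # the beam attenuation c = a + b
        p = make_profile([(0.0, 30.0, 0.06, 0.2, 0.004)], phase_fn=PF)
        g = LidarGeometry(fov=1e-6)
        bm = simulate_molecular_signal(p, g)
        k, valid = retrieve_klidar(bm, g)
        assert np.nanmedian(k[valid]) == pytest.approx(0.26, rel=0.01)

    def test_klidar_bounded_and_increasing(self, prof_hom, geom40):
        bm = simulate_molecular_signal(prof_hom, geom40)
        k, valid = retrieve_klidar(bm, geom40)
        kk = k[valid]
        a_bb = 0.08 + 0.004
        c = 0.08 + 0.2
        assert np.all(kk >= a_bb - 1e-6)
        assert np.all(kk <= c + 1e-6)
        # multiple scattering: small near the surface, growing with depth
        assert np.all(np.diff(kk) >= -1e-7)
        # the surface value sits near a + b_b (the 11-bin regression window
        # averages over the first ~3 m, so it is slightly above the limit)
        assert a_bb - 1e-6 <= kk[0] <= a_bb * 1.10

    def test_more_scattering_never_brightens_deep_signal_small_fov(self):
        g = LidarGeometry(fov=1e-3)
        deep = []
        for b in (0.1, 0.2, 0.4):
            p = make_profile([(0.0, 30.0, 0.06, b, 0.002)], phase_fn=PF)
            deep.append(simulate_molecular_signal(p, g).values[-1])
        assert deep[0] > deep[1] > deep[2]

    def test_rejects_bad_window(self, prof_hom, geom40):
        bm = simulate_molecular_signal(prof_hom, geom40)
        with pytest.raises(ValueError):
            retrieve_klidar(bm, geom40, window=4)


class TestCombinedSignal:
    def test_no_particles_ratio_is_one(self, geom40):
        const = SeawaterConstants()
        p = make_profile([(0.0, 25.0, 0.08, const.b_bw / 0.02, const.b_bw)], phase_fn=PF)
        cal = ChannelCalibration(T_B=0.85)
        bm = simulate_molecular_signal(p, geom40, const)
        bc = simulate_combined_signal(p, geom40, const, cal)
        ratio = cal.T_B * bc.values / (cal.gain_ratio * bm.values)
        np.testing.assert_allclose(ratio, 1.0, rtol=1e-12)

    def test_bbp_round_trip(self, geom40):
        # a homogeneous b_bp-equivalent input must come back from the
        # two-channel ratio inversion to within 1%
        const = SeawaterConstants()
        bbp_in = 7.54e-4
        bb = bbp_in + const.b_bw
        p = make_profile([(0.0, 25.0, 0.08, bb / 0.02, bb)], phase_fn=PF)
        cal = ChannelCalibration(T_B=0.8, gain_ratio=1.7)
        bm = simulate_molecular_signal(p, geom40, const)
        bc = simulate_combined_signal(p, geom40, const, cal)
        beta, valid, _ = retrieve_beta_p_pi(bc, bm, cal, const)
        bbp_out = retrieve_bbp(beta, const.chi)
        np.testing.assert_allclose(bbp_out[valid], bbp_in, rtol=0.01)

    def test_layer_peaks_in_channel_ratio(self, geom40):
        p = make_profile(
            [(0.0, 25.0, 0.08, 0.2, 0.004)],
            gaussian_layers=[(10.0, 1.0, 0.0, 0.15, 0.003)],
            phase_fn=PF,
        )
        bm = simulate_molecular_signal(p, geom40)
        bc = simulate_combined_signal(p, geom40)
        ratio = bc.values / bm.values
        assert p.depth_grid[np.argmax(ratio)] == pytest.approx(10.0, abs=p.dz)


class TestMCOracle:
    def test_absorption_only_limit(self, geom40):
        p = make_profile([(0.0, 20.0, 0.1, 0.0, 0.0)], phase_fn=PF)
        const = SeawaterConstants()
        mc = mc_oracle(p, geom40, n_photons=20000, seed=3, const=const)
        z = p.depth_grid
        analytic = (
            const.beta_B_pi
            * geom40.range_factor(z) ** -2
            * np.exp(-2 * 0.1 * z / np.cos(geom40.theta_r))
        )
        np.testing.assert_allclose(mc.values, analytic, rtol=1e-10)

    def test_standard_error_scaling(self, prof_hom, geom40):
        mc1 = mc_oracle(prof_hom, geom40, n_photons=20000, seed=5)
        mc2 = mc_oracle(prof_hom, geom40, n_photons=80000, seed=6)
        sel = (prof_hom.depth_grid > 5) & (prof_hom.depth_grid < 20)
        ratio = np.median(mc1.stderr[sel] / mc2.stderr[sel])
        assert ratio == pytest.approx(2.0, rel=0.25)  # 4x photons halves the SE

    def test_matches_qssa_within_5pct(self, prof_hom, geom40):
        bm = simulate_molecular_signal(prof_hom, geom40)
        mc = mc_oracle(prof_hom, geom40, n_photons=100000, seed=7)
        c = 0.28
        sel = prof_hom.depth_grid * c <= 3.0  # first three optical depths
        rel = bm.values[sel] / mc.values[sel] - 1.0
        assert 100 * np.sqrt(np.mean(rel**2)) <= 5.0

    def test_rejects_tiny_photon_budget(self, prof_hom, geom40):
        with pytest.raises(ValueError):
            mc_oracle(prof_hom, geom40, n_photons=100)


class TestNoise:
    def test_identity_when_disabled(self, prof_hom, geom40):
        bm = simulate_molecular_signal(prof_hom, geom40)
        out = add_noise(bm, background=0.0, shot_noise=False)
        np.testing.assert_array_equal(out.values, bm.values)

    def test_deterministic_under_seed(self, prof_hom, geom40):
        bm = simulate_molecular_signal(prof_hom, geom40)
        n1 = add_noise(bm, background=1e-9, seed=42)
        n2 = add_noise(bm, background=1e-9, seed=42)
        np.testing.assert_array_equal(n1.values, n2.values)

    def test_unbiased(self):
        z = np.arange(0, 5, 0.5)
        sig = SignalProfile(z, np.full_like(z, 2.5e-7))
        draws = np.stack(
            [add_noise(sig, background=5e-8, seed=s, counts_per_unit=1e9).values
             for s in range(2000)]
        )
        expected = 2.5e-7 + 5e-8
        se = draws.std(axis=0).mean() / np.sqrt(draws.shape[0])
        assert abs(draws.mean() - expected) < 3 * se

    def test_negative_background_rejected(self, prof_hom, geom40):
        bm = simulate_molecular_signal(prof_hom, geom40)
        with pytest.raises(ValueError):
            add_noise(bm, background=-1.0)


class TestScenes:
    def test_homogeneous_truth_constant_and_consistent(self):
        scene = generate_scene({"template": "homogeneous", "n_columns": 3,
                                "a": 0.1, "b_b": 0.005}, seed=2)
        kd = scene.truth["K_d"]
        assert np.ptp(kd) == 0
        assert kd[0, 0] == pytest.approx(lee_kd(0.1, 0.005))
        # truth b_bp excludes the pure-seawater backscatter
        assert scene.truth["b_bp"][0, 0] == pytest.approx(0.005 - scene.const.b_bw)

    def test_same_seed_identical(self):
        cfg = {"template": "homogeneous", "n_columns": 2,
               "noise": {"enabled": True, "background": 1e-9}}
        s1 = generate_scene(cfg, seed=9)
        s2 = generate_scene(cfg, seed=9)
        for (c1, m1), (c2, m2) in zip(s1.signals, s2.signals):
            np.testing.assert_array_equal(c1.values, c2.values)
            np.testing.assert_array_equal(m1.values, m2.values)

    def test_diel_layer_follows_schedule(self):
        sched = [[14.0, 12.0, 10.0, 8.0, 6.0]]
        scene = generate_scene(
            {"template": "diel", "n_columns": 5, "diel_schedule": sched}, seed=4)
        for icol, expected in enumerate(sched[0]):
            bb = scene.profiles[icol].b_b
            z = scene.profiles[icol].depth_grid
            assert z[np.argmax(bb)] == pytest.approx(expected, abs=scene.profiles[0].dz)

    def test_truth_matches_lee_relation(self):
        scene = generate_scene({"template": "gaussian_layer", "n_columns": 1,
                                "layers": [(8.0, 1.0, 0.004)]}, seed=5)
        p = scene.profiles[0]
        np.testing.assert_allclose(scene.truth["K_d"][0], lee_kd(p.a, p.b_b))

    def test_strictly_positive_before_noise(self, prof_hom, geom40):
        bm = simulate_molecular_signal(prof_hom, geom40)
        assert np.all(bm.values > 0)
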