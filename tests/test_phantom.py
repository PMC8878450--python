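import numpy as np
import pytest
from scipy.linalg import svdvals

import lpsmri as lp
from lpsmri.phantom import _PARKER, warp_frame


class TestPopulationAIF:
    def test_zero_before_arrival(self):
        assert lp.population_aif(np.array([-1.0]))[0] == 0.0
        assert np.all(lp.population_aif(np.array([-3.0, -0.5])) == 0)

    def test_matches_direct_formula_evaluation(self):
        # independent re-evaluation of the published bi-Gaussian +
        # sigmoid-washout form at a few time points
        t = np.array([1.0, 2.0, 5.0])
        p = _PARKER
        expected = np.zeros(3)
        for i, ti in enumerate(t):
            val = 0.0
            for a, tc, sg in zip(p["A"], p["T"], p["sigma"]):
                val += a * np.exp(-((ti - tc) ** 2) / (2 * sg**2)) / (
                    sg * np.sqrt(2 * np.pi)
                )
            val += p["alpha"] * np.exp(-p["beta"] * ti) / (
                1 + np.exp(-p["s"] * (ti - p["tau"]))
            )
            expected[i] = val
        assert np.allclose(lp.population_aif(t), expected, rtol=1e-12)

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError):
            lp.population_aif(np.array([]))

    def test_nonnegative_and_finite(self):
        cp = lp.population_aif(np.linspace(-1, 10, 500))
        assert np.all(np.isfinite(cp)) and np.all(cp >= 0)


class TestExtendedTofts:
    def test_zero_parameters_give_zero(self):
        t = np.linspace(0, 5, 100)
        cp = lp.population_aif(t)
        assert np.all(lp.extended_tofts(0.0, 1.0, 0.0, cp, t) == 0)

    def test_pure_plasma_fraction(self):
        t = np.linspace(0, 5, 100)
        cp = lp.population_aif(t)
        assert np.allclose(lp.extended_tofts(0.0, 1.0, 0.5, cp, t), 0.5 * cp)

    def test_constant_cp_closed_form(self):
        # Ct(t) = (Ktrans/kep)(1 - exp(-kep t)) c0 + vp c0 for Cp = c0
        dt = 3.0 / 60.0  # 3 s frames in minutes
        t = np.arange(0, 2.5, dt)
        c0, ktrans, kep, vp = 1.0, 0.25, 0.9, 0.05
        cp = np.full_like(t, c0)
        ct = lp.extended_tofts(ktrans, kep, vp, cp, t)
        exact = (ktrans / kep) * (1 - np.exp(-kep * t)) * c0 + vp * c0
        err = np.abs(ct[1:] - exact[1:]) / np.abs(exact[1:])
        assert err.max() < 0.01

    def test_negative_parameters_raise(self):
        t = np.linspace(0, 1, 10)
        with pytest.raises(ValueError):
            lp.extended_tofts(-0.1, 1.0, 0.0, np.ones_like(t), t)


class TestSignalModel:
    def test_zero_concentration_gives_baseline(self):
        s = lp.concentration_to_signal(np.zeros(10), t1_ms=900)
        assert np.allclose(s, s[0])

    def test_zero_relaxivity_ignores_concentration(self):
        ct = np.linspace(0, 5, 10)
        s = lp.concentration_to_signal(ct, t1_ms=900, r1=0.0)
        assert np.allclose(s, s[0])

    def test_monotone_in_concentration(self):
        ct = np.linspace(0, 10, 200)
        s = lp.concentration_to_signal(ct, t1_ms=1600, flip_angle_deg=10)
        assert np.all(np.diff(s) >= 0)

    def test_invalid_t1_raises(self):
        with pytest.raises(ValueError):
            lp.concentration_to_signal(np.zeros(3), t1_ms=0.0)


class TestDCEPhantom:
    def test_default_has_fifty_frames(self, dce_phantom):
        image, _ = dce_phantom
        assert image.n_frames == 50

    def test_no_kinetics_means_static_rank_one(self):
        tissues = {
            k: (v[0], 0.0, 0.0, 0.0, v[4])
            for k, v in lp.phantom._DEFAULT_TISSUES.items()
        }
        cfg = lp.DCEPhantomConfig(tissues=tissues)
        image, _ = lp.generate_dce_phantom(cfg, seed=0)
        assert np.allclose(image.data, image.data[:, :, :1])
        assert lp.numerical_rank(image.casorati) == 1

    def test_enhancement_confined_to_support(self, dce_phantom):
        image, gt = dce_phantom
        diff = np.abs(image.data - image.data[:, :, :1]).max(axis=2)
        # outside the (smoothing-dilated) enhancing support the frames
        # agree to numerical noise of the separable Gaussian filter
        assert diff[~gt.sparse_support].max() < 1e-6 * diff.max()

    def test_deterministic(self):
        a, _ = lp.generate_dce_phantom(seed=3)
        b, _ = lp.generate_dce_phantom(seed=3)
        assert np.array_equal(a.data, b.data)

    def test_bad_tissue_parameters_rejected(self):
        tissues = dict(lp.phantom._DEFAULT_TISSUES)
        tissues["liver"] = (800.0, -0.1, 0.5, 0.03, 1.0)
        with pytest.raises(ValueError):
            lp.DCEPhantomConfig(tissues=tissues)


class TestBowelPhantom:
    def test_default_segment_lengths(self, bowel_phantom):
        image, gt = bowel_phantom
        assert image.n_frames == 80
        assert gt.bh_frames == 20

    def test_fully_static_when_no_motion(self):
        cfg = lp.BowelPhantomConfig(
            respiratory_amplitude_px=0.0,
            motility_rate_per_frame=0.0,
            noise_sigma=0.0,
        )
        image, _ = lp.generate_bowel_phantom(cfg, seed=0)
        assert np.allclose(image.data, image.data[:, :, :1])

    def test_respiration_is_single_temporal_mode(self):
        # noiseless, motility-free free-breathing series: mean + one
        # periodic mode carry >= 99% of the spectral energy
        cfg = lp.BowelPhantomConfig(
            n_bh=0, n_fb=50, motility_rate_per_frame=0.0, noise_sigma=0.0
        )
        image, _ = lp.generate_bowel_phantom(cfg, seed=1)
        s = svdvals(image.casorati)
        assert (s[:2] ** 2).sum() / (s**2).sum() >= 0.99

    def test_bh_segment_has_no_respiration(self, bowel_phantom):
        _, gt = bowel_phantom
        cfg = lp.BowelPhantomConfig(motility_rate_per_frame=0.0)
        _, gt0 = lp.generate_bowel_phantom(cfg, seed=7)
        assert np.abs(gt0.deformation_fields[:, :, :, : cfg.n_bh]).max() == 0

    def test_fields_finite_and_smooth(self, bowel_phantom):
        _, gt = bowel_phantom
        f = gt.deformation_fields
        assert np.all(np.isfinite(f))
        # bounded second spatial differences (smoothness)
        d2 = np.diff(f, n=2, axis=1)
        assert np.abs(d2).max() < 1.0

    def test_support_tracks_motility_events(self):
        with_events, without = (
            lp.generate_bowel_phantom(lp.BowelPhantomConfig(noise_sigma=0.0), seed=7),
            lp.generate_bowel_phantom(
                lp.BowelPhantomConfig(noise_sigma=0.0, motility_rate_per_frame=0.0),
                seed=7,
            ),
        )
        assert with_events[1].sparse_support.any()
        assert not without[1].sparse_support.any()
        # motility is local: support is a small fraction of the grid
        assert with_events[1].sparse_support.mean() < 0.5

    def test_deterministic(self):
        cfg = lp.BowelPhantomConfig()
        a, _ = lp.generate_bowel_phantom(cfg, seed=5)
        b, _ = lp.generate_bowel_phantom(cfg, seed=5)
        assert np.array_equal(a.data, b.data)


class TestWarp:
    def test_integer_shift_matches_roll(self):
        rng = np.random.default_rng(0)
        frame = rng.standard_normal((32, 32))
        dx = np.full((32, 32), 2.0)
        dy = np.zeros((32, 32))
        out = warp_frame(frame, dx, dy)
        assert np.allclose(out[:, 2:-2], np.roll(frame, 2, axis=1)[:, 2:-2])
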