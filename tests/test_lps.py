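import numpy as np
import pytest
import scipy.linalg

import lpsmri as lp

from conftest import random_complex


class TestShrink:
    def test_printed_formula_values(self):
        assert lp.shrink(np.array([3.0]), 1.0)[0] == pytest.approx(2.0)
        assert lp.shrink(np.array([1.0]), 2.0)[0] == 0.0
        assert lp.shrink(np.array([0.0]), 1.0)[0] == 0.0  # no 0/0 blow-up

    @pytest.mark.parametrize("theta", [0.3, 1.2, -2.5])
    def test_phase_preserved(self, theta):
        z = 3.0 * np.exp(1j * theta)
        out = lp.shrink(np.array([z]), 1.0)[0]
        assert out == pytest.approx(2.0 * np.exp(1j * theta))

    def test_negative_threshold_raises(self):
        with pytest.raises(ValueError):
            lp.shrink(np.ones(3), -0.1)


class TestSVT:
    def test_diagonal_case(self):
        x = np.diag([3.0, 1.0])
        out = lp.svt(x, 2.0)
        assert np.allclose(out, np.diag([1.0, 0.0]), atol=1e-12)

    def test_zero_threshold_is_identity(self, rng):
        x = random_complex(rng, (6, 4))
        assert np.allclose(lp.svt(x, 0.0), x, atol=1e-10)

    def test_matches_bruteforce_oracle(self, rng):
        x = random_complex(rng, (6, 4))
        u, s, vh = np.linalg.svd(x, full_matrices=False)
        expected = u @ np.diag(np.maximum(s - 0.5, 0.0)) @ vh
        assert np.allclose(lp.svt(x, 0.5), expected, atol=1e-10)

    def test_nuclear_norm_never_grows(self, rng):
        x = random_complex(rng, (8, 5))
        before = scipy.linalg.svdvals(x).sum()
        after = scipy.linalg.svdvals(lp.svt(x, 0.3)).sum()
        assert after <= before + 1e-12

    def test_nonfinite_raises(self):
        x = np.ones((3, 3))
        x[1, 1] = np.nan
        with pytest.raises(ValueError):
            lp.svt(x, 0.1)


class TestNumericalRank:
    def test_zero_matrix(self):
        assert lp.numerical_rank(np.zeros((4, 4))) == 0

    def test_identity(self):
        assert lp.numerical_rank(np.eye(5)) == 5

    def test_tiny_singular_value_ignored(self):
        assert lp.numerical_rank(np.diag([1.0, 1e-12])) == 1


class TestLPSDecompose:
    def test_zero_input_returns_zero(self, shearlet64):
        cfg = lp.LPSConfig(transform=lp.shearlet_transform(64, 64, system=shearlet64))
        res = lp.lps_decompose(np.zeros((64, 64, 8), complex), cfg)
        assert np.all(res.L.data == 0) and np.all(res.S.data == 0)
        assert res.rank_l == 0 and res.rank_s == 0

    def test_temporally_constant_image_is_pure_low_rank(self, rng):
        frame = np.abs(random_complex(rng, (32, 32))) + 1.0
        x = np.repeat(frame[:, :, None], 10, axis=2).astype(complex)
        # the SVT threshold removes lambda_l * sigma_1 from the dominant
        # mode, so L tracks the input only up to that fraction; use
        # weights well below the 1e-3 accuracy being asserted
        cfg = lp.LPSConfig(lambda_l=2e-4, lambda_s=2e-4)
        res = lp.lps_decompose(x, cfg)
        assert np.linalg.norm(res.L.data - x) / np.linalg.norm(x) < 1e-3
        assert np.linalg.norm(res.S.data) < 1e-3 * np.linalg.norm(x)
        assert res.rank_l == 1

    def test_m_equals_l_plus_s(self, rng):
        x = random_complex(rng, (32, 32, 6))
        res = lp.lps_decompose(x, lp.LPSConfig(max_iter=5))
        assert np.allclose(res.M.data, res.L.data + res.S.data, atol=1e-12)

    def test_rank_r_plus_sparse_recovery(self, rng):
        # smooth rank-2 background + sparse localized events, noiseless
        nx = ny = 32
        nt = 24
        u = np.arange(nx)[:, None] / nx
        v = np.arange(ny)[None, :] / ny
        base1 = np.exp(-((u - 0.5) ** 2 + (v - 0.5) ** 2) / 0.08)
        base2 = u * (1 - v)
        t = np.arange(nt)
        x = (
            base1[:, :, None] * np.ones(nt)[None, None, :]
            + 0.3 * base2[:, :, None] * np.sin(2 * np.pi * t / 8)[None, None, :]
        ).astype(complex)
        support = np.zeros((nx, ny), bool)
        events = [(8, 8, 3), (20, 14, 10), (15, 25, 17)]
        for r, c, t0 in events:
            x[r - 1 : r + 2, c - 1 : c + 2, t0 : t0 + 3] += 0.5
            support[r - 1 : r + 2, c - 1 : c + 2] = True
        cfg = lp.LPSConfig(lambda_l=0.0025, lambda_s=0.00125)
        res = lp.lps_decompose(x, cfg)
        assert res.rank_l == 2
        s_energy = (np.abs(res.S.data) ** 2).sum(axis=2)
        assert (s_energy[support] > 1e-6 * s_energy.max()).mean() >= 0.9

    def test_noiseless_consistency_identity(self, rng):
        # reconstruction mode: the consistency-corrected iterate matches
        # the data exactly on sampled entries
        x = random_complex(rng, (32, 32, 6))
        m = lp.generate_vd_mask(32, 6, accel=2, seed=0)
        kt = lp.simulate_acquisition(x, m, noise_sigma=0.0)
        res = lp.lps_decompose(kt, lp.LPSConfig(max_iter=10))
        ls = res.L.data + res.S.data
        m_corr = ls - lp.fu_adjoint(lp.fu_forward(ls, m) - kt.samples, m)
        sampled = np.broadcast_to(m.lines[None, :, :], kt.samples.shape)
        assert np.allclose(
            lp.fu_forward(m_corr, m)[sampled], kt.samples[sampled], atol=1e-10
        )

    def test_deterministic_rerun(self, rng):
        x = random_complex(rng, (32, 32, 6))
        a = lp.lps_decompose(x, lp.LPSConfig(max_iter=5))
        b = lp.lps_decompose(x, lp.LPSConfig(max_iter=5))
        assert np.array_equal(a.L.data, b.L.data)
        assert np.array_equal(a.S.data, b.S.data)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            lp.LPSConfig(lambda_l=0.0)
        with pytest.raises(ValueError):
            lp.LPSConfig(tol=-1.0)
        with pytest.raises(ValueError):
            lp.LPSConfig(scaling="weird")
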