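import numpy as np
import pytest

import lpsmri as lp
from lpsmri.phantom import warp_frame
from lpsmri.registration import DeformationField


def _smooth_blob(n=64, seed=0):
    rng = np.random.default_rng(seed)
    u = np.arange(n)[:, None] / n
    v = np.arange(n)[None, :] / n
    img = (
        np.exp(-((u - 0.45) ** 2 + (v - 0.55) ** 2) / 0.03)
        + 0.7 * np.exp(-((u - 0.65) ** 2 + (v - 0.3) ** 2) / 0.02)
        + 0.4 * np.exp(-((u - 0.3) ** 2 + (v - 0.4) ** 2) / 0.05)
    )
    from scipy.ndimage import gaussian_filter

    img += 0.05 * gaussian_filter(rng.standard_normal((n, n)), 2.0)
    return img


class TestRegisterPair:
    def test_identical_frames_give_null_field(self):
        img = _smooth_blob()
        f = lp.register_pair(img, img)
        assert np.abs(f.dx).max() < 1e-6
        assert np.abs(f.dy).max() < 1e-6
        assert np.abs(f.c).max() < 1e-6

    def test_recovers_known_rigid_shift(self):
        # moving = img shifted by -1.5 px along columns, so the
        # registration must displace it by +1.5 px to match the reference
        img = _smooth_blob()
        shift = 1.5
        dx = np.full_like(img, -shift)
        moving = warp_frame(img, dx, np.zeros_like(img))
        f = lp.register_pair(img, moving)
        assert abs(np.mean(f.dx[8:-8, 8:-8]) - shift) < 0.2
        assert np.abs(np.mean(f.dy[8:-8, 8:-8])) < 0.2

    def test_global_intensity_offset_absorbed_by_c(self):
        img = _smooth_blob() + 0.3
        moving = img - 0.1
        f = lp.register_pair(img, moving)
        rms = np.sqrt(np.mean(f.dx**2 + f.dy**2))
        assert rms < 0.1
        assert abs(np.median(f.c) - 0.1) < 0.05

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            lp.register_pair(np.zeros((8, 8)), np.zeros((8, 9)))


class TestRegisterSeries:
    def test_static_series_gives_null_fields(self):
        img = _smooth_blob()
        series = np.repeat(img[:, :, None], 4, axis=2)
        fields = lp.register_series(series)
        assert len(fields) == 4
        for f in fields:
            assert np.abs(f.dx).max() < 1e-6

    def test_too_few_frames_raises(self):
        with pytest.raises(ValueError):
            lp.register_series(np.zeros((8, 8, 1)))


class TestJacobian:
    def test_zero_field_gives_unity(self):
        f = DeformationField(np.zeros((16, 16)), np.zeros((16, 16)), np.zeros((16, 16)))
        assert np.allclose(lp.jacobian_determinant(f), 1.0)

    def test_uniform_dilation_closed_form(self):
        alpha = 0.05
        r = np.arange(20)[:, None] * np.ones((1, 20))
        c = np.ones((20, 1)) * np.arange(20)[None, :]
        f = DeformationField(alpha * c, alpha * r, np.zeros_like(r))
        j = lp.jacobian_determinant(f)
        assert np.allclose(j, (1 + alpha) ** 2, atol=1e-12)

    def test_matches_independent_finite_difference_oracle(self, rng):
        from scipy.ndimage import gaussian_filter

        dx = gaussian_filter(rng.standard_normal((24, 24)), 3.0)
        dy = gaussian_filter(rng.standard_normal((24, 24)), 3.0)
        j = lp.jacobian_determinant((dx, dy))
        # element-wise oracle with explicit loops
        expected = np.empty_like(dx)
        for i in range(24):
            for k in range(24):
                def d(arr, axis):
                    if axis == 0:
                        lo, hi = max(i - 1, 0), min(i + 1, 23)
                        return (arr[hi, k] - arr[lo, k]) / (hi - lo)
                    lo, hi = max(k - 1, 0), min(k + 1, 23)
                    return (arr[i, hi] - arr[i, lo]) / (hi - lo)

                expected[i, k] = (1 + d(dx, 1)) * (1 + d(dy, 0)) - d(dx, 0) * d(dy, 1)
        assert np.allclose(j, expected, atol=1e-10)

    def test_nonfinite_field_raises(self):
        bad = np.zeros((8, 8))
        bad[0, 0] = np.inf
        with pytest.raises(ValueError):
            lp.jacobian_determinant((bad, np.zeros((8, 8))))


class TestMotility:
    def test_constant_fields_give_zero_sigma(self):
        f = DeformationField(np.ones((16, 16)), np.zeros((16, 16)), np.zeros((16, 16)))
        sigma = lp.motility_map([f, f, f])
        assert np.allclose(sigma, 0.0)
        assert lp.motility_score(sigma) == 0.0

    def test_sigma_invariant_under_rigid_offset(self, rng):
        # a rigid (spatially constant) translation added to every frame
        # has zero displacement gradient, so J and hence sigma_J are
        # untouched
        from scipy.ndimage import gaussian_filter

        fields = []
        offset_fields = []
        for t in range(5):
            dx = gaussian_filter(rng.standard_normal((16, 16)), 2.0)
            dy = gaussian_filter(rng.standard_normal((16, 16)), 2.0)
            z = np.zeros((16, 16))
            fields.append(DeformationField(dx, dy, z))
            offset_fields.append(DeformationField(dx + 3.0, dy - 1.5, z))
        assert np.allclose(
            lp.motility_map(fields), lp.motility_map(offset_fields), atol=1e-12
        )

    def test_full_image_score_is_mean(self, rng):
        sigma = np.abs(rng.standard_normal((16, 16)))
        assert lp.motility_score(sigma) == pytest.approx(sigma.mean())

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError):
            lp.motility_score(np.ones((8, 8)), np.zeros((8, 8), bool))

    def test_single_frame_raises(self):
        f = DeformationField(np.zeros((8, 8)), np.zeros((8, 8)), np.zeros((8, 8)))
        with pytest.raises(ValueError):
            lp.motility_map([f])
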