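"""Unit and property tests for the patch PCA, noise line and thresholds."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lcpca import (ContrastStack, LcpcaParams, NoiseLine, PatchMatrix,
                   decompose_patch, denoise_patch, denoise_stack,
                   estimate_spectrum, fit_noise_line, patch_origins, recombine,
                   rmt_threshold, sweep_patches, threshold_spectrum)


def _patch(values, size=4):
    values = np.asarray(values, dtype=float)
    return PatchMatrix(values, (0, 0, 0), size, values.mean(axis=0))


def _stack(data):
    return ContrastStack(np.asarray(data, dtype=float))


class TestSweepPatches:
    @pytest.mark.parametrize("shape,expected", [
        ((4, 4, 4), 1),     # exact fit, single patch
        ((8, 8, 8), 27),    # 3 origins per axis
        ((5, 4, 4), 2),     # clamped boundary origin at x=1
    ])
    def test_patch_counts(self, shape, expected):
        params = LcpcaParams(patch_size=4, stride=2)
        origins = patch_origins(shape, params)
        assert len(origins) == expected

    def test_clamped_origins(self):
        params = LcpcaParams(patch_size=4, stride=2)
        assert patch_origins((5, 4, 4), params) == [(0, 0, 0), (1, 0, 0)]

    def test_every_voxel_covered_bounded_times(self):
        params = LcpcaParams(patch_size=4, stride=2)
        cover = np.zeros((8, 8, 8), dtype=int)
        for ox, oy, oz in patch_origins(cover.shape, params):
            cover[ox:ox + 4, oy:oy + 4, oz:oz + 4] += 1
        assert cover.min() >= 1 and cover.max() <= 8

    def test_patches_carry_means(self, rng):
        data = rng.normal(size=(6, 6, 6, 4))
        params = LcpcaParams(patch_size=4, stride=2)
        for patch in sweep_patches(_stack(data), params):
            np.testing.assert_allclose(
                patch.means,
                data[patch.origin[0]:patch.origin[0] + 4,
                     patch.origin[1]:patch.origin[1] + 4,
                     patch.origin[2]:patch.origin[2] + 4].reshape(64, 4).mean(0))
            assert np.allclose(patch.centered.sum(axis=0), 0, atol=1e-9)

    def test_too_small_volume_raises(self):
        with pytest.raises(ValueError, match="smaller than patch"):
            patch_origins((3, 8, 8), LcpcaParams(patch_size=4))


class TestDecomposePatch:
    def test_constant_patch_all_zero_singular_values(self):
        vals = np.tile([1.0, 2.0, 3.0], (64, 1))
        spec = decompose_patch(_patch(vals))
        np.testing.assert_allclose(spec.singular_values, 0, atol=1e-12)

    def test_rank_one_patch(self, rng):
        pattern = rng.normal(size=64)
        weights = rng.normal(size=5)
        vals = np.outer(pattern, weights)
        spec = decompose_patch(_patch(vals))
        centered = vals - vals.mean(0)
        assert spec.singular_values[0] == pytest.approx(np.linalg.norm(centered))
        np.testing.assert_allclose(spec.singular_values[1:], 0, atol=1e-9)

    def test_covariance_eigenvalue_oracle(self, rng):
        """Squared singular values / (n-1) equal brute-force covariance eigenvalues."""
        vals = rng.normal(size=(64, 10))
        spec = decompose_patch(_patch(vals))
        cov = np.cov(vals, rowvar=False)  # brute-force covariance, ddof=1
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(spec.singular_values ** 2 / 63, eig, rtol=1e-8)

    def test_basis_orthonormal(self, rng):
        spec = decompose_patch(_patch(rng.normal(size=(64, 10))))
        gram = spec.basis @ spec.basis.T
        assert np.abs(gram - np.eye(10)).max() < 1e-8

    def test_nonfinite_raises(self):
        vals = np.zeros((64, 3))
        vals[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            decompose_patch(_patch(vals))


class TestFitNoiseLine:
    def test_exact_line(self):
        s = 10.0 - np.arange(10)
        line = fit_noise_line(s, 5)
        assert line.slope == pytest.approx(-1.0)
        assert line.intercept == pytest.approx(10.0)
        assert line.r_squared == pytest.approx(1.0)

    def test_degenerate_constant_values(self):
        line = fit_noise_line([5.0, 4.0, 2.0, 2.0, 2.0, 2.0, 2.0], 5)
        assert line.slope == pytest.approx(0.0)
        assert line.intercept == pytest.approx(2.0)
        assert line.r_squared == 1.0

    def test_normal_equations_oracle(self, rng):
        """OLS matches an explicit normal-equations solve on noise values."""
        s = np.sort(np.abs(rng.normal(size=8)))[::-1]
        fc = 5
        line = fit_noise_line(s, fc)
        x = np.arange(8 - fc, 8, dtype=float)
        design = np.stack([x, np.ones_like(x)], axis=1)
        coef = np.linalg.solve(design.T @ design, design.T @ s[-fc:])
        assert line.slope == pytest.approx(coef[0], abs=1e-12)
        assert line.intercept == pytest.approx(coef[1], abs=1e-12)

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError):
            fit_noise_line([1.0, 2.0], 1)


class TestThresholdSpectrum:
    def test_values_on_line_keep_nothing(self):
        s = 10.0 - np.arange(10)
        line = fit_noise_line(s, 5)
        assert threshold_spectrum(s, line, 0.05) == 0

    def test_one_strong_component(self):
        s = np.array([50.0, 4.0, 3.5, 3.0, 2.5, 2.0])
        line = fit_noise_line(s, 5)
        assert threshold_spectrum(s, line, 0.05) == 1

    def test_prefix_truncation(self):
        """Exceedances below the first failing rank do not count: with a
        steeply falling line, rank 2 would pass (clamped line is 0 there)
        but rank 1 fails, so only the prefix of length 1 is kept."""
        line = NoiseLine(-1.2, 2.0, 1.0)
        s = np.array([5.0, 0.8, 0.5, 0.4, 0.3])
        assert threshold_spectrum(s, line, 0.05) == 1

    def test_negative_line_clamped(self):
        line = NoiseLine(-1.0, 0.5, 1.0)  # negative beyond rank 0
        # rank 0: limit 1.05 * 0.5; 0.2 fails -> nothing kept
        assert threshold_spectrum(np.array([0.2, 0.1, 0.05]), line, 0.05) == 0
        # once past rank 0 the line clamps to 0, so every positive value passes
        assert threshold_spectrum(np.array([0.6, 0.1, 0.05]), line, 0.05) == 3

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.1, 100.0), min_size=6, max_size=12),
           st.floats(0.01, 0.5), st.floats(0.5, 5.0))
    def test_alpha_monotonicity(self, values, alpha, factor):
        """Raising alpha never increases the kept-count; alpha -> inf keeps 0."""
        s = np.sort(np.asarray(values))[::-1]
        line = fit_noise_line(s, len(s) // 2)
        k1 = threshold_spectrum(s, line, alpha)
        k2 = threshold_spectrum(s, line, alpha * (1.0 + factor))
        assert k2 <= k1
        if line.predict(0) > 0:
            assert threshold_spectrum(s, line, 1e9) == 0


class TestRmtThreshold:
    def test_equal_eigenvalues_pure_bulk(self):
        assert rmt_threshold(np.full(10, 2.5), 64) == 0

    def test_all_zero(self):
        assert rmt_threshold(np.zeros(10), 64) == 0

    def test_clear_signal_components(self, rng):
        noise = rng.normal(size=(64, 10))
        lam = np.sort(np.linalg.eigvalsh(noise.T @ noise / 64))[::-1]
        lam[:2] += 50.0
        assert rmt_threshold(lam, 64) == 2


class TestDenoisePatch:
    def test_full_rank_identity(self, rng):
        vals = rng.normal(size=(64, 6))
        spec = decompose_patch(_patch(vals))
        spec.kept = 6
        out = denoise_patch(_patch(vals), spec)
        np.testing.assert_allclose(out, vals, atol=1e-10)

    def test_kept_zero_returns_means(self, rng):
        vals = rng.normal(size=(64, 6)) + 5.0
        patch = _patch(vals)
        spec = decompose_patch(patch)
        spec.kept = 0
        out = denoise_patch(patch, spec)
        np.testing.assert_allclose(out, np.tile(patch.means, (64, 1)))

    def test_true_subspace_projection_lossless(self, rng):
        """Rank-2 noiseless patch, kept=2: projection onto the true subspace."""
        u = np.linalg.qr(rng.normal(size=(64, 2)))[0]
        v = np.linalg.qr(rng.normal(size=(6, 2)))[0]
        vals = u @ np.diag([9.0, 4.0]) @ v.T + rng.normal(size=6)  # plus offsets
        patch = _patch(vals)
        spec = decompose_patch(patch)
        spec.kept = 2
        np.testing.assert_allclose(denoise_patch(patch, spec), vals, atol=1e-8)


class TestRecombine:
    def test_single_patch_identity(self, rng):
        vals = rng.normal(size=(8, 2))
        res = recombine([(vals, (0, 0, 0), 3, 0.9)], (2, 2, 2), 2)
        np.testing.assert_allclose(res.denoised.data.reshape(8, 2), vals)
        np.testing.assert_allclose(res.dimension_map, 3.0)
        np.testing.assert_allclose(res.fit_map, 0.9)

    def test_weighted_overlap_formula(self):
        """Two full overlaps with kept 0 and 1: value = (1*a + 0.5*b) / 1.5."""
        a = np.full((8, 1), 4.0)
        b = np.full((8, 1), 1.0)
        res = recombine([(a, (0, 0, 0), 0, 1.0), (b, (0, 0, 0), 1, 0.5)],
                        (2, 2, 2), 1)
        np.testing.assert_allclose(res.denoised.data, (1.0 * 4.0 + 0.5 * 1.0) / 1.5)
        np.testing.assert_allclose(res.dimension_map, 0.5 / 1.5)
        np.testing.assert_allclose(res.fit_map, (1.0 + 0.5 * 0.5) / 1.5)

    def test_constant_patches_convexity(self):
        c = 7.5
        origins = [(x, y, z) for x in (0, 1) for y in (0, 1) for z in (0, 1)]
        parts = [(np.full((8, 1), c), o, k, 0.5)
                 for o, k in zip(origins, [0, 2, 5, 1, 3, 0, 4, 2])]
        res = recombine(parts, (3, 3, 3), 1)
        np.testing.assert_allclose(res.denoised.data, c)

    def test_output_within_contribution_range(self, rng):
        """The recombined voxel estimate is a convex combination of patch values."""
        origins = [(x, y, z) for x in (0, 2) for y in (0, 2) for z in (0, 2)]
        origins.append((1, 1, 1))
        parts = []
        for o in origins:
            parts.append((rng.uniform(2.0, 9.0, size=(8, 1)), o,
                          int(rng.integers(0, 5)), 0.5))
        res = recombine(parts, (4, 4, 4), 1)
        lo = np.full((4, 4, 4), np.inf)
        hi = np.full((4, 4, 4), -np.inf)
        for vals, (ox, oy, oz), _, _ in parts:
            blk = vals.reshape(2, 2, 2, 1)[..., 0]
            sl = (slice(ox, ox + 2), slice(oy, oy + 2), slice(oz, oz + 2))
            lo[sl] = np.minimum(lo[sl], blk)
            hi[sl] = np.maximum(hi[sl], blk)
        covered = np.isfinite(lo)
        out = res.denoised.data[..., 0]
        assert np.all(out[covered] >= lo[covered] - 1e-12)
        assert np.all(out[covered] <= hi[covered] + 1e-12)

    def test_uncovered_voxel_raises(self):
        with pytest.raises(ValueError, match="not covered"):
            recombine([(np.zeros((8, 1)), (0, 0, 0), 0, 1.0)], (4, 4, 4), 1)


class TestDenoiseStack:
    def test_deterministic(self, rng):
        data = rng.normal(size=(8, 8, 8, 6)) + 10.0
        r1 = denoise_stack(_stack(data))
        r2 = denoise_stack(_stack(data))
        assert np.array_equal(r1.denoised.data, r2.denoised.data)
        assert np.array_equal(r1.dimension_map, r2.dimension_map)

    def test_reduces_noise_on_lowrank_signal(self, rng):
        """Rank-2 spatial signal + noise: output closer to truth than input."""
        u = rng.normal(size=(10, 10, 10, 1))
        w = rng.normal(size=6)
        truth = 20.0 + u * w  # rank-1 around a constant offset
        noisy = truth + rng.normal(0, 0.5, size=truth.shape)
        res = denoise_stack(_stack(noisy))
        assert np.mean((res.denoised.data - truth) ** 2) < np.mean((noisy - truth) ** 2)

    def test_qc_maps_in_range(self, rng):
        data = rng.normal(size=(8, 8, 8, 6))
        res = denoise_stack(_stack(data))
        assert res.dimension_map.min() >= 0 and res.dimension_map.max() <= 6
        assert res.fit_map.min() >= 0 and res.fit_map.max() <= 1


class TestParams:
    @pytest.mark.parametrize("kwargs", [
        {"patch_size": 1}, {"stride": 0}, {"stride": 5, "patch_size": 4},
        {"alpha": 0.0}, {"alpha": -0.1}, {"fit_count": 1},
    ])
    def test_invalid_params_raise(self, kwargs):
        with pytest.raises(ValueError):
            LcpcaParams(**kwargs)

    def test_fit_count_defaults_to_half(self):
        assert LcpcaParams().resolve_fit_count(10) == 5
        assert LcpcaParams().resolve_fit_count(7) == 3
        assert LcpcaParams(fit_count=4).resolve_fit_count(10) == 4
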