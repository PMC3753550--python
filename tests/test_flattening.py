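"""Protrusion-coverage pipeline: bleach correction, oriented filter bank,
segmentation, skeleton coverage and the small-sample KS test."""

import numpy as np
import pytest
from scipy import stats

from apicoquant import (
    FilterBankParams,
    bleach_correct,
    coverage_timeseries,
    ks_compare,
    mexican_hat_kernel,
    orientation_filter_bank,
    segment_response,
    skeleton_coverage,
    skeletonize_mask,
)

from conftest import make_stack


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def zhang_suen_reference(mask):
    """Naive per-pixel-loop parallel Zhang–Suen thinning (oracle)."""
    img = np.pad(np.asarray(mask, bool), 1).astype(int)
    H, W = img.shape

    def neighbours(i, j):
        return [img[i - 1, j], img[i - 1, j + 1], img[i, j + 1],
                img[i + 1, j + 1], img[i + 1, j], img[i + 1, j - 1],
                img[i, j - 1], img[i - 1, j - 1]]

    changed = True
    while changed:
        changed = False
        for step in (0, 1):
            to_delete = []
            for i in range(1, H - 1):
                for j in range(1, W - 1):
                    if img[i, j] != 1:
                        continue
                    p = neighbours(i, j)
                    b = sum(p)
                    if not (2 <= b <= 6):
                        continue
                    ring = p + [p[0]]
                    a = sum(
                        1 for k in range(8) if ring[k] == 0 and ring[k + 1] == 1
                    )
                    if a != 1:
                        continue
                    if step == 0:
                        if p[0] * p[2] * p[4] != 0 or p[2] * p[4] * p[6] != 0:
                            continue
                    else:
                        if p[0] * p[2] * p[6] != 0 or p[0] * p[4] * p[6] != 0:
                            continue
                    to_delete.append((i, j))
            for i, j in to_delete:
                img[i, j] = 0
            if to_delete:
                changed = True
    return img[1:-1, 1:-1].astype(bool)


def exhaustive_otsu(values, nbins=256):
    """Brute-force Otsu: scan every bin edge for max between-class variance."""
    counts, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    best, best_thr = -1.0, centers[0]
    total = counts.sum()
    for k in range(1, nbins):
        w0 = counts[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[:k] * centers[:k]).sum() / w0
        m1 = (counts[k:] * centers[k:]).sum() / w1
        var_b = w0 * w1 * (m0 - m1) ** 2
        if var_b > best:
            best, best_thr = var_b, centers[k - 1]
    return best_thr


def ks_enumeration_reference(a, b):
    """Brute-force two-sample KS: enumerate every assignment of the pooled
    values to the two groups; p = fraction with D at least the observed."""
    from itertools import combinations

    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    n, m = len(a), len(b)
    pooled = np.sort(np.concatenate([a, b]))
    grid = np.unique(pooled)

    def ecdf_d(x, y):
        fx = np.searchsorted(np.sort(x), grid, side="right") / len(x)
        fy = np.searchsorted(np.sort(y), grid, side="right") / len(y)
        return np.max(np.abs(fx - fy))

    d_obs = ecdf_d(a, b)
    count = 0
    total = 0
    for idx in combinations(range(n + m), n):
        x = pooled[list(idx)]
        y = np.delete(pooled, list(idx))
        total += 1
        if ecdf_d(x, y) >= d_obs - 1e-12:
            count += 1
    return d_obs, count / total


# --------------------------------------------------------------------------
# bleach correction
# --------------------------------------------------------------------------

class TestBleachCorrect:
    def test_constant_stack_unchanged(self):
        stack = make_stack(np.full((3, 16, 16), 7.0))
        out = bleach_correct(stack)
        np.testing.assert_allclose(out.data, stack.data)

    def test_halved_frame_scaled_by_two(self):
        data = np.ones((2, 16, 16))
        data[0] *= 100.0
        data[1] *= 50.0
        out = bleach_correct(make_stack(data))
        np.testing.assert_allclose(out.data[1], data[1] * 2.0)

    def test_zero_mean_frame_named_in_error(self):
        data = np.ones((3, 16, 16))
        data[2] = 0.0
        with pytest.raises(ValueError, match="frame 2"):
            bleach_correct(make_stack(data))

    def test_means_conserved_on_random_stacks(self, rng):
        for _ in range(5):
            data = rng.uniform(1, 50, size=(6, 12, 12)) * \
                rng.uniform(0.2, 3.0, size=(6, 1, 1))
            out = bleach_correct(make_stack(data))
            means = out.data.mean(axis=(1, 2))
            np.testing.assert_allclose(means, means[0], rtol=1e-9)


# --------------------------------------------------------------------------
# oriented Mexican-hat bank
# --------------------------------------------------------------------------

class TestKernel:
    @pytest.mark.parametrize("theta", [0.0, 0.4, np.pi / 2, 3.0])
    def test_exact_zero_mean(self, theta):
        k = mexican_hat_kernel(theta, FilterBankParams())
        assert abs(k.sum()) < 1e-12

    def test_quarter_turn_is_transpose(self):
        p = FilterBankParams()
        k0 = mexican_hat_kernel(0.0, p)
        k90 = mexican_hat_kernel(np.pi / 2, p)
        np.testing.assert_allclose(k90, k0.T, atol=1e-9)

    def test_center_is_maximum_at_default_scales(self):
        k = mexican_hat_kernel(0.0, FilterBankParams())
        h = FilterBankParams().halfwidth
        assert k[h, h] == k.max()

    @pytest.mark.parametrize("theta", [-0.1, np.pi, 4.0])
    def test_angle_domain_enforced(self, theta):
        with pytest.raises(ValueError):
            mexican_hat_kernel(theta, FilterBankParams())

    def test_scale_ordering_enforced(self):
        with pytest.raises(ValueError):
            FilterBankParams(sigma_x=1.0, sigma_y=7.0)


def draw_ridge(theta, size=160, halflen=60):
    """1-px-wide bright straight ridge at angle theta through the center."""
    from skimage.draw import line

    c = size // 2
    dy, dx = np.sin(theta), np.cos(theta)
    y0, x0 = int(round(c - dy * halflen)), int(round(c - dx * halflen))
    y1, x1 = int(round(c + dy * halflen)), int(round(c + dx * halflen))
    img = np.zeros((size, size))
    rr, cc = line(y0, x0, y1, x1)
    img[rr, cc] = 100.0
    return img, (rr, cc)


class TestFilterBank:
    def test_uniform_frame_gives_zero_response(self):
        params = FilterBankParams()
        responses, mip = orientation_filter_bank(np.full((80, 80), 5.0), params)
        assert np.abs(responses).max() < 1e-9
        assert np.abs(mip).max() < 1e-9

    def test_mip_dominates_every_angle(self, rng):
        params = FilterBankParams(n_angles=6)
        frame = rng.uniform(0, 10, size=(80, 80))
        responses, mip = orientation_filter_bank(frame, params)
        assert (mip >= responses - 1e-12).all()

    def test_ridge_assigned_to_its_angle_bin(self):
        # brute force over all bins for a 40-degree ridge
        params = FilterBankParams()
        theta = np.deg2rad(40)
        frame, (rr, cc) = draw_ridge(theta)
        responses, _ = orientation_filter_bank(frame, params)
        on_ridge = responses[:, rr, cc].mean(axis=1)
        assert int(np.argmax(on_ridge)) == 4  # 40 deg at 10-deg sampling

    def test_frame_smaller_than_kernel_rejected(self):
        params = FilterBankParams()
        with pytest.raises(ValueError, match="smaller"):
            orientation_filter_bank(np.ones((16, 16)), params)

    def test_rotation_permutes_angle_responses(self, rng):
        # quarter turn: responses shift by n_angles/2 bins exactly
        params = FilterBankParams(n_angles=8)
        frame, _ = draw_ridge(np.deg2rad(22.5), size=120, halflen=40)
        responses, _ = orientation_filter_bank(frame, params)
        rotated = np.rot90(frame)
        responses_rot, _ = orientation_filter_bank(rotated, params)
        # interior comparison, away from boundary effects
        sl = slice(30, 90)
        scale = np.abs(responses).max()
        j = params.n_angles // 2
        for k in range(params.n_angles):
            expected = np.rot90(responses[k])[sl, sl]
            got = responses_rot[(k + j) % params.n_angles][sl, sl]
            rms = np.sqrt(np.mean((expected - got) ** 2))
            assert rms < 0.05 * scale


# --------------------------------------------------------------------------
# segmentation and skeleton coverage
# --------------------------------------------------------------------------

class TestSegmentation:
    def test_constant_response_yields_empty_mask(self):
        assert not segment_response(np.full((32, 32), 3.3)).any()

    def test_two_valued_response_separates_exactly(self):
        mip = np.zeros((32, 32))
        mip[10:12, 5:25] = 4.0
        mask = segment_response(mip)
        np.testing.assert_array_equal(mask, mip > 0)

    def test_bimodal_mixture_matches_exhaustive_otsu(self, rng):
        lo = rng.normal(1.0, 0.2, size=4000)
        hi = rng.normal(5.0, 0.4, size=1000)
        mip = np.concatenate([lo, hi]).reshape(100, 50)
        mip = np.abs(mip)
        mask = segment_response(mip)
        thr_ref = exhaustive_otsu(mip[mip > 0])
        ref_mask = mip > thr_ref
        disagree = np.mean(mask != ref_mask)
        assert disagree < 0.02
        truth = np.zeros(5000, bool)
        truth[4000:] = True
        mis = np.mean(mask.ravel() != truth)
        assert mis < 0.02


class TestSkeletonCoverage:
    def test_empty_mask(self):
        assert skeleton_coverage(np.zeros((20, 20), bool)) == 0.0

    def test_thin_line_is_its_own_skeleton(self):
        mask = np.zeros((20, 40), bool)
        mask[10, 5:30] = True
        assert skeleton_coverage(mask) == 25 / (20 * 40)

    def test_disk_matches_thinning_oracle(self):
        from skimage.draw import disk as sk_disk

        mask = np.zeros((40, 40), bool)
        rr, cc = sk_disk((20, 20), 10.5)
        mask[rr, cc] = True
        ours = skeletonize_mask(mask)
        ref = zhang_suen_reference(mask)
        np.testing.assert_array_equal(ours, ref)
        assert skeleton_coverage(mask) == ref.sum() / mask.size

    def test_adding_disjoint_line_never_reduces_coverage(self, rng):
        for _ in range(5):
            mask = rng.uniform(size=(30, 30)) > 0.8
            mask[:, 25:] = False
            aug = mask.copy()
            aug[:, 28] = True  # disjoint vertical line
            assert skeleton_coverage(aug) >= skeleton_coverage(mask)

    def test_coverage_bounded(self, rng):
        for _ in range(10):
            mask = rng.uniform(size=(16, 16)) > rng.uniform(0.2, 0.9)
            c = skeleton_coverage(mask)
            assert 0.0 <= c <= 1.0


# --------------------------------------------------------------------------
# KS comparison
# --------------------------------------------------------------------------

class TestKSCompare:
    def test_identical_samples(self):
        d, p = ks_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0 and p == 1.0

    def test_fully_separated_three_vs_three(self):
        d, p = ks_compare([1, 2, 3], [10, 11, 12])
        assert d == 1.0
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 orderings

    def test_matches_enumeration_oracle(self):
        d, p = ks_compare([1, 2, 3], [1.5, 2.5, 3.5])
        d_ref, p_ref = ks_enumeration_reference([1, 2, 3], [1.5, 2.5, 3.5])
        assert d == pytest.approx(d_ref)
        assert p == pytest.approx(p_ref)

    def test_matches_scipy_exact_on_random_samples(self, rng):
        for _ in range(10):
            n, m = rng.integers(2, 8, size=2)
            a, b = rng.normal(size=n), rng.normal(size=m) + rng.uniform(-1, 1)
            d, p = ks_compare(a, b)
            ref = stats.ks_2samp(a, b, method="exact")
            assert d == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_handles_ties(self):
        d, p = ks_compare([1, 1, 2], [1, 2, 2])
        d_ref, p_ref = ks_enumeration_reference([1, 1, 2], [1, 2, 2])
        assert d == pytest.approx(d_ref)
        assert p == pytest.approx(p_ref)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([], [1.0])

    def test_large_samples_use_asymptotic(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        d, p = ks_compare(a, b)
        ref = stats.ks_2samp(a, b, method="asymp")
        assert d == pytest.approx(ref.statistic)
        assert 0.0 <= p <= 1.0


# --------------------------------------------------------------------------
# full pipeline on compact synthetic input
# --------------------------------------------------------------------------

class TestCoverageTimeseries:
    def test_noise_only_movie_has_negligible_coverage(self, rng):
        data = rng.poisson(40.0, size=(4, 128, 128)).astype(float)
        series = coverage_timeseries(make_stack(data))
        assert series.coverage.max() < 0.005

    def test_series_length_and_bounds(self):
        from apicoquant import ProtrusionMovieConfig, gen_protrusion_movie

        cfg = ProtrusionMovieConfig(T=3, height=128, width=128,
                                    n_protrusions0=40, seed=5)
        stack, _ = gen_protrusion_movie(cfg)
        series = coverage_timeseries(stack)
        assert len(series.coverage) == 3
        assert (series.coverage >= 0).all() and (series.coverage <= 1).all()
        assert (series.mask_area_fraction >= series.coverage - 1e-12).all()
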