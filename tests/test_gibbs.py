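"""Sub-voxel-shift unringing and the Gx/Gy weighting filters."""

import numpy as np
import pytest

from mrenhance import (
    PhantomSpec,
    UnringParams,
    add_gibbs_ringing,
    compute_weight_filters,
    make_phantom,
    unring_1d,
    unring_2d,
    unring_volume,
)
from mrenhance.gibbs import combine_directions

from _oracles import bruteforce_unring_1d


def ringed_step(n=128, oversample=4, h=100.0):
    """Step with acquisition-rate ringing: k-space of a finely sampled step
    cropped to the n central coefficients and reconstructed at length n, so
    the ringing oscillates near the Nyquist rate of the stored grid — the
    regime the sub-voxel-shift method addresses."""
    big = n * oversample
    hi = np.zeros(big)
    hi[big // 4 : 3 * big // 4] = h
    spectrum = np.fft.fftshift(np.fft.fft(hi))
    c = big // 2
    crop = spectrum[c - n // 2 : c + n // 2]
    ringed = np.fft.ifft(np.fft.ifftshift(crop)).real / oversample
    ideal = np.zeros(n)
    ideal[n // 4 : 3 * n // 4] = h
    return ideal, ringed


class TestWeightFilters:
    @pytest.mark.parametrize("shape", [(4, 4), (5, 5), (8, 6), (7, 12), (64, 64), (240, 155)])
    def test_normalization_exact_everywhere(self, shape):
        f = compute_weight_filters(shape)
        assert np.all(f.gx + f.gy == 1.0)
        assert np.all((f.gx >= 0) & (f.gx <= 1))
        assert np.all((f.gy >= 0) & (f.gy <= 1))

    def test_dc_point_is_half_half(self):
        f = compute_weight_filters((16, 16))
        assert f.gx[0, 0] == 0.5
        assert f.gy[0, 0] == 0.5

    def test_nyquist_axis_values(self):
        # at (kx, ky) = (pi, 0): Gx = 2/(2+0) = 1, Gy = 0
        f = compute_weight_filters((16, 16))
        assert f.gx[8, 0] == 1.0
        assert f.gy[8, 0] == 0.0
        # the doubly-singular corner (pi, pi) is defined by symmetry
        assert f.gx[8, 8] == 0.5
        assert f.gy[8, 8] == 0.5

    def test_zero_sized_dimension_rejected(self):
        with pytest.raises(ValueError):
            compute_weight_filters((0, 8))


class TestUnring1D:
    def test_constant_line_exact(self):
        line = np.full(32, 7.25)
        assert np.array_equal(unring_1d(line), line)

    def test_linear_ramp_nearly_preserved(self):
        # non-periodic input: the circular wrap itself rings at the two ends,
        # so the guarantee is interior preservation plus small overall RMSE
        ramp = np.linspace(0.0, 100.0, 64)
        out = unring_1d(ramp)
        span = np.ptp(ramp)
        assert np.sqrt(np.mean((out - ramp) ** 2)) < 0.01 * span
        assert np.max(np.abs(out - ramp)[4:-4]) < 0.01 * span

    def test_step_matches_exhaustive_search_and_reduces_oscillation(self):
        ideal, ringed = ringed_step()
        out = unring_1d(ringed)
        oracle = bruteforce_unring_1d(ringed)
        assert np.array_equal(out, oracle)
        # oscillation on the plateaus (away from the blurred edges) shrinks
        plateau = np.r_[4:28, 36:60, 68:92, 100:124]
        before = np.abs(ringed - ideal)[plateau]
        after = np.abs(out - ideal)[plateau]
        assert np.sqrt(np.mean(after**2)) < 0.5 * np.sqrt(np.mean(before**2))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce_on_random_lines(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            n = int(rng.integers(8, 65))
            line = rng.normal(0, 1, n)
            assert np.array_equal(unring_1d(line), bruteforce_unring_1d(line))

    def test_too_short_line_rejected(self):
        with pytest.raises(ValueError):
            unring_1d(np.ones(5), UnringParams(max_window=3))

    def test_param_validation(self):
        with pytest.raises(ValueError):
            UnringParams(num_shifts=0)
        with pytest.raises(ValueError):
            UnringParams(min_window=2, max_window=1)
        with pytest.raises(ValueError):
            UnringParams(slice_plane=(0, 0))


class TestUnring2D:
    def test_smooth_polynomial_preserved(self):
        x, y = np.meshgrid(np.linspace(-1, 1, 48), np.linspace(-1, 1, 48), indexing="ij")
        img = 10 + 3 * x + 2 * y + 1.5 * x * y + x**2
        out = unring_2d(img)
        rel = np.sqrt(np.mean((out - img) ** 2)) / np.sqrt(np.mean(img**2))
        assert rel < 0.01

    def test_recombination_identity(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, (24, 20))
        filters = compute_weight_filters(a.shape)
        out = combine_directions(a, a, filters)
        assert np.max(np.abs(out - a)) < 1e-10 * np.ptp(a)

    def test_interior_oscillation_strictly_reduced(self):
        # mild truncation (the method's validity regime); oscillation is
        # measured away from edges, where band-limitation blur dominates
        vol, _ = make_phantom(PhantomSpec(shape=(96, 96, 8), seed=0))
        clean = vol.data[:, :, 4]
        ringed = add_gibbs_ringing(vol, (0.9, 0.9, 1.0)).data[:, :, 4]
        out = unring_2d(ringed)
        from scipy import ndimage

        edges = ndimage.maximum_filter(clean, 3) != ndimage.minimum_filter(clean, 3)
        interior = (clean > 0) & ~ndimage.binary_dilation(edges, iterations=3)
        before = np.sqrt(np.mean((ringed[interior] - clean[interior]) ** 2))
        after = np.sqrt(np.mean((out[interior] - clean[interior]) ** 2))
        assert after < before

    def test_mean_preserved_within_half_percent(self):
        vol, _ = make_phantom(PhantomSpec(shape=(64, 64, 8), seed=1))
        ringed = add_gibbs_ringing(vol, (0.9, 0.9, 1.0)).data[:, :, 4]
        out = unring_2d(ringed)
        assert abs(out.mean() - ringed.mean()) < 0.005 * abs(ringed.mean())

    def test_second_pass_changes_less_than_first(self):
        vol, _ = make_phantom(PhantomSpec(shape=(64, 64, 8), seed=2))
        ringed = add_gibbs_ringing(vol, (0.9, 0.9, 1.0)).data[:, :, 4]
        once = unring_2d(ringed)
        twice = unring_2d(once)
        first = np.sqrt(np.mean((once - ringed) ** 2))
        second = np.sqrt(np.mean((twice - once) ** 2))
        assert second < first

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            unring_2d(np.ones((5, 32)))


class TestUnringVolume:
    def test_single_slice_reduces_to_2d(self, small_phantom):
        vol, _ = small_phantom
        sl = vol.with_data(vol.data[:, :, 10:11])
        out = unring_volume(sl)
        expected = unring_2d(vol.data[:, :, 10])
        assert np.array_equal(out.data[:, :, 0], expected)

    def test_identical_slices_stay_identical(self, small_phantom):
        vol, _ = small_phantom
        ringed2d = add_gibbs_ringing(vol, (0.8, 0.8, 1.0)).data[:, :, 10]
        stack = vol.with_data(np.repeat(ringed2d[:, :, None], 4, axis=2))
        out = unring_volume(stack)
        for k in range(1, 4):
            assert np.array_equal(out.data[:, :, k], out.data[:, :, 0])

    def test_slice_plane_configurable(self, small_phantom):
        vol, _ = small_phantom
        p = UnringParams(slice_plane=(0, 2))
        out = unring_volume(vol, p)
        # processing plane (0, 2): slice k of axis 1 equals unring_2d of it
        expected = unring_2d(vol.data[:, 5, :], p)
        assert np.array_equal(out.data[:, 5, :], expected)

    def test_metadata_preserved(self, small_phantom):
        vol, _ = small_phantom
        out = unring_volume(vol)
        assert out.spacing == vol.spacing
        assert np.array_equal(out.affine, vol.affine)

    def test_degenerate_inplane_rejected(self, small_phantom):
        vol, _ = small_phantom
        thin = vol.with_data(vol.data[:3, :, :])
        with pytest.raises(ValueError):
            unring_volume(thin)
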