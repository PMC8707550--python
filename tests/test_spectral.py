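import numpy as np
import pytest

from augforge import Config, RandomSource
from augforge.spectral_aug import (
    CQTKernel,
    WaveletCoefficients,
    app10,
    app11,
    cqt_forward,
    cqt_inverse,
    dwt_forward,
    dwt_inverse,
    perturb_cqt,
    perturb_wavelet,
)


def _haar_block_oracle(x):
    """Explicit 2x2-block Haar analysis for even-sized arrays.

    Derived from the length-2 filter pair (lo = [1,1]/sqrt2, hi = [1,-1]/sqrt2
    applied as first-minus-second) convolved and downsampled along each axis.
    """
    a, b = x[0::2, 0::2], x[0::2, 1::2]
    c, d = x[1::2, 0::2], x[1::2, 1::2]
    cA = (a + b + c + d) / 2
    cH = (a + b - c - d) / 2
    cV = (a - b + c - d) / 2
    cD = (a - b - c + d) / 2
    return cA, cH, cV, cD


class TestDWT:
    def test_227_channel_yields_114_subbands(self):
        ch = RandomSource(0).random((227, 227))
        coeffs = dwt_forward(ch)
        assert coeffs.shape == (114, 114)

    def test_constant_channel_has_zero_details(self):
        coeffs = dwt_forward(np.full((16, 16), 0.3))
        assert np.allclose(coeffs.cA, 0.6, atol=1e-12)  # Haar average scales by 2
        for band in (coeffs.cH, coeffs.cV, coeffs.cD):
            assert np.abs(band).max() <= 1e-12

    def test_agrees_with_block_haar_oracle(self):
        x = RandomSource(1).generator.integers(0, 10, (4, 4)).astype(float)
        coeffs = dwt_forward(x)
        oA, oH, oV, oD = _haar_block_oracle(x)
        assert np.allclose(coeffs.cA, oA, atol=1e-12)
        assert np.allclose(coeffs.cH, oH, atol=1e-12)
        assert np.allclose(coeffs.cV, oV, atol=1e-12)
        assert np.allclose(coeffs.cD, oD, atol=1e-12)

    @pytest.mark.parametrize("shape", [(31, 45), (64, 64), (227, 227)])
    def test_perfect_reconstruction(self, shape):
        ch = RandomSource(2).random(shape)
        rec = dwt_inverse(dwt_forward(ch), shape)
        assert np.abs(rec - ch).max() <= 1e-10

    def test_zero_coefficients_give_zero_channel(self):
        z = np.zeros((8, 8))
        coeffs = WaveletCoefficients(z, z, z, z)
        assert np.abs(dwt_inverse(coeffs, (16, 16))).max() == 0.0

    def test_inverse_is_linear(self):
        ch = RandomSource(3).random((20, 20))
        coeffs = dwt_forward(ch)
        scaled = WaveletCoefficients(*(2.5 * m for m in coeffs.bands()))
        rec1 = dwt_inverse(scaled, (20, 20))
        rec2 = 2.5 * dwt_inverse(coeffs, (20, 20))
        assert np.allclose(rec1, rec2, atol=1e-10)


class TestPerturbWavelet:
    def _coeffs(self, seed=0, side=16):
        return dwt_forward(RandomSource(seed).random((side * 2, side * 2)))

    def test_zero_mode_with_p0_is_identity(self, rng):
        c = self._coeffs()
        out = perturb_wavelet(c, "zero", rng, p_zero=0.0)
        assert all(np.array_equal(a, b) for a, b in zip(c.bands(), out.bands()))

    def test_zero_mode_never_increases_subband_energy(self, rng):
        c = self._coeffs()
        out = perturb_wavelet(c, "zero", rng, p_zero=0.5)
        for before, after in zip(c.bands(), out.bands()):
            assert np.linalg.norm(after) <= np.linalg.norm(before) + 1e-12

    def test_additive_constant_bounded_for_flat_channel(self):
        # std 0 leaves only the uniform draw, so |c| <= 0.5
        c = self._coeffs()
        for seed in range(50):
            out = perturb_wavelet(c, "additive", RandomSource(seed), channel_std=0.0)
            delta = out.cA - c.cA
            assert np.allclose(delta, delta.flat[0])
            assert np.abs(delta).max() <= 0.5

    def test_additive_shifts_every_band_by_one_constant(self, rng):
        c = self._coeffs()
        out = perturb_wavelet(c, "additive", rng, channel_std=0.2)
        deltas = [after - before for before, after in zip(c.bands(), out.bands())]
        ref = deltas[0].flat[0]
        assert all(np.allclose(d, ref, atol=1e-12) for d in deltas)

    def test_swap_rate_matches_binomial_law(self, rng):
        side = 114
        z = np.zeros((side, side))
        c = WaveletCoefficients(z, z, z, z)
        o = np.ones((side, side))
        peers = [WaveletCoefficients(o, o, o, o)] * 5
        out = perturb_wavelet(c, "swap", rng, peers=peers, p_swap=0.05)
        frac = np.mean([b.mean() for b in out.bands()])
        assert abs(frac - 0.05) <= 0.01

    def test_swap_closure_at_p1(self, rng):
        c = self._coeffs(0)
        peers = [self._coeffs(s) for s in range(1, 6)]
        out = perturb_wavelet(c, "swap", rng, peers=peers, p_swap=1.0)
        for b in range(4):
            stacked = np.stack([p.bands()[b] for p in peers])
            member = np.any(np.isclose(out.bands()[b][None], stacked), axis=0)
            assert member.all()

    def test_swap_without_peers_rejected(self, rng):
        with pytest.raises(ValueError):
            perturb_wavelet(self._coeffs(), "swap", rng)


class TestApp10:
    def test_three_outputs_shapes_determinism(self, rgb_set):
        img, label = rgb_set[0]
        a = app10(img, label, rgb_set, RandomSource(5))
        b = app10(img, label, rgb_set, RandomSource(5))
        assert len(a) == 3
        assert all(o.shape == img.shape for o in a)
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))

    def test_no_perturbation_config_reproduces_input(self, rgb_set):
        cfg = Config({"spectral.p_zero": 0.0, "spectral.p_swap": 0.0})
        img, label = rgb_set[0]
        outs = app10(img, label, rgb_set, RandomSource(5), cfg)
        for out in (outs[0], outs[2]):  # zero and swap modes become identity
            assert np.abs(out.pixels - img.pixels).max() <= 1e-6


class TestCQT:
    def test_stack_length_equals_width(self):
        ch = RandomSource(0).random((32, 20))
        assert len(cqt_forward(ch)) == 20

    def test_zero_channel_gives_zero_coefficients(self):
        stack = cqt_forward(np.zeros((32, 8)))
        assert all(np.abs(b).max() == 0.0 for b in stack.blocks)

    def test_round_trip_on_random_channel(self):
        ch = RandomSource(1).random((64, 64))
        rec = cqt_inverse(cqt_forward(ch), (64, 64))
        rel = np.linalg.norm(rec - ch) / np.linalg.norm(ch)
        assert rel <= 1e-6

    def test_round_trip_row_axis(self):
        ch = RandomSource(4).random((24, 40))
        rec = cqt_inverse(cqt_forward(ch, axis="rows"), (24, 40), axis="rows")
        assert np.linalg.norm(rec - ch) / np.linalg.norm(ch) <= 1e-6

    def test_inverse_is_linear(self):
        ch = RandomSource(2).random((32, 4))
        stack = cqt_forward(ch)
        from augforge.spectral_aug import CQTStack

        scaled = CQTStack(tuple(3.0 * b for b in stack.blocks), stack.kernel)
        rec1 = cqt_inverse(scaled, (32, 4))
        rec2 = 3.0 * cqt_inverse(stack, (32, 4))
        assert np.allclose(rec1, rec2, atol=1e-8)

    def test_short_column_error_names_minimum(self):
        with pytest.raises(ValueError, match="8"):
            CQTKernel(4)

    def test_kernel_geometry(self):
        k = CQTKernel(64, bins_per_octave=12)
        # geometric ladder: 12 bins per octave plus a DC band
        ratios = k.frequencies[2:] / k.frequencies[1:-1]
        assert np.allclose(ratios, 2 ** (1 / 12))
        assert k.frequencies[0] == 0.0
        assert k.frequencies[-1] <= 0.5


class TestPerturbCQT:
    def _stack(self, seed=0):
        return cqt_forward(RandomSource(seed).random((32, 10)))

    def test_zero_mode_never_increases_energy(self, rng):
        stack = self._stack()
        out = perturb_cqt(stack, "zero", rng, p_zero=0.5)
        for before, after in zip(stack.blocks, out.blocks):
            assert np.linalg.norm(after) <= np.linalg.norm(before) + 1e-12

    def test_additive_adds_constant_to_real_part(self, rng):
        stack = self._stack()
        out = perturb_cqt(stack, "additive", rng, channel_std=0.1)
        delta = out.blocks[0] - stack.blocks[0]
        assert np.abs(delta.imag).max() <= 1e-12
        assert np.allclose(delta.real, delta.real.flat[0])

    def test_swap_closure_at_p1(self, rng):
        stack = self._stack(0)
        peers = [self._stack(s) for s in range(1, 6)]
        out = perturb_cqt(stack, "swap", rng, peers=peers, p_swap=1.0)
        for j, b in enumerate(out.blocks):
            stacked = np.stack([p.blocks[j] for p in peers])
            member = np.any(np.isclose(b[None], stacked), axis=0)
            assert member.all()

    def test_swap_rate_matches_binomial_law(self, rng):
        stack = self._stack()
        n = sum(b.size for b in stack.blocks)
        peers = [self._stack(s) for s in range(1, 6)]
        out = perturb_cqt(stack, "swap", rng, peers=peers, p_swap=0.05)
        changed = sum(
            int(np.sum(a != b)) for a, b in zip(stack.blocks, out.blocks)
        )
        assert abs(changed / n - 0.05) <= 0.01


class TestApp11:
    def test_three_outputs_shapes_determinism(self, rgb_set):
        img, label = rgb_set[0]
        a = app11(img, label, rgb_set, RandomSource(6))
        b = app11(img, label, rgb_set, RandomSource(6))
        assert len(a) == 3
        assert all(o.shape == img.shape for o in a)
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))

    def test_no_perturbation_config_reproduces_input(self, rgb_set):
        cfg = Config({"spectral.p_zero": 0.0, "spectral.p_swap": 0.0})
        img, label = rgb_set[0]
        outs = app11(img, label, rgb_set, RandomSource(6), cfg)
        for out in (outs[0], outs[2]):
            assert np.abs(out.pixels - img.pixels).max() <= 1e-4
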