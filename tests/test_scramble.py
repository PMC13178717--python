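"""Soft phase scrambling, filtering, and the augmentation policy."""

import numpy as np
import pytest
from scipy import stats

from sfprobe.frequency import build_frequency_grid, constant_mask, human_channel_mask
from sfprobe.scramble import (
    AugmentationPolicy,
    PhaseField,
    apply_policy,
    filter_augment,
    phase_scramble,
    sample_phase_field,
    soft_clip,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def image64(rng):
    return rng.random((64, 64, 3))


class TestPhaseField:
    def test_same_seed_gives_identical_fields(self, grid64):
        a = sample_phase_field(grid64, 7)
        b = sample_phase_field(grid64, 7)
        assert np.array_equal(a.values, b.values)

    def test_hermitian_antisymmetry(self, grid64):
        f = sample_phase_field(grid64, 3)
        assert f.is_hermitian()
        v = f.values
        mirrored = v[np.mod(-np.arange(64), 64)][:, np.mod(-np.arange(64), 64)]
        assert np.allclose(np.exp(1j * mirrored), np.exp(-1j * v))

    def test_self_conjugate_coefficients_real_phase(self, grid64):
        f = sample_phase_field(grid64, 5)
        sc = grid64.self_conjugate()
        assert np.allclose(np.abs(np.sin(f.values[sc])), 0.0, atol=1e-9)

    def test_phases_uniform_on_circle(self):
        # pool non-self-conjugate phases from many fields: KS vs U(-pi, pi)
        g = build_frequency_grid(32, 32)
        sc = g.self_conjugate()
        rng = np.random.default_rng(0)
        samples = np.concatenate(
            [sample_phase_field(g, rng).values[~sc] for _ in range(100)]
        )
        assert samples.size >= 100_000
        res = stats.kstest(samples, stats.uniform(loc=-np.pi, scale=2 * np.pi).cdf)
        assert res.pvalue > 0.01


class TestPhaseScramble:
    def test_full_mask_is_identity(self, grid64, image64):
        out = phase_scramble(image64, constant_mask(grid64, 1.0), sample_phase_field(grid64, 0))
        assert np.abs(out - image64).max() < 1e-6

    def test_zero_mask_with_original_phase_is_identity(self, grid64, image64):
        # blend degenerates to the original phase when phi_r == phi_c
        spec = np.fft.fft2(image64[:, :, 0])
        field = PhaseField(values=np.angle(spec), grid=grid64)
        img = np.repeat(image64[:, :, :1], 3, axis=2)
        out = phase_scramble(img, constant_mask(grid64, 0.0), field)
        assert np.abs(out - img).max() < 1e-6

    def test_half_mask_blend_matches_complex_midpoint_oracle(self):
        g = build_frequency_grid(16, 16)
        rng = np.random.default_rng(1)
        img = rng.random((16, 16, 3))
        field = sample_phase_field(g, 9)
        out = phase_scramble(img, constant_mask(g, 0.5), field, clip_mode="none")
        for c in range(3):
            spec_in = np.fft.fft2(img[:, :, c])
            spec_out = np.fft.fft2(out[:, :, c])
            # oracle: per coefficient, angle of the midpoint of the two unit
            # phasors; degenerate (antipodal) blends keep the original phase,
            # as does DC
            mid = 0.5 * np.exp(1j * np.angle(spec_in)) + 0.5 * np.exp(1j * field.values)
            mid[0, 0] = np.exp(1j * np.angle(spec_in)[0, 0])
            phase = np.where(
                np.abs(mid) < 1e-12, np.angle(spec_in), np.angle(mid)
            )
            expected = np.abs(spec_in) * np.exp(1j * phase)
            assert np.allclose(spec_out, expected, atol=1e-8)

    @pytest.mark.parametrize("mask_value", [0.0, 0.3, 1.0])
    def test_amplitude_spectrum_preserved(self, grid64, image64, mask_value):
        out = phase_scramble(
            image64, constant_mask(grid64, mask_value), sample_phase_field(grid64, 4),
            clip_mode="none",
        )
        for c in range(3):
            a_in = np.abs(np.fft.fft2(image64[:, :, c]))
            a_out = np.abs(np.fft.fft2(out[:, :, c]))
            assert np.abs(a_out - a_in).max() / a_in.max() < 1e-6

    def test_parseval_energy_conserved_pre_clip(self, grid64, image64):
        out = phase_scramble(
            image64, human_channel_mask(grid64, mu_octaves=3.0),
            sample_phase_field(grid64, 8), clip_mode="none",
        )
        assert np.sum(out**2) == pytest.approx(np.sum(image64**2), rel=1e-9)

    def test_reconstruction_is_real(self, grid64, image64):
        # imaginary residual of the inverse DFT must be negligible
        m = human_channel_mask(grid64, mu_octaves=3.0).weights.copy()
        m[0, 0] = 1.0
        field = sample_phase_field(grid64, 11)
        spec = np.fft.fft2(image64[:, :, 0])
        blend = m * np.exp(1j * np.angle(spec)) + (1 - m) * np.exp(1j * field.values)
        recon = np.fft.ifft2(np.abs(spec) * np.exp(1j * np.angle(blend)))
        assert np.abs(recon.imag).max() < 1e-8

    def test_dc_phase_preserved_mean_unchanged(self, grid64, image64):
        out = phase_scramble(
            image64, constant_mask(grid64, 0.0), sample_phase_field(grid64, 2),
            clip_mode="none",
        )
        assert out.mean(axis=(0, 1)) == pytest.approx(image64.mean(axis=(0, 1)), abs=1e-9)

    def test_shape_mismatch_rejected(self, grid64, rng):
        with pytest.raises(ValueError):
            phase_scramble(
                rng.random((32, 32, 3)), constant_mask(grid64, 1.0),
                sample_phase_field(grid64, 0),
            )

    def test_non_hermitian_phase_rejected(self, grid64, image64, rng):
        bad = PhaseField(values=rng.uniform(-np.pi, np.pi, (64, 64)), grid=grid64)
        with pytest.raises(ValueError):
            phase_scramble(image64, constant_mask(grid64, 1.0), bad)


class TestFilterAugment:
    def test_full_mask_is_identity(self, grid64, image64):
        out = filter_augment(image64, constant_mask(grid64, 1.0))
        assert np.abs(out - image64).max() < 1e-6

    def test_dc_only_mask_yields_channel_means(self, grid64, image64):
        m = constant_mask(grid64, 0.0).weights.copy()
        m[0, 0] = 1.0
        from sfprobe.frequency import SFMask

        mask = SFMask(weights=m, grid=grid64)
        out = filter_augment(image64, mask, clip_mode="none")
        for c in range(3):
            assert np.allclose(out[:, :, c], image64[:, :, c].mean(), atol=1e-9)

    def test_single_coefficient_power_scales_as_weight_squared(self, grid64):
        # pure sinusoid beyond a low-pass band: output power = w^2 * input power
        x = np.arange(64)
        carrier = np.tile(np.cos(2 * np.pi * 20 * x / 64), (64, 1))
        img = np.repeat((0.5 + 0.3 * carrier)[:, :, None], 3, axis=2)
        w = np.full((64, 64), 0.25)
        w[0, 0] = 1.0
        from sfprobe.frequency import SFMask

        out = filter_augment(img, SFMask(weights=w, grid=grid64), clip_mode="none")
        ac_in = img[:, :, 0] - img[:, :, 0].mean()
        ac_out = out[:, :, 0] - out[:, :, 0].mean()
        assert np.sum(ac_out**2) / np.sum(ac_in**2) == pytest.approx(0.25**2, rel=1e-9)


class TestSoftClip:
    def test_clamp_bounds_and_identity_inside(self):
        x = np.array([-0.5, 0.2, 0.8, 1.7])
        out = soft_clip(x, "clamp")
        assert np.array_equal(out, [0.0, 0.2, 0.8, 1.0])

    def test_tanh_compressor_stays_in_range_and_monotone(self):
        x = np.linspace(-1, 2, 301)
        out = soft_clip(x, "tanh", sharpness=10.0)
        assert np.all((out >= 0) & (out <= 1))
        assert np.all(np.diff(out) >= 0)
        inside = (x > 0.15) & (x < 0.85)
        assert np.allclose(out[inside], x[inside])

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            soft_clip(np.zeros(3), "wrap")


class TestApplyPolicy:
    def test_zero_probability_returns_batch_unchanged(self, grid64, rng):
        batch = rng.random((8, 64, 64, 3))
        policy = AugmentationPolicy(masks=(constant_mask(grid64, 1.0),), replace_prob=0.0)
        out = apply_policy(batch, policy, rng=0)
        assert np.array_equal(out, batch)

    def test_probability_one_scrambles_all_and_preserves_amplitudes(self, grid64, rng):
        batch = rng.random((4, 64, 64, 3))
        mask = human_channel_mask(grid64, mu_octaves=3.0)
        policy = AugmentationPolicy(masks=(mask,), replace_prob=1.0, clip_mode="none")
        out = apply_policy(batch, policy, rng=1)
        for i in range(4):
            assert not np.array_equal(out[i], batch[i])
            for c in range(3):
                a_in = np.abs(np.fft.fft2(batch[i, :, :, c]))
                a_out = np.abs(np.fft.fft2(out[i, :, :, c]))
                assert np.abs(a_out - a_in).max() / a_in.max() < 1e-6

    def test_replacement_fraction_matches_binomial(self, rng):
        g = build_frequency_grid(8, 8)
        batch = rng.random((10_000, 8, 8, 3))
        policy = AugmentationPolicy(masks=(constant_mask(g, 0.0),), replace_prob=0.5)
        out = apply_policy(batch, policy, rng=3)
        replaced = np.any(out != batch, axis=(1, 2, 3)).mean()
        se = np.sqrt(0.25 / 10_000)
        assert abs(replaced - 0.5) < 3 * se

    def test_seeded_determinism_bit_reproducible(self, grid64, rng):
        batch = rng.random((6, 64, 64, 3))
        mask = human_channel_mask(grid64, mu_octaves=3.0)
        policy = AugmentationPolicy(masks=(mask,), replace_prob=0.7)
        out1 = apply_policy(batch, policy, rng=99)
        out2 = apply_policy(batch, policy, rng=99)
        assert np.array_equal(out1, out2)

    def test_mask_probabilities_must_be_valid(self, grid64):
        with pytest.raises(ValueError):
            AugmentationPolicy(
                masks=(constant_mask(grid64, 1.0),),
                mask_probs=(0.7, 0.6),
                mixture_mode=True,
            )
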