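"""Minimum-noise weighting, dictionary denoising, local linear transfer."""

import numpy as np
import pytest

from sdexa.decomp import SpectralProjectionPair
from sdexa.denoise import (
    DenoiseConfig,
    DenoiseError,
    DictionaryConfig,
    compute_minimum_noise_weight,
    denoise_min_noise_image,
    denoise_pipeline,
    find_bone_free_roi,
    learn_dictionary,
    local_linear_transform,
    overcomplete_dct,
)


def _pair(ph, co):
    return SpectralProjectionPair(
        photoelectric_epl=ph, compton_epl=co, pixel_spacing=(1.0, 1.0)
    )


def _correlated_noise_pair(n, sigma_p, sigma_c, rho, seed=0, mean=10.0):
    rng = np.random.default_rng(seed)
    cov = np.array(
        [[sigma_p**2, rho * sigma_p * sigma_c], [rho * sigma_p * sigma_c, sigma_c**2]]
    )
    z = rng.multivariate_normal([0, 0], cov, size=n * n).reshape(n, n, 2)
    return _pair(mean + z[..., 0], mean + z[..., 1])


class TestMinimumNoiseWeight:
    def test_symmetric_perfect_anticorrelation_gives_half(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 1.0, (32, 32))
        pair = _pair(10.0 + noise, 10.0 - noise)  # sigma_p = sigma_c, rho = -1
        w = compute_minimum_noise_weight(pair, (0, 32, 0, 32))
        assert w == pytest.approx(0.5, abs=1e-12)

    def test_unequal_sigmas_uncorrelated_matches_brute_force(self):
        pair = _correlated_noise_pair(64, sigma_p=2.0, sigma_c=1.0, rho=0.0, seed=1)
        roi = (0, 64, 0, 64)
        w = compute_minimum_noise_weight(pair, roi)
        # closed form: var_c / (var_p + var_c) = 1/5 for the population;
        # brute-force scan over the same sample must agree with the output
        grid = np.linspace(0, 1, 2001)
        ph = pair.photoelectric_epl - pair.photoelectric_epl.mean(axis=0)
        co = pair.compton_epl - pair.compton_epl.mean(axis=0)
        variances = [np.var(g * ph + (1 - g) * co) for g in grid]
        assert w == pytest.approx(grid[np.argmin(variances)], abs=1e-3)
        assert w == pytest.approx(0.2, abs=0.03)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_returned_weight_beats_endpoints(self, seed):
        pair = _correlated_noise_pair(32, 1.5, 0.8, -0.7, seed=seed)
        roi = (0, 32, 0, 32)
        w = compute_minimum_noise_weight(pair, roi)
        ph, co = pair.photoelectric_epl, pair.compton_epl

        def var(g):
            return np.var(g * ph + (1 - g) * co)

        assert var(w) <= var(0.0) + 1e-12
        assert var(w) <= var(1.0) + 1e-12

    def test_degenerate_roi_rejected(self):
        pair = _pair(np.full((16, 16), 3.0), np.full((16, 16), 4.0))
        with pytest.raises(DenoiseError):
            compute_minimum_noise_weight(pair, (0, 16, 0, 16))

    def test_small_roi_rejected(self):
        pair = _correlated_noise_pair(16, 1, 1, 0)
        with pytest.raises(DenoiseError):
            compute_minimum_noise_weight(pair, (0, 4, 0, 4))


class TestBoneFreeROI:
    def test_detected_box_avoids_bone(self, noiseless_scout):
        r0, r1, c0, c1 = find_bone_free_roi(noiseless_scout)
        ph = noiseless_scout.photoelectric_epl
        co = noiseless_scout.compton_epl
        box_excess = (ph - co)[r0:r1, c0:c1].mean()
        # photoelectric excess over Compton flags bone; the box should
        # carry essentially none of it
        assert box_excess < 0.05 * (ph - co).max()


class TestDictionary:
    def test_dct_atoms_unit_norm(self):
        atoms = overcomplete_dct(8, 256)
        np.testing.assert_allclose(np.linalg.norm(atoms, axis=1), 1.0, rtol=1e-12)

    def test_constant_image_rejected(self):
        with pytest.raises(DenoiseError):
            learn_dictionary(np.full((64, 64), 2.0), noise_sigma=0.1)

    def test_tiny_image_rejected(self):
        with pytest.raises(DenoiseError):
            learn_dictionary(np.zeros((6, 6)), noise_sigma=0.1)

    def test_stripes_produce_matching_atom(self):
        x = np.arange(64)
        image = np.sin(2 * np.pi * x / 8.0)[None, :] * np.ones((64, 1))
        cfg = DictionaryConfig(n_atoms=64, patch_size=8, n_iterations=5)
        d = learn_dictionary(image, noise_sigma=0.01, config=cfg)
        stripe_patch = image[:8, :8].ravel()
        stripe_patch -= stripe_patch.mean()
        stripe_patch /= np.linalg.norm(stripe_patch)
        corr = np.abs(d.atoms @ stripe_patch)
        assert corr.max() > 0.9

    def test_same_seed_bitwise_identical(self):
        rng = np.random.default_rng(0)
        image = rng.normal(0, 1, (48, 48)).cumsum(axis=1) / 5.0
        cfg = DictionaryConfig(n_atoms=48, patch_size=6, n_iterations=3, seed=11)
        a = learn_dictionary(image, 0.1, cfg)
        b = learn_dictionary(image, 0.1, cfg)
        assert np.array_equal(a.atoms, b.atoms)


class TestDenoiseMinNoise:
    def test_clean_input_passes_through(self):
        x = np.arange(48)
        image = np.sin(2 * np.pi * x / 12.0)[None, :] * np.ones((32, 1))
        cfg = DictionaryConfig(n_atoms=64, patch_size=8, n_iterations=4)
        sigma = 1e-3
        d = learn_dictionary(image, sigma, cfg)
        out = denoise_min_noise_image(image, d, sigma)
        assert np.sqrt(np.mean((out - image) ** 2)) < 5 * sigma

    def test_noisy_edge_rmse_improves(self):
        rng = np.random.default_rng(4)
        clean = np.zeros((48, 64))
        clean[:, 32:] = 1.0
        sigma = 0.2
        noisy = clean + rng.normal(0, sigma, clean.shape)
        cfg = DictionaryConfig(n_atoms=64, patch_size=8, n_iterations=4)
        d = learn_dictionary(noisy, sigma, cfg)
        out = denoise_min_noise_image(noisy, d, sigma)
        rmse_in = np.sqrt(np.mean((noisy - clean) ** 2))
        rmse_out = np.sqrt(np.mean((out - clean) ** 2))
        assert rmse_out < rmse_in

    def test_mean_preserved(self):
        rng = np.random.default_rng(5)
        image = 5.0 + rng.normal(0, 0.3, (40, 56)) + np.linspace(0, 1, 56)[None, :]
        cfg = DictionaryConfig(n_atoms=64, patch_size=8, n_iterations=3)
        try:
            d = learn_dictionary(image, 0.3, cfg)
        except DenoiseError:
            from sdexa.denoise import PatchDictionary

            d = PatchDictionary(overcomplete_dct(8, 64), 8, 0, 8, 0.3 * 8 * 1.1)
        out = denoise_min_noise_image(image, d, 0.3)
        assert abs(out.mean() - image.mean()) / abs(image.mean()) < 1e-3

    def test_nonpositive_sigma_rejected(self):
        d_atoms = overcomplete_dct(8, 64)
        from sdexa.denoise import PatchDictionary

        d = PatchDictionary(d_atoms, 8, 0, 8, 1.0)
        with pytest.raises(DenoiseError):
            denoise_min_noise_image(np.zeros((16, 16)), d, 0.0)


class TestLocalLinearTransform:
    def test_globally_linear_case_exact(self):
        rng = np.random.default_rng(6)
        guide = rng.normal(0, 1, (40, 40)).cumsum(axis=0) / 3.0
        basis = 2.0 * guide + 1.0
        denoised_guide = rng.normal(0, 1, (40, 40)).cumsum(axis=1) / 3.0
        out = local_linear_transform(
            basis, guide, denoised_guide, window_radius=5, regularizer=1e-12
        )
        np.testing.assert_allclose(out, 2.0 * denoised_guide + 1.0, rtol=1e-6, atol=1e-6)

    def test_passthrough_when_guide_unchanged(self):
        # with an unmodified guide the output reproduces the basis up to
        # the windowed-fit residual, which stays well below the signal
        rng = np.random.default_rng(7)
        guide = rng.normal(0, 1, (40, 40)).cumsum(axis=0) / 3.0
        basis = np.tanh(guide / 2.0)
        out = local_linear_transform(basis, guide, guide, window_radius=5, regularizer=1e-9)
        rmse = np.sqrt(np.mean((out - basis) ** 2))
        assert rmse < 0.25 * basis.std()

    def test_window_larger_than_image_rejected(self):
        img = np.zeros((16, 16))
        with pytest.raises(DenoiseError):
            local_linear_transform(img, img, img, window_radius=20)


class TestPipeline:
    def test_noiseless_input_unchanged(self, noiseless_scout, model):
        out, report = denoise_pipeline(noiseless_scout, DenoiseConfig(), model=model)
        assert report.passthrough
        scale = np.abs(noiseless_scout.photoelectric_epl).max()
        np.testing.assert_allclose(
            out.photoelectric_epl, noiseless_scout.photoelectric_epl, atol=1e-3 * scale
        )

    def test_snr_increases_and_anticorrelation_shrinks(self, noisy_scout, model):
        _, report = denoise_pipeline(noisy_scout, DenoiseConfig(), model=model)
        assert report.snr_after["photoelectric"] >= report.snr_before["photoelectric"]
        assert abs(report.anticorrelation_after) < abs(report.anticorrelation_before)
        assert report.mean_abmd_shift_pct <= 2.0

    def test_minimum_noise_recombination_preserved(self, noisy_scout, model):
        out, report = denoise_pipeline(noisy_scout, DenoiseConfig(), model=model)
        w = report.weight
        recomb_raw = w * noisy_scout.photoelectric_epl + (1 - w) * noisy_scout.compton_epl
        recomb_den = w * out.photoelectric_epl + (1 - w) * out.compton_epl
        from skimage.restoration import estimate_sigma

        sigma_ph = estimate_sigma(noisy_scout.photoelectric_epl)
        assert np.abs(recomb_den - recomb_raw).max() < 0.5 * sigma_ph

    def test_flat_field_no_hallucination(self):
        """Pure-noise flat field: variance drops, mean stays (3 SE)."""
        rng = np.random.default_rng(8)
        n = (48, 64)
        noise = rng.normal(0, 1.0, n)
        pair = _pair(20.0 + noise, 20.0 - 0.5 * noise + 0.3 * rng.normal(0, 1, n))
        out, report = denoise_pipeline(pair, DenoiseConfig(noise_roi=(4, 44, 4, 60)))
        assert out.photoelectric_epl.var() < pair.photoelectric_epl.var()
        se = pair.photoelectric_epl.std() / np.sqrt(pair.photoelectric_epl.size)
        assert abs(out.photoelectric_epl.mean() - pair.photoelectric_epl.mean()) < 3 * se

    def test_anticorrelation_reduced_across_realizations(
        self, phantom_volume, small_geometry, model
    ):
        """|corr| shrinks in repeated noise realizations (subset here;
        the full 20-seed study runs in the acceptance suite)."""
        from sdexa.phantom import ScoutAcquisition, simulate_scout

        reduced = 0
        for seed in range(3):
            sc = simulate_scout(
                phantom_volume, small_geometry, ScoutAcquisition(seed=seed), model
            )
            _, rep = denoise_pipeline(sc, DenoiseConfig())
            if abs(rep.anticorrelation_after) < abs(rep.anticorrelation_before):
                reduced += 1
        assert reduced >= 2
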