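"""Phantom construction and acquisition simulation."""

import numpy as np
import pytest

from sdexa.decomp import DecompositionMatrix, decompose_image_domain
from sdexa.phantom import (
    LabeledVolume,
    PhantomError,
    PhantomSpec,
    ScoutAcquisition,
    VertebraSpec,
    build_phantom,
    default_vertebra_stack,
    generate_cohort,
    label_value,
    simulate_monoenergetic,
    simulate_scout,
)
from sdexa.projector import forward_project


class TestSpecs:
    def test_volume_shape_too_small_rejected(self):
        with pytest.raises(PhantomError):
            PhantomSpec(volume_shape=(8, 96, 48))

    def test_soft_tissue_density_bounds(self):
        with pytest.raises(PhantomError):
            PhantomSpec(soft_tissue_density=1.5)

    def test_trabecular_range_and_cortical_ordering(self):
        with pytest.raises(PhantomError):
            VertebraSpec(label="L1", center=(0, 0, 0), trabecular_hydroxyapatite=500.0)
        with pytest.raises(PhantomError):
            VertebraSpec(
                label="L1",
                center=(0, 0, 0),
                trabecular_hydroxyapatite=300.0,
                cortical_hydroxyapatite=200.0,
            )

    def test_overlapping_vertebrae_rejected(self):
        verts = (
            VertebraSpec(label="L1", center=(0.0, 20.0, 0.0)),
            VertebraSpec(label="L2", center=(0.0, 20.0, 10.0)),
        )
        with pytest.raises(PhantomError, match="overlap"):
            PhantomSpec(vertebrae=verts)

    def test_vertebra_outside_body_rejected(self):
        spec = PhantomSpec(
            body_ellipse=(40.0, 30.0),
            vertebrae=(VertebraSpec(label="L1", center=(0.0, 25.0, 0.0)),),
        )
        with pytest.raises(PhantomError, match="outside the body"):
            build_phantom(spec)


class TestBuildPhantom:
    def test_no_vertebrae_means_no_bone(self, body_only_volume):
        assert np.all(body_only_volume.hydroxyapatite_density == 0)

    def test_constant_trabecular_fill_is_exact(self, phantom_volume):
        sel = phantom_volume.labels == label_value("L1", "trabecular")
        assert sel.any()
        assert phantom_volume.hydroxyapatite_density[sel].mean() == 150.0

    def test_cylinder_volume_matches_analytic(self):
        v = VertebraSpec(
            label="L1",
            center=(0.0, 0.0, 0.0),
            body_radius=12.0,
            body_height=20.0,
            spinous_process_length=15.0,
        )
        spec = PhantomSpec(
            volume_shape=(80, 80, 40),
            voxel_spacing=(1.0, 1.0, 1.0),
            body_ellipse=(38.0, 38.0),
            vertebrae=(v,),
        )
        vol = build_phantom(spec)
        bone = (vol.labels == label_value("L1", "trabecular")) | (
            vol.labels == label_value("L1", "cortical")
        )
        voxel_volume = np.prod(spec.voxel_spacing)
        analytic = np.pi * v.body_radius**2 * v.body_height
        assert bone.sum() * voxel_volume == pytest.approx(analytic, rel=0.03)

    def test_determinism(self, phantom_spec):
        a = build_phantom(phantom_spec)
        b = build_phantom(phantom_spec)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.hydroxyapatite_density, b.hydroxyapatite_density)

    def test_labeled_volume_invariant_rejects_bone_in_soft_tissue(self):
        shape = (16, 16, 16)
        ha = np.zeros(shape)
        ha[0, 0, 0] = 50.0
        with pytest.raises(PhantomError):
            LabeledVolume(
                water_density=np.ones(shape),
                hydroxyapatite_density=ha,
                labels=np.ones(shape, dtype=np.int16),
                voxel_spacing=(1, 1, 1),
            )


class TestMonoenergetic:
    def test_zero_densities_give_zero_mu(self, model):
        shape = (16, 16, 16)
        vol = LabeledVolume(
            water_density=np.zeros(shape),
            hydroxyapatite_density=np.zeros(shape),
            labels=np.zeros(shape, dtype=np.int16),
            voxel_spacing=(1, 1, 1),
        )
        pair = simulate_monoenergetic(vol, model)
        assert np.all(pair.mu_50 == 0) and np.all(pair.mu_200 == 0)

    def test_pure_water_voxel_reproduces_mass_attenuation(self, model):
        shape = (16, 16, 16)
        vol = LabeledVolume(
            water_density=np.ones(shape),
            hydroxyapatite_density=np.zeros(shape),
            labels=np.ones(shape, dtype=np.int16),
            voxel_spacing=(1, 1, 1),
        )
        pair = simulate_monoenergetic(vol, model)
        assert pair.mu_50[0, 0, 0] == pytest.approx(
            float(model.mass_attenuation("water", 50.0)), abs=1e-14
        )

    def test_roundtrip_with_image_domain_decomposition(self, phantom_volume, model):
        pair = simulate_monoenergetic(phantom_volume, model)
        mats = decompose_image_domain(pair, DecompositionMatrix.from_model(model))
        np.testing.assert_allclose(
            mats.hydroxyapatite_density,
            phantom_volume.hydroxyapatite_density,
            atol=150.0 * 1e-8,
        )
        np.testing.assert_allclose(
            mats.water_density, phantom_volume.water_density, atol=1e-8
        )

    def test_noise_is_seeded(self, phantom_volume, model):
        a = simulate_monoenergetic(phantom_volume, model, noise_sigma=0.01, seed=7)
        b = simulate_monoenergetic(phantom_volume, model, noise_sigma=0.01, seed=7)
        assert np.array_equal(a.mu_50, b.mu_50)


class TestScout:
    def test_noiseless_limit_matches_basis_integrals(
        self, phantom_volume, small_geometry, model, noiseless_scout
    ):
        a_w = forward_project(
            phantom_volume.water_density, phantom_volume.voxel_spacing, small_geometry
        ).values
        a_b = forward_project(
            phantom_volume.hydroxyapatite_density / 1000.0,
            phantom_volume.voxel_spacing,
            small_geometry,
        ).values
        pc = np.einsum("ij,j...->i...", model.basis_coefficients, np.stack([a_w, a_b]))
        w_ph, w_co = model.water_epl_coefficients
        scale = np.abs(pc[0] / w_ph).max()
        np.testing.assert_allclose(
            noiseless_scout.photoelectric_epl, pc[0] / w_ph, atol=scale * 1e-6
        )
        np.testing.assert_allclose(
            noiseless_scout.compton_epl, pc[1] / w_co, atol=scale * 1e-6
        )

    def test_decomposition_noise_is_anticorrelated(self, body_only_volume, small_geometry, model):
        """Pooled over seeds, a homogeneous soft-tissue region shows strong
        photoelectric/Compton anticorrelation (>=1e4 pixels)."""
        ph_resid, co_resid = [], []
        ref = simulate_scout(
            body_only_volume, small_geometry, ScoutAcquisition(seed=0), model, noiseless=True
        )
        inside = ref.compton_epl > 0.5 * ref.compton_epl.max()
        n = 0
        seed = 0
        while n < 10_000:
            sc = simulate_scout(
                body_only_volume, small_geometry, ScoutAcquisition(seed=seed), model
            )
            ph_resid.append((sc.photoelectric_epl - ref.photoelectric_epl)[inside])
            co_resid.append((sc.compton_epl - ref.compton_epl)[inside])
            n += int(inside.sum())
            seed += 1
        r = np.corrcoef(np.concatenate(ph_resid), np.concatenate(co_resid))[0, 1]
        assert r < -0.5

    def test_seeds_change_noise_but_not_means(self, phantom_volume, small_geometry, model):
        a = simulate_scout(phantom_volume, small_geometry, ScoutAcquisition(seed=1), model)
        b = simulate_scout(phantom_volume, small_geometry, ScoutAcquisition(seed=2), model)
        assert not np.array_equal(a.photoelectric_epl, b.photoelectric_epl)
        diff = a.photoelectric_epl - b.photoelectric_epl
        se = diff.std() / np.sqrt(diff.size)
        assert abs(diff.mean()) < 3 * se * np.sqrt(2)

    def test_fixed_seed_reproducible(self, phantom_volume, small_geometry, model):
        a = simulate_scout(phantom_volume, small_geometry, ScoutAcquisition(seed=5), model)
        b = simulate_scout(phantom_volume, small_geometry, ScoutAcquisition(seed=5), model)
        assert np.array_equal(a.photoelectric_epl, b.photoelectric_epl)
        assert np.array_equal(a.compton_epl, b.compton_epl)


class TestCohort:
    def test_degenerate_range_gives_constant_cohort(self, small_geometry, model):
        members = generate_cohort(
            4,
            (80.0, 80.0),
            small_geometry,
            ScoutAcquisition(),
            seed=0,
            n_vertebrae=1,
            voxel_spacing=(3.0, 3.0, 3.0),
            model=model,
        )
        assert all(m.truth["vbmd"] == 80.0 for m in members)
        assert all(m.truth["status"] == "osteopenic" for m in members)

    def test_class_labels_partition_at_thresholds(self, small_geometry, model):
        members = generate_cohort(
            8,
            (40.0, 200.0),
            small_geometry,
            ScoutAcquisition(),
            seed=1,
            n_vertebrae=1,
            voxel_spacing=(3.0, 3.0, 3.0),
            model=model,
        )
        for m in members:
            v = m.truth["vbmd"]
            assert 40.0 <= v <= 200.0
            expected = (
                "osteoporotic" if v < 80 else "osteopenic" if v < 120 else "normal"
            )
            assert m.truth["status"] == expected

    def test_same_seed_bit_identical_truth(self, small_geometry, model):
        kw = dict(n_vertebrae=1, voxel_spacing=(3.0, 3.0, 3.0), model=model)
        a = generate_cohort(3, (40.0, 200.0), small_geometry, ScoutAcquisition(), seed=9, **kw)
        b = generate_cohort(3, (40.0, 200.0), small_geometry, ScoutAcquisition(), seed=9, **kw)
        assert [m.truth for m in a] == [m.truth for m in b]
        assert np.array_equal(a[0].scout.photoelectric_epl, b[0].scout.photoelectric_epl)

    def test_cohort_contracts(self, small_geometry):
        with pytest.raises(PhantomError):
            generate_cohort(1, (40.0, 200.0), small_geometry, ScoutAcquisition(), seed=0)
        with pytest.raises(PhantomError):
            generate_cohort(4, (10.0, 200.0), small_geometry, ScoutAcquisition(), seed=0)
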