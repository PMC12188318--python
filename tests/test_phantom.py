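import dataclasses

import numpy as np
import pytest

from livertrack.core import DisplacementField, SurfacePointCloud
from livertrack.phantom import (PhantomConfig, apply_dvf, build_motion_model,
                                make_augmentation_plan, make_phantom,
                                make_phase_dvfs, synthesize_dvf)
from livertrack.projector import RoiSpec, compute_cnr


class TestMakePhantom:
    def test_deterministic_given_seed(self):
        cfg = PhantomConfig(grid=20, spacing_mm=8.0, n_surface_nodes=50, seed=3)
        a, b = make_phantom(cfg), make_phantom(cfg)
        np.testing.assert_array_equal(a.volume, b.volume)
        np.testing.assert_array_equal(a.liver_cloud.coords, b.liver_cloud.coords)
        np.testing.assert_array_equal(a.tumor_points, b.tumor_points)

    def test_tumor_outside_liver_raises(self):
        cfg = PhantomConfig(grid=20, spacing_mm=8.0,
                            tumor_radius_mm=60.0)  # larger than minor axis
        with pytest.raises(ValueError, match="tumor"):
            make_phantom(cfg)

    def test_zero_contrast_removes_liver_signal_exactly(self, small_phantom):
        # with the same seed, the contrast knob adds exactly
        # contrast * sigma inside the liver mask and nothing else
        cfg0 = dataclasses.replace(small_phantom.config, contrast=0.0)
        ph0 = make_phantom(cfg0)
        ph2 = small_phantom
        mask = ph2.liver_label.astype(bool) & (ph2.volume > 0)
        delta = ph2.volume - ph0.volume
        sigma = ph2.config.background_sigma
        np.testing.assert_allclose(delta[mask], 2.0 * sigma, atol=1e-15)
        outside = ~ph2.liver_label.astype(bool)
        np.testing.assert_allclose(delta[outside], 0.0, atol=1e-15)

    def test_liver_has_distinct_intensity_and_nodes_on_boundary(self, small_phantom):
        ph = small_phantom
        inside = ph.volume[ph.liver_label.astype(bool)]
        body = (ph.volume > 0) & ~ph.liver_label.astype(bool)
        assert inside.mean() > ph.volume[body].mean()
        rho = ph.shape.normalized_radius(ph.liver_cloud.coords)
        assert np.allclose(rho, 1.0, atol=1e-9)  # nodes on the analytic surface
        # tumor strictly inside
        assert np.all(ph.shape.normalized_radius(ph.tumor_points) < 1.0)


class TestMotionModel:
    def test_degenerate_identical_inputs(self, small_phantom):
        n = small_phantom.liver_cloud.n_nodes
        field = DisplacementField(np.tile([1.0, 2.0, -3.0], (n, 1)))
        model = build_motion_model([field] * 5, n_components=3)
        np.testing.assert_allclose(model.mean, field.vectors)
        assert model.singular_values == pytest.approx(np.zeros(3), abs=1e-9)

    def test_too_few_phases_raises(self, small_phantom):
        n = small_phantom.liver_cloud.n_nodes
        f = DisplacementField(np.zeros((n, 3)))
        with pytest.raises(ValueError):
            build_motion_model([f, f, f], n_components=3)

    def test_recovers_known_component_subspace(self, rng):
        # fields built as D0 + a*C1 + b*C2 with orthonormal C1, C2: the
        # recovered 2-component subspace must align with span(C1, C2)
        n = 40
        d0 = rng.normal(size=3 * n)
        c = np.linalg.qr(rng.normal(size=(3 * n, 2)))[0].T  # orthonormal rows
        fields = [DisplacementField(
            (d0 + a * c[0] + b * c[1]).reshape(n, 3))
            for a, b in [(1, 0), (0, 1), (2, -1), (-1, 2), (0.5, 0.5), (3, 1)]]
        model = build_motion_model(fields, n_components=2)
        comps = model.components.reshape(2, -1)
        # principal angles between recovered and true subspaces
        sv = np.linalg.svd(comps @ c.T, compute_uv=False)
        angles = np.arccos(np.clip(sv, -1, 1))
        assert np.all(angles < 1e-6)

    def test_full_rank_reconstruction(self, small_phantom):
        dvfs = make_phase_dvfs(small_phantom)
        model = build_motion_model(dvfs, n_components=len(dvfs) - 1)
        for p, d in enumerate(dvfs):
            recon = synthesize_dvf(
                model, np.concatenate([[1.0], model.phase_weights[p]]))
            rms = np.sqrt(np.mean((recon.vectors - d.vectors) ** 2))
            assert rms < 1e-8

    def test_components_orthonormal_and_variance_explained(self, small_phantom):
        dvfs = make_phase_dvfs(small_phantom)
        model = build_motion_model(dvfs, n_components=3)
        flat = model.components.reshape(3, -1)
        np.testing.assert_allclose(flat @ flat.T, np.eye(3), atol=1e-10)
        X = np.stack([d.vectors.ravel() for d in dvfs])
        Xc = X - X.mean(axis=0)
        total = (Xc**2).sum()
        explained = (model.singular_values**2).sum()
        assert explained / total >= 0.999

    def test_synthesize_is_linear(self, small_phantom, rng):
        dvfs = make_phase_dvfs(small_phantom)
        model = build_motion_model(dvfs)
        w, v = rng.normal(size=4), rng.normal(size=4)
        a, b = 0.7, -1.3
        lhs = synthesize_dvf(model, a * w + b * v).vectors
        rhs = (a * synthesize_dvf(model, w).vectors
               + b * synthesize_dvf(model, v).vectors)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_synthesize_against_explicit_sum(self, small_phantom, rng):
        model = build_motion_model(make_phase_dvfs(small_phantom))
        w = rng.normal(size=4)
        expected = w[0] * model.mean.copy()
        for i in range(3):
            expected = expected + w[1 + i] * model.components[i]
        np.testing.assert_allclose(synthesize_dvf(model, w).vectors, expected,
                                   atol=1e-13)


class TestAugmentationPlan:
    def test_study_expansion_counts(self):
        plan = make_augmentation_plan(seed=0)
        assert plan.n_deformations("train") == 768
        assert plan.n_deformations("val") == 384
        assert plan.n_volumes("train") == 3072
        assert plan.n_volumes("val") == 1536
        assert plan.n_deformations("test") == 45
        assert plan.n_volumes("test") == 135

    def test_counts_seed_independent_but_values_vary(self):
        a, b = make_augmentation_plan(seed=1), make_augmentation_plan(seed=2)
        for split in ("train", "val", "test"):
            assert a.n_volumes(split) == b.n_volumes(split)
        assert a.entries[0].scales != b.entries[0].scales

    def test_coefficients_and_translations_within_ranges(self):
        plan = make_augmentation_plan(seed=5)
        for e in plan.entries:
            s = np.asarray(e.scales)
            t = np.asarray(e.translation)
            if e.split == "test":
                assert s[0] == 1.0
                assert np.all(s[1:3] >= 0.0) and np.all(s[1:3] <= 4.0)
                assert 0.0 <= s[3] <= 2.0
                assert np.all(t >= 0.0) and np.all(t <= 10.0)
                assert np.any(t > 0.0)  # zero-shift volumes are discarded
            else:
                assert 0.95 <= s[0] <= 1.05
                assert np.all(s[1:3] >= -1.5) and np.all(s[1:3] <= 3.0)
                assert -1.5 <= s[3] <= 1.5
                assert np.all(np.abs(t) <= 6.0)

    def test_empty_phase_lists_give_empty_plan(self):
        plan = make_augmentation_plan(trainval_phases=(), test_phases=())
        assert plan.n_volumes() == 0

    def test_malformed_range_raises(self):
        with pytest.raises(ValueError):
            make_augmentation_plan(trainval_ranges=((1.0, 0.5), (0, 1), (0, 1),
                                                    (0, 1)))

    def test_json_round_trip(self, tmp_path):
        plan = make_augmentation_plan(seed=3)
        path = tmp_path / "plan.json"
        plan.to_json(path)
        back = type(plan).from_json(path)
        assert back.entries == plan.entries


class TestApplyDvf:
    def test_identity_and_pure_shift(self, small_phantom):
        cloud = small_phantom.liver_cloud
        zero = DisplacementField(np.zeros_like(cloud.coords))
        np.testing.assert_array_equal(apply_dvf(cloud, zero).coords,
                                      cloud.coords)
        moved = apply_dvf(cloud, zero, (0.0, 0.0, 5.0))
        np.testing.assert_allclose(moved.coords - cloud.coords,
                                   np.tile([0, 0, 5.0], (cloud.n_nodes, 1)))

    def test_apply_then_negated_restores(self, small_phantom, rng):
        cloud = small_phantom.liver_cloud
        dvf = DisplacementField(rng.normal(size=cloud.coords.shape))
        back = apply_dvf(apply_dvf(cloud, dvf), -dvf)
        np.testing.assert_allclose(back.coords, cloud.coords, atol=1e-12)

    def test_node_count_mismatch_raises(self, small_phantom):
        with pytest.raises(ValueError):
            apply_dvf(small_phantom.liver_cloud,
                      DisplacementField(np.zeros((3, 3))))
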