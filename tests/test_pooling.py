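import numpy as np
import pytest

from livertrack.autodiff import Tensor
from livertrack.core import SurfacePointCloud
from livertrack.pooling import (BackboneConfig, FeatureExtractor, FeatureStack,
                                extract_feature_stack, global_features,
                                pool_features)
from livertrack.projector import ConeBeamGeometry, ProjectionImage, project_points


@pytest.fixture(scope="module")
def tiny_extractor():
    return FeatureExtractor(BackboneConfig.tiny((8, 16, 32)),
                            np.random.default_rng(0))


class TestBackbone:
    def test_default_config_totals_3840_channels(self):
        cfg = BackboneConfig()
        assert cfg.total_channels == 3840
        assert cfg.downscales == (4, 8, 16, 32)
        # 50 layers: stem conv + 3 convs per bottleneck block (3+4+6+3=16
        # blocks) + the regression head on top in downstream models
        assert 1 + 3 * sum(cfg.stage_blocks) + 1 == 50

    def test_tiny_config_shapes_and_total(self, tiny_extractor, desk_geometry):
        proj = ProjectionImage(np.zeros((48, 64)), desk_geometry)
        stack = extract_feature_stack(proj, tiny_extractor)
        assert stack.total_channels == 56
        assert stack.downscales == (1, 2, 4)
        assert [m.data.shape for m in stack.maps] == [
            (8, 48, 64), (16, 24, 32), (32, 12, 16)]

    def test_deterministic_given_weights(self, tiny_extractor, desk_geometry,
                                         rng):
        proj = ProjectionImage(rng.uniform(0, 3, (48, 64)), desk_geometry)
        a = extract_feature_stack(proj, tiny_extractor)
        b = extract_feature_stack(proj, tiny_extractor)
        for ma, mb in zip(a.maps, b.maps):
            np.testing.assert_array_equal(ma.data, mb.data)

    def test_nonfinite_input_rejected(self, tiny_extractor, desk_geometry):
        bad = np.zeros((48, 64))
        bad[0, 0] = np.inf
        with pytest.raises(ValueError):
            extract_feature_stack(ProjectionImage(bad, desk_geometry),
                                  tiny_extractor)


def _stack_from_arrays(arrays, downscales):
    return FeatureStack(maps=[Tensor(a) for a in arrays],
                        downscales=tuple(downscales))


class TestPoolFeatures:
    def test_constant_map_pools_constant(self, desk_geometry, small_phantom):
        stack = _stack_from_arrays([np.full((2, 48, 64), 7.0)], [1])
        pooled = pool_features(stack, desk_geometry, small_phantom.liver_cloud)
        inview = pooled.valid
        assert inview.any()
        np.testing.assert_allclose(pooled.data[inview], 7.0, atol=1e-12)
        np.testing.assert_allclose(pooled.data[~inview], 0.0)

    def test_hand_bilinear_2x2(self, desk_geometry):
        # a node projecting to pixel coordinate (0.5, 0.5) on a 2x2 map
        # [[0,1],[2,3]] pools (0+1+2+3)/4 = 1.5
        geom = ConeBeamGeometry(source_to_axis_mm=400.0,
                                source_to_detector_mm=700.0, detector_cols=2,
                                detector_rows=2, pixel_pitch_mm=10.0)
        m = np.array([[[0.0, 1.0], [2.0, 3.0]]])
        stack = _stack_from_arrays([m], [1])
        # pick the 3D point that lands exactly at (0.5, 0.5): u_mm = 0
        # means x = 0; row offset 0.5 px -> v_mm = 0 likewise at center
        cloud = SurfacePointCloud(np.zeros((4, 3)))
        pooled = pool_features(stack, geom, cloud)
        np.testing.assert_allclose(pooled.data, 1.5, atol=1e-12)

    def test_integer_pixel_returns_that_pixel(self, rng):
        geom = ConeBeamGeometry(source_to_axis_mm=400.0,
                                source_to_detector_mm=800.0, detector_cols=9,
                                detector_rows=7, pixel_pitch_mm=5.0)
        m = rng.normal(size=(3, 7, 9))
        stack = _stack_from_arrays([m], [1])
        # detector center pixel is (4, 3); the isocenter projects there
        pooled = pool_features(stack, geom, SurfacePointCloud(np.zeros((4, 3))))
        np.testing.assert_allclose(pooled.data, np.tile(m[:, 3, 4], (4, 1)),
                                   atol=1e-12)

    def test_matches_per_node_loop_oracle(self, desk_geometry, small_phantom,
                                          rng):
        arrays = [rng.normal(size=(4, 48, 64)), rng.normal(size=(6, 24, 32))]
        stack = _stack_from_arrays(arrays, [1, 2])
        cloud = small_phantom.liver_cloud
        pooled = pool_features(stack, desk_geometry, cloud)
        uv, valid = project_points(desk_geometry, cloud.coords)
        for i in range(cloud.n_nodes):
            if not valid[i]:
                np.testing.assert_array_equal(pooled.data[i], 0.0)
                continue
            row = []
            for arr, ds in zip(arrays, [1, 2]):
                u, v = uv[i] / ds
                C, H, W = arr.shape
                u = min(max(u, 0), W - 1)
                v = min(max(v, 0), H - 1)
                u0, v0 = int(min(np.floor(u), W - 2)), int(min(np.floor(v),
                                                              H - 2))
                fu, fv = u - u0, v - v0
                val = (arr[:, v0, u0] * (1 - fu) * (1 - fv)
                       + arr[:, v0, u0 + 1] * fu * (1 - fv)
                       + arr[:, v0 + 1, u0] * (1 - fu) * fv
                       + arr[:, v0 + 1, u0 + 1] * fu * fv)
                row.append(val)
            np.testing.assert_allclose(pooled.data[i], np.concatenate(row),
                                       atol=1e-6)

    def test_pooled_values_within_map_range(self, desk_geometry,
                                            small_phantom, rng):
        arr = rng.normal(size=(5, 48, 64))
        stack = _stack_from_arrays([arr], [1])
        pooled = pool_features(stack, desk_geometry, small_phantom.liver_cloud)
        ok = pooled.valid
        assert np.all(pooled.data[ok] >= arr.min() - 1e-12)
        assert np.all(pooled.data[ok] <= arr.max() + 1e-12)

    def test_joint_rotation_equivariance(self, small_phantom, tiny_extractor,
                                         rng):
        geom = ConeBeamGeometry(source_to_axis_mm=400.0,
                                source_to_detector_mm=700.0, detector_cols=64,
                                detector_rows=48, pixel_pitch_mm=6.0)
        proj = ProjectionImage(rng.uniform(0, 2, (48, 48 + 16)), geom)
        stack = extract_feature_stack(proj, tiny_extractor)
        cloud = small_phantom.liver_cloud
        theta = 73.0
        t = np.deg2rad(theta)
        R = np.array([[np.cos(t), -np.sin(t), 0],
                      [np.sin(t), np.cos(t), 0], [0, 0, 1.0]])
        a = pool_features(stack, geom.with_angle(theta),
                          SurfacePointCloud(cloud.coords @ R.T))
        b = pool_features(stack, geom, cloud)
        np.testing.assert_allclose(a.data, b.data, atol=1e-9)

    def test_out_of_view_warning(self, desk_geometry, tiny_extractor):
        proj = ProjectionImage(np.zeros((48, 64)), desk_geometry)
        stack = extract_feature_stack(proj, tiny_extractor)
        far = SurfacePointCloud(np.tile([2000.0, 0.0, 0.0], (10, 1)))
        with pytest.warns(UserWarning, match="outside"):
            pool_features(stack, desk_geometry, far)


def test_global_features_tile_spatial_means(rng):
    arrays = [rng.normal(size=(3, 6, 8)), rng.normal(size=(5, 3, 4))]
    stack = _stack_from_arrays(arrays, [1, 2])
    out = global_features(stack, n_nodes=7)
    expected = np.concatenate([a.mean(axis=(1, 2)) for a in arrays])
    np.testing.assert_allclose(out.data, np.tile(expected, (7, 1)), atol=1e-12)
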