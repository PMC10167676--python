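"""Noise-perturbation sensitivity maps, accumulation semantics, ROI extraction."""

import numpy as np
import pytest

from dbmorph.autoencoder import build_autoencoder
from dbmorph.classifier import build_classifier
from dbmorph.perturbation import (RegionOfInterest, SensitivityMap,
                                  SubsampledFilter, classification_error,
                                  extract_rois, group_importance, make_filters,
                                  perturb, roi_mean_jacobian, sensitivity_map)


class TestMakeFilters:
    def test_zero_filters_empty(self):
        assert make_filters((10, 10, 10), n_filters=0) == []

    def test_origins_enumerate_valid_positions(self):
        """dims 10 with extent 8 leaves exactly origins {0, 1, 2} on that axis."""
        filters = make_filters((10, 8, 8), n_filters=600, extent=(8, 8, 8),
                               seed=0)
        xs = {f.origin[0] for f in filters}
        assert xs == {0, 1, 2}
        assert all(f.origin[1] == 0 and f.origin[2] == 0 for f in filters)

    def test_noise_is_standard_normal(self):
        filters = make_filters((12, 12, 12), n_filters=40, extent=(8, 8, 8),
                               seed=1)
        pooled = np.concatenate([f.noise_block.ravel() for f in filters])
        assert len(pooled) >= 10_000
        assert abs(pooled.mean()) < 0.02
        assert abs(pooled.std() - 1.0) < 0.02

    def test_extent_larger_than_dims_rejected(self):
        with pytest.raises(ValueError):
            make_filters((6, 6, 6), n_filters=1, extent=(8, 8, 8))

    def test_deterministic_given_seed(self):
        a = make_filters((12, 12, 12), n_filters=5, seed=3, extent=(8, 8, 8))
        b = make_filters((12, 12, 12), n_filters=5, seed=3, extent=(8, 8, 8))
        for fa, fb in zip(a, b):
            assert fa.origin == fb.origin
            np.testing.assert_array_equal(fa.noise_block, fb.noise_block)

    def test_coverage_of_interior_voxels_at_scale(self):
        """Many filters visit essentially every interior voxel (border
        voxels have few valid block origins and are visited more rarely)."""
        dims = (20, 20, 20)
        filters = make_filters(dims, n_filters=500, extent=(8, 8, 8), seed=2)
        visits = np.zeros(dims)
        for f in filters:
            visits[f.slices()] += 1
        interior = visits[7:13, 7:13, 7:13]
        assert (interior > 0).mean() >= 0.99
        assert (visits > 0).mean() >= 0.95


class TestPerturb:
    def test_zero_noise_is_identity(self, rng):
        x = rng.random((10, 10, 10))
        k = SubsampledFilter((2, 3, 4), (2, 2, 2), np.zeros((2, 2, 2)))
        np.testing.assert_array_equal(perturb(x, k), x)

    def test_locality_exactly_eight_voxels(self):
        x = np.zeros((6, 6, 6))
        k = SubsampledFilter((0, 0, 0), (2, 2, 2), np.ones((2, 2, 2)))
        out = perturb(x, k)
        assert (out == 1.0).sum() == 8
        assert out.sum() == 8.0

    def test_sum_conservation(self, rng):
        x = rng.random((10, 10, 10))
        block = rng.standard_normal((3, 3, 3))
        k = SubsampledFilter((4, 5, 6), (3, 3, 3), block)
        out = perturb(x, k)
        assert out.sum() - x.sum() == pytest.approx(block.sum(), rel=1e-10)

    def test_out_of_bounds_rejected(self, rng):
        x = rng.random((6, 6, 6))
        k = SubsampledFilter((5, 5, 5), (2, 2, 2), np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            perturb(x, k)


class TestClassificationError:
    @pytest.mark.parametrize("y_star,y,expected", [
        (1.0, 0.6, 0.4), (0.0, 0.3, -0.3), (0.7, 0.7, 0.0)])
    def test_signed_difference(self, y_star, y, expected):
        assert classification_error(y_star, y) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classification_error(1.2, 0.5)


def _tiny_models(seed=0, zero=False):
    ae = build_autoencoder((8, 8, 8), latent_channels=4, seed=seed)
    cnn = build_classifier((1, 1, 1), latent_channels=4, seed=seed)
    # a 1x1x1 latent cannot feed a 3x3x3 conv; use (24,...) instead
    return ae, cnn


def _models_for(dims=(24, 24, 24), seed=0, zero_weights=False):
    ae = build_autoencoder(dims, latent_channels=4, seed=seed)
    cnn = build_classifier((3, 3, 3), latent_channels=4, seed=seed)
    if zero_weights:
        for p in cnn.net.params:
            p.value[...] = 0.0
    return ae, cnn


class TestSensitivityMap:
    def test_constant_classifier_gives_identically_zero_map(self, rng):
        """Zero-weight classifier predicts 0.5 everywhere: every error is 0."""
        ae, cnn = _models_for(zero_weights=True)
        x = rng.random((24, 24, 24))
        filters = make_filters((24, 24, 24), n_filters=30, extent=(8, 8, 8),
                               seed=0)
        m = sensitivity_map(x, 0.5, filters, ae, cnn)
        assert np.all(m.normalized == 0.0)
        assert m.visits.sum() == 30 * 512

    def test_single_filter_hand_oracle(self, rng):
        """One filter: the map equals the scalar error inside the block and
        zero outside — computed here by hand from the same forward calls."""
        from dbmorph.classifier import predict_batch
        ae, cnn = _models_for(seed=5)
        x = rng.random((24, 24, 24))
        filters = make_filters((24, 24, 24), n_filters=1, extent=(8, 8, 8),
                               seed=7)
        y_star = 0.8
        m = sensitivity_map(x, y_star, filters, ae, cnn)
        z = ae.encoder.forward(perturb(x, filters[0])[None, None], train=False)
        e = y_star - float(predict_batch(cnn, z)[0])
        sl = filters[0].slices()
        inside = np.zeros((24, 24, 24), dtype=bool)
        inside[sl] = True
        np.testing.assert_allclose(m.normalized[inside], e, rtol=1e-12)
        assert np.all(m.normalized[~inside] == 0.0)

    def test_accumulation_conservation(self, rng):
        """sum(accum) equals the sum over filters of error x block volume."""
        from dbmorph.classifier import predict_batch
        ae, cnn = _models_for(seed=2)
        x = rng.random((24, 24, 24))
        filters = make_filters((24, 24, 24), n_filters=20, extent=(4, 4, 4),
                               seed=3)
        y_star = 0.6
        m = sensitivity_map(x, y_star, filters, ae, cnn)
        total = 0.0
        for k in filters:
            z = ae.encoder.forward(perturb(x, k)[None, None], train=False)
            total += (y_star - float(predict_batch(cnn, z)[0])) * 64
        assert m.accum.sum() == pytest.approx(total, rel=1e-9)

    def test_batching_does_not_change_result(self, rng):
        ae, cnn = _models_for(seed=3)
        x = rng.random((24, 24, 24))
        filters = make_filters((24, 24, 24), n_filters=10, extent=(8, 8, 8),
                               seed=4)
        a = sensitivity_map(x, 0.5, filters, ae, cnn, batch_size=3)
        b = sensitivity_map(x, 0.5, filters, ae, cnn, batch_size=10)
        np.testing.assert_allclose(a.normalized, b.normalized, atol=1e-12)

    def test_empty_filters_rejected(self, rng):
        ae, cnn = _models_for()
        with pytest.raises(ValueError):
            sensitivity_map(rng.random((24, 24, 24)), 0.5, [], ae, cnn)


class TestGroupImportance:
    def _map(self, field):
        return SensitivityMap(accum=field, visits=np.ones_like(field))

    def test_identical_maps_mean_is_that_map(self, rng):
        f = rng.normal(size=(4, 4, 4))
        case, ctrl = group_importance([self._map(f)] * 2 + [self._map(f)],
                                      [1, 1, 0])
        np.testing.assert_allclose(case, f)
        np.testing.assert_allclose(ctrl, f)

    def test_opposite_maps_cancel(self, rng):
        f = rng.normal(size=(3, 3, 3))
        case, _ = group_importance(
            [self._map(f), self._map(-f), self._map(np.zeros_like(f))],
            [1, 1, 0])
        np.testing.assert_allclose(case, 0.0, atol=1e-15)

    def test_matches_loop_oracle(self, rng):
        maps = [self._map(rng.normal(size=(3, 3, 3))) for _ in range(5)]
        labels = [1, 0, 1, 0, 1]
        case, ctrl = group_importance(maps, labels)
        expected = np.zeros((3, 3, 3))
        for m, l in zip(maps, labels):
            if l == 1:
                expected += m.normalized / 3
        np.testing.assert_allclose(case, expected, rtol=1e-12)

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError):
            group_importance([self._map(rng.normal(size=(2, 2, 2)))], [1])


class TestExtractRois:
    def test_zero_map_gives_no_rois(self):
        assert extract_rois(np.zeros((8, 8, 8))) == []

    def test_single_cube_single_roi(self):
        m = np.zeros((10, 10, 10))
        m[2:5, 2:5, 2:5] = 0.3
        rois = extract_rois(m, threshold=0.25, min_size=27)
        assert len(rois) == 1
        assert rois[0].size == 27
        assert rois[0].sign == "case_important"

    def test_corner_touching_cubes_match_flood_fill(self):
        """Two cubes of opposite sign touching only at a corner: component
        count must equal an independent 26-connectivity flood fill."""
        m = np.zeros((10, 10, 10))
        m[2:4, 2:4, 2:4] = 0.3
        m[4:6, 4:6, 4:6] = -0.3

        def flood_count(mask):
            seen = np.zeros_like(mask, dtype=bool)
            count = 0
            for start in np.argwhere(mask):
                if seen[tuple(start)]:
                    continue
                count += 1
                stack = [tuple(start)]
                seen[tuple(start)] = True
                while stack:
                    i, j, k = stack.pop()
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            for dk in (-1, 0, 1):
                                p = (i + di, j + dj, k + dk)
                                if all(0 <= c < 10 for c in p) and mask[p] \
                                        and not seen[p]:
                                    seen[p] = True
                                    stack.append(p)
            return count

        expected = flood_count(np.abs(m) >= 0.25)
        rois = extract_rois(m, threshold=0.25, min_size=1)
        assert len(rois) == expected

    def test_small_components_dropped(self):
        m = np.zeros((10, 10, 10))
        m[1, 1, 1] = 0.9
        assert extract_rois(m, min_size=27) == []

    def test_negative_component_signed_control(self):
        m = np.zeros((8, 8, 8))
        m[2:5, 2:5, 2:5] = -0.4
        rois = extract_rois(m, min_size=1)
        assert rois[0].sign == "control_important"


class TestRoiMeanJacobian:
    def _roi(self, dims, sel):
        v = np.zeros(dims, dtype=bool)
        v[sel] = True
        return RegionOfInterest(1, v, "case_important")

    def test_constant_volume(self):
        roi = self._roi((4, 4, 4), (slice(0, 2),))
        assert roi_mean_jacobian(np.full((4, 4, 4), 0.7), roi) == pytest.approx(0.7)

    def test_two_voxel_mean(self):
        v = np.zeros((3, 3, 3))
        v[0, 0, 0], v[0, 0, 1] = 0.2, 0.4
        roi_mask = np.zeros((3, 3, 3), dtype=bool)
        roi_mask[0, 0, :2] = True
        roi = RegionOfInterest(1, roi_mask, "case_important")
        assert roi_mean_jacobian(v, roi) == pytest.approx(0.3)

    def test_matches_loop_oracle(self, rng):
        data = rng.random((5, 5, 5))
        sel = rng.random((5, 5, 5)) < 0.3
        sel[0, 0, 0] = True
        roi = RegionOfInterest(1, sel, "case_important")
        total, count = 0.0, 0
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    if sel[i, j, k]:
                        total += data[i, j, k]
                        count += 1
        assert roi_mean_jacobian(data, roi) == pytest.approx(total / count)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            RegionOfInterest(1, np.zeros((2, 2, 2), dtype=bool), "case_important")
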