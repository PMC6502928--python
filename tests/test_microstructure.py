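"""Voxel classification, dual-reconstruction fusion, collagen quantification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from cardioxpci import Volume3D
from cardioxpci import microstructure as micro
from cardioxpci.pipeline import classify_and_fuse

LBL = micro


class TestFeatureStack:
    def test_constant_volume_has_zero_derivative_features(self):
        v = Volume3D(np.full((16, 16, 16), 0.3, dtype=np.float32), 1.0)
        f = micro.compute_feature_stack(v, scales=(1.0, 2.0))
        # feature 0 is raw intensity; each scale contributes
        # [smooth, gradmag, laplace, hess_e1, hess_e2, hess_e3]
        for s in range(2):
            block = f.data[..., 1 + 6 * s: 1 + 6 * (s + 1)]
            # float32 separable filtering leaves ~1e-4 rounding residue
            assert np.abs(block[..., 1:]).max() < 1e-3   # all but smooth
            np.testing.assert_allclose(block[..., 0], 0.3, atol=1e-5)

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        v = Volume3D(rng.random((12, 12, 12)).astype(np.float32), 1.0)
        a = micro.compute_feature_stack(v, scales=(1.0,))
        b = micro.compute_feature_stack(v, scales=(1.0,))
        np.testing.assert_array_equal(a.data, b.data)

    def test_laplacian_matches_direct_log_convolution(self):
        """Laplacian feature equals convolution with an explicit LoG kernel."""
        impulse = np.zeros((21, 21, 21), dtype=np.float32)
        impulse[10, 10, 10] = 1.0
        f = micro.compute_feature_stack(Volume3D(impulse, 1.0), scales=(1.0,))
        lap_feature = f.data[..., 3]  # [raw, smooth, gradmag, laplace, ...]
        kernel = np.zeros((21, 21, 21))
        kernel[10, 10, 10] = 1.0
        log_kernel = ndimage.gaussian_laplace(kernel, 1.0)
        assert np.abs(lap_feature - log_kernel).max() < 1e-8

    def test_small_scale_rejected(self):
        v = Volume3D(np.zeros((8, 8, 8), dtype=np.float32), 1.0)
        with pytest.raises(ValueError, match="0.5"):
            micro.compute_feature_stack(v, scales=(0.25,))


class TestSparseLabels:
    def test_conflicting_duplicate_rejected(self):
        with pytest.raises(ValueError, match="[Cc]onflict"):
            micro.SparseLabels(np.array([[1, 1, 1], [1, 1, 1]]),
                               np.array([1, 2]))

    def test_consistent_duplicate_allowed(self):
        labels = micro.SparseLabels(np.array([[1, 1, 1], [1, 1, 1]]),
                                    np.array([2, 2]))
        assert len(labels.coords) == 2

    def test_out_of_bounds_rejected(self):
        labels = micro.SparseLabels(np.array([[9, 0, 0]]), np.array([1]))
        with pytest.raises(ValueError, match="bounds"):
            labels.validate_bounds((8, 8, 8))


class TestClassifier:
    @pytest.fixture(scope="class")
    def trained(self, collagen_phantom_small):
        retr, nonretr, gt = collagen_phantom_small
        labels = micro.sample_sparse_labels(gt.labels, n_per_class=1500,
                                            seed=11)
        f = micro.compute_feature_stack(nonretr, scales=(1.0, 2.0))
        clf = micro.train_voxel_classifier(f, labels, seed=11)
        return f, clf, labels, gt

    def test_missing_class_rejected(self, collagen_phantom_small):
        retr, _, _ = collagen_phantom_small
        f = micro.compute_feature_stack(retr, scales=(1.0,))
        labels = micro.SparseLabels(np.array([[1, 1, 1], [2, 2, 2]]),
                                    np.array([0, 0]))
        with pytest.raises(ValueError, match="missing.*collagen"):
            micro.train_voxel_classifier(f, labels)

    def test_training_labels_reproduced(self, trained):
        f, clf, labels, _ = trained
        pred = micro.classify_volume(clf, f)
        agree = pred.data[tuple(labels.coords.T)] == labels.classes
        assert agree.mean() >= 0.95

    def test_fixed_seed_gives_identical_predictions(self, trained):
        f, clf, labels, _ = trained
        clf2 = micro.train_voxel_classifier(f, labels, seed=11)
        a = micro.classify_volume(clf, f)
        b = micro.classify_volume(clf2, f)
        np.testing.assert_array_equal(a.data, b.data)

    def test_collagen_dice_on_nonretrieved_rendering(self, trained):
        f, clf, _, gt = trained
        pred = micro.classify_volume(clf, f)
        a = pred.data == micro.LBL_COLLAGEN
        b = gt.labels == micro.LBL_COLLAGEN
        dice = 2.0 * np.sum(a & b) / (a.sum() + b.sum())
        assert dice > 0.8

    def test_cell_background_dice_on_retrieved_rendering(
            self, collagen_phantom_small):
        retr, _, gt = collagen_phantom_small
        labels = micro.sample_sparse_labels(gt.labels, n_per_class=1500,
                                            seed=11)
        f = micro.compute_feature_stack(retr, scales=(1.0, 2.0))
        clf = micro.train_voxel_classifier(f, labels, seed=11)
        pred = micro.classify_volume(clf, f)
        a = pred.data == micro.LBL_CARDIOMYOCYTE
        b = gt.labels == micro.LBL_CARDIOMYOCYTE
        dice = 2.0 * np.sum(a & b) / (a.sum() + b.sum())
        assert dice > 0.9

    def test_scale_mismatch_rejected(self, trained):
        _, clf, _, _ = trained
        v = Volume3D(np.zeros((8, 8, 8), dtype=np.float32), 1.0)
        f_other = micro.compute_feature_stack(v, scales=(1.0,))
        with pytest.raises(ValueError, match="scales"):
            micro.classify_volume(clf, f_other)

    def test_incremental_retraining_accepts_new_labels(self, trained):
        f, clf, labels, gt = trained
        extra = micro.sample_sparse_labels(gt.labels, n_per_class=100, seed=99)
        clf2 = clf.add_labels(f, extra)
        assert len(clf2.train_coords) == len(labels.coords) + len(extra.coords)
        pred = micro.classify_volume(clf2, f)
        assert pred.data.shape == gt.labels.shape


class TestFusion:
    @pytest.mark.parametrize("non,ret,expected", [
        (0, 0, 0), (0, 1, 1), (0, 2, 1),
        (1, 0, 0), (1, 1, 1), (1, 2, 1),
        (2, 0, 2), (2, 1, 2), (2, 2, 2),
    ])
    def test_truth_table(self, non, ret, expected):
        """Collagen from non-retrieved; cell/background from retrieved."""
        a = micro.LabelVolume(np.full((1, 1, 1), non, dtype=np.uint8))
        b = micro.LabelVolume(np.full((1, 1, 1), ret, dtype=np.uint8))
        assert micro.fuse_segmentations(a, b).data[0, 0, 0] == expected

    def test_identical_inputs_are_fixed_point(self):
        rng = np.random.default_rng(0)
        lab = micro.LabelVolume(
            rng.integers(0, 3, (6, 6, 6)).astype(np.uint8))
        out = micro.fuse_segmentations(lab, lab)
        out2 = micro.fuse_segmentations(out, out)
        np.testing.assert_array_equal(out.data, out2.data)

    def test_orphan_collagen_uses_probabilities(self):
        a = micro.LabelVolume(np.full((1, 1, 1), 1, dtype=np.uint8))
        b = micro.LabelVolume(np.full((1, 1, 1), 2, dtype=np.uint8))
        prob = np.zeros((1, 1, 1, 3), dtype=np.float32)
        prob[..., 0] = 0.6  # background more likely than cardiomyocyte
        prob[..., 1] = 0.1
        out = micro.fuse_segmentations(a, b, retrieved_probabilities=prob)
        assert out.data[0, 0, 0] == micro.LBL_BACKGROUND

    def test_shape_mismatch_rejected(self):
        a = micro.LabelVolume(np.zeros((2, 2, 2), dtype=np.uint8))
        b = micro.LabelVolume(np.zeros((3, 2, 2), dtype=np.uint8))
        with pytest.raises(ValueError, match="shape"):
            micro.fuse_segmentations(a, b)


class TestCollagenFraction:
    def _volume(self, n_col, n_cell, n_bg=10):
        data = np.concatenate([
            np.full(n_col, 2), np.full(n_cell, 1), np.full(n_bg, 0)])
        side = int(np.ceil(len(data) ** (1 / 3))) + 1
        pad = np.zeros(side ** 3 - len(data), dtype=int)
        return micro.LabelVolume(
            np.concatenate([data, pad]).reshape(side, side, side)
            .astype(np.uint8))

    def test_simple_arithmetic(self):
        lab = micro.LabelVolume(np.concatenate(
            [np.full(50, 2), np.full(1000, 1), np.zeros(950)]
        ).astype(np.uint8).reshape(10, 10, 20))
        rep = micro.collagen_fraction(lab, denominator="cardiomyocyte")
        assert rep.collagen_fraction_pct == pytest.approx(5.0)

    def test_no_collagen_is_zero(self):
        rep = micro.collagen_fraction(self._volume(0, 100))
        assert rep.collagen_fraction_pct == 0.0

    def test_total_cellular_denominator(self):
        rep = micro.collagen_fraction(
            self._volume(50, 950),
            denominator="cardiomyocyte_plus_collagen")
        assert rep.collagen_fraction_pct == pytest.approx(5.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="denominator"):
            micro.collagen_fraction(self._volume(0, 0))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(extra=st.integers(1, 50))
    def test_monotone_in_added_collagen(self, extra):
        base = self._volume(20, 500)
        more = base.data.copy()
        bg = np.argwhere(more == 0)[:extra]
        more[tuple(bg.T)] = 2
        f0 = micro.collagen_fraction(base).collagen_fraction_pct
        f1 = micro.collagen_fraction(
            micro.LabelVolume(more)).collagen_fraction_pct
        assert f1 > f0

    def test_invariant_under_background_relabelling(self):
        lab = self._volume(20, 500)
        f0 = micro.collagen_fraction(lab).collagen_fraction_pct
        shuffled = lab.data.copy()
        shuffled[shuffled == 0] = 0  # background stays background
        assert micro.collagen_fraction(
            micro.LabelVolume(shuffled)).collagen_fraction_pct == f0


class TestEndToEndFractionRecovery:
    def test_classify_fuse_quantify_recovers_fraction(
            self, collagen_phantom_small):
        retr, nonretr, gt = collagen_phantom_small
        true_pct = 100.0 * (gt.labels == 2).sum() / (gt.labels == 1).sum()
        labels = micro.sample_sparse_labels(gt.labels, n_per_class=1500,
                                            seed=11)
        fused = classify_and_fuse(retr, nonretr, labels, (1.0, 2.0), seed=11)
        rep = micro.collagen_fraction(fused)
        assert rep.collagen_fraction_pct == pytest.approx(true_pct, abs=1.0)


class TestSparseInterpolation:
    def test_identical_planes_extrude_constantly(self):
        disc = (np.hypot(*(np.indices((32, 32)) - 16)) < 8).astype(np.uint8)
        out = micro.interpolate_sparse_labels({0: disc, 10: disc},
                                              (11, 32, 32))
        for z in range(11):
            np.testing.assert_array_equal(out.data[z], disc)

    def test_concentric_discs_blend_linearly(self):
        yy, xx = np.indices((64, 64))
        r = np.hypot(yy - 32, xx - 32)
        small = (r < 10).astype(np.uint8)
        large = (r < 20).astype(np.uint8)
        out = micro.interpolate_sparse_labels({0: small, 10: large},
                                              (11, 64, 64))
        mid = out.data[5] == 1
        radius = np.hypot(*(np.argwhere(mid) - [32, 32]).T).max()
        assert radius == pytest.approx(15.0, abs=1.0)

    def test_labelled_planes_anchored_exactly(self):
        rng = np.random.default_rng(0)
        a = (rng.random((16, 16)) > 0.6).astype(np.uint8)
        b = (rng.random((16, 16)) > 0.6).astype(np.uint8) * 2
        out = micro.interpolate_sparse_labels({2: a, 9: b}, (12, 16, 16))
        np.testing.assert_array_equal(out.data[2], a)
        np.testing.assert_array_equal(out.data[9], b)

    def test_single_plane_object_extrudes_halfway_with_warning(self):
        disc = (np.hypot(*(np.indices((32, 32)) - 16)) < 8).astype(np.uint8)
        empty = np.zeros((32, 32), dtype=np.uint8)
        with pytest.warns(UserWarning, match="halfway"):
            out = micro.interpolate_sparse_labels({0: disc, 10: empty},
                                                  (11, 32, 32))
        assert out.data[4].any()
        assert not out.data[6].any()

    def test_plane_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            micro.interpolate_sparse_labels(
                {0: np.zeros((8, 9), dtype=np.uint8)}, (4, 8, 8))
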