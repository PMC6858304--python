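"""Patch extraction, object detection/labelling, splits, augmentation."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

import netquant as nq
from netquant.errors import LeakageError, ValidationError
from netquant.fieldio import AnnotatedField
from netquant.patches import (DetectedObject, PatchSet, augment,
                              detect_objects, extract_pl_patches,
                              label_objects, split_patches, training_arrays,
                              zscore)


def _in_box(y, x, r0, c0, size):
    return r0 <= y < r0 + size and c0 <= x < c0 + size


class TestExtractPLPatches:
    def test_counts_and_classes(self, small_field):
        ps = extract_pl_patches(small_field, n_negative=10, seed=0)
        n_pos = int(small_field.annotations.label.isin((1, 2)).sum())
        assert len(ps) == n_pos + 10
        assert (ps.labels == 0).sum() == 10
        assert set(ps.labels) <= {0, 1, 2}

    def test_negative_boxes_contain_no_mark_brute_force(self, small_field):
        ps, boxes = extract_pl_patches(small_field, n_negative=40, seed=1,
                                       return_boxes=True)
        marks = small_field.annotations[["y", "x"]].to_numpy()
        for (r0, c0), lab in zip(boxes, ps.labels):
            inside = [(y, x) for y, x in marks if _in_box(y, x, r0, c0, 32)]
            if lab == 0:
                assert inside == []

    def test_centered_single_annotation_yields_whole_image(self):
        img = (np.arange(1024).reshape(32, 32) % 60000).astype(np.uint16)
        field = AnnotatedField(
            image=img,
            annotations=pd.DataFrame({"x": [16], "y": [16], "label": [2]}))
        ps = extract_pl_patches(field, n_negative=0)
        assert len(ps) == 1
        assert np.array_equal(ps.patches[0], img)


class TestDetectObjects:
    def test_blank_image_yields_nothing(self):
        field = AnnotatedField(
            image=np.full((64, 64), 200, dtype=np.uint16),
            annotations=pd.DataFrame(columns=["x", "y", "label"]))
        assert detect_objects(field) == []

    def test_well_separated_nuclei_found_near_truth(self, small_field):
        objs = detect_objects(small_field)
        ann = small_field.annotations
        assert len(objs) == len(ann)
        from scipy.spatial import cKDTree
        tree = cKDTree(ann[["y", "x"]].to_numpy(float))
        d, _ = tree.query([o.center for o in objs])
        assert d.max() <= 3.0

    def test_opening_cuts_one_pixel_bridge(self):
        img = np.zeros((40, 60), dtype=np.uint16)
        rr, cc = np.ogrid[:40, :60]
        img[(rr - 20) ** 2 + (cc - 15) ** 2 <= 36] = 1000
        img[(rr - 20) ** 2 + (cc - 35) ** 2 <= 36] = 1000
        img[20, 15:36] = 1000  # 1-px bridge
        field = AnnotatedField(image=img, annotations=pd.DataFrame(
            columns=["x", "y", "label"]))
        fused = detect_objects(field, opening_radius=0, min_area=5,
                               threshold=500)
        cut = detect_objects(field, opening_radius=1, min_area=5,
                             threshold=500)
        assert len(fused) == 1
        assert len(cut) == 2

    def test_translation_equivariance(self):
        img = np.zeros((60, 80), dtype=np.uint16)
        rr, cc = np.ogrid[:60, :80]
        img[(rr - 20) ** 2 + (cc - 25) ** 2 <= 50] = 2000
        shifted = np.roll(np.roll(img, 7, axis=0), 11, axis=1)
        mk = lambda im: AnnotatedField(image=im, annotations=pd.DataFrame(
            columns=["x", "y", "label"]))
        [a] = detect_objects(mk(img), threshold=500, min_area=5)
        [b] = detect_objects(mk(shifted), threshold=500, min_area=5)
        assert b.bounding_box == (a.bounding_box[0] + 7,
                                  a.bounding_box[1] + 11,
                                  a.bounding_box[2] + 7,
                                  a.bounding_box[3] + 11)


class TestLabelObjects:
    def _obj(self, r, c):
        return DetectedObject(bounding_box=(int(r) - 2, int(c) - 2,
                                            int(r) + 2, int(c) + 2),
                              center=(r, c), pixel_count=9)

    def test_coincident_annotation_label(self):
        ann = pd.DataFrame({"x": [10], "y": [10], "label": [2]})
        [obj] = label_objects([self._obj(10, 10)], ann)
        assert obj.label == 2

    def test_tie_breaks_toward_smaller_yx(self):
        ann = pd.DataFrame({"x": [7, 3], "y": [5, 5], "label": [2, 1]})
        [obj] = label_objects([self._obj(5, 5)], ann)
        assert obj.label == 1  # (5, 3) sorts before (5, 7)

    def test_far_objects_and_catchall_labels_map_to_zero(self):
        ann = pd.DataFrame({"x": [10, 40], "y": [10, 40], "label": [4, 5]})
        objs = label_objects([self._obj(10, 10), self._obj(90, 90)], ann,
                             capture_radius=20)
        assert [o.label for o in objs] == [0, 0]

    def test_matches_brute_force_nearest_neighbor(self, rng):
        ann = pd.DataFrame({
            "x": rng.integers(0, 100, 30), "y": rng.integers(0, 100, 30),
            "label": rng.choice([1, 2, 4], 30)})
        objs = [self._obj(r, c) for r, c in
                zip(rng.uniform(3, 97, 20), rng.uniform(3, 97, 20))]
        got = label_objects(objs, ann, capture_radius=1e9)
        table = ann.sort_values(["y", "x"], kind="stable")
        for o, g in zip(objs, got):
            d = np.hypot(table.y - o.center[0], table.x - o.center[1])
            expected = {1: 1, 2: 2, 4: 0}[int(table.label.iloc[
                int(np.argmin(d.to_numpy()))])]
            assert g.label == expected


class TestSplitPatches:
    def _ps(self, n=100, n_classes=2):
        return PatchSet(np.zeros((n, 8, 8), dtype=np.uint16),
                        np.arange(n) % n_classes, 8)

    def test_eighty_twenty_exact_counts(self):
        out = split_patches(self._ps(100), (0.8, 0.0, 0.2), seed=0)
        assert (out.split == "train").sum() == 80
        assert (out.split == "test").sum() == 20

    def test_split_is_a_partition(self):
        out = split_patches(self._ps(103), (0.65, 0.15, 0.2), seed=1)
        counts = {s: (out.split == s).sum() for s in ("train", "val", "test")}
        assert sum(counts.values()) == 103
        for cls in (0, 1):
            m = out.labels == cls
            assert (out.split[m] == "test").sum() == int(0.2 * m.sum())

    def test_tiny_class_degenerates_to_train_with_warning(self):
        ps = PatchSet(np.zeros((5, 8, 8), dtype=np.uint16),
                      np.array([0, 0, 0, 0, 1]), 8)
        with pytest.warns(UserWarning, match="fewer than"):
            out = split_patches(ps, (0.6, 0.2, 0.2), seed=0)
        assert (out.split[out.labels == 1] == "train").all()

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValidationError):
            split_patches(self._ps(), (0.8, 0.3, 0.2))


class TestAugment:
    def _trainset(self, n=6):
        rng = np.random.default_rng(0)
        return PatchSet(rng.integers(0, 60000, (n, 16, 16)).astype(
            np.uint16), np.arange(n) % 2, 16)

    def test_flips_only_quadruple_the_set(self):
        ps = self._trainset()
        out = augment(ps, rotations_deg=(0.0, 0.0), flips=True, seed=0)
        assert len(out) == 4 * len(ps)
        # the three appended orientations of patch 0 are its exact flips
        copies = out.patches[len(ps):][::len(ps)] \
            if False else out.patches[[len(ps), len(ps) + 1, len(ps) + 2]]
        p = ps.patches[0]
        expected = {p[:, ::-1].tobytes(), p[::-1, :].tobytes(),
                    p[::-1, ::-1].tobytes()}
        assert {c.tobytes() for c in copies} == expected

    def test_double_horizontal_flip_is_identity(self):
        p = self._trainset().patches[0]
        assert np.array_equal(p[:, ::-1][:, ::-1], p)

    def test_rotation_roundtrip_on_disc_symmetric_patch(self):
        from netquant.patches import _rotate
        yy, xx = np.mgrid[:33, :33]
        disc = np.exp(-((yy - 16) ** 2 + (xx - 16) ** 2) / 50.0) * 40000
        disc = disc.astype(np.float32)
        back = _rotate(_rotate(disc, 10.0), -10.0)
        rms = np.sqrt(np.mean((back - disc) ** 2))
        assert rms <= 0.01 * disc.max()

    def test_augmenting_heldout_split_refused(self):
        ps = self._trainset()
        with pytest.raises(LeakageError, match="train"):
            augment(ps, split="test")

    def test_augmented_copies_inherit_label_and_provenance(self):
        ps = self._trainset()
        out = augment(ps, rotations_deg=(-10, 10), flips=False, seed=3)
        n = len(ps)
        assert np.array_equal(out.labels[n:], ps.labels)
        assert np.array_equal(np.asarray(out.annotation_ids)[n:],
                              np.asarray(ps.annotation_ids))


class TestNormalization:
    def test_zscore_moments(self):
        rng = np.random.default_rng(2)
        ps = PatchSet(rng.integers(0, 60000, (5, 12, 12)).astype(np.uint16),
                      np.zeros(5, dtype=int), 12)
        z = zscore(ps)
        assert np.allclose(z.patches.mean(axis=(1, 2)), 0, atol=1e-4)
        assert np.allclose(z.patches.std(axis=(1, 2)), 1, atol=1e-4)

    def test_constant_patch_maps_to_zero(self):
        ps = PatchSet(np.full((1, 8, 8), 123, dtype=np.uint16),
                      np.zeros(1, dtype=int), 8)
        assert np.allclose(zscore(ps).patches, 0)

    def test_training_arrays_scale_raw_to_unit(self):
        ps = PatchSet(np.full((2, 8, 8), 65535, dtype=np.uint16),
                      np.zeros(2, dtype=int), 8)
        x, y = training_arrays(ps, "train")
        assert x.shape == (2, 8, 8, 1)
        assert x.max() == pytest.approx(1.0)
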