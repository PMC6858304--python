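"""From annotated fields to the patch datasets the networks train on.

Three patch geometries are in play: 32x32 pixel-level (PL) patches centred
on annotation marks plus random mark-free negatives; variable objects
detected by classical morphology and cropped at 112x112 for the
object-level (OL) route; and 100x100 phenotype patches. Boxes that would
cross the image border are shifted inward, never padded. Splits are
stratified by class with floor rounding of the held-out fractions, and the
augmentation step refuses to touch anything but the training split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import measure, morphology

from .baseline import isodata_threshold
from .errors import LeakageError, SamplingError, ValidationError
from .fieldio import AnnotatedField

__all__ = ["PatchSet", "DetectedObject", "extract_pl_patches",
           "detect_objects", "label_objects", "split_patches", "augment",
           "zscore", "training_arrays"]


@dataclass
class DetectedObject:
    """A connected component found by classical morphology.

    ``bounding_box`` is half-open (row0, col0, row1, col1); ``center`` is
    the geometric centre of the box in (row, col) pixels.
    """

    bounding_box: tuple[int, int, int, int]
    center: tuple[float, float]
    pixel_count: int
    label: int | None = None

    def __post_init__(self):
        r0, c0, r1, c1 = self.bounding_box
        if not (r0 < r1 and c0 < c1):
            raise ValidationError("degenerate bounding box")


@dataclass
class PatchSet:
    """A stack of same-size single-channel patches with labels and splits.

    ``split`` entries are ``train``/``val``/``test`` (everything starts as
    ``train`` until :func:`split_patches` runs). ``field_ids`` and
    ``annotation_ids`` record provenance for the leakage guard: an
    augmented copy inherits the ids of its source patch.
    """

    patches: np.ndarray  # (n, s, s) uint16 or float32
    labels: np.ndarray  # (n,) int
    patch_size: int
    split: np.ndarray = None  # (n,) '<U5'
    normalization: str = "raw"
    field_ids: np.ndarray = None
    annotation_ids: np.ndarray = None

    def __post_init__(self):
        n = len(self.patches)
        if self.patches.ndim != 3 or self.patches.shape[1:] != (
                self.patch_size, self.patch_size):
            raise ValidationError(
                f"patches must be (n, {self.patch_size}, {self.patch_size})")
        if len(self.labels) != n:
            raise ValidationError("labels length mismatch")
        if self.split is None:
            self.split = np.full(n, "train", dtype="<U5")
        if self.field_ids is None:
            self.field_ids = np.full(n, "field", dtype=object)
        if self.annotation_ids is None:
            self.annotation_ids = np.arange(n)

    def __len__(self) -> int:
        return len(self.patches)

    def subset(self, mask: np.ndarray) -> "PatchSet":
        return PatchSet(self.patches[mask], self.labels[mask],
                        self.patch_size, self.split[mask].copy(),
                        self.normalization, self.field_ids[mask].copy(),
                        np.asarray(self.annotation_ids)[mask].copy())

    def provenance_keys(self, split: str) -> set:
        m = self.split == split
        return set(zip(self.field_ids[m], np.asarray(self.annotation_ids)[m]))

    def concat(self, other: "PatchSet") -> "PatchSet":
        if other.patch_size != self.patch_size:
            raise ValidationError("patch sizes differ")
        return PatchSet(
            np.concatenate([self.patches, other.patches]),
            np.concatenate([self.labels, other.labels]), self.patch_size,
            np.concatenate([self.split, other.split]), self.normalization,
            np.concatenate([self.field_ids, other.field_ids]),
            np.concatenate([np.asarray(self.annotation_ids),
                            np.asarray(other.annotation_ids)]))


def _clip_box(y: float, x: float, size: int, h: int, w: int):
    """Top-left corner of a size-box centred at (y, x), shifted inward so
    the box lies fully inside an h x w image."""
    r0 = int(round(y)) - size // 2
    c0 = int(round(x)) - size // 2
    r0 = min(max(r0, 0), h - size)
    c0 = min(max(c0, 0), w - size)
    return r0, c0


def extract_pl_patches(field: AnnotatedField, n_negative: int,
                       seed: int = 0, size: int = 32,
                       max_attempts_factor: int = 1000,
                       return_boxes: bool = False):
    """PL patch extraction: one ``size``-box per label-1/2 annotation
    (classes 1/2) plus ``n_negative`` random boxes containing no annotation
    mark at all (class 0; half-open box membership). Boxes are clipped to
    lie inside the image. With ``return_boxes`` the (row0, col0) top-left
    corner of every patch is returned alongside the set.
    """
    h, w = field.image.shape
    if h < size or w < size:
        raise ValidationError(f"field smaller than the {size} px patch")
    ann = field.annotations
    pos = ann[ann.label.isin((1, 2))]
    if len(pos) == 0 and n_negative == 0:
        raise ValidationError("nothing to extract: no positive annotations "
                              "and no negatives requested")
    rng = np.random.default_rng(seed)
    patches, labels, ann_ids, boxes = [], [], [], []
    for idx, row in pos.iterrows():
        r0, c0 = _clip_box(row.y, row.x, size, h, w)
        patches.append(field.image[r0:r0 + size, c0:c0 + size])
        labels.append(int(row.label))
        ann_ids.append(idx)
        boxes.append((r0, c0))
    # negatives: rejection-sample boxes with no mark inside (half-open box
    # membership); a KD-tree in the Chebyshev metric makes the test O(log n)
    marks = ann[["y", "x"]].to_numpy(dtype=float)
    tree = cKDTree(marks) if len(marks) else None
    needed = n_negative
    budget = max_attempts_factor * max(n_negative, 1)
    neg_id = -1
    while needed > 0 and budget > 0:
        take = min(needed * 2, budget, 4096)
        r0s = rng.integers(0, h - size + 1, take)
        c0s = rng.integers(0, w - size + 1, take)
        budget -= take
        if tree is not None:
            centers = np.column_stack([r0s + (size - 1) / 2.0,
                                       c0s + (size - 1) / 2.0])
            # a mark lies inside the half-open box iff its Chebyshev
            # distance to the box centre is < size/2 (for even size the
            # centre sits between pixels, so the test is exact)
            dist, _ = tree.query(centers, k=1, p=np.inf)
            ok = dist >= size / 2.0
        else:
            ok = np.ones(take, dtype=bool)
        for r0, c0 in zip(r0s[ok], c0s[ok]):
            if needed == 0:
                break
            patches.append(field.image[r0:r0 + size, c0:c0 + size])
            labels.append(0)
            boxes.append((int(r0), int(c0)))
            ann_ids.append(neg_id)
            neg_id -= 1
            needed -= 1
    if needed > 0:
        raise SamplingError(
            f"could not place {n_negative} annotation-free {size} px boxes "
            f"after {max_attempts_factor}x attempts; field too crowded")
    ps = PatchSet(np.stack(patches), np.asarray(labels, dtype=np.int64),
                  size,
                  field_ids=np.full(len(labels), field.field_id,
                                    dtype=object),
                  annotation_ids=np.asarray(ann_ids))
    return (ps, boxes) if return_boxes else ps


def detect_objects(field: AnnotatedField, opening_radius: int = 1,
                   min_area: int = 30, n_openings: int = 2,
                   threshold: float | None = None) -> list[DetectedObject]:
    """Classical object detection: global (Isodata) threshold, repeated
    morphological opening to cut noise bridges, then 8-connected components
    with area >= ``min_area``."""
    image = field.image
    if image.size == 0:
        return []
    if threshold is None:
        try:
            threshold = isodata_threshold(image)
        except Exception:
            return []
        # blank-field guard: on a signal-free image the intermeans threshold
        # falls inside the noise bulk and half the pixels light up; require
        # the two intensity populations to be separated well beyond the
        # background spread before declaring foreground
        below = image[image <= threshold]
        above = image[image > threshold]
        if (len(below) == 0 or len(above) == 0
                or above.mean() - below.mean() < 5.0 * max(below.std(), 1.0)):
            return []
    binary = image > threshold
    if opening_radius > 0:
        selem = morphology.disk(opening_radius)
        for _ in range(n_openings):
            binary = ndi.binary_opening(binary, structure=selem)
    labels = measure.label(binary, connectivity=2)
    out = []
    for r in measure.regionprops(labels):
        if r.area < min_area:
            continue
        r0, c0, r1, c1 = r.bbox
        out.append(DetectedObject(
            bounding_box=(r0, c0, r1, c1),
            center=((r0 + r1) / 2.0, (c0 + c1) / 2.0),
            pixel_count=int(r.area)))
    return out


_DEFAULT_LABEL_MAP = {1: 1, 2: 2, 3: 0, 4: 0, 5: 0}


def label_objects(objects: list[DetectedObject], annotations,
                  capture_radius: float = 24.0,
                  label_map: dict[int, int] | None = None
                  ) -> list[DetectedObject]:
    """Assign each object the class of the annotation nearest its centre.

    Objects with no annotation within ``capture_radius`` px get class 0
    (the object-level catch-all), as do labels 4/5. Exact distance ties
    break toward the annotation with the smaller (y, x).
    """
    label_map = _DEFAULT_LABEL_MAP if label_map is None else label_map
    ann = annotations.sort_values(["y", "x"], kind="stable")
    pts = ann[["y", "x"]].to_numpy(dtype=float)
    labs = ann["label"].to_numpy()
    out = []
    for obj in objects:
        if len(pts) == 0:
            cls = 0
        else:
            d = np.hypot(pts[:, 0] - obj.center[0], pts[:, 1] - obj.center[1])
            j = int(np.argmin(d))  # first minimum == smallest (y, x) tie-break
            cls = label_map.get(int(labs[j]), 0) if d[j] <= capture_radius else 0
        out.append(DetectedObject(obj.bounding_box, obj.center,
                                  obj.pixel_count, label=cls))
    return out


def split_patches(ps: PatchSet, ratio=(0.8, 0.0, 0.2),
                  seed: int = 0) -> PatchSet:
    """Stratified random train/val/test split.

    Per class, the test and val counts are ``floor(fraction * n_class)``
    and the remainder trains; reproducible under ``seed``. A class with
    fewer patches than populated split bins degenerates to all-train with a
    warning.
    """
    ratio = np.asarray(ratio, dtype=float)
    if len(ratio) != 3 or abs(ratio.sum() - 1.0) > 1e-9 or np.any(ratio < 0):
        raise ValidationError("ratio must be 3 non-negative fractions "
                              "summing to 1 (train, val, test)")
    rng = np.random.default_rng(seed)
    split = np.full(len(ps), "train", dtype="<U5")
    n_bins = int(np.count_nonzero(ratio))
    for cls in np.unique(ps.labels):
        idx = np.flatnonzero(ps.labels == cls)
        if len(idx) < n_bins:
            warnings.warn(f"class {cls} has {len(idx)} patches, fewer than "
                          f"the {n_bins} split bins; assigning all to train",
                          stacklevel=2)
            continue
        idx = rng.permutation(idx)
        n_test = int(np.floor(ratio[2] * len(idx)))
        n_val = int(np.floor(ratio[1] * len(idx)))
        split[idx[:n_test]] = "test"
        split[idx[n_test:n_test + n_val]] = "val"
    out = PatchSet(ps.patches, ps.labels, ps.patch_size, split,
                   ps.normalization, ps.field_ids, ps.annotation_ids)
    assert_no_leakage(out)
    return out


def assert_no_leakage(ps: PatchSet) -> None:
    """Raise if any (field, annotation) provenance key appears both in the
    held-out splits and in train/val."""
    test = ps.provenance_keys("test")
    for other in ("train", "val"):
        overlap = test & ps.provenance_keys(other)
        if overlap:
            raise LeakageError(
                f"{len(overlap)} provenance keys shared between test and "
                f"{other}: {sorted(overlap)[:5]}")


def _rotate(patch: np.ndarray, angle: float) -> np.ndarray:
    if angle == 0.0:
        return patch.copy()
    out = ndi.rotate(patch.astype(np.float32), angle, reshape=False,
                     order=1, mode="reflect")
    if np.issubdtype(patch.dtype, np.integer):
        out = np.clip(np.rint(out), 0, 65535)
    return out.astype(patch.dtype)


def augment(ps: PatchSet, rotations_deg: tuple[float, float] = (-10.0, 10.0),
            flips: bool = True, seed: int = 0,
            split: str = "train") -> PatchSet:
    """Enlarge the training split with flipped/rotated copies.

    Each copy is a flip orientation (identity, horizontal, vertical, both,
    when ``flips`` is on) rotated by an angle drawn uniformly from
    ``rotations_deg``; the unrotated identity copy is skipped since the
    original is retained, so rotations disabled + flips on gives exactly
    4x the input (identity, H, V, HV). Copies inherit label and
    provenance. Requesting any split other than ``train`` raises
    :class:`LeakageError`.
    """
    if split != "train":
        raise LeakageError(
            f"augmentation on the {split!r} split would leak augmented "
            "views into held-out evaluation; only 'train' is allowed")
    rng = np.random.default_rng(seed)
    lo, hi = rotations_deg
    mask = ps.split == "train"
    new_patches, new_labels, new_fields, new_ann = [], [], [], []
    orientations = [(False, False), (True, False), (False, True),
                    (True, True)] if flips else [(False, False)]
    for i in np.flatnonzero(mask):
        patch = ps.patches[i]
        for k, (fh, fv) in enumerate(orientations):
            if k == 0 and lo == hi == 0.0:
                continue  # identity copy would duplicate the original
            p = patch
            if fh:
                p = p[:, ::-1]
            if fv:
                p = p[::-1, :]
            angle = rng.uniform(lo, hi) if (lo, hi) != (0.0, 0.0) else 0.0
            new_patches.append(_rotate(p, angle))
            new_labels.append(ps.labels[i])
            new_fields.append(ps.field_ids[i])
            new_ann.append(np.asarray(ps.annotation_ids)[i])
    if not new_patches:
        return ps
    extra = PatchSet(np.stack(new_patches),
                     np.asarray(new_labels, dtype=ps.labels.dtype),
                     ps.patch_size,
                     np.full(len(new_patches), "train", dtype="<U5"),
                     ps.normalization,
                     np.asarray(new_fields, dtype=object),
                     np.asarray(new_ann))
    out = ps.concat(extra)
    assert_no_leakage(out)
    return out


def zscore(ps: PatchSet) -> PatchSet:
    """Per-patch z-score normalisation (mean 0, sd 1; constant patches map
    to zero), as used by the object-level route."""
    x = ps.patches.astype(np.float32)
    mean = x.mean(axis=(1, 2), keepdims=True)
    sd = x.std(axis=(1, 2), keepdims=True)
    sd = np.where(sd < 1e-8, 1.0, sd)
    return PatchSet((x - mean) / sd, ps.labels, ps.patch_size,
                    ps.split.copy(), "zscore", ps.field_ids.copy(),
                    np.asarray(ps.annotation_ids).copy())


def training_arrays(ps: PatchSet, split: str):
    """(x, y) arrays for one split: x is (n, s, s, 1) float32, scaled to
    [0, 1] for raw patch sets and passed through for z-scored ones."""
    m = ps.split == split
    x = ps.patches[m].astype(np.float32)
    if ps.normalization == "raw":
        x = x / 65535.0
    return x[..., None], ps.labels[m]
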