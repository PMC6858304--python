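"""Rule-based (ImageJ-style) segmentation and shape classification.

The classical pipeline this package's CNNs are compared against: Isodata
intermeans thresholding to define primary objects, removal of small objects
(area under 100 px) and of objects touching the image border, then a
threshold on a shape statistic to split "large diffuse" (NETotic-like) from
"small compact" cells.

The historical shape threshold is 5.677 on "solidity"; solidity as defined
(area / convex area) never exceeds 1, so that constant cannot apply to it
literally. The statistic is therefore pluggable (``solidity``,
``inverse_solidity``, ``area_over_solidity`` — i.e. the convex area —
``perimeter2_over_area``, ``area``) while 5.677 is kept as the default
threshold constant; choose the statistic/threshold pair that matches your
data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology

from .errors import NoThresholdError, ValidationError

__all__ = ["ShapeRecord", "isodata_threshold", "segment_objects",
           "filter_objects", "classify_by_shape", "shape_features",
           "baseline_counts", "SHAPE_STATISTICS",
           "DEFAULT_SHAPE_THRESHOLD", "DEFAULT_MIN_AREA"]

DEFAULT_SHAPE_THRESHOLD = 5.677
DEFAULT_MIN_AREA = 100


@dataclass
class ShapeRecord:
    """Per-object shape summary used for rule-based classification."""

    object_id: int
    area: int
    convex_area: int
    solidity: float
    border_touching: bool
    shape_class: str  # large_diffuse | small_compact | unclassifiable
    statistic: float = float("nan")
    centroid: tuple[float, float] = (0.0, 0.0)


def isodata_threshold(image: np.ndarray) -> float:
    """Iterative intermeans (Isodata/Ridler-Calvard) threshold.

    Starting from the global mean, iterate t <- (mean below t + mean above
    t) / 2 until the step is below 0.5 grey levels; raises
    :class:`NoThresholdError` on a constant image.
    """
    x = np.asarray(image, dtype=np.float64).ravel()
    if x.size == 0 or x.min() == x.max():
        raise NoThresholdError("constant image has no intermeans threshold")
    t = x.mean()
    for _ in range(500):
        below = x[x <= t]
        above = x[x > t]
        if len(below) == 0 or len(above) == 0:
            break
        t_new = 0.5 * (below.mean() + above.mean())
        if abs(t_new - t) < 0.5:
            return float(t_new)
        t = t_new
    return float(t)


def segment_objects(image: np.ndarray, threshold: float | None = None,
                    min_size_prefilter: int = 0):
    """Threshold and 8-connected label; returns skimage regionprops.

    ``threshold=None`` uses :func:`isodata_threshold`.
    """
    if threshold is None:
        threshold = isodata_threshold(image)
    binary = image > threshold
    if min_size_prefilter:
        binary = morphology.remove_small_objects(binary, min_size_prefilter)
    labels = measure.label(binary, connectivity=2)
    return measure.regionprops(labels, intensity_image=image)


def _touches_border(region, shape) -> bool:
    r0, c0, r1, c1 = region.bbox
    return r0 == 0 or c0 == 0 or r1 == shape[0] or c1 == shape[1]


def filter_objects(regions, image_shape,
                   min_area: int = DEFAULT_MIN_AREA,
                   drop_border: bool = True):
    """Drop objects with area under ``min_area`` px (area == min_area is
    retained) and, if ``drop_border``, any object with a boundary pixel."""
    out = []
    for r in regions:
        if r.area < min_area:
            continue
        if drop_border and _touches_border(r, image_shape):
            continue
        out.append(r)
    return out


def _statistic(region, name: str) -> float:
    area = float(region.area)
    solidity = float(region.solidity)
    if name == "solidity":
        return solidity
    if name == "inverse_solidity":
        return 1.0 / solidity
    if name == "area_over_solidity":  # == convex hull area
        return area / solidity
    if name == "perimeter2_over_area":
        return float(region.perimeter) ** 2 / area
    if name == "area":
        return area
    raise ValidationError(f"unknown shape statistic {name!r}")


SHAPE_STATISTICS = ("solidity", "inverse_solidity", "area_over_solidity",
                    "perimeter2_over_area", "area")


def classify_by_shape(regions, image_shape, statistic: str = "solidity",
                      threshold: float = DEFAULT_SHAPE_THRESHOLD
                      ) -> list[ShapeRecord]:
    """Classify each object as large_diffuse (statistic > threshold) or
    small_compact; degenerate objects (< 3 px, no hull) are flagged
    unclassifiable. Pure in the object list: order never affects classes."""
    records = []
    for i, r in enumerate(regions):
        if r.area < 3:
            records.append(ShapeRecord(
                object_id=i, area=int(r.area), convex_area=0,
                solidity=float("nan"),
                border_touching=_touches_border(r, image_shape),
                shape_class="unclassifiable",
                centroid=tuple(map(float, r.centroid))))
            continue
        stat = _statistic(r, statistic)
        records.append(ShapeRecord(
            object_id=i, area=int(r.area),
            convex_area=int(round(r.area / r.solidity)),
            solidity=float(r.solidity),
            border_touching=_touches_border(r, image_shape),
            shape_class=("large_diffuse" if stat > threshold
                         else "small_compact"),
            statistic=float(stat),
            centroid=tuple(map(float, r.centroid))))
    return records


def shape_features(image: np.ndarray) -> tuple[float, float, float] | None:
    """(area, solidity, peak intensity) of the largest segmented object,
    or None when nothing segments; the feature triple the synthetic
    difficulty dial is calibrated against."""
    try:
        regions = segment_objects(image)
    except NoThresholdError:
        return None
    regions = [r for r in regions if r.area >= 3]
    if not regions:
        return None
    r = max(regions, key=lambda q: q.area)
    return float(r.area), float(r.solidity), float(r.intensity_max)


def baseline_counts(image: np.ndarray, statistic: str = "area_over_solidity",
                    threshold: float = 200.0,
                    min_area: int = DEFAULT_MIN_AREA,
                    drop_border: bool = True) -> dict:
    """End-to-end rule-based tally on one image.

    Returns ``{"large_diffuse": n, "small_compact": n, "percent_diffuse": p,
    "records": [...]}. The default statistic/threshold pair is the package's
    own calibration for the synthetic stain (convex-hull area 200 px); the
    historical pair (solidity, 5.677) is available but classifies every
    object small_compact since solidity <= 1.
    """
    regions = filter_objects(segment_objects(image), image.shape,
                             min_area=min_area, drop_border=drop_border)
    records = classify_by_shape(regions, image.shape, statistic=statistic,
                                threshold=threshold)
    n_ld = sum(1 for r in records if r.shape_class == "large_diffuse")
    n_sc = sum(1 for r in records if r.shape_class == "small_compact")
    total = n_ld + n_sc
    return {"large_diffuse": n_ld, "small_compact": n_sc,
            "percent_diffuse": (100.0 * n_ld / total) if total else None,
            "records": records}
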