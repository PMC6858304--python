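"""Reading, writing and tiling of annotated fluorescence fields.

An :class:`AnnotatedField` couples one 16-bit grayscale image with a table
of point annotations. Coordinates are 0-based with ``x`` the column and
``y`` the row — the convention of common point-annotation exports; it is
restated on every I/O boundary because upstream tools disagree on it.

Label vocabulary (``VALID_LABELS``): 1 = non-NETotic, 2 = NETotic,
3 = necrotic (this package's label; the source annotation scheme has no
necrosis label), 4 = unidentifiable, 5 = spread NETs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ValidationError

__all__ = ["AnnotatedField", "VALID_LABELS", "NECROTIC_LABEL",
           "read_annotated_field", "write_annotated_field", "cut_grid"]

NECROTIC_LABEL = 3
VALID_LABELS = frozenset({1, 2, 3, 4, 5})

_ANN_COLUMNS = ("x", "y", "label")


@dataclass
class AnnotatedField:
    """A 16-bit grayscale image plus its per-nucleus point annotations.

    ``annotations`` is a DataFrame with integer columns ``x`` (column px),
    ``y`` (row px) and ``label``; ``provenance`` records where the field
    came from (a file path or a generator spec dict).
    """

    image: np.ndarray
    annotations: pd.DataFrame
    provenance: object = None
    field_id: str = "field"

    def __post_init__(self):
        self.validate()

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape

    def validate(self) -> None:
        if self.image.ndim != 2:
            raise ValidationError(
                f"image must be 2-D grayscale, got shape {self.image.shape}")
        if self.image.dtype != np.uint16:
            raise ValidationError(
                f"image dtype must be uint16, got {self.image.dtype}")
        ann = self.annotations
        missing = [c for c in _ANN_COLUMNS if c not in ann.columns]
        if missing:
            raise ValidationError(f"annotation table lacks columns {missing}")
        h, w = self.image.shape
        oob = ann[(ann.x < 0) | (ann.x >= w) | (ann.y < 0) | (ann.y >= h)]
        if len(oob):
            raise ValidationError(
                "annotations outside image bounds at rows "
                f"{oob.index.tolist()[:10]}: {oob.head(10).to_dict('records')}")
        bad = set(ann.label.unique()) - VALID_LABELS
        if bad:
            raise ValidationError(f"unknown annotation labels {sorted(bad)}")

    def counts(self) -> dict[int, int]:
        """Number of annotations per label."""
        return self.annotations.label.value_counts().to_dict()


def write_annotated_field(field: AnnotatedField, image_path, annotation_path,
                          spec_json_path=None) -> None:
    """Write the image as 16-bit TIFF, annotations as CSV (x, y, label) and
    optionally a sidecar JSON with the generating spec/provenance."""
    tifffile.imwrite(str(image_path), field.image)
    field.annotations[list(_ANN_COLUMNS)].to_csv(str(annotation_path),
                                                 index=False)
    if spec_json_path is not None:
        with open(str(spec_json_path), "w") as fh:
            json.dump({"field_id": field.field_id,
                       "provenance": _jsonable(field.provenance)}, fh,
                      indent=1)


def _jsonable(obj):
    try:
        json.dumps(obj)
        return obj
    except TypeError:
        return repr(obj)


def read_annotated_field(image_path, annotation_path,
                         field_id: str | None = None) -> AnnotatedField:
    """Read a TIFF image and its annotation CSV; validates bounds/labels.

    Round-trips bit-exactly with :func:`write_annotated_field`.
    """
    image = tifffile.imread(str(image_path))
    if image.dtype != np.uint16:
        raise ValidationError(
            f"{image_path}: expected a 16-bit grayscale TIFF, got {image.dtype}")
    ann = pd.read_csv(str(annotation_path))
    missing = [c for c in _ANN_COLUMNS if c not in ann.columns]
    if missing:
        raise ValidationError(
            f"{annotation_path}: annotation CSV lacks columns {missing}")
    ann = ann[list(_ANN_COLUMNS)].astype(int)
    return AnnotatedField(image=image, annotations=ann,
                          provenance=str(image_path),
                          field_id=field_id or Path(str(image_path)).stem)


def cut_grid(field: AnnotatedField, rows: int, cols: int) -> list[AnnotatedField]:
    """Partition a field into a ``rows x cols`` grid of tiles.

    Tile heights/widths are the floor division of the image dimensions; the
    last tile along each axis absorbs the remainder, so the tiles cover
    every pixel exactly once. Annotations are reassigned to the tile that
    contains them, with coordinates translated into the tile frame. Tile ids
    follow ``<field_id>_r<i>_c<j>``.
    """
    if rows < 1 or cols < 1:
        raise ValidationError("rows and cols must be >= 1")
    h, w = field.image.shape
    if rows > h or cols > w:
        raise ValidationError(
            f"grid {rows}x{cols} exceeds image dimensions {h}x{w}")
    th, tw = h // rows, w // cols
    ann = field.annotations
    # tile index per annotation; the last tile absorbs coordinates past the
    # uniform grid edge
    ti = np.minimum(ann.y.to_numpy() // th, rows - 1)
    tj = np.minimum(ann.x.to_numpy() // tw, cols - 1)
    tiles = []
    for i in range(rows):
        r0, r1 = i * th, (i + 1) * th if i < rows - 1 else h
        for j in range(cols):
            c0, c1 = j * tw, (j + 1) * tw if j < cols - 1 else w
            mask = (ti == i) & (tj == j)
            sub = ann[mask].copy()
            sub["x"] = sub.x - c0
            sub["y"] = sub.y - r0
            tiles.append(AnnotatedField(
                image=np.ascontiguousarray(field.image[r0:r1, c0:c1]),
                annotations=sub.reset_index(drop=True),
                provenance={"parent": field.field_id, "offset": (r0, c0)},
                field_id=f"{field.field_id}_r{i}_c{j}"))
    return tiles
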