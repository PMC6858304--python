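"""Whole-field quantitation with trained networks.

Two routes produce per-image counts of non-NETotic and NETotic nuclei:

* the **pixel-level (PL)** route slides the stage-1 32x32 classifier over
  the field at stride 1, producing an (H-32) x (W-32) x 3 class-score map,
  which the stage-2 counter regresses into the two counts;
* the **object-level (OL)** route detects objects by classical morphology,
  classifies a patch around each object centre, and tallies the per-object
  labels — which also yields the per-phenotype centre lists the spatial
  statistics run on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .fieldio import AnnotatedField
from .nn import Sequential, TrainConfig, train
from .patches import DetectedObject, _clip_box, detect_objects

__all__ = ["FeatureMap", "CountResult", "field_to_feature_map",
           "count_from_map", "count_by_objects", "true_counts",
           "fit_stage2_counter"]


@dataclass
class FeatureMap:
    """Stride-1 class-score map of a field: (H-32) x (W-32) x 3."""

    scores: np.ndarray
    field_id: str = "field"

    def __post_init__(self):
        if self.scores.ndim != 3 or self.scores.shape[2] != 3:
            raise ValidationError("scores must be (rows, cols, 3)")


@dataclass
class CountResult:
    """Predicted (and optionally true) per-image counts by phenotype."""

    predicted: tuple[float, float]  # (n_non_netotic, n_netotic)
    truth: tuple[int, int] | None = None
    field_id: str = "field"
    route: str = "ol"

    def __post_init__(self):
        if min(self.predicted) < 0:
            raise ValidationError("counts must be non-negative")

    @property
    def percent_netotic(self) -> float | None:
        total = self.predicted[0] + self.predicted[1]
        return 100.0 * self.predicted[1] / total if total > 0 else None


def true_counts(field: AnnotatedField) -> tuple[int, int]:
    """(non-NETotic, NETotic) annotation tallies of a field."""
    c = field.counts()
    return int(c.get(1, 0)), int(c.get(2, 0))


def field_to_feature_map(field: AnnotatedField, stage1: Sequential,
                         patch_size: int = 32, batch_rows: int = 4,
                         ) -> FeatureMap:
    """Stride-1 scan of the stage-1 classifier over the field.

    Scan positions run over offsets 0..H-33 and 0..W-33, i.e. the map is
    (H-32) x (W-32) x 3 — the convention that turns a 512 x 672 field into
    a 480 x 640 x 3 map. Patches are scaled to [0, 1] exactly as in
    training.
    """
    h, w = field.image.shape
    s = patch_size
    if h <= s or w <= s:
        raise ValidationError(
            f"field {h}x{w} too small for a stride-1 {s} px scan "
            f"(needs at least {s + 1} px per side)")
    windows = np.lib.stride_tricks.sliding_window_view(field.image, (s, s))
    rows_out, cols_out = h - s, w - s
    scores = np.empty((rows_out, cols_out, 3), dtype=np.float32)
    for r0 in range(0, rows_out, batch_rows):
        r1 = min(r0 + batch_rows, rows_out)
        chunk = windows[r0:r1, :cols_out].reshape(-1, s, s)
        x = chunk.astype(np.float32)[..., None] / 65535.0
        scores[r0:r1] = stage1.predict_proba(x, batch=512).reshape(
            r1 - r0, cols_out, 3)
    return FeatureMap(scores=scores, field_id=field.field_id)


def count_from_map(fmap: FeatureMap, counter: Sequential,
                   truth: tuple[int, int] | None = None) -> CountResult:
    """Regress the two phenotype counts from a class-score map."""
    pred = counter.predict(fmap.scores[None].astype(np.float32))[0]
    return CountResult(predicted=(float(pred[0]), float(pred[1])),
                       truth=truth, field_id=fmap.field_id, route="pl")


def fit_stage2_counter(maps: list[FeatureMap], counts: list[tuple[int, int]],
                       counter: Sequential,
                       config: TrainConfig | None = None):
    """Train a stage-2 counter on (map, true-count) pairs; returns history."""
    x = np.stack([m.scores for m in maps]).astype(np.float32)
    y = np.asarray(counts, dtype=np.float32)
    config = config or TrainConfig(loss="mean_absolute_error", epochs=30)
    if config.loss != "mean_absolute_error":
        raise ValidationError("stage-2 counting trains with MAE loss")
    return train(counter, x, y, config)


def count_by_objects(field: AnnotatedField, model: Sequential,
                     patch_size: int = 32,
                     detector_params: dict | None = None,
                     batch: int = 256
                     ) -> tuple[CountResult, list[DetectedObject]]:
    """Object-level counting: detect, classify a patch per object, tally.

    Returns the per-image count result (classes 1 and 2) plus the labelled
    objects, whose centres feed the spatial-clustering statistics.
    """
    objs = detect_objects(field, **(detector_params or {}))
    h, w = field.image.shape
    if not objs:
        return (CountResult(predicted=(0.0, 0.0), truth=true_counts(field),
                            field_id=field.field_id, route="ol"), [])
    crops = []
    for obj in objs:
        r0, c0 = _clip_box(obj.center[0], obj.center[1], patch_size, h, w)
        crops.append(field.image[r0:r0 + patch_size, c0:c0 + patch_size])
    x = np.stack(crops).astype(np.float32)[..., None] / 65535.0
    pred = model.predict(x, batch=batch)
    labelled = [DetectedObject(o.bounding_box, o.center, o.pixel_count,
                               label=int(p)) for o, p in zip(objs, pred)]
    n1 = sum(1 for o in labelled if o.label == 1)
    n2 = sum(1 for o in labelled if o.label == 2)
    return (CountResult(predicted=(float(n1), float(n2)),
                        truth=true_counts(field), field_id=field.field_id,
                        route="ol"), labelled)
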