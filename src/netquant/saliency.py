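"""Per-pixel attribution maps for trained classifiers.

Two methods, both emitting non-negative maps of the input's spatial shape:

* **guided backpropagation** — the gradient of the target class score
  (pre-softmax logit) with respect to the input pixels, where every
  rectifier's backward pass additionally discards negative upstream
  gradients; residual negative values at the input are removed, so the map
  keeps only positively contributing pixels.
* **guided Grad-CAM** — the class-gradient-weighted average of the last
  convolutional layer's activation maps, rectified and bilinearly
  upsampled to the input size, multiplied elementwise with the guided
  backpropagation map.

Raw map values are returned as computed; :func:`normalize_for_display`
rescales to [0, 1] for rendering only, so tests and downstream analysis
can assert on the raw gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile
from skimage import transform

from .errors import ValidationError
from .nn import Sequential

__all__ = ["SaliencyMap", "guided_backprop", "guided_grad_cam",
           "normalize_for_display", "write_saliency"]


@dataclass
class SaliencyMap:
    """Non-negative per-pixel importance map for one patch and class."""

    values: np.ndarray
    method: str  # guided_backprop | guided_grad_cam
    target_class: int

    def __post_init__(self):
        if (self.values < 0).any():
            raise ValidationError("saliency values must be non-negative")


def _prepare(patch: np.ndarray) -> np.ndarray:
    x = np.asarray(patch, dtype=np.float32)
    if x.ndim == 2:
        x = x[..., None]
    if x.ndim != 3:
        raise ValidationError("patch must be (H, W) or (H, W, C)")
    return x[None]


def _class_grad(model: Sequential, n_classes: int, cls: int) -> np.ndarray:
    if not 0 <= cls < n_classes:
        raise ValidationError(
            f"class index {cls} out of range for a {n_classes}-way head")
    d = np.zeros((1, n_classes), dtype=np.float32)
    d[0, cls] = 1.0
    return d


def guided_backprop(model: Sequential, patch: np.ndarray,
                    target_class: int) -> SaliencyMap:
    """Guided-backpropagation map of the class logit w.r.t. input pixels.

    ``patch`` must already be in the model's input scale (e.g. [0, 1] for
    the patch classifiers).
    """
    x = _prepare(patch)
    logits = model.forward(x)
    d = _class_grad(model, logits.shape[-1], target_class)
    g = model.backward(d, guided=True)
    values = np.maximum(g[0, ..., 0] if g.shape[-1] == 1 else g[0].sum(-1),
                        0.0)
    return SaliencyMap(values=values.astype(np.float32),
                       method="guided_backprop", target_class=target_class)


def input_gradient(model: Sequential, patch: np.ndarray,
                   target_class: int) -> np.ndarray:
    """Plain (unguided, unrectified) input gradient of the class logit —
    the quantity finite differences approximate."""
    x = _prepare(patch)
    logits = model.forward(x)
    d = _class_grad(model, logits.shape[-1], target_class)
    g = model.backward(d, guided=False)
    return (g[0, ..., 0] if g.shape[-1] == 1 else g[0].sum(-1)).astype(
        np.float32)


def guided_grad_cam(model: Sequential, patch: np.ndarray,
                    target_class: int) -> SaliencyMap:
    """Guided Grad-CAM: rectified gradient-weighted CAM of the last conv
    layer, upsampled bilinearly, times the guided-backprop map."""
    x = _prepare(patch)
    conv_idx = model.last_conv_index()  # raises on conv-free models
    logits = model.forward(x)
    d = _class_grad(model, logits.shape[-1], target_class)
    # gradient with respect to the last conv layer's output
    grad_a = model.backward(d, guided=False, upto=conv_idx + 1)
    # that layer's rectified activation maps, recomputed from its cache
    conv = model.layers[conv_idx]
    act = np.maximum(conv.forward(conv._x), 0.0)
    # position-wise gradient weighting: with a fully connected head (not a
    # global-average-pooled one) the classic spatially-pooled weights lose
    # localisation, so each activation is weighted by its own rectified
    # class gradient before summing over channels
    cam = (act[0] * np.maximum(grad_a[0], 0.0)).sum(axis=-1)
    cam_up = _upsample_to_input(cam, model, conv_idx, x.shape[1:3])
    gbp = guided_backprop(model, patch, target_class)
    return SaliencyMap(values=(cam_up * gbp.values).astype(np.float32),
                       method="guided_grad_cam", target_class=target_class)


def _upsample_to_input(cam: np.ndarray, model: Sequential, conv_idx: int,
                       shape: tuple[int, int]) -> np.ndarray:
    """Bilinearly upsample a CAM to the input grid, aligning each CAM cell
    with the centre of its receptive field (tracked through the conv/pool
    stack) rather than stretching corner-to-corner."""
    from scipy import ndimage as ndi

    from .nn import AvgPool2, Conv2D, MaxPool2
    stride, offset = 1.0, 0.0
    for layer in model.layers[:conv_idx + 1]:
        if isinstance(layer, Conv2D):
            offset += stride * (layer.k - 1) / 2.0
        elif isinstance(layer, (MaxPool2, AvgPool2)):
            offset += stride * 0.5
            stride *= 2.0
    rows = (np.arange(shape[0]) - offset) / stride
    cols = (np.arange(shape[1]) - offset) / stride
    grid = np.meshgrid(rows, cols, indexing="ij")
    return ndi.map_coordinates(cam, grid, order=1, mode="nearest")


def normalize_for_display(m: SaliencyMap) -> np.ndarray:
    """Rescale to [0, 1] (max -> 1); display only, never asserted on."""
    peak = m.values.max()
    return m.values / peak if peak > 0 else m.values.copy()


def write_saliency(m: SaliencyMap, tiff_path, png_path=None) -> None:
    """Raw values as 32-bit float TIFF, plus an optional 8-bit PNG."""
    tifffile.imwrite(str(tiff_path), m.values.astype(np.float32))
    if png_path is not None:
        from matplotlib import image as mpimg
        mpimg.imsave(str(png_path), normalize_for_display(m), cmap="gray",
                     vmin=0.0, vmax=1.0)
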