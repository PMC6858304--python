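"""Builders for the four networks used by the pipeline.

All four are compact VGG/DenseNet-style stacks sized for commodity CPUs:

* ``pl_stage1`` — 32x32 patch classifier: four 3x3 convolutions (64 filters
  each), 2x2 max-pooling and 25% dropout between the second and third, a
  256-unit fully connected layer and a 3-way softmax head.
* ``pl_stage2_counter`` — count regressor over a class-score map: two 3x3
  convolutions (32 filters), 2x2 average-pooling between them, 2x2
  max-pooling after them, a 256-unit layer and a rectified 2-unit head that
  emits the (non-NETotic, NETotic) counts.
* ``phenotype`` — 100x100 patch binary classifier: nine 3x3 convolutions
  (64 filters), with 2x2 max-pooling and 25% dropout after each block of
  three, then 256 units and a 2-way softmax head.
* ``ol_classifier`` — object-level classifier: a compact densely connected
  backbone (configurable depth/growth) with global average pooling and a
  3-way softmax head; accepts any input size above its pooling minimum.

Hidden activations are rectified linear throughout. A ``width`` multiplier
scales the convolutional filter counts for reduced-size experiments without
touching the layer topology; the defaults are the full filter counts.
"""

from __future__ import annotations

import numpy as np

from .layers import (AvgPool2, Conv2D, Dense, DenseBlock, Dropout, Flatten,
                     GlobalAvgPool, MaxPool2, ReLU)
from .network import Sequential

__all__ = ["build_pl_stage1", "build_pl_stage2_counter", "build_phenotype",
           "build_ol_classifier", "conv_output_shape"]


def conv_output_shape(shape: tuple[int, int], ops: list[str],
                      k: int = 3) -> tuple[int, int]:
    """Spatial bookkeeping for a stack of valid convs ('c') and 2x2 pools
    ('p'); raises if any stage would collapse below 1 px."""
    h, w = shape
    for op in ops:
        if op == "c":
            h, w = h - (k - 1), w - (k - 1)
        elif op == "p":
            h, w = h // 2, w // 2
        if h < 1 or w < 1:
            raise ValueError(
                f"input {shape} too small for the conv/pool cascade at {op!r}")
    return h, w


def build_pl_stage1(input_shape: tuple[int, int] = (32, 32), width: int = 64,
                    seed: int = 0) -> Sequential:
    rng = np.random.default_rng(seed)
    h, w = conv_output_shape(input_shape, ["c", "c", "p", "c", "c"])
    layers = [
        Conv2D(1, width, rng=rng), ReLU(),
        Conv2D(width, width, rng=rng), ReLU(),
        MaxPool2(), Dropout(0.25),
        Conv2D(width, width, rng=rng), ReLU(),
        Conv2D(width, width, rng=rng), ReLU(),
        Flatten(),
        Dense(h * w * width, 256, rng=rng), ReLU(),
        Dense(256, 3, rng=rng),
    ]
    return Sequential(layers, head="softmax", name="pl_stage1")


def build_pl_stage2_counter(input_shape: tuple[int, int], width: int = 32,
                            seed: int = 0) -> Sequential:
    """``input_shape`` is the (rows, cols) of the 3-channel class-score map."""
    rng = np.random.default_rng(seed)
    h, w = conv_output_shape(input_shape, ["c", "p", "c", "p"])
    layers = [
        Conv2D(3, width, rng=rng), ReLU(),
        AvgPool2(),
        Conv2D(width, width, rng=rng), ReLU(),
        MaxPool2(),
        Flatten(),
        Dense(h * w * width, 256, rng=rng), ReLU(),
        Dense(256, 2, rng=rng), ReLU(),  # rectified head: counts are >= 0
    ]
    return Sequential(layers, head="linear", name="pl_stage2_counter")


def build_phenotype(input_shape: tuple[int, int] = (100, 100), width: int = 64,
                    seed: int = 0) -> Sequential:
    rng = np.random.default_rng(seed)
    ops = ["c", "c", "c", "p"] * 3
    h, w = conv_output_shape(input_shape, ops)
    layers: list = []
    c_in = 1
    for _ in range(3):
        for _ in range(3):
            layers += [Conv2D(c_in, width, rng=rng), ReLU()]
            c_in = width
        layers += [MaxPool2(), Dropout(0.25)]
    layers += [Flatten(), Dense(h * w * width, 256, rng=rng), ReLU(),
               Dense(256, 2, rng=rng)]
    return Sequential(layers, head="softmax", name="phenotype")


def build_ol_classifier(width: int = 16, block_layers: int = 3,
                        growth: int = 12, n_blocks: int = 2,
                        seed: int = 0) -> Sequential:
    """Compact densely connected backbone with a 3-unit softmax head.

    Global average pooling makes the network input-size agnostic (any patch
    at least ~16 px on a side); the canonical object-level patch is 112x112.
    """
    rng = np.random.default_rng(seed)
    layers: list = [Conv2D(1, width, rng=rng), ReLU(), MaxPool2()]
    c = width
    for _ in range(n_blocks):
        block = DenseBlock(c, block_layers, growth, rng=rng)
        c = block.c_out
        layers += [block, MaxPool2()]
    layers += [GlobalAvgPool(), Dense(c, 3, rng=rng)]
    return Sequential(layers, head="softmax", name="ol_classifier")
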