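"""Shared fixtures: small synthetic fields and a lightly trained stage-1
patch classifier reused across quantitation/saliency tests."""

from __future__ import annotations

import numpy as np
import pytest

import netquant as nq
from netquant.nn import TrainConfig, build_pl_stage1, train
from netquant.patches import PatchSet, split_patches, training_arrays


def make_field(seed: int, n: int = 14, height: int = 160, width: int = 224,
               fractions=(0.5, 0.5, 0.0), hardcore: float = 28.0,
               difficulty: float = 0.0, process: str = "hardcore_poisson"):
    return nq.render_field(nq.FieldSpec(
        height=height, width=width, n_nuclei=n,
        phenotype_fractions=fractions, point_process=process,
        hardcore_distance=hardcore, difficulty=difficulty, seed=seed))


@pytest.fixture(scope="session")
def small_field():
    """One deterministic 160x224 field, 7+7 nuclei, difficulty 0."""
    return make_field(seed=42)


@pytest.fixture(scope="session")
def easy_patchset() -> PatchSet:
    """450 difficulty-0 patches (background / non-NETotic / NETotic),
    stratified 70:10:20."""
    patches, labels = nq.make_patch_arrays(
        ["background", "non_netotic", "netotic"], 250, 32, 0.0, seed=11)
    return split_patches(PatchSet(patches, labels, 32), (0.7, 0.1, 0.2),
                         seed=0)


@pytest.fixture(scope="session")
def tiny_stage1(easy_patchset):
    """A narrow (width-8) stage-1 classifier trained to high accuracy on
    the easy patch set; shared by quantitation and saliency tests."""
    x, y = training_arrays(easy_patchset, "train")
    net = build_pl_stage1(width=8, seed=0)
    train(net, x, y, TrainConfig(epochs=12, seed=0))
    xt, yt = training_arrays(easy_patchset, "test")
    assert (net.predict(xt) == yt).mean() > 0.9  # fixture sanity
    return net


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
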