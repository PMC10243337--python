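"""Shared fixtures.

The expensive artifacts — full-size forward passes of both networks and the
CPU-scale overfitting runs — are session-scoped so every test (including
the acceptance suite) reuses one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from lumbarseg import nn
from lumbarseg.locnet import (
    LocNetConfig,
    TrainConfig,
    build_localization_net,
    train_localization,
)
from lumbarseg.phantom import PhantomConfig, generate_dataset, generate_phantom
from lumbarseg.pipeline import PipelineConfig, run_training
from lumbarseg.preprocess import apply_window
from lumbarseg.xunet import XUnetConfig, build_xunet, train_segmentation

# narrow CPU-scale architectures used by training and pipeline tests;
# same topology as the defaults, reduced channel widths
SMALL_LOC_CFG = LocNetConfig(input_shape=(32, 32, 32), encoder_channels=8,
                             skip_slice=(2, 6))
SMALL_SEG_CFG = XUnetConfig(input_shape=(32, 32, 32),
                            encoder_channels=(8, 16, 32, 64),
                            decoder_channels=(32, 16, 8), n_classes=6)
# a 32^3 phantom whose five-body stack fits the small grid
SMALL_PHANTOM_CFG = PhantomConfig(shape=(32, 32, 32), n_vertebrae=5,
                                  body_radius_range=(2.0, 2.8), gap=1.5, seed=7)


@pytest.fixture(scope="session")
def small_phantom():
    """One 32^3 phantom triple (volume, labels, heatmap)."""
    return generate_phantom(SMALL_PHANTOM_CFG)


@pytest.fixture(scope="session")
def locnet_default_record():
    """Activation record of the localization net at its 96x96x128 input."""
    net = build_localization_net(LocNetConfig(), seed=0).eval()
    x = np.random.default_rng(0).normal(size=(1, 1, 96, 96, 128)).astype(np.float32)
    record: dict = {}
    with nn.no_grad():
        out = net(x, record=record)
    return record, out.data


@pytest.fixture(scope="session")
def xunet_default_record():
    """Activation record of the XUnet at its 64x64x128 input."""
    net = build_xunet(XUnetConfig(), seed=0).eval()
    x = np.random.default_rng(0).normal(size=(1, 1, 64, 64, 128)).astype(np.float32)
    record: dict = {}
    with nn.no_grad():
        out = net(x, record=record)
    return record, out.data


@pytest.fixture(scope="session")
def overfit_loc(small_phantom):
    """Localization net overfit on one 32^3 phantom for 200 MSE steps."""
    vol, lm, hm = small_phantom
    win = apply_window(vol).voxels
    net = build_localization_net(SMALL_LOC_CFG, seed=1)
    losses = train_localization(net, [(win, hm.values)],
                                TrainConfig(steps=200, seed=1))
    return net, losses


@pytest.fixture(scope="session")
def overfit_seg(small_phantom):
    """XUnet overfit on one 32^3 phantom for 300 Dice+CE steps."""
    vol, lm, hm = small_phantom
    win = apply_window(vol).voxels
    net = build_xunet(SMALL_SEG_CFG, seed=1)
    losses = train_segmentation(net, [(win, lm.labels)],
                                TrainConfig(loss_kind="dice_ce", steps=300, seed=1))
    return net, losses


@pytest.fixture(scope="session")
def pipeline_setup(tmp_path_factory):
    """Two 64x64x96 phantoms, both stages trained briefly, checkpoints on disk."""
    tmp = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(loc=SMALL_LOC_CFG, seg=SMALL_SEG_CFG, seed=3)
    triples, manifest = generate_dataset(2, PhantomConfig(seed=3), n_train=2)
    loc_ckpt, seg_ckpt = tmp / "loc.npz", tmp / "seg.npz"
    loc_losses = run_training(manifest, cfg, "loc", loc_ckpt,
                              TrainConfig(steps=120, seed=3))
    seg_losses = run_training(manifest, cfg, "seg", seg_ckpt,
                              TrainConfig(loss_kind="dice_ce", steps=150, seed=3))
    return {
        "cfg": cfg,
        "triples": triples,
        "manifest": manifest,
        "loc_ckpt": loc_ckpt,
        "seg_ckpt": seg_ckpt,
        "loc_losses": loc_losses,
        "seg_losses": seg_losses,
    }
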