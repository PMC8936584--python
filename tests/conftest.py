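"""Session fixtures: phantom datasets and the two scaled-down training runs.

The heavy fixtures (stage-1 pre-training; the end-to-end fine-tuning run)
are computed once per session and shared by the module tests and the
acceptance tests that look at different aspects of the same run.
"""

import numpy as np
import pytest

from tanet.model import TaNet, TaNetConfig
from tanet.phantom import generate_dataset
from tanet.train import (TrainConfig, finetune_end_to_end, pretrain_coarse,
                         pretrain_localizer, split_dataset)


@pytest.fixture(scope="session")
def plax_frames_64():
    """A small 64 px PLAX set for cheap structural tests."""
    return generate_dataset("plax", 4, 2, seed=7, size=64)


@pytest.fixture(scope="session")
def stage1_run():
    """Stage-1 pre-training at the desk-scale study conditions:
    50 PLAX phantoms (10 subjects x 5 frames) at 128 px."""
    samples = generate_dataset("plax", 10, 5, seed=123, size=128)
    coarse_train, fine_train, test = split_dataset(samples, (0.2, 0.6, 0.2), seed=0)
    model = TaNet(TaNetConfig.tiny(5, seed=0))
    cfg = TrainConfig.tiny(seed=0)
    coarse_history = pretrain_coarse(coarse_train, fine_train, model.coarse, cfg)
    loc_history = pretrain_localizer(fine_train, coarse_train, model, cfg)
    return {
        "model": model,
        "cfg": cfg,
        "splits": (coarse_train, fine_train, test),
        "coarse_history": coarse_history,
        "loc_history": loc_history,
    }


@pytest.fixture(scope="session")
def e2e_run():
    """The full two-stage pipeline at the desk-scale study conditions:
    30 PLAX phantoms (10 subjects x 3 frames) at 128 px, 30 fine-tune
    epochs, fixed seed."""
    samples = generate_dataset("plax", 10, 3, seed=321, size=128)
    coarse_train, fine_train, test = split_dataset(samples, (0.2, 0.6, 0.2), seed=0)
    model = TaNet(TaNetConfig.tiny(5, seed=0))
    cfg = TrainConfig.tiny(seed=0)
    pretrain_coarse(coarse_train, fine_train, model.coarse, cfg)
    pretrain_localizer(fine_train, coarse_train, model, cfg)
    history = finetune_end_to_end(fine_train, coarse_train, model, cfg)
    return {
        "model": model,
        "cfg": cfg,
        "splits": (coarse_train, fine_train, test),
        "history": history,
    }
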