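"""Shared fixtures.

The expensive artifacts (scaled-down trained classifiers, the
default-configuration generator draw) are session-scoped so the training
and recovery tests share one pair of models and one manifest draw.
"""

from __future__ import annotations

import numpy as np
import pytest

from nmrphaser import PeakList, Spectrum1D, VoigtPeak, fixture_peaklists, synthesize_spectrum
from nmrphaser.nn import TrainConfig, build_model, default_net_config, train
from nmrphaser.synth import SynthConfig, build_dataset, scaled_training_sets

#: pretraining-database size per task (the fine train/val sizes are fixed at
#: 600/150; a larger coarse-error foundation measurably helps the harder
#: first-order task)
PRETRAIN_SIZE = {"ph0": 600, "ph1": 1800}

#: Seed of record for the scaled-down pilot runs (thresholds in the
#: acceptance tests were recorded against this seed).
TRAIN_SEED = 7


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def lorentzian_spec():
    """Noiseless single Lorentzian, perfectly phased."""
    pl = PeakList(peaks=[VoigtPeak(position=2048, fwhh=10, height=1.0)], axis_len=4096)
    return synthesize_spectrum(pl, 4096)


@pytest.fixture
def dense_peaklist():
    return fixture_peaklists(1, np.random.default_rng(42), axis_len=4096)[0]


@pytest.fixture
def dense_spec(dense_peaklist):
    return synthesize_spectrum(dense_peaklist, 4096)


@pytest.fixture(scope="session")
def scaled_sets():
    """Scaled-down curriculum datasets for both tasks (600/150 + pretrain)."""
    return {
        task: scaled_training_sets(
            task, TRAIN_SEED, n_pretrain=PRETRAIN_SIZE[task]
        )
        for task in ("ph0", "ph1")
    }


def _train_one(task: str, sets) -> object:
    model = build_model(default_net_config(task), seed=TRAIN_SEED, verbose=False)
    model.task = task
    tcfg = TrainConfig(epochs=30, seed=TRAIN_SEED, curriculum="both")
    model, history = train(
        model,
        sets["train"],
        sets["val"],
        tcfg,
        pretrain_set=sets["pretrain"],
        pretrain_epochs=15,
    )
    model.history = history
    return model


@pytest.fixture(scope="session")
def trained_models(scaled_sets):
    """The tandem pair trained with the documented scaled configuration.

    4096-point spectra, 600 train / 150 val per task, curriculum =
    15 pretraining + 30 fine-tuning epochs, batch 4, seed of record.
    """
    return {task: _train_one(task, scaled_sets[task]) for task in ("ph0", "ph1")}


@pytest.fixture(scope="session")
def default_draw_manifests():
    """2,000-sample manifest draw at the full default generator config.

    Spectra are discarded (manifest-only) — the draw feeds the
    generator-fidelity checks on broad-peak rate and injected-phase ranges.
    """
    out = {}
    for task, seed in (("ph0", 17), ("ph1", 18)):
        bases = fixture_peaklists(2, np.random.default_rng(seed))
        cfg = SynthConfig(n_augment_per_list=200)
        manifest, _ = build_dataset(
            bases, cfg, task, master_seed=seed, max_samples=1000, collect=False
        )
        out[task] = manifest
    return out
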