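"""Shared fixtures: synthetic corpora and one session-scoped trained model.

The trained model is the expensive fixture (a full scaled-down training
run); every test that needs trained embeddings shares it.
"""

from __future__ import annotations

import numpy as np
import pytest

from mosqid.embednet import BackboneConfig, build_model
from mosqid.synth import (SyntheticSpec, default_class_generators, demo_spec,
                          external_source, generate_synthetic_dataset)
from mosqid.trainer import TrainConfig, train_model

E2E_SEED = 7
E2E_EPOCHS = 20
E2E_BATCHES_PER_EPOCH = 40


@pytest.fixture(scope="session")
def synth_dataset(tmp_path_factory):
    """5 balanced classes x 40 images over the two standard sources."""
    out = tmp_path_factory.mktemp("synth_main")
    spec = demo_spec(n_classes=5, per_class=40, seed=E2E_SEED)
    manifest = generate_synthetic_dataset(spec, out)
    return manifest


@pytest.fixture(scope="session")
def unseen_class_dataset(tmp_path_factory):
    """A 6th class the model never trains on, rendered under the external
    (second, uncontrolled) source; 90% pseudo-training / 10% queries."""
    out = tmp_path_factory.mktemp("synth_ext")
    gens = default_class_generators(6)
    spec = SyntheticSpec(n_classes=1, per_class_counts=[60],
                         image_size=(64, 64), sources=[external_source()],
                         class_generators=[gens[5]], seed=E2E_SEED,
                         class_codes=["syn05_f"])
    return generate_synthetic_dataset(spec, out)


@pytest.fixture(scope="session")
def trained(synth_dataset):
    """Scaled-down training run: smallcnn, 20 epochs, 40 batches/epoch."""
    codes = sorted(synth_dataset.counts())
    model = build_model(BackboneConfig(), n_classes=len(codes), seed=E2E_SEED,
                        vocabulary=codes)
    cfg = TrainConfig(epochs=E2E_EPOCHS, seed=E2E_SEED,
                      batches_per_epoch=E2E_BATCHES_PER_EPOCH)
    model, history = train_model(model, synth_dataset, cfg)
    return model, history


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_model():
    """A small untrained model for shape/determinism contracts."""
    return build_model(BackboneConfig(channels=(8, 16)), embed_dim=64,
                       n_out=20, seed=3)
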