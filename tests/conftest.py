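"""Shared fixtures: synthetic segments, datasets and extracted feature batteries.

Everything is generated programmatically and seeded; the heavier feature
batteries are session-scoped so the classifier and evaluation tests share
one extraction pass.
"""

from __future__ import annotations

import numpy as np
import pytest

import segvoice as sv
from segvoice.labels import EMOTIONS, LABEL_TO_INT


def extract_battery(n_per_class: int, separation: float, seed: int):
    """Feature matrix + integer labels for a balanced synthetic dataset."""
    cfg = sv.SynthConfig(n_per_class=n_per_class, separation=separation, seed=seed)
    X, y = [], []
    for label in EMOTIONS:
        for i in range(n_per_class):
            seg = sv.synth_segment(label, cfg, i)
            X.append(sv.extract_feature_vector(seg).values)
            y.append(LABEL_TO_INT[label])
    return np.asarray(X), np.asarray(y)


@pytest.fixture(scope="session")
def anger_segment() -> sv.AudioSegment:
    return sv.synth_segment("anger", sv.SynthConfig(seed=7), 0)


@pytest.fixture(scope="session")
def silence_segment() -> sv.AudioSegment:
    return sv.AudioSegment(samples=np.zeros(24_000), rate=16_000)


@pytest.fixture(scope="session")
def sine_segment() -> sv.AudioSegment:
    t = np.arange(24_000) / 16_000
    return sv.AudioSegment(samples=0.8 * np.sin(2 * np.pi * 440.0 * t), rate=16_000)


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory):
    """A written-to-disk synthetic dataset: 3 files per class."""
    out = tmp_path_factory.mktemp("synthset")
    manifest = sv.make_dataset(sv.SynthConfig(n_per_class=3, seed=5), out)
    return out, manifest


@pytest.fixture(scope="session")
def battery_high():
    """n=360 feature battery at full class separation (the high-signal condition)."""
    return extract_battery(60, 1.0, seed=11)


@pytest.fixture(scope="session")
def battery_zero():
    """n=360 feature battery at zero separation (labels carry no information)."""
    return extract_battery(60, 0.0, seed=12)


@pytest.fixture(scope="session")
def battery_small():
    """n=60 battery at full separation for quick classifier checks."""
    return extract_battery(10, 1.0, seed=3)
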