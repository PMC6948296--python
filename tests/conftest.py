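"""Shared fixtures: synthetic recordings and featurized study datasets.

Everything is generated at test time from seeds; the heavier featurized
datasets are cached per session so several tests can share them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from apneatw.config import RunConfig
from apneatw.features import featurize_recording
from apneatw.io import EcgRecording
from apneatw.synth import SynthConfig, generate_recording

warnings.filterwarnings("ignore", message=".*undefined.*")

# study conditions for the model-level experiments: a released-set-sized
# corpus of multi-hour synthetic recordings, one third near-normal subjects
N_TRAIN_RECORDINGS = 20
N_TEST_RECORDINGS = 7
RECORDING_MINUTES = 100
LOW_AHI = 3.0  # near-normal subjects' fixed AHI (class C, below the 5 rule)


def clean_synth_config(**overrides) -> SynthConfig:
    """A noise-free, unmodulated generator config for exactness tests."""
    base = dict(
        duration_min=1,
        noise_sd=0.0,
        apnea_rr_modulation_depth=0.0,
        normal_hf_depth=0.0,
        amp_modulation_depth=0.0,
        rr_jitter_frac=0.0,
        rr_wander_sd=0.0,
        amp_wander_sd=0.0,
        label_pattern="N",
        seed=0,
    )
    base.update(overrides)
    return SynthConfig(**base)


def make_frames(
    seed: int,
    n_recordings: int,
    duration_min: int,
    cfg: RunConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Generate and featurize a set of recordings through the full pipeline.

    Every third recording is a near-normal subject (fixed low AHI) so the
    per-recording evaluation sees both diagnostic classes.
    """
    cfg = cfg or RunConfig()
    out: dict[str, pd.DataFrame] = {}
    for i in range(n_recordings):
        label_pattern = LOW_AHI if i % 3 == 2 else None
        rec_id = f"r{seed}_{i}"
        syn = generate_recording(
            SynthConfig(
                duration_min=duration_min, seed=seed * 1000 + i, label_pattern=label_pattern
            ),
            record_id=rec_id,
        )
        ecg = EcgRecording(rec_id, syn.signal, syn.fs, syn.minute_labels)
        out[rec_id] = featurize_recording(ecg, cfg)
    return out


@pytest.fixture(scope="session")
def study_data():
    """Cached factory for (train_frames, test_frames) per seed."""
    cache: dict[int, tuple[dict, dict]] = {}

    def get(seed: int) -> tuple[dict, dict]:
        if seed not in cache:
            cache[seed] = (
                make_frames(seed, N_TRAIN_RECORDINGS, RECORDING_MINUTES),
                make_frames(seed + 100, N_TEST_RECORDINGS, RECORDING_MINUTES),
            )
        return cache[seed]

    return get


@pytest.fixture(scope="session")
def default_recording():
    """One 20-minute synthetic recording with default (noisy) settings."""
    return generate_recording(SynthConfig(duration_min=20, seed=42), record_id="default20")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
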