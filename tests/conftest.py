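"""Shared fixtures: scaled-down synthetic recordings and epochs.

Session-scoped so the expensive generation happens once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

import neurointent as ni
from neurointent.preprocessing import preprocess_eeg, preprocess_fnirs


SMALL_PARADIGM = ni.ParadigmConfig(n_colors=3, n_reps=2, n_sessions=2)  # 18 trials
FAST_GEN = ni.GeneratorConfig(eeg_rate_hz=250.0)


@pytest.fixture(scope="session")
def small_recording() -> ni.RawRecording:
    """18-trial subject at 250 Hz EEG with default ground truth."""
    return ni.generate_subject(SMALL_PARADIGM, generator=FAST_GEN, seed=42)


@pytest.fixture(scope="session")
def small_eeg_epochs(small_recording) -> ni.EpochSet:
    rec = small_recording
    return preprocess_eeg(rec.eeg, rec.eog, rec.eeg_rate_hz, rec.schedule,
                          channel_names=rec.eeg_channel_names)


@pytest.fixture(scope="session")
def small_hbo_epochs(small_recording) -> ni.EpochSet:
    rec = small_recording
    return preprocess_fnirs(
        rec.fnirs_intensity, rec.fnirs_rate_hz, rec.schedule,
        channel_names=rec.fnirs_channel_names,
    )["HbO"]


@pytest.fixture(scope="session")
def full_recording() -> ni.RawRecording:
    """Full 84-trial subject (250 Hz EEG) with default ground truth."""
    return ni.generate_subject(ni.ParadigmConfig(), generator=FAST_GEN, seed=7)


@pytest.fixture(scope="session")
def full_eeg_epochs(full_recording) -> ni.EpochSet:
    rec = full_recording
    return preprocess_eeg(rec.eeg, rec.eog, rec.eeg_rate_hz, rec.schedule,
                          channel_names=rec.eeg_channel_names)


@pytest.fixture(scope="session")
def toy_epochs() -> ni.EpochSet:
    """Tiny deterministic epochs for arithmetic-level checks."""
    rng = np.random.default_rng(0)
    data = rng.standard_normal((12, 4, 100))
    labels = np.array(["Sd", "Sm", "Su"] * 4)
    return ni.EpochSet(
        data=data, rate_hz=50.0, labels=labels, modality="EEG",
        window_s=(-0.5, 1.5), baseline_window_s=(-0.5, -0.3),
    )


def random_adjacency(rng: np.random.Generator, n: int, p: float = 0.4) -> np.ndarray:
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    a = a | a.T
    return a.astype(bool)
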