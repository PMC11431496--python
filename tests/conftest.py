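"""Shared fixtures: study conditions for synthetic cohorts and small model
configurations that train quickly on a single CPU."""

from __future__ import annotations

import numpy as np
import pytest

from hstarousal.model import ModelConfig
from hstarousal.preprocess import PreprocessedRecord
from hstarousal.synthetic import SyntheticConfig
from hstarousal.train import TrainConfig

# High-signal-to-noise study conditions for end-to-end recovery runs:
# 20-minute records, 20 arousals per sleep hour, strong thoracic and
# heart-rate signatures, mild noise.  Fixed once for all tests.
HIGH_SNR_KWARGS = dict(
    duration_s=1200.0,
    arousal_rate=20.0,
    hr_surge_bpm=20.0,
    thor_amplitude_factor=3.0,
    wake_fraction=0.1,
    noise_sd_per_channel={"Thor": 0.02, "DHR": 0.5, "Snore": 0.02},
)


def high_snr_config(seed: int) -> SyntheticConfig:
    return SyntheticConfig(seed=seed, **HIGH_SNR_KWARGS)


@pytest.fixture
def small_model_config() -> ModelConfig:
    return ModelConfig(
        inception_filters_per_branch=4, residual_channels=16, lstm_hidden=32
    )


@pytest.fixture
def fast_train_config() -> TrainConfig:
    # learning rate raised for the short desk-scale schedule
    return TrainConfig(lr_init=1e-3, max_epochs=10)


def make_record(
    probs_or_channels,
    labels: np.ndarray,
    sleep_mask: np.ndarray | None = None,
    record_id: str = "r0",
) -> PreprocessedRecord:
    """Build a PreprocessedRecord directly for metric-level tests."""
    labels = np.asarray(labels)
    n = labels.shape[0]
    if sleep_mask is None:
        sleep_mask = np.ones(n, dtype=np.int8)
    if isinstance(probs_or_channels, dict):
        channels = probs_or_channels
    else:
        channels = {"Thor": np.repeat(np.asarray(probs_or_channels, float), 4)}
    return PreprocessedRecord(
        record_id=record_id,
        channels=channels,
        labels_1hz=labels,
        sleep_mask_1hz=np.asarray(sleep_mask, dtype=np.int8),
    )
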