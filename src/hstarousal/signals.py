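"""Signal containers: sampled traces, multichannel recordings, hypnograms.

The channel vocabulary follows the limited-channel home-sleep-testing
setting: thoracic effort (``Thor``), ECG-derived heart rate (``DHR``),
cannula-vibration snore (``Snore``), body position (``Pos``), the derived
position-change indicator (``Pos_chg``) and the hypnogram-derived binary
wake/sleep trace (``WS``, 1 = asleep).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EPOCH_S",
    "CHANNEL_NAMES",
    "CONTINUOUS_CHANNELS",
    "CATEGORICAL_CHANNELS",
    "SLEEP_STAGES",
    "WAKE_STAGE",
    "SignalTrace",
    "Recording",
    "Hypnogram",
]

#: Hypnogram scoring epoch length in seconds.
EPOCH_S = 30.0

CONTINUOUS_CHANNELS = frozenset({"Thor", "DHR", "Snore"})
CATEGORICAL_CHANNELS = frozenset({"Pos", "Pos_chg", "WS"})
CHANNEL_NAMES = CONTINUOUS_CHANNELS | CATEGORICAL_CHANNELS

WAKE_STAGE = "W"
SLEEP_STAGES = ("N1", "N2", "N3", "R")
_KNOWN_STAGES = frozenset((WAKE_STAGE,) + SLEEP_STAGES)


@dataclass
class SignalTrace:
    """A uniformly sampled 1-D signal."""

    samples: np.ndarray
    rate_hz: float
    name: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def times(self) -> np.ndarray:
        """Sample timestamps in seconds from record start."""
        return np.arange(self.n_samples) / self.rate_hz


@dataclass
class Recording:
    """A multichannel recording with per-channel sampling rates."""

    record_id: str
    channels: dict[str, SignalTrace]
    duration_s: float

    def __post_init__(self):
        for name, trace in self.channels.items():
            if name not in CHANNEL_NAMES:
                raise ValueError(f"unknown channel name {name!r}")
            # every channel must span the record within one sample period
            if abs(trace.duration_s - self.duration_s) > 1.0 / trace.rate_hz:
                raise ValueError(
                    f"channel {name!r} duration {trace.duration_s:.3f}s does "
                    f"not match record duration {self.duration_s:.3f}s"
                )

    def channel_names(self) -> list[str]:
        return sorted(self.channels)


@dataclass
class Hypnogram:
    """Per-30 s-epoch sleep-stage codes (``W`` or one of N1/N2/N3/R).

    The last epoch may be truncated by the end of the recording; the stage
    sequence still covers the full record duration.
    """

    stages: list[str] = field(default_factory=list)

    def __post_init__(self):
        unknown = set(self.stages) - _KNOWN_STAGES
        if unknown:
            raise ValueError(f"unknown stage codes: {sorted(unknown)}")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * EPOCH_S

    def is_sleep(self) -> np.ndarray:
        """Boolean vector per epoch: True where the epoch is a sleep stage."""
        return np.array([s != WAKE_STAGE for s in self.stages], dtype=bool)

    def sleep_epoch_indices(self) -> np.ndarray:
        return np.nonzero(self.is_sleep())[0]

    def total_sleep_time_s(self, duration_s: float | None = None) -> float:
        """Summed sleep-epoch time, clipping the final epoch at ``duration_s``."""
        sleep = self.is_sleep()
        if duration_s is None:
            return float(sleep.sum() * EPOCH_S)
        starts = np.arange(self.n_epochs) * EPOCH_S
        ends = np.minimum(starts + EPOCH_S, duration_s)
        spans = np.clip(ends - starts, 0.0, None)
        return float(spans[sleep].sum())
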