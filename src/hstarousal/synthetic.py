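"""Synthetic limited-channel home-sleep-testing recordings.

Generates multichannel recordings with ground-truth arousal events whose
autonomic signatures mirror the physiology an EEG-free detector can
exploit: a transient heart-rate surge, a change in thoracic-effort
amplitude, and interruption of snoring.  All signal channels are emitted
at 4 Hz (the pipeline's working resolution); the hypnogram uses 30 s
epochs.

The generator is deliberately simple — respiration is an amplitude- and
frequency-jittered sinusoid, not a validated respiratory model — because
the detector only needs arousal-locked signal changes, not waveform
realism.  See ``docs/methods.md`` for what this does and does not emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .events import EventList
from .signals import EPOCH_S, Hypnogram, Recording, SignalTrace, WAKE_STAGE

__all__ = [
    "SyntheticConfig",
    "generate_recording",
    "generate_cohort",
    "corrupt_wake_sleep",
]

FS = 4.0  # Hz, working sample rate of all synthetic channels

_DEF_NOISE = {"Thor": 0.05, "DHR": 1.0, "Snore": 0.05}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic recording.

    Parameters
    ----------
    duration_s
        Recording length in seconds (>= one 30 s epoch).
    arousal_rate
        Target arousal events per hour of sleep.  MESA-like populations
        show arousal indices around 15–25/h; default 15.
    arousal_duration_range
        (min, max) event duration in seconds.  The minimum must respect
        the 3 s scoring minimum so ground truth can never be invalidated
        by duration filtering.
    min_event_gap_s
        Minimum silence between consecutive ground-truth events; must be
        >= 10 s so the 5 s merge rule can never alter ground truth.
    hr_surge_bpm
        Peak additive heart-rate surge during an arousal (beats/min).
    thor_amplitude_factor
        Multiplicative thoracic-effort amplitude change during an event.
    snore_probability
        Per-epoch probability that a sleep epoch contains snoring bursts.
    wake_fraction
        Fraction of 30 s epochs scored Wake.
    noise_sd_per_channel
        Additive white-noise standard deviation per channel, in the
        channel's native units (Thor/Snore: fraction of unit amplitude,
        DHR: bpm).
    seed
        Master seed; identical configs produce bitwise-identical output.
    """

    duration_s: float = 3600.0
    arousal_rate: float = 15.0
    arousal_duration_range: tuple[float, float] = (5.0, 15.0)
    min_event_gap_s: float = 15.0
    hr_surge_bpm: float = 12.0
    thor_amplitude_factor: float = 2.0
    snore_probability: float = 0.3
    wake_fraction: float = 0.15
    noise_sd_per_channel: dict[str, float] = field(
        default_factory=lambda: dict(_DEF_NOISE)
    )
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.arousal_duration_range
        if lo < 3.0:
            raise ValueError("minimum arousal duration must be >= 3 s")
        if hi < lo:
            raise ValueError("arousal_duration_range must be (min, max)")
        if self.min_event_gap_s < 10.0:
            raise ValueError("min_event_gap_s must be >= 10 s")
        if self.arousal_rate < 0:
            raise ValueError("arousal_rate must be >= 0")
        if not 0.0 <= self.wake_fraction <= 1.0:
            raise ValueError("wake_fraction must lie in [0, 1]")
        if self.duration_s < EPOCH_S:
            raise ValueError("duration_s must cover at least one 30 s epoch")


def _smooth_noise(rng: np.random.Generator, n: int, cutoff_samples: float) -> np.ndarray:
    """Zero-mean slow noise: white noise low-passed by a moving average."""
    w = max(int(cutoff_samples), 1)
    x = rng.standard_normal(n + w)
    kernel = np.ones(w) / w
    y = np.convolve(x, kernel, mode="valid")[:n]
    return y - y.mean()


def _make_hypnogram(rng: np.random.Generator, n_epochs: int, wake_fraction: float) -> Hypnogram:
    n_wake = int(round(wake_fraction * n_epochs))
    stages = list(
        rng.choice(["N1", "N2", "N3", "R"], size=n_epochs, p=[0.15, 0.5, 0.2, 0.15])
    )
    wake_idx = rng.choice(n_epochs, size=n_wake, replace=False)
    for i in wake_idx:
        stages[i] = WAKE_STAGE
    return Hypnogram(stages=stages)


def _place_events(
    rng: np.random.Generator, cfg: SyntheticConfig, hyp: Hypnogram
) -> EventList:
    """Rejection-sample non-overlapping events wholly inside sleep epochs."""
    sleep = hyp.is_sleep()
    sleep_h = hyp.total_sleep_time_s(cfg.duration_s) / 3600.0
    n_target = rng.poisson(cfg.arousal_rate * sleep_h) if cfg.arousal_rate > 0 else 0
    if n_target == 0:
        return EventList()

    lo, hi = cfg.arousal_duration_range
    accepted: list[tuple[float, float]] = []
    max_attempts = 10 * n_target
    attempts = 0
    while len(accepted) < n_target and attempts < max_attempts:
        attempts += 1
        dur = rng.uniform(lo, hi)
        onset = rng.uniform(0.0, max(cfg.duration_s - dur, 0.0))
        offset = onset + dur
        # every epoch the event touches must be a sleep epoch
        e0 = int(onset // EPOCH_S)
        e1 = int(math.ceil(offset / EPOCH_S))
        if e1 > hyp.n_epochs or not sleep[e0:e1].all():
            continue
        ok = all(
            onset - b >= cfg.min_event_gap_s or a - offset >= cfg.min_event_gap_s
            for a, b in accepted
        )
        if ok:
            accepted.append((onset, offset))
    accepted.sort()
    return EventList(accepted)


def _event_indicator(events: EventList, n: int) -> np.ndarray:
    ind = np.zeros(n)
    t = np.arange(n) / FS
    for onset, offset in events:
        ind[(t >= onset) & (t < offset)] = 1.0
    return ind


def _hr_surge_profile(events: EventList, n: int, surge_bpm: float, tau_s: float = 5.0) -> np.ndarray:
    """Additive tachycardia: fast linear rise (1 s), plateau, exp decay after."""
    t = np.arange(n) / FS
    out = np.zeros(n)
    for onset, offset in events:
        rise = min(1.0, offset - onset)
        seg = np.zeros(n)
        m = (t >= onset) & (t < onset + rise)
        seg[m] = surge_bpm * (t[m] - onset) / rise
        m = (t >= onset + rise) & (t < offset)
        seg[m] = surge_bpm
        m = t >= offset
        seg[m] = surge_bpm * np.exp(-(t[m] - offset) / tau_s)
        out = np.maximum(out, seg)
    return out


def generate_recording(
    config: SyntheticConfig, record_id: str = "synth-000"
) -> tuple[Recording, Hypnogram, EventList]:
    """Generate one recording, its hypnogram and ground-truth arousals.

    Channels (all 4 Hz): ``Thor`` quasi-periodic respiration whose
    amplitude is multiplied by ``thor_amplitude_factor`` during events;
    ``DHR`` heart rate in bpm with an additive surge during and shortly
    after each event; ``Snore`` epoch-gated oscillatory bursts suppressed
    during events; ``Pos`` piecewise-constant position codes; ``Pos_chg``
    position-change indicator; ``WS`` binary wake/sleep (1 = asleep).
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * FS))
    t = np.arange(n) / FS
    n_epochs = int(math.ceil(config.duration_s / EPOCH_S))

    hyp = _make_hypnogram(rng, n_epochs, config.wake_fraction)
    events = _place_events(rng, config, hyp)
    ind = _event_indicator(events, n)
    noise = {**_DEF_NOISE, **config.noise_sd_per_channel}

    # --- Thor: frequency- and amplitude-jittered sinusoid -----------------
    f_resp = 0.25 * (1.0 + 0.08 * _smooth_noise(rng, n, 30 * FS))
    phase = 2.0 * np.pi * np.cumsum(f_resp) / FS
    amp = 1.0 + 0.1 * _smooth_noise(rng, n, 60 * FS)
    amp = amp * (1.0 + (config.thor_amplitude_factor - 1.0) * ind)
    thor = amp * np.sin(phase) + noise["Thor"] * rng.standard_normal(n)

    # --- DHR: baseline bpm + slow variability + arousal surge -------------
    hr = (
        62.0
        + 3.0 * _smooth_noise(rng, n, 120 * FS)
        + _hr_surge_profile(events, n, config.hr_surge_bpm)
        + noise["DHR"] * rng.standard_normal(n)
    )

    # --- Snore: epoch-gated bursts, silenced during arousals --------------
    sleep_epochs = hyp.is_sleep()
    snoring_epoch = sleep_epochs & (rng.random(n_epochs) < config.snore_probability)
    epoch_of_sample = np.minimum((t // EPOCH_S).astype(int), n_epochs - 1)
    gate = snoring_epoch[epoch_of_sample].astype(float)
    burst = np.abs(np.sin(phase)) * np.sin(2.0 * np.pi * 1.5 * t)
    snore = gate * (1.0 - 0.9 * ind) * burst + noise["Snore"] * rng.standard_normal(n)

    # --- Pos / Pos_chg: piecewise-constant codes with sparse transitions --
    pos = np.zeros(n)
    code = int(rng.integers(0, 4))
    i = 0
    while i < n:
        dwell = int(rng.exponential(30 * 60) * FS) + int(FS)  # mean dwell 30 min
        pos[i : i + dwell] = code
        code = int((code + rng.integers(1, 4)) % 4)
        i += dwell
    pos_chg = np.zeros(n)
    pos_chg[1:] = (np.diff(pos) != 0).astype(float)

    # --- WS: hypnogram replicated at 4 Hz, sleep -> 1 ----------------------
    ws = sleep_epochs[epoch_of_sample].astype(float)

    channels = {
        "Thor": SignalTrace(thor, FS, "Thor"),
        "DHR": SignalTrace(hr, FS, "DHR"),
        "Snore": SignalTrace(snore, FS, "Snore"),
        "Pos": SignalTrace(pos, FS, "Pos"),
        "Pos_chg": SignalTrace(pos_chg, FS, "Pos_chg"),
        "WS": SignalTrace(ws, FS, "WS"),
    }
    rec = Recording(record_id=record_id, channels=channels, duration_s=n / FS)
    return rec, hyp, events


def generate_cohort(
    n_records: int, config: SyntheticConfig
) -> list[tuple[Recording, Hypnogram, EventList]]:
    """Generate ``n_records`` independent recordings, seeded from ``config.seed``."""
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    children = np.random.SeedSequence(config.seed).spawn(n_records)
    out = []
    for i, ss in enumerate(children):
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        sub = replace(config, seed=sub_seed, noise_sd_per_channel=dict(config.noise_sd_per_channel))
        out.append(generate_recording(sub, record_id=f"synth-{config.seed}-{i:03d}"))
    return out


def corrupt_wake_sleep(hypnogram: Hypnogram, error_rate: float, seed: int) -> Hypnogram:
    """Flip each epoch's wake/sleep label independently with ``error_rate``.

    Models an imperfect EEG-free sleep/wake classifier standing in for the
    hypnogram.  Stage detail is not preserved: a flipped sleep epoch
    becomes Wake and a flipped wake epoch becomes N2.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    flip = rng.random(hypnogram.n_epochs) < error_rate
    stages = []
    for s, f in zip(hypnogram.stages, flip):
        if not f:
            stages.append(s)
        elif s == WAKE_STAGE:
            stages.append("N2")
        else:
            stages.append(WAKE_STAGE)
    return Hypnogram(stages=stages)
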