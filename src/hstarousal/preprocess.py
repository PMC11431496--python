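"""Channel derivation and preprocessing for the arousal-detection pipeline.

All model inputs are brought to 4 Hz and robust-standardized (median
removed, interquartile range scaled to 1); the heart-rate channel is
outlier-corrected beforehand to undo R-peak misdetection artifacts.  No
frequency filtering is applied — noise robustness is left to the
convolutional front end of the detector.

Conventions: time in seconds from record start, 0-based; intervals are
half-open ``[onset, offset)``; the 1 Hz label at index ``t`` covers
``[t, t+1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import EventList
from .signals import (
    CATEGORICAL_CHANNELS,
    EPOCH_S,
    Hypnogram,
    Recording,
    SignalTrace,
)

__all__ = [
    "TARGET_RATE_HZ",
    "QualityReport",
    "PreprocessedRecord",
    "resample_to_4hz",
    "robust_standardize",
    "correct_hr_outliers",
    "derive_wake_sleep",
    "derive_position_change",
    "assess_quality",
    "make_labels",
    "preprocess_record",
]

TARGET_RATE_HZ = 4.0

HR_MIN_BPM = 25.0
HR_MAX_BPM = 220.0
HR_JUMP_BPM = 30.0
HR_MEDIAN_WIN_S = 5.0

FLAT_RUN_S = 5.0  # a channel flat for longer than this counts as bad
BAD_FRACTION_LIMIT = 0.5  # record excluded iff bad fraction > 50% of sleep


@dataclass
class QualityReport:
    """Per-record signal-quality assessment driving record inclusion."""

    record_id: str
    per_channel_bad_fraction: dict[str, float] = field(default_factory=dict)
    degenerate_channels: set[str] = field(default_factory=set)

    @property
    def include(self) -> bool:
        """False iff any assessed channel is bad for more than half of sleep."""
        return all(
            frac <= BAD_FRACTION_LIMIT
            for frac in self.per_channel_bad_fraction.values()
        )


@dataclass
class PreprocessedRecord:
    """Model-ready record: standardized 4 Hz channels plus 1 Hz labels."""

    record_id: str
    channels: dict[str, np.ndarray]  # each length 4 * floor(duration_s)
    labels_1hz: np.ndarray
    sleep_mask_1hz: np.ndarray
    quality: QualityReport | None = None

    @property
    def n_seconds(self) -> int:
        return int(self.labels_1hz.shape[0])

    def input_matrix(self, channel_names: list[str]) -> np.ndarray:
        """Stack the requested channels into a ``(n_channels, 4*T)`` array."""
        return np.stack([self.channels[c] for c in channel_names])


def resample_to_4hz(trace: SignalTrace, method: str | None = None) -> SignalTrace:
    """Resample a trace to 4 Hz.

    Continuous channels are linearly interpolated onto the 0.25 s grid;
    binary/categorical channels use nearest-neighbor so no fractional
    codes appear.  ``method`` overrides the per-channel-name default
    (``"linear"`` or ``"nearest"``).
    """
    if trace.n_samples == 0:
        raise ValueError("cannot resample an empty trace")
    if method is None:
        method = "nearest" if trace.name in CATEGORICAL_CHANNELS else "linear"
    if trace.rate_hz == TARGET_RATE_HZ:
        return SignalTrace(trace.samples.copy(), TARGET_RATE_HZ, trace.name)

    n_out = int(round(trace.duration_s * TARGET_RATE_HZ))
    t_out = np.arange(n_out) / TARGET_RATE_HZ
    t_in = trace.times()
    if method == "linear":
        out = np.interp(t_out, t_in, trace.samples)
    elif method == "nearest":
        idx = np.clip(
            np.round(t_out * trace.rate_hz).astype(int), 0, trace.n_samples - 1
        )
        out = trace.samples[idx]
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    return SignalTrace(out, TARGET_RATE_HZ, trace.name)


def robust_standardize(
    trace: SignalTrace, quality: QualityReport | None = None
) -> SignalTrace:
    """Remove the record-wise median and scale the interquartile range to 1.

    A flat channel (IQR = 0) is only median-centered and flagged as
    degenerate in the quality report when one is supplied.
    """
    x = trace.samples
    med = np.median(x)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        if quality is not None:
            quality.degenerate_channels.add(trace.name)
        return SignalTrace(x - med, trace.rate_hz, trace.name)
    return SignalTrace((x - med) / iqr, trace.rate_hz, trace.name)


def _rolling_median(x: np.ndarray, win: int) -> np.ndarray:
    from scipy.ndimage import median_filter

    return median_filter(x, size=win, mode="nearest")


def correct_hr_outliers(
    hr: SignalTrace, quality: QualityReport | None = None
) -> SignalTrace:
    """Repair R-peak-misdetection artifacts in the heart-rate channel.

    Samples outside [25, 220] bpm or deviating by more than 30 bpm from a
    5 s rolling median are replaced by linear interpolation between the
    neighboring valid samples.  Operates on bpm-scale values, before
    standardization.  If more than half the samples are invalid the
    channel is flagged in the quality report.
    """
    x = hr.samples.astype(float).copy()
    n = x.shape[0]
    win = max(int(round(HR_MEDIAN_WIN_S * hr.rate_hz)), 1)
    rolling = _rolling_median(x, win)
    bad = (
        (x < HR_MIN_BPM)
        | (x > HR_MAX_BPM)
        | (np.abs(x - rolling) > HR_JUMP_BPM)
        | ~np.isfinite(x)
    )
    if bad.all():
        raise ValueError("heart-rate channel contains no valid samples")
    if bad.mean() > BAD_FRACTION_LIMIT and quality is not None:
        quality.degenerate_channels.add(hr.name or "DHR")

    good_idx = np.nonzero(~bad)[0]
    t = np.arange(n)
    x[bad] = np.interp(t[bad], good_idx, x[good_idx])
    np.clip(x, HR_MIN_BPM, HR_MAX_BPM, out=x)
    return SignalTrace(x, hr.rate_hz, hr.name)


def derive_wake_sleep(hypnogram: Hypnogram, target_rate: float = TARGET_RATE_HZ) -> SignalTrace:
    """Binary wake/sleep trace replicated from 30 s epochs (sleep -> 1)."""
    if hypnogram.n_epochs == 0:
        raise ValueError("empty hypnogram")
    per_epoch = hypnogram.is_sleep().astype(float)
    samples_per_epoch = int(round(EPOCH_S * target_rate))
    out = np.repeat(per_epoch, samples_per_epoch)
    return SignalTrace(out, target_rate, "WS")


def derive_position_change(pos: SignalTrace) -> SignalTrace:
    """1 exactly at samples where the position code changes; first sample 0."""
    x = pos.samples
    out = np.zeros_like(x)
    if x.shape[0] > 1:
        out[1:] = (np.diff(x) != 0).astype(float)
    return SignalTrace(out, pos.rate_hz, "Pos_chg")


def _bad_sample_mask(name: str, x: np.ndarray, rate_hz: float) -> np.ndarray:
    """Missing, flat-for->5 s, or out-of-physiological-range samples.

    Binary/categorical channels are legitimately piecewise constant, so
    the flat-run criterion only applies to continuous channels.
    """
    bad = ~np.isfinite(x)
    if name == "DHR":
        bad |= (x < HR_MIN_BPM) | (x > HR_MAX_BPM)
    if name in CATEGORICAL_CHANNELS:
        return bad
    # flat runs longer than FLAT_RUN_S
    n = x.shape[0]
    if n > 1:
        same = np.concatenate([[False], np.diff(x) == 0])
        # run-length encode the "same as previous" indicator
        run_len = np.zeros(n, dtype=int)
        count = 0
        limit = int(FLAT_RUN_S * rate_hz)
        flat = np.zeros(n, dtype=bool)
        for i in range(n):
            count = count + 1 if same[i] else 1
            run_len[i] = count
        # mark every sample belonging to a run longer than the limit
        i = n - 1
        while i >= 0:
            if run_len[i] > limit:
                flat[i - run_len[i] + 1 : i + 1] = True
                i -= run_len[i]
            else:
                i -= 1
        bad |= flat
    return bad


def assess_quality(
    recording: Recording,
    hypnogram: Hypnogram,
    selected_channels: list[str],
) -> QualityReport:
    """Share of sleep time each selected channel is missing, flat or out of range.

    A record is kept unless some selected channel is bad for more than 50 %
    of sleep time (a bad fraction of exactly 0.5 still passes).
    """
    report = QualityReport(record_id=recording.record_id)
    sleep_epochs = hypnogram.is_sleep()
    for name in selected_channels:
        if name not in recording.channels:
            raise KeyError(f"channel {name!r} not present in recording")
        trace = recording.channels[name]
        t = trace.times()
        epoch_idx = np.minimum((t // EPOCH_S).astype(int), hypnogram.n_epochs - 1)
        in_sleep = sleep_epochs[epoch_idx]
        if not in_sleep.any():
            report.per_channel_bad_fraction[name] = 0.0
            continue
        bad = _bad_sample_mask(name, trace.samples, trace.rate_hz)
        report.per_channel_bad_fraction[name] = float(
            bad[in_sleep].mean()
        )
    return report


def make_labels(
    events: EventList, hypnogram: Hypnogram, duration_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-second arousal labels and sleep mask.

    ``labels_1hz[t]`` is 1 iff the second ``[t, t+1)`` intersects a
    ground-truth event; ``sleep_mask_1hz[t]`` is 1 iff second ``t`` lies
    in a sleep epoch.
    """
    n = int(np.floor(duration_s))
    labels = np.zeros(n, dtype=np.int8)
    for onset, offset in events:
        if onset < 0 or offset > duration_s:
            raise ValueError("event outside the record span")
        lo = int(np.floor(onset))
        hi = min(int(np.ceil(offset)), n)
        labels[lo:hi] = 1
    sec_epoch = np.minimum(
        (np.arange(n) // int(EPOCH_S)).astype(int), hypnogram.n_epochs - 1
    )
    sleep_mask = hypnogram.is_sleep()[sec_epoch].astype(np.int8)
    return labels, sleep_mask


def preprocess_record(
    recording: Recording,
    hypnogram: Hypnogram,
    events: EventList,
    selected_channels: list[str] | None = None,
) -> PreprocessedRecord:
    """Full preprocessing of one record.

    Derives missing ``WS``/``Pos_chg`` channels, corrects heart-rate
    outliers, resamples everything to 4 Hz, robust-standardizes the
    continuous channels (binary channels are left on their 0/1 scale) and
    builds 1 Hz labels and sleep mask.
    """
    if selected_channels is None:
        selected_channels = sorted(recording.channels)
    quality = assess_quality(
        recording, hypnogram,
        [c for c in selected_channels if c in recording.channels],
    )

    out: dict[str, np.ndarray] = {}
    n_4hz = int(np.floor(recording.duration_s)) * int(TARGET_RATE_HZ)
    for name in selected_channels:
        if name in recording.channels:
            trace = recording.channels[name]
        elif name == "WS":
            trace = derive_wake_sleep(hypnogram)
        elif name == "Pos_chg":
            trace = derive_position_change(recording.channels["Pos"])
        else:
            raise KeyError(f"cannot derive channel {name!r}")
        if name == "DHR":
            trace = correct_hr_outliers(trace, quality)
        trace = resample_to_4hz(trace)
        if name not in CATEGORICAL_CHANNELS:
            trace = robust_standardize(trace, quality)
        x = trace.samples
        if x.shape[0] < n_4hz:
            x = np.pad(x, (0, n_4hz - x.shape[0]), mode="edge")
        out[name] = x[:n_4hz]

    labels, sleep_mask = make_labels(events, hypnogram, recording.duration_s)
    return PreprocessedRecord(
        record_id=recording.record_id,
        channels=out,
        labels_1hz=labels,
        sleep_mask_1hz=sleep_mask,
        quality=quality,
    )
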