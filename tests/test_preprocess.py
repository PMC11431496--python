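"""Tests of channel derivation, resampling, standardization and quality rules."""

import numpy as np
import pytest

from hstarousal.events import EventList
from hstarousal.preprocess import (
    QualityReport,
    assess_quality,
    correct_hr_outliers,
    derive_position_change,
    derive_wake_sleep,
    make_labels,
    preprocess_record,
    resample_to_4hz,
    robust_standardize,
)
from hstarousal.signals import Hypnogram, Recording, SignalTrace
from hstarousal.synthetic import SyntheticConfig, generate_recording


class TestResample:
    def test_constant_trace_preserved(self):
        out = resample_to_4hz(SignalTrace(np.full(320, 7.0), 32.0, "Thor"))
        assert out.rate_hz == 4.0
        assert out.n_samples == 40
        np.testing.assert_allclose(out.samples, 7.0)

    def test_4hz_input_identity(self):
        x = np.arange(40.0)
        out = resample_to_4hz(SignalTrace(x, 4.0, "Thor"))
        np.testing.assert_array_equal(out.samples, x)

    def test_upsampled_ramp_matches_linear_interpolation(self):
        ramp = SignalTrace(np.arange(10.0), 1.0, "Thor")
        out = resample_to_4hz(ramp)
        assert out.n_samples == 40
        assert np.all(np.diff(out.samples) >= 0)
        # oracle: direct linear interpolation on the 0.25 s grid
        expected = np.interp(np.arange(40) / 4.0, np.arange(10.0), np.arange(10.0))
        np.testing.assert_allclose(out.samples, expected)

    def test_binary_channel_keeps_integer_codes(self):
        pos = SignalTrace(np.repeat([0.0, 2.0, 1.0], 16), 16.0, "Pos")
        out = resample_to_4hz(pos)
        assert set(np.unique(out.samples)) <= {0.0, 1.0, 2.0}

    def test_idempotent_at_4hz(self):
        x = SignalTrace(np.random.default_rng(0).standard_normal(80), 8.0, "Thor")
        once = resample_to_4hz(x)
        twice = resample_to_4hz(once)
        np.testing.assert_array_equal(once.samples, twice.samples)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            resample_to_4hz(SignalTrace(np.array([]), 4.0, "Thor"))


class TestRobustStandardize:
    def test_small_sample_centered_and_scaled(self):
        out = robust_standardize(SignalTrace(np.array([1.0, 2, 3, 4, 5]), 4.0, "Thor"))
        assert np.median(out.samples) == pytest.approx(0.0, abs=1e-12)
        q75, q25 = np.percentile(out.samples, [75, 25])
        assert q75 - q25 == pytest.approx(1.0, abs=1e-12)

    def test_idempotence(self):
        x = SignalTrace(np.random.default_rng(1).normal(10, 5, 1000), 4.0, "Thor")
        once = robust_standardize(x)
        twice = robust_standardize(once)
        np.testing.assert_allclose(once.samples, twice.samples, atol=1e-12)

    def test_large_sample_median_near_zero(self):
        x = SignalTrace(np.random.default_rng(2).normal(10, 5, 10**5), 4.0, "Thor")
        out = robust_standardize(x)
        assert -0.02 <= np.median(out.samples) <= 0.02

    def test_flat_signal_flagged_degenerate(self):
        q = QualityReport(record_id="r")
        out = robust_standardize(SignalTrace(np.full(100, 3.0), 4.0, "Snore"), q)
        np.testing.assert_array_equal(out.samples, 0.0)
        assert "Snore" in q.degenerate_channels


class TestCorrectHrOutliers:
    def test_clean_constant_unchanged(self):
        hr = SignalTrace(np.full(400, 60.0), 4.0, "DHR")
        np.testing.assert_array_equal(correct_hr_outliers(hr).samples, 60.0)

    def test_single_spike_interpolated(self):
        x = np.full(400, 60.0)
        x[200] = 300.0
        out = correct_hr_outliers(SignalTrace(x, 4.0, "DHR"))
        assert out.samples[200] == pytest.approx(60.0, abs=1e-6)
        assert out.samples.max() <= 220.0

    def test_spike_correction_reduces_rmse_tenfold(self):
        rng = np.random.default_rng(4)
        t = np.arange(4 * 600) / 4.0
        clean = 65.0 + 8.0 * np.sin(2 * np.pi * t / 300.0)
        noisy = clean.copy()
        spikes = rng.random(noisy.size) < 0.01
        noisy[spikes] += rng.choice([-1, 1], spikes.sum()) * rng.uniform(
            60, 200, spikes.sum()
        )
        corrected = correct_hr_outliers(SignalTrace(noisy, 4.0, "DHR")).samples
        rmse_before = np.sqrt(np.mean((noisy - clean) ** 2))
        rmse_after = np.sqrt(np.mean((corrected - clean) ** 2))
        assert rmse_after * 10 <= rmse_before

    def test_mostly_invalid_channel_flagged(self):
        q = QualityReport(record_id="r")
        x = np.full(400, 10.0)  # below physiological floor
        x[:100] = 70.0
        correct_hr_outliers(SignalTrace(x, 4.0, "DHR"), q)
        assert "DHR" in q.degenerate_channels


class TestDeriveChannels:
    def test_all_wake_gives_zero_trace(self):
        out = derive_wake_sleep(Hypnogram(stages=["W"] * 4))
        np.testing.assert_array_equal(out.samples, 0.0)

    def test_wake_then_sleep_epochs(self):
        out = derive_wake_sleep(Hypnogram(stages=["W", "N2"]), target_rate=4.0)
        np.testing.assert_array_equal(out.samples[:120], 0.0)
        np.testing.assert_array_equal(out.samples[120:], 1.0)
        assert out.n_samples == 240

    def test_agreement_with_per_sample_epoch_lookup(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            stages = list(rng.choice(["W", "N1", "N2", "N3", "R"], size=20))
            hyp = Hypnogram(stages=stages)
            out = derive_wake_sleep(hyp, target_rate=4.0)
            # oracle: independent index mapping per sample
            for i in rng.choice(out.n_samples, size=50, replace=False):
                epoch = int((i / 4.0) // 30.0)
                assert out.samples[i] == (0.0 if stages[epoch] == "W" else 1.0)

    def test_position_change_examples(self):
        out = derive_position_change(
            SignalTrace(np.array([1.0, 1, 2, 2, 1]), 4.0, "Pos")
        )
        np.testing.assert_array_equal(out.samples, [0, 0, 1, 0, 1])
        const = derive_position_change(SignalTrace(np.full(50, 2.0), 4.0, "Pos"))
        assert const.samples.sum() == 0

    def test_position_change_counts_adjacent_differences(self):
        rng = np.random.default_rng(8)
        codes = rng.integers(0, 4, size=10**4).astype(float)
        out = derive_position_change(SignalTrace(codes, 4.0, "Pos"))
        assert out.samples.sum() == np.sum(codes[1:] != codes[:-1])


class TestAssessQuality:
    def _recording(self, thor: np.ndarray) -> tuple[Recording, Hypnogram]:
        n = thor.size
        hyp = Hypnogram(stages=["N2"] * int(np.ceil(n / 4.0 / 30.0)))
        rec = Recording(
            record_id="r",
            channels={"Thor": SignalTrace(thor, 4.0, "Thor")},
            duration_s=n / 4.0,
        )
        return rec, hyp

    def test_clean_record_included(self):
        cfg = SyntheticConfig(duration_s=600, seed=5)
        rec, hyp, _ = generate_recording(cfg)
        report = assess_quality(rec, hyp, ["Thor", "DHR", "Snore"])
        assert report.include
        assert all(v < 0.05 for v in report.per_channel_bad_fraction.values())

    def test_60_percent_flat_excluded(self):
        x = np.random.default_rng(0).standard_normal(2400)
        x[: int(0.6 * x.size)] = 0.0
        rec, hyp = self._recording(x)
        assert not assess_quality(rec, hyp, ["Thor"]).include

    def test_exactly_half_flat_still_included(self):
        """The exclusion rule requires strictly more than half of sleep time."""
        x = np.random.default_rng(0).standard_normal(2400)
        x[: x.size // 2] = 0.0
        rec, hyp = self._recording(x)
        report = assess_quality(rec, hyp, ["Thor"])
        assert report.per_channel_bad_fraction["Thor"] == pytest.approx(0.5)
        assert report.include

    def test_monotone_in_zeroed_span(self):
        x = np.random.default_rng(1).standard_normal(2400)
        fracs = []
        for frac in (0.2, 0.4, 0.6, 0.8):
            y = x.copy()
            y[: int(frac * y.size)] = 0.0
            rec, hyp = self._recording(y)
            fracs.append(assess_quality(rec, hyp, ["Thor"]).per_channel_bad_fraction["Thor"])
        assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))


class TestMakeLabels:
    def _hyp(self, n_epochs):
        return Hypnogram(stages=["N2"] * n_epochs)

    def test_event_marks_intersecting_seconds_only(self):
        labels, _ = make_labels(EventList([(10.0, 13.0)]), self._hyp(2), 60.0)
        assert labels[9] == 0 and labels[13] == 0
        np.testing.assert_array_equal(labels[10:13], 1)

    def test_empty_events_all_zero(self):
        labels, mask = make_labels(EventList(), self._hyp(2), 60.0)
        assert labels.sum() == 0
        assert mask.all()

    def test_agreement_with_per_second_intersection_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            dur = 120.0
            onsets = np.sort(rng.uniform(0, dur - 10, size=3))
            events = []
            last = -10.0
            for o in onsets:
                if o > last + 1.0:
                    e = min(o + rng.uniform(0.5, 6.0), dur)
                    events.append((o, e))
                    last = e
            ev = EventList(events)
            labels, _ = make_labels(ev, self._hyp(4), dur)
            # oracle: O(T * N) interval intersection per second
            for t in range(int(dur)):
                expected = any(a < t + 1 and b > t for a, b in ev)
                assert bool(labels[t]) == expected

    def test_out_of_range_event_rejected(self):
        with pytest.raises(ValueError):
            make_labels(EventList([(50.0, 70.0)]), self._hyp(2), 60.0)

    def test_overlapping_events_rejected_by_container(self):
        with pytest.raises(ValueError):
            EventList([(0.0, 5.0), (3.0, 8.0)])


class TestPreprocessRecord:
    def test_channels_standardized_and_labels_sized(self):
        cfg = SyntheticConfig(duration_s=600, seed=6)
        rec, hyp, ev = generate_recording(cfg)
        prep = preprocess_record(rec, hyp, ev, ["Thor", "DHR", "WS"])
        assert prep.labels_1hz.shape == (600,)
        for name in ("Thor", "DHR"):
            x = prep.channels[name]
            assert np.median(x) == pytest.approx(0.0, abs=1e-9)
            q75, q25 = np.percentile(x, [75, 25])
            assert q75 - q25 == pytest.approx(1.0, abs=1e-9)
        assert set(np.unique(prep.channels["WS"])) <= {0.0, 1.0}
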