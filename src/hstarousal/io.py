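"""Reading and writing recordings (EDF) and annotations (NSRR-style XML).

EDF reading goes through MNE.  Writing uses a minimal EDF encoder (16-bit,
1 s data records) because no EDF writer is available as a library
dependency; the encoder emits standard EDF that MNE reads back.

Annotations follow the Compumedics-Profusion dialect used by the National
Sleep Research Resource: ``ScoredEvent`` elements with an event concept
name, onset (``Start``, seconds) and ``Duration`` (seconds), plus a
``SleepStages`` sequence of per-30 s-epoch stage codes
(0 = Wake, 1–3 = N1–N3, 5 = REM).
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np
from lxml import etree

from .events import EventList
from .signals import Hypnogram, Recording, SignalTrace

__all__ = [
    "write_recording_edf",
    "read_recording_edf",
    "write_annotations_xml",
    "read_annotations_xml",
    "ingest",
]

_STAGE_TO_CODE = {"W": 0, "N1": 1, "N2": 2, "N3": 3, "R": 5}
_CODE_TO_STAGE = {0: "W", 1: "N1", 2: "N2", 3: "N3", 4: "N3", 5: "R"}

AROUSAL_CONCEPT = "Arousal|Arousal ()"


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_recording_edf(recording: Recording, path) -> None:
    """Write a recording as 16-bit EDF with 1 s data records.

    Channel sampling rates must be integers (samples per 1 s record);
    the recording is truncated to whole seconds.
    """
    names = recording.channel_names()
    traces = [recording.channels[n] for n in names]
    for t in traces:
        if abs(t.rate_hz - round(t.rate_hz)) > 1e-9:
            raise ValueError("EDF export needs integer sampling rates")
    n_records = int(recording.duration_s)
    ns = len(traces)

    phys_min, phys_max, scaled = [], [], []
    dig_min, dig_max = -32768, 32767
    for t in traces:
        x = t.samples[: n_records * int(t.rate_hz)]
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            hi = lo + 1.0
        # round the physical range outward to the 8-char field precision
        lo, hi = float(f"{lo:.6g}"), float(f"{hi:.6g}")
        lo = min(lo, float(np.min(x)))
        hi = max(hi, float(np.max(x)))
        gain = (hi - lo) / (dig_max - dig_min)
        digital = np.round((x - lo) / gain + dig_min).astype("<i2")
        phys_min.append(lo)
        phys_max.append(hi)
        scaled.append(digital)

    now = datetime.datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii(recording.record_id, 80),
            _ascii("Startdate 01-JAN-2000 synthetic", 80),
            _ascii(now.strftime("%d.%m.%y"), 8),
            _ascii(now.strftime("%H.%M.%S"), 8),
            _ascii(256 * (1 + ns), 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii(1, 8),
            _ascii(ns, 4),
        ]
    )
    fields = [
        b"".join(_ascii(n, 16) for n in names),
        b"".join(_ascii("", 80) for _ in names),  # transducer
        b"".join(_ascii("", 8) for _ in names),  # physical dimension
        b"".join(_ascii(f"{v:.6g}"[:8], 8) for v in phys_min),
        b"".join(_ascii(f"{v:.6g}"[:8], 8) for v in phys_max),
        b"".join(_ascii(dig_min, 8) for _ in names),
        b"".join(_ascii(dig_max, 8) for _ in names),
        b"".join(_ascii("", 80) for _ in names),  # prefiltering
        b"".join(_ascii(int(t.rate_hz), 8) for t in traces),
        b"".join(_ascii("", 32) for _ in names),
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(f)
        for rec_i in range(n_records):
            for t, digital in zip(traces, scaled):
                spr = int(t.rate_hz)
                fh.write(digital[rec_i * spr : (rec_i + 1) * spr].tobytes())


def read_recording_edf(path, record_id: str | None = None) -> Recording:
    """Read an EDF file into a :class:`Recording` via MNE."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    sfreq = float(raw.info["sfreq"])
    data = raw.get_data()
    # MNE rescales channels it types as physiological (e.g. V for EEG);
    # undo any such unit factor so samples come back in file units.
    units = raw._orig_units if hasattr(raw, "_orig_units") else {}
    channels = {}
    for i, name in enumerate(raw.ch_names):
        x = data[i]
        unit = units.get(name, "")
        if unit in ("µV", "uV"):
            x = x * 1e6
        elif unit == "mV":
            x = x * 1e3
        elif unit == "V":
            x = x * 1.0
        channels[name] = SignalTrace(np.asarray(x, dtype=float), sfreq, name)
    duration = data.shape[1] / sfreq
    return Recording(
        record_id=record_id or Path(path).stem,
        channels=channels,
        duration_s=duration,
    )


def write_annotations_xml(hypnogram: Hypnogram, events: EventList, path) -> None:
    """Write staging and arousal events in the NSRR/Profusion XML dialect."""
    root = etree.Element("CMPStudyConfig")
    etree.SubElement(root, "EpochLength").text = "30"
    scored = etree.SubElement(root, "ScoredEvents")
    for onset, offset in events:
        ev = etree.SubElement(scored, "ScoredEvent")
        etree.SubElement(ev, "EventConcept").text = AROUSAL_CONCEPT
        etree.SubElement(ev, "Start").text = f"{onset:.6f}"
        etree.SubElement(ev, "Duration").text = f"{offset - onset:.6f}"
    stages = etree.SubElement(root, "SleepStages")
    for s in hypnogram.stages:
        etree.SubElement(stages, "SleepStage").text = str(_STAGE_TO_CODE[s])
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def read_annotations_xml(path) -> tuple[Hypnogram, EventList]:
    """Read a Profusion-dialect annotation file: stages plus arousal events."""
    tree = etree.parse(str(path))
    stages = [
        _CODE_TO_STAGE[int(el.text)]
        for el in tree.findall(".//SleepStages/SleepStage")
    ]
    pairs = []
    for ev in tree.findall(".//ScoredEvents/ScoredEvent"):
        concept = ev.findtext("EventConcept") or ""
        if "arousal" not in concept.lower():
            continue
        start = float(ev.findtext("Start"))
        dur = float(ev.findtext("Duration"))
        pairs.append((start, start + dur))
    pairs.sort()
    return Hypnogram(stages=stages), EventList(pairs)


def ingest(edf_path, annot_path) -> tuple[Recording, Hypnogram, EventList]:
    """Read a record (EDF) together with its annotation sidecar (XML)."""
    recording = read_recording_edf(edf_path)
    hypnogram, events = read_annotations_xml(annot_path)
    return recording, hypnogram, events
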