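"""Event lists: sorted, non-overlapping, half-open time intervals in seconds.

Arousal annotations and detector outputs share this container.  Intervals
are half-open ``[onset, offset)`` with onsets strictly increasing and no
pairwise overlap, so per-second label vectors and event arithmetic are
unambiguous.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Sequence

import numpy as np

__all__ = ["EventList"]


class EventList:
    """An ordered list of non-overlapping ``(onset_s, offset_s)`` intervals."""

    __slots__ = ("_arr",)

    def __init__(self, events: Iterable[Sequence[float]] = ()):
        arr = np.asarray(list(events), dtype=float)
        if arr.size == 0:
            arr = np.empty((0, 2), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("events must be (onset, offset) pairs")
        if np.any(arr[:, 1] <= arr[:, 0]):
            raise ValueError("every event needs offset > onset")
        if arr.shape[0] > 1:
            if np.any(np.diff(arr[:, 0]) <= 0):
                raise ValueError("event onsets must be strictly increasing")
            if np.any(arr[1:, 0] < arr[:-1, 1]):
                raise ValueError("events must not overlap")
        self._arr = arr

    @property
    def array(self) -> np.ndarray:
        """``(n, 2)`` float array of (onset, offset); read-only view."""
        v = self._arr.view()
        v.flags.writeable = False
        return v

    def __len__(self) -> int:
        return self._arr.shape[0]

    def __iter__(self) -> Iterator[tuple[float, float]]:
        for onset, offset in self._arr:
            yield float(onset), float(offset)

    def __getitem__(self, i) -> tuple[float, float]:
        onset, offset = self._arr[i]
        return float(onset), float(offset)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventList):
            return NotImplemented
        return self._arr.shape == other._arr.shape and np.array_equal(
            self._arr, other._arr
        )

    def __repr__(self) -> str:
        return f"EventList(n={len(self)})"

    def durations(self) -> np.ndarray:
        return self._arr[:, 1] - self._arr[:, 0]

    def gaps(self) -> np.ndarray:
        """Silence between consecutive events (length ``n - 1``)."""
        return self._arr[1:, 0] - self._arr[:-1, 1]

    def total_duration(self) -> float:
        return float(self.durations().sum())

    def shifted(self, dt: float) -> "EventList":
        return EventList(self._arr + dt)
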