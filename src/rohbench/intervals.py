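"""Half-open genomic interval arithmetic on 0-based coordinates.

Intervals are represented as ``(k, 2)`` integer arrays of ``[start, end)``
rows. All public functions expect and return arrays in sorted, pairwise
disjoint form, which is the invariant carried by :class:`ROHSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

__all__ = [
    "ROHInterval",
    "ROHSet",
    "as_interval_array",
    "total_length",
    "merge",
    "intersect",
    "subtract",
]


class ROHInterval(NamedTuple):
    """A 0-based half-open genomic interval ``[start, end)``."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def as_interval_array(intervals: Iterable | np.ndarray) -> np.ndarray:
    """Coerce an iterable of (start, end) pairs to a ``(k, 2)`` int64 array."""
    arr = np.asarray(list(intervals) if not isinstance(intervals, np.ndarray) else intervals,
                     dtype=np.int64)
    if arr.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    arr = arr.reshape(-1, 2)
    if np.any(arr[:, 0] >= arr[:, 1]):
        raise ValueError("empty or inverted interval: start must be < end")
    return arr


def _check_disjoint_sorted(arr: np.ndarray) -> None:
    if len(arr) > 1 and np.any(arr[1:, 0] < arr[:-1, 1]):
        raise ValueError("intervals overlap or are unsorted")


def total_length(arr: np.ndarray) -> int:
    """Total bp covered by a disjoint interval array."""
    if len(arr) == 0:
        return 0
    return int((arr[:, 1] - arr[:, 0]).sum())


def merge(arr: np.ndarray) -> np.ndarray:
    """Sort and merge touching/overlapping intervals into disjoint form."""
    arr = as_interval_array(arr)
    if len(arr) <= 1:
        return arr
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection of two disjoint, sorted interval arrays."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if lo < hi:
            out.append((lo, hi))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return as_interval_array(out)


def subtract(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Set difference a \\ b of two disjoint, sorted interval arrays."""
    out = []
    j = 0
    for s, e in a:
        cur = int(s)
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            if b[k, 0] > cur:
                out.append((cur, int(b[k, 0])))
            cur = max(cur, int(b[k, 1]))
            k += 1
        if cur < e:
            out.append((cur, int(e)))
    return as_interval_array(out)


@dataclass(frozen=True)
class ROHSet:
    """A sorted, pairwise-disjoint set of ROH intervals on one chromosome.

    Parameters
    ----------
    intervals
        ``(k, 2)`` array of 0-based half-open ``[start, end)`` rows.
    min_len
        The bp length threshold that was applied to produce this set;
        every interval satisfies ``end - start >= min_len``.
    """

    intervals: np.ndarray = field(default_factory=lambda: np.empty((0, 2), np.int64))
    min_len: int = 0

    def __post_init__(self):
        arr = as_interval_array(self.intervals)
        arr = arr[np.argsort(arr[:, 0], kind="stable")] if len(arr) else arr
        _check_disjoint_sorted(arr)
        if len(arr) and np.any(arr[:, 1] - arr[:, 0] < self.min_len):
            raise ValueError("interval shorter than min_len")
        object.__setattr__(self, "intervals", arr)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        for s, e in self.intervals:
            yield ROHInterval(int(s), int(e))

    @property
    def total_length(self) -> int:
        return total_length(self.intervals)

    def filtered(self, min_len: int) -> "ROHSet":
        """Drop intervals shorter than ``min_len`` bp (closed threshold)."""
        arr = self.intervals
        keep = arr[:, 1] - arr[:, 0] >= min_len if len(arr) else np.empty(0, bool)
        return ROHSet(arr[keep] if len(arr) else arr, min_len=max(min_len, self.min_len))
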