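"""Per-base boolean-array oracle for interval arithmetic tests.

Deliberately naive: every operation is computed base by base on a numpy
bool array, independently of the interval-set implementation under test.
"""

import numpy as np


def bitmap(pairs, size):
    """Bool coverage array from (start, end) half-open pairs."""
    arr = np.zeros(size, dtype=bool)
    for s, e in pairs:
        arr[s:e] = True
    return arr


def pairs_from_bitmap(arr):
    """Canonical disjoint (start, end) runs of True in a bool array."""
    padded = np.concatenate(([False], arr, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def random_pairs(rng, n, size, max_len=None):
    max_len = max_len or max(size // 10, 2)
    starts = rng.integers(0, size - 1, size=n)
    lengths = rng.integers(1, max_len, size=n)
    ends = np.minimum(starts + lengths, size)
    return list(zip(starts.tolist(), ends.tolist()))
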