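"""Shared fixtures and brute-force oracle helpers.

The oracles here are deliberately naive (per-base boolean arrays, quadratic
all-pairs scans, exhaustive placement enumeration) and independent of the
library code paths they validate.
"""

from __future__ import annotations

import numpy as np
import pytest

from enhmap.intervals import GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20240131)


def random_intervals(rng, n, chrom="toy", max_pos=10_000, max_len=400):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos - 1))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, min(start + length, max_pos)))
    return out


def coverage_mask(intervals, size, chrom="toy"):
    """Per-base boolean occupancy oracle on a toy chromosome."""
    mask = np.zeros(size, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            mask[iv.start : iv.end] = True
    return mask


def runs_of(mask):
    """Maximal True runs of a boolean array as (start, end) half-open pairs."""
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def quadratic_overlap_pairs(a, b, min_overlap=1):
    """All-pairs overlap oracle."""
    pairs = set()
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            if x.chrom == y.chrom:
                ov = min(x.end, y.end) - max(x.start, y.start)
                if ov >= min_overlap:
                    pairs.add((i, j))
    return pairs
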