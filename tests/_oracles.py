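"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration rather than
calling the library's own algorithms, so that agreement is evidence of
correctness rather than tautology.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def brute_force_regions(masks: dict[str, np.ndarray], kind: str,
                        probe_map, config) -> set[tuple]:
    """Enumerate all intervals per chromosome; keep constant-support
    plateaus that are local maxima above the kind's minimum support, and
    extend them by outward scan. Returns {(kind, chrom, core, ext)}."""
    min_support = config.min_support(kind)
    slack = config.slack(kind)
    counts = np.zeros(len(probe_map), dtype=int)
    for m in masks.values():
        counts += m.astype(int)
    found = set()
    for chrom in probe_map.chroms:
        sl = probe_map.chrom_slice(chrom)
        c = counts[sl]
        n = c.size
        for i in range(n):
            for j in range(i, n):
                h = c[i]
                if h < min_support:
                    continue
                if not np.all(c[i:j + 1] == h):
                    continue
                left_ok = i == 0 or c[i - 1] < h
                right_ok = j == n - 1 or c[j + 1] < h
                if not (left_ok and right_ok):
                    continue
                lo, hi = i, j
                while lo > 0 and c[lo - 1] >= h - slack:
                    lo -= 1
                while hi < n - 1 and c[hi + 1] >= h - slack:
                    hi += 1
                found.add((kind, chrom,
                           (sl.start + i, sl.start + j),
                           (sl.start + lo, sl.start + hi)))
    return found


def enumerate_hypergeom_tails(n: int, ka: int, kb: int,
                              overlap: int) -> tuple[float, float]:
    """Exact tail probabilities by enumerating all C(n, kb) carrier
    placements of feature b against a fixed feature a."""
    a = set(range(ka))
    n_ge = n_le = 0
    total = comb(n, kb)
    for b in itertools.combinations(range(n), kb):
        x = len(a & set(b))
        if x >= overlap:
            n_ge += 1
        if x <= overlap:
            n_le += 1
    return n_ge / total, n_le / total


def overlap_histogram(n: int, ka: int, kb: int) -> np.ndarray:
    """Counts of each overlap size over all C(n, kb) placements."""
    a = set(range(ka))
    hist = np.zeros(min(ka, kb) + 1, dtype=np.int64)
    for b in itertools.combinations(range(n), kb):
        hist[len(a & set(b))] += 1
    return hist
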