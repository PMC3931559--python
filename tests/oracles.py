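"""Independent brute-force oracles used to pin down expected values.

Everything here is deliberately naive — string scanning, per-fragment
interval painting, direct per-base Gaussian summation, closed-form OLS —
and shares no code path with the package implementations it checks.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def count_occurrences(haystack: str, needle: str) -> int:
    """Overlapping occurrence count by repeated str.find."""
    if "N" in needle:
        return 0
    n, start = 0, 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def genome_occurrences(sequences: Dict[str, str], kmer: str) -> int:
    """Occurrence loci of ``kmer`` or its reverse complement across all
    forward strands; palindromes count once per locus."""
    fwd = sum(count_occurrences(s, kmer) for s in sequences.values())
    r = rc(kmer)
    if r == kmer:
        return fwd
    return fwd + sum(count_occurrences(s, r) for s in sequences.values())


def brute_force_mappability(
    sequences: Dict[str, str],
    repeat: str,
    k: int,
    ext: int,
) -> np.ndarray:
    """Materialize every uniquely-aligning extended fragment from both
    strand tilings of the repeat and paint its interval base by base."""
    L = len(repeat)
    counts = np.zeros(L, dtype=np.int64)
    intervals: List[Tuple[int, int]] = []
    seen = set()
    for s in range(L - k + 1):
        fwd_tile = repeat[s : s + k]
        rev_tile = rc(fwd_tile)
        for tile, strand in ((fwd_tile, "+"), (rev_tile, "-")):
            if "N" in tile:
                continue
            if genome_occurrences(sequences, tile) != 1:
                continue
            key = (s, "+") if tile == rc(tile) else (s, strand)
            if key in seen:
                continue
            seen.add(key)
            if key[1] == "+":
                lo, hi = s, s + ext
            else:
                lo, hi = s + k - ext, s + k
            intervals.append((max(lo, 0), min(hi, L)))
    for lo, hi in intervals:
        if lo < hi:
            counts[lo:hi] += 1
    return counts


def direct_gaussian_sum(
    centers: Sequence[float], length: int, bandwidth: float
) -> np.ndarray:
    """Untruncated per-base Gaussian summation (full broadcasting)."""
    b = np.arange(length, dtype=float)[:, None]
    c = np.asarray(centers, dtype=float)[None, :]
    h = float(bandwidth)
    return (np.exp(-0.5 * ((b - c) / h) ** 2) / (math.sqrt(2 * math.pi) * h)).sum(axis=1)


def ols_closed_form(x: Sequence[float], y: Sequence[float]) -> dict:
    """Textbook simple linear regression with F-test, via scipy's
    independently implemented linregress plus the adjusted-R2 formula."""
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    return {
        "slope": res.slope,
        "intercept": res.intercept,
        "r_squared": r2,
        "r_squared_adjusted": 1 - (1 - r2) * (n - 1) / (n - 2),
        "f_test_p": res.pvalue,  # t-test on slope == F-test for simple OLS
    }
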