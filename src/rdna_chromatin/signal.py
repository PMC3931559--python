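"""Read density estimation and peak calling.

Aligned reads are deduplicated, notionally extended to the estimated
fragment size, and converted to a continuous per-base signal by summing
a Gaussian kernel at each fragment center (the kernel-density approach
of F-seq-style callers).  An input (non-immunoprecipitated chromatin)
track scaled by library size can be subtracted per base, and peaks are
maximal runs of signal above a background threshold derived from the
null model of the same number of fragments placed uniformly at random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "AlignedFragment",
    "FragmentSet",
    "SignalTrack",
    "Peak",
    "dedup",
    "fragment_centers",
    "kde_track",
    "subtract_input",
    "call_peaks",
    "background_stats",
]

SQRT_2PI = math.sqrt(2.0 * math.pi)

# Kernel support radius in bandwidths.  8h makes the omitted tail mass
# < 1e-14 of a kernel, so truncation is numerically invisible at double
# precision while the per-fragment window stays small.
DEFAULT_TRUNCATE = 8.0


@dataclass(frozen=True)
class AlignedFragment:
    """One aligned read, BED-style: ``start`` is the leftmost (smallest)
    genomic coordinate of the read regardless of strand."""

    chrom: str
    start: int
    strand: str
    read_length: int = 36

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("fragment start must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class FragmentSet:
    fragments: List[AlignedFragment]
    frag_size: int = 200
    dedup_applied: bool = False

    def __len__(self) -> int:
        return len(self.fragments)


@dataclass
class SignalTrack:
    """Per-base signal over [start, start+len(values)) of ``chrom``."""

    chrom: str
    start: int
    values: np.ndarray
    total_fragments: int
    bandwidth: float

    @property
    def end(self) -> int:
        return self.start + len(self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    summit: int
    intensity: float
    area: float = 0.0

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError("summit must lie within [start, end)")


def dedup(reads: Iterable[AlignedFragment], frag_size: int = 200) -> FragmentSet:
    """Keep exactly one read per (chrom, start, strand).

    PCR duplicates of single-end reads are indistinguishable beyond
    their mapping position, so position-level collapsing is the standard
    false-positive guard.  The result is order-independent (kept reads
    are sorted by position).
    """
    unique = {(r.chrom, r.start, r.strand): r for r in reads}
    frags = [unique[k] for k in sorted(unique)]
    return FragmentSet(fragments=frags, frag_size=frag_size, dedup_applied=True)


def _center(frag: AlignedFragment, frag_size: int) -> float:
    # Extend the read to frag_size in its 3' direction; the kernel sits
    # at the midpoint of that notional fragment.
    if frag.strand == "+":
        return frag.start + frag_size / 2.0
    return frag.start + frag.read_length - frag_size / 2.0


def fragment_centers(
    frags: FragmentSet, chrom: Optional[str] = None
) -> np.ndarray:
    fs = frags.frag_size
    return np.array(
        [
            _center(f, fs)
            for f in frags.fragments
            if chrom is None or f.chrom == chrom
        ],
        dtype=float,
    )


def kde_track(
    frags: FragmentSet,
    region: Tuple[str, int, int],
    bandwidth: float = 50.0,
    truncate: float = DEFAULT_TRUNCATE,
) -> SignalTrack:
    """Gaussian kernel density of fragment centers over ``region``.

    ``values[b] = sum_i exp(-(b - c_i)^2 / (2 h^2)) / (sqrt(2 pi) h)``
    over fragments on the region's chromosome, evaluated at integer base
    positions; each kernel integrates to ~1 so the track's sum
    approximates the fragment count.  Kernels are truncated at
    ``truncate`` bandwidths from their center.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    chrom, start, end = region
    L = end - start
    h = float(bandwidth)
    radius = truncate * h
    centers = fragment_centers(frags, chrom) - start
    total = len(centers)
    centers = centers[(centers > -radius) & (centers < L + radius)]
    values = np.zeros(L, dtype=float)
    if centers.size:
        if np.allclose(centers, np.round(centers)):
            # integer centers: exact evaluation via discrete convolution
            R = int(math.ceil(radius))
            offsets = np.arange(-R, R + 1, dtype=float)
            kernel = np.exp(-0.5 * (offsets / h) ** 2) / (SQRT_2PI * h)
            counts = np.bincount(
                np.round(centers).astype(int) + R, minlength=L + 2 * R
            )
            conv = np.convolve(counts, kernel)
            values = conv[2 * R : 2 * R + L]
        else:
            base = np.arange(L, dtype=float)
            for c in centers:
                lo = max(0, int(math.floor(c - radius)) + 1)
                hi = min(L, int(math.ceil(c + radius)))
                if lo < hi:
                    d = base[lo:hi] - c
                    values[lo:hi] += np.exp(-0.5 * (d / h) ** 2) / (SQRT_2PI * h)
    return SignalTrack(
        chrom=chrom, start=start, values=values, total_fragments=total, bandwidth=h
    )


def subtract_input(chip: SignalTrack, input_track: SignalTrack) -> SignalTrack:
    """Per-base input subtraction with library-size scaling.

    ``out[b] = chip[b] - (N_chip / N_input) * input[b]``, so identical
    ChIP and input libraries cancel exactly.  Negative residuals are
    retained (not clamped) for faithful visualization of depletion.
    """
    if (chip.chrom, chip.start, len(chip)) != (
        input_track.chrom,
        input_track.start,
        len(input_track),
    ):
        raise ValueError("ChIP and input tracks must cover the same region")
    if input_track.total_fragments == 0:
        raise ValueError("input track has zero fragments; cannot scale")
    scale = chip.total_fragments / input_track.total_fragments
    return SignalTrack(
        chrom=chip.chrom,
        start=chip.start,
        values=chip.values - scale * input_track.values,
        total_fragments=chip.total_fragments,
        bandwidth=chip.bandwidth,
    )


def background_stats(
    n_fragments: int,
    region_length: int,
    bandwidth: float,
    method: str = "analytic",
    seed: int = 0,
    n_shuffles: int = 20,
    truncate: float = DEFAULT_TRUNCATE,
) -> Tuple[float, float]:
    """Mean and s.d. of the KDE value at a base under uniform random
    placement of ``n_fragments`` centers over the region.

    Analytic: each kernel contributes mass ~1, so the mean is N/L; the
    variance is N * (I2/L - (1/L)^2) with I2 = integral of the squared
    kernel = 1/(2 h sqrt(pi)).  Monte Carlo: empirical moments pooled
    over ``n_shuffles`` seeded uniform placements.
    """
    N, L, h = n_fragments, region_length, float(bandwidth)
    if method == "analytic":
        mu = N / L
        i2 = 1.0 / (2.0 * h * math.sqrt(math.pi))
        var = N * (i2 / L - 1.0 / L**2)
        return mu, math.sqrt(max(var, 0.0))
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        n_shuffles = max(n_shuffles, 20)
        acc_sum = 0.0
        acc_sq = 0.0
        count = 0
        for _ in range(n_shuffles):
            centers = rng.integers(0, L, size=N)
            frags = FragmentSet(
                [AlignedFragment("shuffle", int(c), "+", 0) for c in centers],
                frag_size=0,
            )
            track = kde_track(frags, ("shuffle", 0, L), h, truncate=truncate)
            acc_sum += float(track.values.sum())
            acc_sq += float((track.values**2).sum())
            count += L
        mu = acc_sum / count
        var = acc_sq / count - mu**2
        return mu, math.sqrt(max(var, 0.0))
    raise ValueError(f"unknown background method {method!r}")


def call_peaks(
    track: SignalTrack,
    threshold_sd: float = 4.0,
    background: str = "analytic",
    seed: int = 0,
    n_shuffles: int = 20,
) -> List[Peak]:
    """Call peaks as maximal runs of signal above the background threshold.

    The threshold is ``mu0 + threshold_sd * sigma0`` where (mu0, sigma0)
    describe the per-base KDE value under uniform placement of the same
    number of fragments (see :func:`background_stats`).  The summit is
    the leftmost maximum within a run; its value is the peak intensity.
    ``area`` is the summed signal over the run (an alternative intensity
    definition available downstream).
    """
    if threshold_sd < 0:
        raise ValueError("threshold_sd must be >= 0")
    if len(track) == 0:
        raise ValueError("empty signal track")
    mu0, sigma0 = background_stats(
        track.total_fragments,
        len(track),
        track.bandwidth,
        method=background,
        seed=seed,
        n_shuffles=n_shuffles,
    )
    threshold = mu0 + threshold_sd * sigma0
    above = track.values > threshold
    if not above.any():
        return []
    peaks: List[Peak] = []
    idx = np.flatnonzero(above)
    # split indices into maximal runs
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[0], breaks + 1])
    run_ends = np.concatenate([breaks, [len(idx) - 1]])
    for rs, re in zip(run_starts, run_ends):
        s, e = int(idx[rs]), int(idx[re]) + 1
        window = track.values[s:e]
        summit = s + int(np.argmax(window))  # argmax returns leftmost tie
        peaks.append(
            Peak(
                chrom=track.chrom,
                start=track.start + s,
                end=track.start + e,
                summit=track.start + summit,
                intensity=float(track.values[summit]),
                area=float(window.sum()),
            )
        )
    return peaks
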