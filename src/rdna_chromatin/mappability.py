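"""Per-base mappability of the repeat unit by k-mer tiling.

Because a repeat locus has dispersed partial copies (pseudogenes)
elsewhere in the genome, short reads from parts of the repeat cannot be
aligned uniquely and those regions are blind to ChIP-seq.  The
mappability track quantifies this: the repeat is tiled into k-mers (one
per base, both orientations), each k-mer is tested for genome-wide
uniqueness, unique hits are extended to the estimated fragment size in
the read's 3' direction, and every base is scored by the number of
extended fragments that overlap it.  With k=36 and 200-bp fragments the
maximum score is 400 (200 start positions x 2 strands = 100%
mappability); bases at or below 25% of the maximum are conventionally
considered poorly mappable and excluded from downstream analysis.

The built-in uniqueness search is exact-match over a hash index of all
genomic k-mers.  A mismatch-tolerant aligner's output can be consumed
instead via the SAM reader in :mod:`rdna_chromatin.io`; on real data
mismatch tolerance only removes hits (it can reveal extra alignment
locations, never new unique ones).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .genome_build import GenomeBuild, RepeatAnnotation

__all__ = [
    "MappabilityParams",
    "MappabilityTrack",
    "MappabilitySummary",
    "KmerRecord",
    "tile_kmers",
    "unique_hits",
    "extend_and_count",
    "classify_and_summarize",
    "mappability_track",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MappabilityParams:
    """Tiling and extension parameters.

    k: tile (read) length in bp.
    ext: total extended fragment length in bp; each unique hit is
        extended to this length in the read's 3' direction.
    max_mismatches: 0 for the built-in exact matcher (mismatch-tolerant
        uniqueness requires external alignments).
    poor_threshold: fraction of the maximum below or at which a base is
        called poorly mappable (strict ``>`` to count as mappable).
    """

    k: int = 36
    ext: int = 200
    max_mismatches: int = 0
    poor_threshold: float = 0.25

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.ext < self.k:
            raise ValueError("extension length must be >= k")
        if not (0.0 <= self.poor_threshold <= 1.0):
            raise ValueError("poor_threshold must be in [0, 1]")

    @property
    def max_possible(self) -> int:
        # one fragment per start position per strand
        return 2 * self.ext


@dataclass
class MappabilityTrack:
    """Per-base overlap counts over the repeat, in [0, 2*ext]."""

    counts: np.ndarray
    params: MappabilityParams

    @property
    def max_possible(self) -> int:
        return self.params.max_possible

    def fractions(self) -> np.ndarray:
        return self.counts / float(self.max_possible)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class MappabilitySummary:
    region: str
    bases_total: int
    bases_above_threshold: int

    @property
    def fraction_above_threshold(self) -> float:
        return self.bases_above_threshold / self.bases_total if self.bases_total else 0.0


@dataclass(frozen=True)
class KmerRecord:
    """A tile of the repeat: its sequence, repeat-local start, and the
    strand it was read from ('+' = repeat forward strand)."""

    seq: str
    start: int
    strand: str = "+"


def tile_kmers(seq: str, k: int, strand: str = "+") -> List[KmerRecord]:
    """Tile ``seq`` into overlapping k-mers at 1-bp intervals.

    For ``strand == '-'`` the record at start ``s`` carries the reverse
    complement of ``seq[s:s+k]`` — the read a sequencer would emit from
    the opposite strand of that interval.
    """
    if len(seq) < k:
        raise ValueError(f"interval of length {len(seq)} shorter than k={k}")
    seq = seq.upper()
    if strand == "+":
        return [KmerRecord(seq[s : s + k], s, "+") for s in range(len(seq) - k + 1)]
    elif strand == "-":
        return [
            KmerRecord(reverse_complement(seq[s : s + k]), s, "-")
            for s in range(len(seq) - k + 1)
        ]
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def _genome_kmer_index(genome: GenomeBuild, k: int) -> Counter:
    """Count every k-mer occurrence on the forward strand of every
    chromosome.  K-mers containing N are not indexed (they never match)."""
    index: Counter = Counter()
    for seq in genome.sequences.values():
        seq = seq.upper()
        n_pos = {i for i, c in enumerate(seq) if c == "N"}
        for s in range(len(seq) - k + 1):
            if n_pos and any((s + j) in n_pos for j in range(k)):
                continue
            index[seq[s : s + k]] += 1
    return index


def unique_hits(
    kmers: Iterable[KmerRecord],
    genome: GenomeBuild,
    params: MappabilityParams = MappabilityParams(),
    index: Optional[Counter] = None,
) -> List[Tuple[int, str]]:
    """Return (repeat-local start, strand) for k-mers aligning uniquely.

    A k-mer is unique iff the total number of occurrence loci of the
    k-mer or its reverse complement across all chromosomes is exactly 1.
    A palindromic k-mer (equal to its own reverse complement) counts
    once per locus, as an aligner reports one alignment per locus.
    K-mers containing N never match.  Duplicate hits at the same
    (locus, strand) — possible only for palindromes tiled from both
    strands — are collapsed.
    """
    if not genome.sequences:
        raise ValueError("genome is empty")
    if index is None:
        k = None
        kmers = list(kmers)
        if kmers:
            k = len(kmers[0].seq)
            index = _genome_kmer_index(genome, k)
        else:
            return []
    hits: List[Tuple[int, str]] = []
    seen = set()
    for rec in kmers:
        if "N" in rec.seq:
            continue
        rc = reverse_complement(rec.seq)
        fwd = index[rec.seq]
        if rc == rec.seq:
            total = fwd  # palindrome: both-strand matches at one locus count once
        else:
            total = fwd + index[rc]
        if total != 1:
            continue
        # The unique locus is necessarily the tile's own position in the
        # repeat; the alignment strand is the strand the tile was read
        # from, except that a palindromic tile is one alignment ('+' by
        # convention) no matter which strand tiling produced it.
        key = (rec.start, "+") if rc == rec.seq else (rec.start, rec.strand)
        if key not in seen:
            seen.add(key)
            hits.append(key)
    return hits


def extend_and_count(
    hits: Sequence[Tuple[int, str]],
    params: MappabilityParams,
    repeat_length: int,
) -> MappabilityTrack:
    """Extend each unique hit to ``ext`` bp in its 3' direction and count
    per-base fragment overlaps.

    A '+' hit starting at s covers [s, s+ext); a '-' hit whose k-mer
    occupies [s, s+k) covers [s+k-ext, s+k).  Fragments are clipped to
    the repeat interval (the build contains one linear copy; no
    wraparound).
    """
    diff = np.zeros(repeat_length + 1, dtype=np.int64)
    k, ext = params.k, params.ext
    for start, strand in hits:
        if strand == "+":
            lo, hi = start, start + ext
        else:
            lo, hi = start + k - ext, start + k
        lo = max(lo, 0)
        hi = min(hi, repeat_length)
        if lo < hi:
            diff[lo] += 1
            diff[hi] -= 1
    counts = np.cumsum(diff[:-1])
    return MappabilityTrack(counts=counts, params=params)


def mappability_track(
    build: GenomeBuild, params: MappabilityParams = MappabilityParams()
) -> MappabilityTrack:
    """Full mappability pipeline over the build's repeat insertion:
    tile both strands, test uniqueness genome-wide, extend and count."""
    repeat = build.repeat_sequence()
    tiles = tile_kmers(repeat, params.k, "+") + tile_kmers(repeat, params.k, "-")
    index = _genome_kmer_index(build, params.k)
    hits = unique_hits(tiles, build, params, index=index)
    return extend_and_count(hits, params, len(repeat))


def classify_and_summarize(
    track: MappabilityTrack,
    annotation: Optional[RepeatAnnotation] = None,
    params: Optional[MappabilityParams] = None,
) -> List[MappabilitySummary]:
    """Summarize mappable-base fractions overall and per annotated feature.

    A base is mappable iff its count strictly exceeds
    ``poor_threshold * max_possible`` (e.g. > 100 of 400 at the
    defaults — strictly more than 25% mappability).
    """
    params = params or track.params
    if annotation is not None and annotation.repeat_length != len(track):
        raise ValueError(
            f"annotation length {annotation.repeat_length} != track length {len(track)}"
        )
    cutoff = params.poor_threshold * params.max_possible
    mappable = track.counts > cutoff
    summaries = [
        MappabilitySummary("overall", len(track), int(mappable.sum()))
    ]
    if annotation is not None:
        for name, start, end in annotation:
            summaries.append(
                MappabilitySummary(name, end - start, int(mappable[start:end].sum()))
            )
    return summaries
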