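"""Seeded desk-scale genomes and read sets with recorded ground truth.

The generator reproduces the statistical structure the analysis
assumes, at laptop scale and with no downloads: a random host
chromosome carrying one full copy of a random repeat unit at its
proximal end, partial "pseudogene" copies of the repeat scattered
elsewhere (which degrade repeat mappability structurally, exactly as
dispersed rDNA pseudogenes do), ChIP read sets that are mixtures of a
uniform background and Gaussian-localized enrichment at designed
repeat-local sites, matched uniform input reads, and PCR duplicates.
Every read carries a provenance label so downstream claims (peak
recovery, deduplication counts, enrichment ratios) can be checked
against truth rather than eyeballed.

One global seed expands into per-component substreams
(``numpy.random.default_rng([seed, stream])``) so genome and read sets
can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .genome_build import GenomeBuild, build_augmented_genome
from .signal import AlignedFragment

__all__ = [
    "SyntheticGenomeSpec",
    "SyntheticReadSpec",
    "EnrichmentSite",
    "GroundTruth",
    "ReadSimResult",
    "simulate_genome",
    "simulate_reads",
    "standard_sites",
    "write_fastq",
]

_BASES = np.array(list("ACGT"))

# seed substreams
_STREAM_GENOME = 0
_STREAM_READS = 1


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Host + repeat + pseudogene geometry.

    Defaults mirror the mouse rDNA setting at full repeat scale: a
    45,309-bp repeat unit prepended to a 150-kb host chromosome with a
    handful of dispersed partial copies, at mammalian-like 42% GC.
    """

    host_length: int = 150_000
    repeat_length: int = 45_309
    n_pseudogenes: int = 5
    pseudogene_fraction: float = 0.1
    gc: float = 0.42
    seed: int = 0
    chrom: str = "chrHost"

    def __post_init__(self) -> None:
        if self.repeat_length > self.host_length / 2:
            raise ValueError("repeat_length must be <= host_length / 2")
        if not (0.0 < self.pseudogene_fraction <= 1.0):
            raise ValueError("pseudogene_fraction must be in (0, 1]")
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must be in (0, 1)")


@dataclass(frozen=True)
class EnrichmentSite:
    """A designed binding site: repeat-local center, mixture weight, and
    the s.d. (bp) of the Gaussian spread of fragment centers around it."""

    center: int
    weight: float
    sd: float = 50.0


@dataclass(frozen=True)
class SyntheticReadSpec:
    n_reads: int = 50_000
    read_length: int = 36
    frag_size: int = 200
    enrichment_sites: Tuple[EnrichmentSite, ...] = ()
    enriched_fraction: float = 0.3
    dup_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.enriched_fraction <= 1.0):
            raise ValueError("enriched_fraction must be in [0, 1]")
        if not (0.0 <= self.dup_rate <= 1.0):
            raise ValueError("dup_rate must be in [0, 1]")
        if self.enrichment_sites:
            w = sum(s.weight for s in self.enrichment_sites)
            if any(s.weight < 0 for s in self.enrichment_sites):
                raise ValueError("site weights must be >= 0")
            if not math.isclose(w, 1.0, rel_tol=1e-9):
                raise ValueError("site weights must sum to 1")


@dataclass
class GroundTruth:
    """What the generator actually did, for verification downstream."""

    # (build start, build end, repeat-local source start, source end)
    pseudogenes: List[Tuple[int, int, int, int]] = field(default_factory=list)
    enrichment_centers: List[int] = field(default_factory=list)  # build coords


@dataclass
class ReadSimResult:
    reads: List[AlignedFragment]
    # one label per read: "background" | "site-<k>" | "duplicate"
    provenance: List[str]
    site_centers_build: List[int]

    def __post_init__(self) -> None:
        assert len(self.reads) == len(self.provenance)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def standard_sites(repeat_length: int, sd: float = 50.0) -> Tuple[EnrichmentSite, ...]:
    """Three equal-weight sites at 10%, 40% and 80% of the repeat —
    roughly a promoter-proximal, mid-coding, and spacer-region site."""
    return tuple(
        EnrichmentSite(int(f * repeat_length), 1.0 / 3.0, sd) for f in (0.1, 0.4, 0.8)
    )


def simulate_genome(
    spec: SyntheticGenomeSpec, max_retries: int = 1000
) -> Tuple[GenomeBuild, GroundTruth]:
    """Generate the augmented build: random host, repeat prepended at
    offset 0, pseudogene copies pasted verbatim at non-overlapping
    random host positions outside the repeat.  Fully reproducible from
    ``spec.seed``."""
    rng = np.random.default_rng([spec.seed, _STREAM_GENOME])
    repeat = _random_seq(rng, spec.repeat_length, spec.gc)
    host = list(_random_seq(rng, spec.host_length, spec.gc))

    plen = max(1, round(spec.pseudogene_fraction * spec.repeat_length))
    placed: List[Tuple[int, int]] = []  # host-local intervals
    truth = GroundTruth()
    for _ in range(spec.n_pseudogenes):
        for _attempt in range(max_retries):
            src = int(rng.integers(0, spec.repeat_length - plen + 1))
            pos = int(rng.integers(0, spec.host_length - plen + 1))
            if all(pos + plen <= a or pos >= b for a, b in placed):
                break
        else:
            raise RuntimeError(
                f"could not place pseudogene without overlap after {max_retries} tries"
            )
        host[pos : pos + plen] = repeat[src : src + plen]
        placed.append((pos, pos + plen))
        # build coordinates: host follows the prepended repeat
        truth.pseudogenes.append(
            (spec.repeat_length + pos, spec.repeat_length + pos + plen, src, src + plen)
        )

    build = build_augmented_genome(
        {spec.chrom: "".join(host)},
        repeat,
        spec.chrom,
        position="proximal",
        repeat_id="synthetic_repeat",
        build_name="synthetic_build",
    )
    return build, truth


def simulate_reads(
    build: GenomeBuild,
    spec: SyntheticReadSpec,
    mode: str = "chip",
) -> ReadSimResult:
    """Emit pre-aligned reads (true coordinates, BED-style starts).

    ``input`` mode: fragment centers uniform over the build chromosome.
    ``chip`` mode: with probability ``enriched_fraction`` the center is
    drawn Normal(site, sd) around a weight-sampled designed site,
    otherwise uniform.  Strands are coin flips; the read start is
    ``center - frag_size/2`` on '+' and ``center + frag_size/2 -
    read_length`` on '-', i.e. reads sit at the 5' end of the notional
    fragment.  Duplicates are injected afterwards by re-emitting
    already-generated reads at rate ``dup_rate``; all reads carry
    provenance labels.
    """
    if mode not in ("chip", "input"):
        raise ValueError(f"mode must be 'chip' or 'input', got {mode!r}")
    ins = build.insertion
    chrom_len = len(build.sequences[ins.chrom])
    half = spec.frag_size // 2
    lo, hi = half, chrom_len - half  # keep reads fully on the chromosome
    sites = spec.enrichment_sites
    for s in sites:
        if not (0 <= s.center < ins.length):
            raise ValueError(f"enrichment site {s.center} outside repeat [0, {ins.length})")
    site_centers_build = [ins.offset + s.center for s in sites]

    rng = np.random.default_rng([spec.seed, _STREAM_READS])
    n = spec.n_reads
    centers = rng.integers(lo, hi, size=n)
    labels = ["background"] * n
    if mode == "chip" and sites and spec.enriched_fraction > 0:
        enriched = rng.random(n) < spec.enriched_fraction
        weights = np.array([s.weight for s in sites])
        which = rng.choice(len(sites), size=n, p=weights)
        gauss = rng.normal(0.0, 1.0, size=n)
        for i in np.flatnonzero(enriched):
            k = which[i]
            c = int(round(site_centers_build[k] + gauss[i] * sites[k].sd))
            centers[i] = min(max(c, lo), hi - 1)
            labels[i] = f"site-{k}"

    strands = np.where(rng.random(n) < 0.5, "+", "-")
    reads: List[AlignedFragment] = []
    for c, strand in zip(centers, strands):
        c = int(c)
        if strand == "+":
            start = c - half
        else:
            start = c + half - spec.read_length
        reads.append(AlignedFragment(ins.chrom, start, str(strand), spec.read_length))

    n_dup = int(round(spec.dup_rate * n))
    if n_dup:
        dup_idx = rng.integers(0, n, size=n_dup)
        for i in dup_idx:
            reads.append(reads[int(i)])
            labels.append("duplicate")

    return ReadSimResult(
        reads=reads, provenance=labels, site_centers_build=site_centers_build
    )


def write_fastq(build: GenomeBuild, reads: Sequence[AlignedFragment], path) -> None:
    """Write read sequences (reverse-complemented for '-' strand) as
    FASTQ with uniform maximal qualities, for integration tests with a
    real aligner."""
    from .mappability import reverse_complement

    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            seq = build.sequences[r.chrom][r.start : r.start + r.read_length]
            if r.strand == "-":
                seq = reverse_complement(seq)
            fh.write(f"@read_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
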