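"""Readers and writers for the interchange formats of the pipeline.

BED6 is the canonical internal interchange for aligned reads; SAM/BAM
is a reader concern only (flag-filtered through pysam).  Signal tracks
go to bedGraph with runs of equal value merged and full-precision
values, so a written track reads back base-exact.  Peaks go to BED6+1
with the summit offset in the extra column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .signal import AlignedFragment, Peak, SignalTrack

__all__ = [
    "read_reads",
    "write_reads_bed",
    "write_bedgraph",
    "read_bedgraph",
    "write_peaks",
    "read_peaks",
    "write_tsv",
]

_DROP_FLAGS = 0x4 | 0x100 | 0x800  # unmapped, secondary, supplementary


def read_reads(path: Union[str, Path], fmt: Optional[str] = None) -> List[AlignedFragment]:
    """Read aligned reads from BED6 or SAM/BAM (format sniffed from the
    extension unless given).

    BED: chrom/start/strand from columns 1, 2, 6; read length from
    end−start.  SAM/BAM: unmapped, secondary and supplementary records
    are dropped via their flags (multi-mapper removal is the aligner's
    job; only its surviving primary alignments are consumed), and
    coordinates arrive 0-based half-open from pysam.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".bed": "bed", ".sam": "sam", ".bam": "bam"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer read format from {path.name!r}")
    if fmt == "bed":
        return _read_bed(path)
    if fmt in ("sam", "bam"):
        return _read_sam(path)
    raise ValueError(f"unknown read format {fmt!r}")


def _read_bed(path: Path) -> List[AlignedFragment]:
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 requires 6 columns")
            try:
                chrom, start, end, strand = parts[0], int(parts[1]), int(parts[2]), parts[5]
                reads.append(AlignedFragment(chrom, start, strand, end - start))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED record: {exc}") from exc
    return reads


def _read_sam(path: Path) -> List[AlignedFragment]:
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.flag & _DROP_FLAGS:
                continue
            strand = "-" if rec.is_reverse else "+"
            length = rec.query_length or (rec.reference_length or 0)
            reads.append(
                AlignedFragment(rec.reference_name, rec.reference_start, strand, length)
            )
    return reads


def write_reads_bed(reads: Iterable[AlignedFragment], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.start + r.read_length}\tread_{i}\t0\t{r.strand}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(track: SignalTrack, path: Union[str, Path]) -> None:
    """Write a signal track as bedGraph, merging runs of equal value.

    Values use Python's shortest round-tripping float repr, and track
    metadata (fragment count, bandwidth) goes into header comments, so
    :func:`read_bedgraph` restores the per-base vector exactly.
    """
    v = track.values
    with open(path, "w") as fh:
        fh.write(
            f"#total_fragments={track.total_fragments}\t"
            f"bandwidth={track.bandwidth!r}\n"
        )
        if len(v) == 0:
            return
        run_start = 0
        for i in range(1, len(v) + 1):
            if i == len(v) or v[i] != v[run_start]:
                fh.write(
                    f"{track.chrom}\t{track.start + run_start}\t"
                    f"{track.start + i}\t{float(v[run_start])!r}\n"
                )
                run_start = i


def read_bedgraph(path: Union[str, Path]) -> SignalTrack:
    total_fragments, bandwidth = 0, 0.0
    chrom = None
    intervals: List[Tuple[int, int, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split("\t"):
                    key, _, val = token.partition("=")
                    if key == "total_fragments":
                        total_fragments = int(val)
                    elif key == "bandwidth":
                        bandwidth = float(val)
                continue
            if line.startswith(("track", "browser")):
                continue
            c, s, e, v = line.split("\t")
            chrom = chrom or c
            intervals.append((int(s), int(e), float(v)))
    if not intervals:
        raise ValueError(f"no data lines in {path}")
    start = intervals[0][0]
    end = intervals[-1][1]
    values = np.zeros(end - start)
    for s, e, v in intervals:
        values[s - start : e - start] = v
    return SignalTrack(
        chrom=chrom,
        start=start,
        values=values,
        total_fragments=total_fragments,
        bandwidth=bandwidth,
    )


# ---------------------------------------------------------------------------
# peaks


_PEAK_HEADER = "#chrom\tstart\tend\tname\tintensity\tstrand\tsummit_offset\tarea"


def write_peaks(peaks: Sequence[Peak], path: Union[str, Path]) -> None:
    """BED6+2: name column numbered, strand '.', summit as offset from
    peak start, plus the run area.  An empty list yields a header-only file."""
    with open(path, "w") as fh:
        fh.write(_PEAK_HEADER + "\n")
        for i, p in enumerate(peaks, start=1):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t{p.intensity!r}\t.\t"
                f"{p.summit - p.start}\t{p.area!r}\n"
            )


def read_peaks(path: Union[str, Path]) -> List[Peak]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end, _name, intensity, _strand, offset, area = line.split("\t")
            start, end = int(start), int(end)
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=start,
                    end=end,
                    summit=start + int(offset),
                    intensity=float(intensity),
                    area=float(area),
                )
            )
    return peaks


def write_tsv(rows: Sequence[Sequence], header: Sequence[str], path: Union[str, Path]) -> None:
    """Plain deterministic TSV: floats via repr, everything else via str."""
    def fmt(x) -> str:
        if isinstance(x, (float, np.floating)):
            return repr(float(x))
        return str(x)

    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(fmt(x) for x in row) + "\n")
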