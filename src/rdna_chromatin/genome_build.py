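"""Repeat-augmented genome builds and coordinate bookkeeping.

The analysis strategy for a multicopy repeat locus (e.g. ribosomal DNA,
present in hundreds of near-identical copies per genome but absent from
standard assemblies) is to insert a single canonical repeat unit into a
host chromosome and align all sequencing reads against that augmented
build.  This module constructs such builds, records where the repeat was
inserted, maps between repeat-local and build coordinates, and carries
the feature annotation of the repeat unit (coding region, intergenic
spacer, promoters).

All coordinates are 0-based half-open internally; 1-based conventions
appear only at BED/GenBank file boundaries.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Tuple, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeBuild",
    "Insertion",
    "RepeatAnnotation",
    "build_augmented_genome",
    "repeat_to_build_coords",
    "build_to_repeat_coords",
    "load_annotation",
    "default_annotation",
    "read_fasta",
    "write_fasta",
    "read_repeat_unit",
]

_NUCLEOTIDES = frozenset("ACGTN")


@dataclass(frozen=True)
class Insertion:
    """Record of where a repeat unit sits inside an augmented chromosome."""

    chrom: str
    offset: int  # 0-based start of the repeat on the augmented chromosome
    length: int
    repeat_id: str = "repeat"

    @property
    def end(self) -> int:
        return self.offset + self.length


@dataclass
class GenomeBuild:
    """A set of named chromosome sequences plus one repeat insertion record.

    Invariants (checked in ``validate``): the insertion interval lies
    within its chromosome, and the sequence at that interval equals the
    repeat unit that was inserted.
    """

    name: str
    sequences: dict
    insertion: Insertion
    repeat_unit: str = ""

    def validate(self) -> None:
        ins = self.insertion
        if ins.chrom not in self.sequences:
            raise ValueError(f"insertion chromosome {ins.chrom!r} not in build")
        chrom_len = len(self.sequences[ins.chrom])
        if not (0 <= ins.offset and ins.end <= chrom_len):
            raise ValueError(
                f"insertion [{ins.offset}, {ins.end}) outside chromosome "
                f"{ins.chrom!r} of length {chrom_len}"
            )
        if self.repeat_unit:
            found = self.sequences[ins.chrom][ins.offset : ins.end]
            if found != self.repeat_unit:
                raise ValueError("sequence at insertion interval differs from repeat unit")

    @property
    def repeat_length(self) -> int:
        return self.insertion.length

    def repeat_sequence(self) -> str:
        ins = self.insertion
        return self.sequences[ins.chrom][ins.offset : ins.end]


def _check_alphabet(seq: str, what: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _NUCLEOTIDES
    if bad:
        raise ValueError(f"{what} contains non-nucleotide characters: {sorted(bad)!r}")
    return seq


def build_augmented_genome(
    reference: Mapping[str, str],
    repeat_unit: str,
    target_chrom: str,
    position: Union[str, int] = "proximal",
    repeat_id: str = "repeat",
    build_name: Optional[str] = None,
) -> GenomeBuild:
    """Insert ``repeat_unit`` into ``target_chrom`` of ``reference``.

    ``position`` is either the string ``"proximal"`` (prepend, offset 0 —
    the default, so that repeat-local and build-local coordinates agree)
    or an explicit 0-based offset on the original chromosome.  Existing
    sequence is never replaced; the chromosome grows by the repeat length.
    """
    if target_chrom not in reference:
        raise KeyError(f"unknown chromosome {target_chrom!r}")
    if not repeat_unit:
        raise ValueError("repeat unit is empty")
    repeat_unit = _check_alphabet(repeat_unit, "repeat unit")

    host = _check_alphabet(reference[target_chrom], f"chromosome {target_chrom!r}")
    if position == "proximal":
        offset = 0
    else:
        offset = int(position)
        if not (0 <= offset <= len(host)):
            raise ValueError(
                f"insertion position {offset} outside chromosome of length {len(host)}"
            )

    sequences = {name: seq.upper() for name, seq in reference.items()}
    sequences[target_chrom] = host[:offset] + repeat_unit + host[offset:]
    build = GenomeBuild(
        name=build_name or f"{target_chrom}_plus_{repeat_id}",
        sequences=sequences,
        insertion=Insertion(target_chrom, offset, len(repeat_unit), repeat_id),
        repeat_unit=repeat_unit,
    )
    build.validate()
    return build


def repeat_to_build_coords(build: GenomeBuild, pos: int) -> Tuple[str, int]:
    """Map a repeat-local position to (chromosome, build position)."""
    ins = build.insertion
    if not (0 <= pos < ins.length):
        raise ValueError(f"repeat-local position {pos} outside [0, {ins.length})")
    return ins.chrom, ins.offset + pos


def build_to_repeat_coords(build: GenomeBuild, chrom: str, pos: int) -> Optional[int]:
    """Inverse of :func:`repeat_to_build_coords`; ``None`` outside the insertion."""
    ins = build.insertion
    if chrom != ins.chrom or not (ins.offset <= pos < ins.end):
        return None
    return pos - ins.offset


# ---------------------------------------------------------------------------
# Repeat annotation


@dataclass
class RepeatAnnotation:
    """Named features of the repeat unit in repeat-local half-open coordinates.

    By convention the transcription start site of the repeat's coding
    region is repeat-local position 0, so the coding region starts at 0
    and the intergenic spacer (IGS) fills the remainder of the unit.
    """

    features: list  # of (name, start, end)
    repeat_length: int
    tss: int = 0

    def __post_init__(self) -> None:
        names = [f[0] for f in self.features]
        if len(names) != len(set(names)):
            raise ValueError("feature names must be unique")
        for name, start, end in self.features:
            if not (0 <= start < end <= self.repeat_length):
                raise ValueError(
                    f"feature {name!r} [{start}, {end}) outside repeat of "
                    f"length {self.repeat_length}"
                )

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)


# Mouse-style default geometry: a ~13.4 kb coding region starting at the
# TSS, the IGS filling out the unit, and a spacer promoter ~2 kb upstream
# of the TSS (i.e. near the distal end of the IGS of the preceding unit).
DEFAULT_CODING_END = 13_400
DEFAULT_SPACER_PROMOTER_UPSTREAM = 2_000
DEFAULT_SPACER_PROMOTER_WIDTH = 200


def default_annotation(
    repeat_length: int,
    coding_end: int = DEFAULT_CODING_END,
    spacer_promoter_upstream: int = DEFAULT_SPACER_PROMOTER_UPSTREAM,
    spacer_promoter_width: int = DEFAULT_SPACER_PROMOTER_WIDTH,
) -> RepeatAnnotation:
    """Default coding/IGS/spacer-promoter annotation for a repeat unit.

    Positions are configuration, not constants: published feature
    boundaries for rDNA are approximate and assembly-dependent.
    """
    coding_end = min(coding_end, repeat_length)
    features = [("coding", 0, coding_end)]
    if coding_end < repeat_length:
        features.append(("IGS", coding_end, repeat_length))
    sp_start = repeat_length - spacer_promoter_upstream
    sp_end = sp_start + spacer_promoter_width
    if 0 <= sp_start < sp_end <= repeat_length:
        features.append(("spacer_promoter", sp_start, sp_end))
    return RepeatAnnotation(features=features, repeat_length=repeat_length)


def load_annotation(
    source: Union[str, Path, Iterable[Tuple[str, int, int]], None],
    repeat_length: int,
) -> RepeatAnnotation:
    """Load a repeat annotation from a TSV/BED-like file, an iterable of
    (name, start, end) rows, or ``None`` for the built-in default.

    File rows may be ``name<TAB>start<TAB>end`` or BED order
    ``chrom<TAB>start<TAB>end<TAB>name`` (detected per line by whether
    column 2 parses as an integer).
    """
    if source is None:
        return default_annotation(repeat_length)
    if isinstance(source, (str, Path)):
        rows = []
        for lineno, line in enumerate(Path(source).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{source}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else parts[0]
            except ValueError:
                # name<TAB>start<TAB>end layout
                name, start, end = parts[0], int(parts[1]), int(parts[2])
            rows.append((name, start, end))
        return RepeatAnnotation(features=rows, repeat_length=repeat_length)
    return RepeatAnnotation(features=list(source), repeat_length=repeat_length)


# ---------------------------------------------------------------------------
# FASTA / GenBank I/O (Bio.SeqIO behind the module surface)


def read_fasta(path: Union[str, Path]) -> dict:
    """Read a multi-record FASTA into an ordered {name: sequence} map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: Union[str, Path]) -> None:
    """Write sequences as FASTA wrapped at 60 columns (round-trips exactly)."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def read_repeat_unit(path: Union[str, Path]) -> str:
    """Read a repeat-unit sequence from FASTA or a GenBank flat file.

    The format is sniffed from the extension (.gb/.gbk/.genbank ->
    GenBank, otherwise FASTA); the first record's sequence is returned.
    """
    path = Path(path)
    fmt = "genbank" if path.suffix.lower() in {".gb", ".gbk", ".genbank"} else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        return str(rec.seq).upper()
    raise ValueError(f"no sequence records found in {path}")


def write_annotation_tsv(annotation: RepeatAnnotation, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("name\tstart\tend\n")
        for name, start, end in annotation:
            fh.write(f"{name}\t{start}\t{end}\n")
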