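"""Normalized tag density: repeat-locus vs host-chromosome peak intensity.

Because the repeat is present in many genomic copies but only once in
the augmented build, signal piling onto the single inserted copy should
be at least as intense as signal on single-copy chromatin.  The
normalized tag density quantifies this as the ratio of the mean
intensity of peaks called within the repeat interval to the mean
intensity of peaks called elsewhere on the same (host) chromosome.
Peaks on other chromosomes do not enter the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

from .signal import Peak

__all__ = [
    "NormalizedTagDensity",
    "TagDensityUndefinedError",
    "normalized_tag_density",
]


class TagDensityUndefinedError(ValueError):
    """Raised when no peaks fall inside or no peaks fall outside the
    repeat, leaving the ratio undefined (deliberately not 0 or NaN)."""


@dataclass(frozen=True)
class NormalizedTagDensity:
    value: float
    mean_inside: float
    mean_outside: float
    n_peaks_inside: int
    n_peaks_outside: int


def normalized_tag_density(
    peaks: Iterable[Peak],
    repeat_interval: Tuple[str, int, int],
    host_chrom: Optional[str] = None,
    intensity: str = "summit",
) -> NormalizedTagDensity:
    """Mean peak intensity inside the repeat over mean intensity outside.

    Membership is decided by the summit position: a peak is inside iff
    its summit lies in ``repeat_interval`` (half-open), outside iff it
    is on the host chromosome with its summit elsewhere.  ``intensity``
    selects summit height (default) or total peak ``area``.
    """
    chrom, start, end = repeat_interval
    host = host_chrom or chrom
    if host != chrom:
        raise ValueError("repeat interval must lie on the host chromosome")
    if intensity not in ("summit", "area"):
        raise ValueError(f"intensity must be 'summit' or 'area', got {intensity!r}")

    def score(p: Peak) -> float:
        return p.intensity if intensity == "summit" else p.area

    inside: List[float] = []
    outside: List[float] = []
    for p in peaks:
        if p.chrom != host:
            continue
        if start <= p.summit < end:
            inside.append(score(p))
        else:
            outside.append(score(p))
    if not inside or not outside:
        raise TagDensityUndefinedError(
            f"normalized tag density undefined: {len(inside)} peaks inside, "
            f"{len(outside)} outside the repeat interval"
        )
    mean_in = sum(inside) / len(inside)
    mean_out = sum(outside) / len(outside)
    return NormalizedTagDensity(
        value=mean_in / mean_out,
        mean_inside=mean_in,
        mean_outside=mean_out,
        n_peaks_inside=len(inside),
        n_peaks_outside=len(outside),
    )
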