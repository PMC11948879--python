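"""Genomic regions and the user-facing ``chrom:start-end`` convention.

Coordinates are 1-based and inclusive on both ends, matching how loci are
written in the genome browsers and papers this tool's users read (e.g. the
GNAS imprinted locus ``chr20:58,839,718-58,911,192``). Any half-open
arithmetic needed to talk to htslib is confined to the modules that call it
and is never serialized.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import RegionFormatError

#: Sentinel meaning "to the end of the chromosome" for bare-chromosome
#: regions; htslib's maximum coordinate, safe to pass to tabix/BAM fetch.
CHROM_END = 2**31 - 1

# Thousands separators people paste from papers and browsers: comma,
# narrow/thin/no-break spaces, underscore.
_SEPARATORS = str.maketrans("", "", ",_   ")
# En/em dashes are accepted as the start-end dash.
_DASHES = re.compile("[–—]")


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """A 1-based, fully-closed genomic interval."""

    chrom: str
    start: int = 1
    end: int = CHROM_END

    def __post_init__(self) -> None:
        if not self.chrom:
            raise RegionFormatError("empty chromosome name")
        if self.start < 1:
            raise RegionFormatError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise RegionFormatError(
                f"inverted region: end {self.end} < start {self.start}"
            )

    def __str__(self) -> str:
        if self.start == 1 and self.end == CHROM_END:
            return self.chrom
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def span(self) -> int:
        """Number of bases covered (inclusive of both ends)."""
        return self.end - self.start + 1

    def contains(self, chrom: str, position: int) -> bool:
        return chrom == self.chrom and self.start <= position <= self.end


def parse_region(text: str) -> GenomicRegion:
    """Parse ``"chrom"`` or ``"chrom:start-end"`` into a :class:`GenomicRegion`.

    Thousands separators (commas, thin spaces, underscores) in the
    coordinates are stripped, and en-dashes are accepted for the hyphen,
    so region strings copied verbatim from publications parse unchanged.

    >>> parse_region("chr20:58,839,718-58,911,192")
    GenomicRegion(chrom='chr20', start=58839718, end=58911192)
    """
    text = text.strip()
    if not text:
        raise RegionFormatError("empty region string")
    if ":" not in text:
        return GenomicRegion(chrom=text)
    chrom, _, coords = text.rpartition(":")
    if not chrom:
        raise RegionFormatError(f"empty chromosome name in {text!r}")
    coords = _DASHES.sub("-", coords).translate(_SEPARATORS)
    start_s, dash, end_s = coords.partition("-")
    if not dash:
        raise RegionFormatError(
            f"expected 'start-end' coordinates, got {coords!r}"
        )
    try:
        start = int(start_s)
        end = int(end_s)
    except ValueError:
        bad = start_s if not start_s.isdigit() else end_s
        raise RegionFormatError(
            f"non-numeric coordinate {bad!r} in region {text!r}"
        ) from None
    return GenomicRegion(chrom=chrom, start=start, end=end)
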