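"""Genomic regions and region lists.

Coordinates are 1-based fully-closed throughout the package (the convention
under which chr1:110246810-110255596 has length 8,787 bp).  The only place a
conversion to 0-based half-open happens is inside the array-slicing helpers
here and in :mod:`hapsweep.vcf_io`.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class GenomicRegion:
    """A 1-based, fully-closed genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"region start {self.start} > end {self.end} ({self.chrom})"
            )

    def __len__(self) -> int:
        return region_length(self)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


def region_length(region: GenomicRegion) -> int:
    """Length in bp of a 1-based closed interval: ``end - start + 1``."""
    return region.end - region.start + 1


def read_region_table(path, bed_standard: bool = False) -> list[GenomicRegion]:
    """Read a TSV of regions (chrom, start, end[, name]).

    By default coordinates are interpreted as 1-based fully-closed, matching
    the rest of the package.  With ``bed_standard=True`` the file is treated
    as BED proper (0-based half-open) and converted on the way in.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "name"], dtype={"chrom": str},
    )
    regions = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if bed_standard:
            start += 1  # BED start is 0-based; end already equals closed end
        name = "" if pd.isna(row.name) else str(row.name)
        regions.append(GenomicRegion(str(row.chrom), start, end, name))
    return regions


def write_region_table(regions: list[GenomicRegion], path) -> None:
    df = pd.DataFrame(
        [(r.chrom, r.start, r.end, r.name) for r in regions],
        columns=["chrom", "start", "end", "name"],
    )
    df.to_csv(path, sep="\t", header=False, index=False)
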