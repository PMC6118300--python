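"""The phased haplotype panel container.

A :class:`HaplotypePanel` is a binary matrix of haplotypes x segregating
sites, with physical positions, a population label per haplotype and an
optional per-haplotype deletion status for a linked structural variant.
Allele coding is 0 = reference/ancestral, 1 = alternative/derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .regions import GenomicRegion


@dataclass
class HaplotypePanel:
    alleles: np.ndarray                    # (n_hap, n_sites) uint8 in {0,1}
    positions: np.ndarray                  # bp (int) or fractional [0,1)
    pop_labels: np.ndarray                 # str per haplotype
    sample_ids: np.ndarray                 # str per haplotype
    hap_index: np.ndarray                  # 0/1 within each sample
    deletion_status: Optional[np.ndarray] = None  # uint8 per haplotype
    region: Optional[GenomicRegion] = None
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.positions = np.asarray(self.positions)
        self.pop_labels = np.asarray(self.pop_labels)
        self.sample_ids = np.asarray(self.sample_ids)
        self.hap_index = np.asarray(self.hap_index, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        n_hap, n_sites = self.alleles.shape
        if len(self.positions) != n_sites:
            raise ValueError("positions length does not match site count")
        if n_sites > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        for name, arr in (
            ("pop_labels", self.pop_labels),
            ("sample_ids", self.sample_ids),
            ("hap_index", self.hap_index),
        ):
            if len(arr) != n_hap:
                raise ValueError(f"{name} length does not match haplotype count")
        if self.deletion_status is not None:
            self.deletion_status = np.asarray(self.deletion_status, dtype=np.uint8)
            if len(self.deletion_status) != n_hap:
                raise ValueError("deletion_status length does not match haplotype count")
        if self.alleles.size and not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("allele matrix entries must be 0/1")

    # -- basic geometry ----------------------------------------------------

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def span_bp(self) -> int:
        """Physical span used for per-site scaling of diversity."""
        if self.region is not None:
            return len(self.region)
        if self.n_sites == 0:
            raise ValueError("panel has no region and no sites; span undefined")
        return int(self.positions.max() - self.positions.min() + 1)

    # -- subsetting --------------------------------------------------------

    def take_haplotypes(self, idx) -> "HaplotypePanel":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return HaplotypePanel(
            alleles=self.alleles[idx],
            positions=self.positions,
            pop_labels=self.pop_labels[idx],
            sample_ids=self.sample_ids[idx],
            hap_index=self.hap_index[idx],
            deletion_status=None if self.deletion_status is None
            else self.deletion_status[idx],
            region=self.region,
            chrom=self.chrom,
        )

    def population(self, label: str) -> "HaplotypePanel":
        return self.take_haplotypes(self.pop_labels == label)

    def restrict(self, region: GenomicRegion) -> "HaplotypePanel":
        keep = (self.positions >= region.start) & (self.positions <= region.end)
        return HaplotypePanel(
            alleles=self.alleles[:, keep],
            positions=self.positions[keep],
            pop_labels=self.pop_labels,
            sample_ids=self.sample_ids,
            hap_index=self.hap_index,
            deletion_status=self.deletion_status,
            region=region,
            chrom=self.chrom,
        )

    def populations(self) -> list[str]:
        seen: list[str] = []
        for p in self.pop_labels:
            if p not in seen:
                seen.append(str(p))
        return seen

    # -- comparison --------------------------------------------------------

    def equals(self, other: "HaplotypePanel") -> bool:
        if self.alleles.shape != other.alleles.shape:
            return False
        same = (
            np.array_equal(self.alleles, other.alleles)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.pop_labels, other.pop_labels)
            and np.array_equal(self.sample_ids, other.sample_ids)
            and np.array_equal(self.hap_index, other.hap_index)
        )
        if not same:
            return False
        a, b = self.deletion_status, other.deletion_status
        if (a is None) != (b is None):
            return False
        return a is None or np.array_equal(a, b)


def concat_regions(panel_a: HaplotypePanel, panel_b: HaplotypePanel) -> HaplotypePanel:
    """Concatenate two panels over the same haplotypes (e.g. an upstream and a
    downstream target region around a deletion), preserving each source
    region's position offsets."""
    for name in ("pop_labels", "sample_ids", "hap_index"):
        if not np.array_equal(getattr(panel_a, name), getattr(panel_b, name)):
            raise ValueError(f"haplotype sets differ between panels ({name})")
    if panel_b.n_sites == 0:
        return panel_a
    if panel_a.n_sites == 0:
        return panel_b
    positions = np.concatenate([panel_a.positions, panel_b.positions])
    if not np.all(np.diff(positions) > 0):
        raise ValueError("regions overlap or are out of order; cannot concatenate")
    region = None
    if panel_a.region is not None and panel_b.region is not None:
        region = GenomicRegion(
            panel_a.region.chrom,
            panel_a.region.start,
            panel_b.region.end,
            name=f"{panel_a.region.name}+{panel_b.region.name}",
        )
    return HaplotypePanel(
        alleles=np.hstack([panel_a.alleles, panel_b.alleles]),
        positions=positions,
        pop_labels=panel_a.pop_labels,
        sample_ids=panel_a.sample_ids,
        hap_index=panel_a.hap_index,
        deletion_status=panel_a.deletion_status,
        region=region,
        chrom=panel_a.chrom,
    )


def fractional_to_bp(positions: Sequence[float], region_length: int) -> np.ndarray:
    """Map fractional coalescent positions in [0,1) to 1-based bp.

    ``floor(pos * L) + 1``, with collisions resolved by bumping to the next
    free bp so positions stay strictly increasing (physical distances are
    needed downstream by the run-of-homozygosity analysis).
    """
    out = []
    last = 0
    for p in positions:
        bp = int(np.floor(p * region_length)) + 1
        if bp <= last:
            bp = last + 1
        out.append(bp)
        last = bp
    return np.asarray(out, dtype=np.int64)
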