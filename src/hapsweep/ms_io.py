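"""Read and write the ms text dialect.

The dialect is the plain-text output convention of Hudson's coalescent
simulator: a header line, then one ``//`` block per replicate with
``segsites:`` and ``positions:`` lines followed by 0/1 haplotype rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np


@dataclass
class SimReplicate:
    """One simulated dataset: fractional positions, binary haplotype matrix
    (1 = derived) and a deme label per haplotype."""

    positions: np.ndarray          # float in [0, 1), non-decreasing
    alleles: np.ndarray            # (n_hap, n_sites) uint8
    demes: np.ndarray              # int deme index per haplotype (0-based)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.demes = np.asarray(self.demes, dtype=np.int64)
        if self.alleles.shape[1] != len(self.positions):
            raise ValueError("positions length does not match site count")
        if self.alleles.shape[0] != len(self.demes):
            raise ValueError("deme labels do not match haplotype count")
        if len(self.positions) > 1 and np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be non-decreasing")

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def deme_haplotypes(self, deme: int) -> np.ndarray:
        return self.alleles[self.demes == deme]


def read_ms_output(text: str, demes: Optional[Iterable[int]] = None) -> list[SimReplicate]:
    """Parse ms-dialect text into replicates.

    ``demes`` gives per-haplotype deme assignments (defaults to a single
    deme).  Haplotype rows are checked against the ``segsites:`` count so a
    silently truncated file is rejected.
    """
    lines = text.splitlines()
    blocks: list[list[str]] = []
    current: Optional[list[str]] = None
    for line in lines:
        if line.startswith("//"):
            current = []
            blocks.append(current)
        elif current is not None:
            current.append(line)

    replicates = []
    for rep_idx, block in enumerate(blocks):
        segsites = None
        positions: np.ndarray = np.empty(0)
        rows: list[str] = []
        for line in block:
            if line.startswith("segsites:"):
                segsites = int(line.split(":", 1)[1])
            elif line.startswith("positions:"):
                positions = np.array(
                    [float(x) for x in line.split(":", 1)[1].split()]
                )
            elif line.strip() and set(line.strip()) <= {"0", "1"}:
                rows.append(line.strip())
        if segsites is None:
            raise ValueError(f"replicate {rep_idx}: missing segsites line")
        if segsites != len(positions):
            raise ValueError(
                f"replicate {rep_idx}: positions count {len(positions)} "
                f"!= segsites {segsites}"
            )
        for row in rows:
            if len(row) != segsites:
                raise ValueError(
                    f"replicate {rep_idx}: haplotype row length {len(row)} "
                    f"!= segsites {segsites}"
                )
        if segsites == 0:
            alleles = np.zeros((len(rows), 0), dtype=np.uint8)
        else:
            alleles = np.array(
                [[int(c) for c in row] for row in rows], dtype=np.uint8
            )
        n_hap = alleles.shape[0]
        deme_arr = (
            np.zeros(n_hap, dtype=np.int64)
            if demes is None
            else np.asarray(list(demes), dtype=np.int64)
        )
        replicates.append(SimReplicate(positions, alleles, deme_arr))
    return replicates


def write_ms_output(
    replicates: Iterable[SimReplicate],
    command: str = "hapsweep simulate",
    precision: int = 5,
) -> str:
    """Render replicates in the ms dialect (positions at fixed precision)."""
    reps = list(replicates)
    out = [command, "", ""]
    for rep in reps:
        out.append("//")
        out.append(f"segsites: {rep.n_sites}")
        if rep.n_sites:
            pos = " ".join(f"{p:.{precision}f}" for p in rep.positions)
            out.append(f"positions: {pos}")
            for row in rep.alleles:
                out.append("".join(str(int(x)) for x in row))
        out.append("")
    return "\n".join(out)
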