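"""Phased VCF reading and writing.

Only biallelic, fully phased records are consumed; multi-allelic records
are skipped (with a count); an unphased genotype is a hard error naming the
sample and site.  A symbolic ``<DEL>`` ALT record is routed to the panel's
per-haplotype deletion status rather than the allele matrix.
"""

from __future__ import annotations

import logging
from typing import Callable, Mapping, Optional, Union

import numpy as np
from cyvcf2 import VCF

from .panel import HaplotypePanel
from .regions import GenomicRegion

logger = logging.getLogger(__name__)


def write_phased_vcf(
    panel: HaplotypePanel, path, deletion_pos: Optional[int] = None
) -> None:
    """Write a panel as VCF 4.2 with phased GT fields.

    Haplotypes 2i and 2i+1 must belong to the same sample.  SNVs are written
    as A->T records; a deletion-status vector becomes one symbolic ``<DEL>``
    record with an END key, placed at ``deletion_pos`` (default: region
    midpoint, off any SNV).
    """
    if panel.n_hap == 0:
        raise ValueError("cannot write an empty panel")
    if panel.n_hap % 2:
        raise ValueError("panel must contain whole diploids (even haplotypes)")
    sample_names = []
    for i in range(0, panel.n_hap, 2):
        if panel.sample_ids[i] != panel.sample_ids[i + 1]:
            raise ValueError("haplotype pairs must share a sample id")
        sample_names.append(str(panel.sample_ids[i]))
    chrom = panel.chrom
    region_end = panel.region.end if panel.region else int(panel.positions.max())
    lines = [
        "##fileformat=VCFv4.2",
        "##source=hapsweep",
        f"##contig=<ID={chrom},length={max(region_end + 1000, 1000)}>",
        '##ALT=<ID=DEL,Description="Deletion">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=POP,Number=.,Type=String,Description="Population per sample (panel metadata)">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    # record per-sample population labels so a round trip is lossless
    pops = ",".join(str(panel.pop_labels[i]) for i in range(0, panel.n_hap, 2))
    lines.append(f"##hapsweep_populations={pops}")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_names)
    )

    records: list[tuple[int, str]] = []
    for s in range(panel.n_sites):
        pos = int(panel.positions[s])
        gts = "\t".join(
            f"{panel.alleles[i, s]}|{panel.alleles[i + 1, s]}"
            for i in range(0, panel.n_hap, 2)
        )
        records.append((pos, f"{chrom}\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}"))
    if panel.deletion_status is not None:
        if deletion_pos is None:
            mid = (panel.region.start + panel.region.end) // 2 if panel.region \
                else int(panel.positions.mean()) if panel.n_sites else 1
            deletion_pos = mid
            while deletion_pos in set(int(p) for p in panel.positions):
                deletion_pos += 1
        gts = "\t".join(
            f"{panel.deletion_status[i]}|{panel.deletion_status[i + 1]}"
            for i in range(0, panel.n_hap, 2)
        )
        info = f"SVTYPE=DEL;END={deletion_pos + 100}"
        records.append(
            (deletion_pos,
             f"{chrom}\t{deletion_pos}\tDEL_1\tN\t<DEL>\t.\tPASS\t{info}\tGT\t{gts}")
        )
    records.sort(key=lambda t: t[0])
    with open(path, "w") as fh:
        fh.write("\n".join(lines + [r for _, r in records]) + "\n")


def read_phased_vcf(
    path,
    region: Optional[GenomicRegion] = None,
    populations: Union[Mapping[str, str], Callable[[str], str], None] = None,
) -> HaplotypePanel:
    """Read a phased VCF into a panel.

    ``populations`` maps sample name to population label (mapping or
    callable); when absent, labels recorded in a ``##hapsweep_populations``
    header line are used, else every sample is labelled "ALL".  Returns the
    panel restricted to ``region`` (an empty region yields a panel with
    zero sites, not an error).  The number of skipped non-biallelic records
    is stored on the panel as ``panel.n_skipped``.
    """
    header_pops: Optional[list[str]] = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("##"):
                break
            if line.startswith("##hapsweep_populations="):
                header_pops = line.strip().split("=", 1)[1].split(",")

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if callable(populations):
        pop_of = {s: populations(s) for s in samples}
    elif populations is not None:
        pop_of = dict(populations)
    elif header_pops is not None and len(header_pops) == len(samples):
        pop_of = dict(zip(samples, header_pops))
    else:
        pop_of = {s: "ALL" for s in samples}
    missing = [s for s in samples if s not in pop_of]
    if missing:
        raise ValueError(f"no population label for samples: {missing[:5]}")

    n_hap = 2 * len(samples)
    positions: list[int] = []
    cols: list[np.ndarray] = []
    deletion: Optional[np.ndarray] = None
    n_skipped = 0
    n_flipped = 0
    for v in vcf:
        if region is not None and not (
            v.CHROM == region.chrom and region.start <= v.POS <= region.end
        ):
            continue
        if len(v.ALT) != 1:
            n_skipped += 1
            continue
        col = np.empty(n_hap, dtype=np.uint8)
        for i, g in enumerate(v.genotypes):
            a, b, phased = g[0], g[1], g[-1]
            if not phased:
                raise ValueError(
                    f"unphased genotype for sample {samples[i]} at "
                    f"{v.CHROM}:{v.POS}"
                )
            if a < 0 or b < 0:
                raise ValueError(
                    f"missing genotype for sample {samples[i]} at "
                    f"{v.CHROM}:{v.POS}"
                )
            col[2 * i] = a
            col[2 * i + 1] = b
        if v.ALT[0] == "<DEL>":
            deletion = col
            continue
        # REF is treated as ancestral unless an AA annotation says otherwise
        aa = v.INFO.get("AA")
        if aa is not None and str(aa).upper().strip(".|") == str(v.ALT[0]):
            col = 1 - col
            n_flipped += 1
            logger.debug("ancestral allele is ALT at %s:%d; coding flipped",
                         v.CHROM, v.POS)
        positions.append(v.POS)
        cols.append(col)
    if n_skipped:
        logger.info("skipped %d non-biallelic records", n_skipped)
    if n_flipped:
        logger.info("flipped allele coding at %d sites with derived REF",
                    n_flipped)

    alleles = (
        np.column_stack(cols) if cols else np.zeros((n_hap, 0), dtype=np.uint8)
    )
    panel = HaplotypePanel(
        alleles=alleles,
        positions=np.asarray(positions, dtype=np.int64),
        pop_labels=np.array([pop_of[s] for s in samples for _ in (0, 1)]),
        sample_ids=np.array([s for s in samples for _ in (0, 1)]),
        hap_index=np.array([h for _ in samples for h in (0, 1)], dtype=np.int8),
        deletion_status=deletion,
        region=region,
        chrom=region.chrom if region else "1",
    )
    panel.n_skipped = n_skipped  # type: ignore[attr-defined]
    return panel
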