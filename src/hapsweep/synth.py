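"""Synthetic phased panels with a partial-sweep haplogroup structure.

The generator emulates the haplotype architecture the downstream analysis
assumes: two populations, a derived haplogroup at high frequency in the
focal population and absent in the other, strongly reduced diversity within
the haplogroup (a star-like genealogy descending from a single founder), a
structural deletion in imperfect linkage with the haplogroup, and an
optional upstream recombination hotspot decoupling flanking background
haplotypes.  Every panel comes with ground-truth membership and deletion
labels so classifier and null-model behaviour can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .coalescent import DemographicModel, simulate
from .panel import HaplotypePanel, fractional_to_bp
from .regions import GenomicRegion
from . import vcf_io


@dataclass
class SweepPanelSpec:
    """Target statistical structure for a generated panel.

    Frequencies are fractions in [0, 1]; diversities are per-site; haplotype
    counts must be even (haplotypes are paired into diploids in order).
    """

    n_hap_pop_a: int = 206              # focal (East-Asian-like) population
    n_hap_pop_b: int = 216              # non-focal (African-like) population
    region_length: int = 8787
    haplogroup_freq_a: float = 0.70
    haplogroup_freq_b: float = 0.0
    background_pi: float = 7.6e-4
    haplogroup_pi: float = 1.2e-4
    deletion_given_haplogroup: float = 0.91
    target_r2_deletion: float = 0.47
    n_core_sites: int = 5
    background_rho: float = 5.0
    hotspot: Optional[tuple[int, float]] = None   # (position bp, intensity)
    pop_a: str = "EAS"
    pop_b: str = "AFR"
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("haplogroup_freq_a", "haplogroup_freq_b",
                     "deletion_given_haplogroup", "target_r2_deletion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_hap_pop_a % 2 or self.n_hap_pop_b % 2:
            raise ValueError("haplotype counts must be even (diploid pairing)")
        if self.region_length <= 0:
            raise ValueError("region_length must be positive")


def default_hotspot(region_length: int) -> tuple[int, float]:
    """An upstream hotspot at a quarter of the region, intensity 1."""
    return (max(1, region_length // 4), 1.0)


def _solve_deletion_rate(f: float, q1: float, r2: float) -> float:
    """Probability of deletion carriage for non-members such that the
    deletion-haplogroup r-squared equals ``r2`` while members carry the
    deletion with probability ``q1``.

    With membership frequency f, P(del|member)=q1, P(del|non-member)=q0:
    p_D = f q1 + (1-f) q0 and p_{MD} = f q1, so
    r2(q0) = (1-f) (f q1 - f q0)^2 / (f p_D (1 - p_D)),
    which decreases monotonically from its maximum at q0=0 to 0 at q0=q1.
    """
    def r2_of(q0: float) -> float:
        p_d = f * q1 + (1 - f) * q0
        if p_d in (0.0, 1.0):
            return 0.0
        return (1 - f) * (f * q1 - f * q0) ** 2 / (f * p_d * (1 - p_d))

    r2_max = r2_of(0.0)
    if r2 > r2_max + 1e-12:
        raise ValueError(
            f"requested deletion-haplogroup r2={r2:.3f} infeasible for "
            f"membership frequency {f:.3f} and carriage {q1:.2f}; "
            f"maximum attainable r2 is {r2_max:.3f}"
        )
    if r2 >= r2_max:
        return 0.0
    return float(brentq(lambda q: r2_of(q) - r2, 0.0, q1, xtol=1e-12))


def generate_sweep_panel(spec: SweepPanelSpec):
    """Generate a phased two-population panel with the structure of ``spec``.

    Returns ``(panel, truth)`` where ``truth`` is a dict of boolean arrays
    (``member``, ``deletion``) over haplotypes in panel order.  Seeded
    generation is bit-reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.region_length
    n_a, n_b = spec.n_hap_pop_a, spec.n_hap_pop_b
    n_mem_a = round(spec.haplogroup_freq_a * n_a)
    n_mem_b = round(spec.haplogroup_freq_b * n_b)
    n_bg = (n_a - n_mem_a) + (n_b - n_mem_b) + 1   # +1 founder template

    # neutral background at the requested per-site diversity
    bg_model = DemographicModel(
        n_sam=max(n_bg, 2), n_reps=1,
        theta=spec.background_pi * L, rho=spec.background_rho,
    )
    bg_seed = int(rng.integers(2**31 - 1))
    rep = next(simulate(bg_model, seed=bg_seed))
    bg_positions = fractional_to_bp(rep.positions, L)
    bg_alleles = rep.alleles

    if spec.hotspot is not None:
        pos_bp, intensity = spec.hotspot
        right = bg_positions > pos_bp
        n_shuffle = int(round((1.0 - np.exp(-intensity)) * bg_alleles.shape[0]))
        if n_shuffle >= 2 and right.any():
            rows = rng.choice(bg_alleles.shape[0], size=n_shuffle, replace=False)
            perm = rng.permutation(rows)
            bg_alleles = bg_alleles.copy()
            bg_alleles[np.ix_(rows, np.flatnonzero(right))] = \
                bg_alleles[np.ix_(perm, np.flatnonzero(right))]

    founder = bg_alleles[0]
    bg_pool = bg_alleles[1:]

    # members: founder copies plus sparse private mutations (star genealogy)
    n_members = n_mem_a + n_mem_b
    lam = spec.haplogroup_pi * L / 2.0
    private_counts = rng.poisson(lam, size=n_members)
    used = set(int(p) for p in bg_positions)
    private_sites: list[tuple[int, int]] = []   # (position, member index)
    for m in range(n_members):
        for _ in range(int(private_counts[m])):
            while True:
                p = int(rng.integers(1, L + 1))
                if p not in used:
                    used.add(p)
                    private_sites.append((p, m))
                    break

    # fully linked core sites tagging the haplogroup (derived in members only)
    core_positions = []
    for k in range(spec.n_core_sites):
        target = int((k + 1) * L / (spec.n_core_sites + 1))
        p = target
        while p in used or p < 1 or p > L:
            p += 1
        used.add(p)
        core_positions.append(p)

    all_positions = np.array(
        sorted(set(int(p) for p in bg_positions)
               | {p for p, _ in private_sites} | set(core_positions)),
        dtype=np.int64,
    )
    pos_index = {int(p): i for i, p in enumerate(all_positions)}

    n_total = n_a + n_b
    alleles = np.zeros((n_total, len(all_positions)), dtype=np.uint8)
    member = np.zeros(n_total, dtype=bool)

    # place members at random haplotype slots within each population
    slots_a = rng.choice(n_a, size=n_mem_a, replace=False)
    slots_b = n_a + rng.choice(n_b, size=n_mem_b, replace=False)
    member[slots_a] = True
    member[slots_b] = True
    member_slots = np.concatenate([np.sort(slots_a), np.sort(slots_b)]).astype(int)

    bg_cols = np.array([pos_index[int(p)] for p in bg_positions], dtype=int)
    # members share the founder background
    for j, slot in enumerate(member_slots):
        alleles[slot, bg_cols] = founder
    for (p, m) in private_sites:
        alleles[member_slots[m], pos_index[p]] = 1
    for p in core_positions:
        alleles[member_slots, pos_index[p]] = 1
    # non-members get independent background draws
    non_slots = np.flatnonzero(~member)
    draw = rng.choice(bg_pool.shape[0], size=len(non_slots),
                      replace=bg_pool.shape[0] < len(non_slots))
    for slot, row in zip(non_slots, draw):
        alleles[slot, bg_cols] = bg_pool[row]

    # deletion carriage: members with probability q1, others with q0 solved
    # to meet the target deletion-haplogroup r2 in the focal population
    f = n_mem_a / n_a
    q1 = spec.deletion_given_haplogroup
    if 0 < f < 1 and q1 > 0:
        q0 = _solve_deletion_rate(f, q1, spec.target_r2_deletion)
    else:
        q0 = 0.0
    deletion = np.where(
        member, rng.random(n_total) < q1, rng.random(n_total) < q0
    ).astype(np.uint8)

    pop_labels = np.array([spec.pop_a] * n_a + [spec.pop_b] * n_b)
    sample_ids = np.array(
        [f"{spec.pop_a}{i // 2:04d}" for i in range(n_a)]
        + [f"{spec.pop_b}{i // 2:04d}" for i in range(n_b)]
    )
    hap_index = np.array([i % 2 for i in range(n_total)], dtype=np.int8)
    drop = _monomorphic(alleles)
    panel = HaplotypePanel(
        alleles=alleles[:, ~drop],
        positions=all_positions[~drop],
        pop_labels=pop_labels,
        sample_ids=sample_ids,
        hap_index=hap_index,
        deletion_status=deletion,
        region=GenomicRegion(spec.chrom, 1, L, name="synthetic"),
        chrom=spec.chrom,
    )
    truth = {
        "member": member,
        "deletion": deletion.astype(bool),
        "core_positions": np.array(
            [p for p in core_positions if not drop[pos_index[p]]], dtype=np.int64
        ),
    }
    return panel, truth


def _monomorphic(alleles: np.ndarray) -> np.ndarray:
    c = alleles.sum(axis=0)
    return (c == 0) | (c == alleles.shape[0])


def write_fixture_vcf(panel: HaplotypePanel, path, deletion_pos: Optional[int] = None) -> None:
    """Write a panel as a phased VCF fixture (SNVs plus one symbolic
    deletion record when the panel carries deletion status)."""
    vcf_io.write_phased_vcf(panel, path, deletion_pos=deletion_pos)
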