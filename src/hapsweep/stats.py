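"""Core population-genetic statistics on haplotype panels.

All statistics operate on binary haplotype matrices (rows = phased
haplotypes, columns = segregating sites, 1 = alternative/derived allele)
and are invariant under haplotype reordering.  Diversity is reported both
per region (mean pairwise differences) and per site (divided by the
physical span in bp).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .panel import HaplotypePanel


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

@dataclass
class DiversityResult:
    pi_region: float         # mean pairwise differences over the region
    pi_per_site: float       # pi_region / span in bp
    S: int                   # segregating sites
    theta_w: float           # Watterson estimator (per region)
    tajima_d: float
    tajima_defined: bool     # False when S == 0 (D reported as 0)


def _pairwise_pi(alleles: np.ndarray) -> float:
    """Mean pairwise Hamming distance via the site-frequency identity
    sum_s 2 c_s (n - c_s) / (n (n-1))."""
    n = alleles.shape[0]
    if n < 2:
        raise ValueError("nucleotide diversity requires >= 2 haplotypes")
    if alleles.shape[1] == 0:
        return 0.0
    c = alleles.sum(axis=0, dtype=np.int64)
    return float((2.0 * c * (n - c)).sum() / (n * (n - 1)))


def harmonic_number(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n + 1)))


def watterson_theta(S: int, n: int) -> float:
    """Watterson's estimator: S over the (n-1)-th harmonic number."""
    if n < 2:
        raise ValueError("Watterson's estimator requires n >= 2")
    if S == 0:
        return 0.0
    return S / harmonic_number(n - 1)


def tajimas_d(alleles: np.ndarray) -> tuple[float, bool]:
    """Tajima's D with the standard a1,a2,b1,b2,c1,c2,e1,e2 coefficients.

    Returns ``(D, defined)``; when S = 0 the statistic is undefined and is
    reported as a flagged 0 so windowed tracks stay numeric.
    """
    n = alleles.shape[0]
    seg = ((alleles.sum(axis=0) % n) != 0) & (alleles.sum(axis=0) != 0)
    S = int(seg.sum())
    if S == 0:
        return 0.0, False
    a1 = harmonic_number(n - 1)
    a2 = harmonic_number(n - 1, power=2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    pi = _pairwise_pi(alleles[:, seg])
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return 0.0, False
    return float((pi - S / a1) / math.sqrt(var)), True


def nucleotide_diversity(
    panel_or_alleles, span_bp: Optional[int] = None
) -> DiversityResult:
    """Diversity summary (π, S, Watterson θ, Tajima's D) for a panel or a
    raw haplotype matrix.  ``span_bp`` overrides the panel's region span."""
    if isinstance(panel_or_alleles, HaplotypePanel):
        alleles = panel_or_alleles.alleles
        if span_bp is None:
            span_bp = panel_or_alleles.span_bp()
    else:
        alleles = np.asarray(panel_or_alleles, dtype=np.uint8)
        if span_bp is None:
            raise ValueError("span_bp required when passing a raw matrix")
    n = alleles.shape[0]
    if n < 2:
        raise ValueError("nucleotide diversity requires >= 2 haplotypes")
    c = alleles.sum(axis=0, dtype=np.int64)
    seg = (c > 0) & (c < n)
    S = int(seg.sum())
    pi = _pairwise_pi(alleles)
    d, defined = tajimas_d(alleles)
    return DiversityResult(
        pi_region=pi,
        pi_per_site=pi / span_bp,
        S=S,
        theta_w=watterson_theta(S, n),
        tajima_d=d,
        tajima_defined=defined,
    )


def carrier_pi(
    alleles: np.ndarray, site: int, span_bp: Optional[int] = None
) -> Optional[float]:
    """π among the haplotypes carrying the derived allele at ``site``
    (per region, or per site when ``span_bp`` is given).  Returns None when
    fewer than two carriers exist (excluded from null distributions)."""
    carriers = alleles[alleles[:, site] == 1]
    if carriers.shape[0] < 2:
        return None
    pi = _pairwise_pi(carriers)
    return pi / span_bp if span_bp else pi


def mean_divergence(alleles: np.ndarray, reference: np.ndarray, span_bp: int) -> float:
    """Mean per-site Hamming distance of a haplotype set from a reference
    haplotype (used to date a haplogroup against an outgroup root)."""
    alleles = np.asarray(alleles, dtype=np.int64)
    reference = np.asarray(reference, dtype=np.int64)
    if alleles.shape[0] == 0:
        raise ValueError("empty haplotype subset")
    return float(np.abs(alleles - reference[None, :]).sum(axis=1).mean() / span_bp)


# ---------------------------------------------------------------------------
# differentiation and linkage disequilibrium
# ---------------------------------------------------------------------------

def fst_per_site(
    counts_a: tuple[float, int], counts_b: tuple[float, int]
) -> Optional[float]:
    """Weir & Cockerham (1984) single-site θ̂ for two haploid samples.

    ``counts_* = (derived copies, sample size)``.  May be negative; equals 1
    for a fixed difference; returns None (flagged undefined, excluded from
    null distributions) when the site is monomorphic across both samples.
    """
    da, na = counts_a
    db, nb = counts_b
    if na < 2 or nb < 2:
        raise ValueError("each sample needs >= 2 haplotypes")
    pa, pb = da / na, db / nb
    if (da + db == 0) or (da + db == na + nb):
        return None
    r = 2
    n_bar = (na + nb) / r
    n_c = (na + nb - (na * na + nb * nb) / (na + nb)) / (r - 1)
    p_bar = (da + db) / (na + nb)
    s2 = (na * (pa - p_bar) ** 2 + nb * (pb - p_bar) ** 2) / ((r - 1) * n_bar)
    # haploid variant: no within-individual heterozygosity component
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - s2 * (r - 1) / r)
    denom = a + b
    if denom == 0:
        return None
    return float(a / denom)


def hudson_fst(counts_a: tuple[float, int], counts_b: tuple[float, int]) -> Optional[float]:
    """Hudson's estimator 1 - Hw/Hb (available for sensitivity analysis)."""
    da, na = counts_a
    db, nb = counts_b
    pa, pb = da / na, db / nb
    if (da + db == 0) or (da + db == na + nb):
        return None
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    if den == 0:
        return None
    return float(num / den)


def fst_between(panel: HaplotypePanel, pop_a: str, pop_b: str) -> np.ndarray:
    """WC84 θ̂ per site between two populations of a panel (NaN where
    monomorphic across both)."""
    a = panel.population(pop_a).alleles
    b = panel.population(pop_b).alleles
    out = np.full(panel.n_sites, np.nan)
    for s in range(panel.n_sites):
        v = fst_per_site((int(a[:, s].sum()), a.shape[0]),
                         (int(b[:, s].sum()), b.shape[0]))
        if v is not None:
            out[s] = v
    return out


def r_squared(vec_a: Sequence[int], vec_b: Sequence[int]) -> Optional[float]:
    """Squared allelic correlation between two loci on phased haplotypes:
    (p_AB - p_A p_B)^2 / (p_A (1-p_A) p_B (1-p_B))."""
    x = np.asarray(vec_a, dtype=float)
    y = np.asarray(vec_b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("haplotype vectors differ in length")
    pa, pb = x.mean(), y.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return None
    pab = (x * y).mean()
    return float((pab - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb)))


# ---------------------------------------------------------------------------
# runs of homozygosity
# ---------------------------------------------------------------------------

def roh_from_core(
    hap1: np.ndarray,
    hap2: np.ndarray,
    positions: np.ndarray,
    core_position: float,
    side: str = "both",
    region_start: Optional[float] = None,
    region_end: Optional[float] = None,
) -> float:
    """Run-of-homozygosity length around a core site for one diploid.

    The length is the distance from ``core_position`` to the first site, in
    the given direction, where the two phased haplotypes differ; when no
    discordant site exists the run extends to the region edge.  ``side`` is
    ``"upstream"``, ``"downstream"`` or ``"both"`` (sum of the one-sided
    lengths).  The individual must be homozygous at the core site itself.
    """
    hap1 = np.asarray(hap1)
    hap2 = np.asarray(hap2)
    positions = np.asarray(positions)
    core_idx = np.flatnonzero(positions == core_position)
    if core_idx.size and hap1[core_idx[0]] != hap2[core_idx[0]]:
        raise ValueError(f"individual heterozygous at core site {core_position}")
    if region_start is None:
        region_start = float(positions.min()) if positions.size else core_position
    if region_end is None:
        region_end = float(positions.max()) if positions.size else core_position
    diff = positions[hap1 != hap2]
    if side == "downstream":
        ahead = diff[diff > core_position]
        return float((ahead.min() if ahead.size else region_end) - core_position)
    if side == "upstream":
        behind = diff[diff < core_position]
        return float(core_position - (behind.max() if behind.size else region_start))
    if side == "both":
        return roh_from_core(hap1, hap2, positions, core_position, "upstream",
                             region_start, region_end) + \
               roh_from_core(hap1, hap2, positions, core_position, "downstream",
                             region_start, region_end)
    raise ValueError(f"side must be upstream/downstream/both, got {side!r}")


@dataclass
class RohResult:
    core_position: float
    side: str
    lengths: np.ndarray        # one per diploid individual
    mean_length: float


def roh_for_individuals(
    panel: HaplotypePanel, core_position: float, side: str = "downstream",
    require_carrier: bool = True,
) -> RohResult:
    """ROH around a core site for every diploid in a panel that is
    homozygous there (for the derived allele when ``require_carrier``)."""
    core_idx = np.flatnonzero(panel.positions == core_position)
    if core_idx.size == 0:
        raise ValueError(f"core position {core_position} not in panel")
    ci = core_idx[0]
    lengths = []
    start = panel.region.start if panel.region else None
    end = panel.region.end if panel.region else None
    for i in range(0, panel.n_hap - 1, 2):
        h1, h2 = panel.alleles[i], panel.alleles[i + 1]
        if h1[ci] != h2[ci]:
            continue
        if require_carrier and h1[ci] != 1:
            continue
        lengths.append(
            roh_from_core(h1, h2, panel.positions, core_position, side, start, end)
        )
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise ValueError("no homozygous individuals at the core site")
    return RohResult(core_position, side, arr, float(arr.mean()))


# ---------------------------------------------------------------------------
# clustering and imputation
# ---------------------------------------------------------------------------

def cluster_haplotypes(panel: HaplotypePanel, method: str = "complete"):
    """Hierarchical clustering of haplotypes on Hamming distance, with no a
    priori haplogroup or deletion-status input.  Returns (linkage matrix,
    leaf order).  Ties are broken deterministically by scipy's ordering of
    the condensed distance matrix (lowest haplotype index first)."""
    if panel.n_hap < 2:
        raise ValueError("clustering requires >= 2 haplotypes")
    d = pdist(panel.alleles, metric="hamming") * panel.n_sites
    z = linkage(d, method=method)
    return z, leaves_list(z)


def impute_deletion(
    train: HaplotypePanel,
    test_alleles: np.ndarray,
) -> np.ndarray:
    """Predict deletion carriage for test haplotypes by nearest-haplotype
    vote (minimum Hamming distance in the training panel; ties broken by the
    lowest training-haplotype index)."""
    if train.deletion_status is None:
        raise ValueError("training panel lacks deletion_status")
    status = train.deletion_status
    if status.min() == status.max():
        raise ValueError("training panel is monomorphic for the deletion")
    test_alleles = np.asarray(test_alleles, dtype=np.uint8)
    dists = np.abs(
        test_alleles[:, None, :].astype(np.int16)
        - train.alleles[None, :, :].astype(np.int16)
    ).sum(axis=2)
    nearest = dists.argmin(axis=1)  # argmin takes the lowest index on ties
    return status[nearest].astype(np.uint8)


def imputation_accuracy(panel: HaplotypePanel, n_folds: int = 5, seed: int = 0) -> float:
    """Cross-validated accuracy of nearest-haplotype deletion imputation."""
    if panel.deletion_status is None:
        raise ValueError("panel lacks deletion_status")
    rng = np.random.default_rng(seed)
    order = rng.permutation(panel.n_hap)
    folds = np.array_split(order, n_folds)
    correct = 0
    for fold in folds:
        mask = np.ones(panel.n_hap, dtype=bool)
        mask[fold] = False
        train = panel.take_haplotypes(mask)
        if train.deletion_status.min() == train.deletion_status.max():
            continue
        pred = impute_deletion(train, panel.alleles[fold])
        correct += int((pred == panel.deletion_status[fold]).sum())
    return correct / panel.n_hap
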