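"""Null-model machinery for the sweep scan.

Builds the three simulated null distributions (frequency-matched per-site
FST, frequency-matched carrier diversity, and core-site-conditioned runs of
homozygosity), the empirical random-region nulls with rank tests, the
bootstrap sampling-bias check, and haplogroup identification from
population differentiation.

Frequency matching: the empirical matching window is stated for the
alternative-allele frequency of the haplogroup-defining variants.  In
simulated data the derived/ancestral labels do not correspond to
reference/alternative labels, so the FST null by default matches sites on
the frequency of *either* allele class (FST is invariant under allele
relabeling); the carrier-diversity null needs an identified carrier class
and therefore matches the derived class, with frequencies compared at the
precision at which the window is stated (two decimals).  Both behaviours
are configurable via ``match_rule`` and ``round_digits``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import mannwhitneyu, percentileofscore

from .coalescent import DemographicModel, simulate
from .panel import HaplotypePanel, fractional_to_bp
from .regions import GenomicRegion
from .stats import carrier_pi, fst_per_site, r_squared, roh_from_core, fst_between


@dataclass(frozen=True)
class FreqWindow:
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lo <= self.hi <= 1.0:
            raise ValueError(f"invalid frequency window [{self.lo}, {self.hi}]")

    def contains(self, f, round_digits: Optional[int] = None):
        f = np.asarray(f, dtype=float)
        if round_digits is not None:
            f = np.round(f, round_digits)
        return (f >= self.lo) & (f <= self.hi)


@dataclass
class NullDistribution:
    """A labelled collection of null statistic values."""

    values: np.ndarray
    source: str                       # empirical-random | empirical-SD | simulated
    matching: Optional[FreqWindow] = None
    n_inputs: int = 0                 # regions or replicates consumed
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_matched(self) -> int:
        return len(self.values)

    def percentile_of(self, x: float) -> float:
        return float(percentileofscore(self.values, x, kind="mean"))

    def to_tsv(self, path, statistic: str = "value") -> None:
        with open(path, "w") as fh:
            fh.write(f"# source: {self.source}\n")
            if self.matching is not None:
                fh.write(f"# matching_window: [{self.matching.lo}, {self.matching.hi}]\n")
            fh.write(f"# n_inputs: {self.n_inputs}\n")
            fh.write(f"# n_matched: {self.n_matched}\n")
            for k, v in self.meta.items():
                fh.write(f"# {k}: {v}\n")
            fh.write(f"{statistic}\n")
            for v in self.values:
                fh.write(f"{v:.8g}\n")


# ---------------------------------------------------------------------------
# empirical nulls
# ---------------------------------------------------------------------------

def sample_random_regions(
    chrom_length: int,
    region_size: int,
    n: int,
    rng: np.random.Generator,
    restrict_to: Optional[Sequence[GenomicRegion]] = None,
    chrom: str = "1",
) -> list[GenomicRegion]:
    """Sample size-matched regions uniformly on a chromosome.

    With ``restrict_to``, starts are drawn uniformly from the exact set of
    positions whose region overlaps at least one provided interval (the
    segmental-duplication variant of the empirical null)."""
    if region_size > chrom_length:
        raise ValueError("region_size exceeds chromosome length")
    max_start = chrom_length - region_size + 1
    if restrict_to is None:
        starts = rng.integers(1, max_start + 1, size=n)
    else:
        # valid starts: union of [s - size + 1, e] over restriction intervals
        ivals = []
        for r in restrict_to:
            lo = max(1, r.start - region_size + 1)
            hi = min(max_start, r.end)
            if lo <= hi:
                ivals.append((lo, hi))
        if not ivals:
            raise ValueError("restriction set admits no size-matched region")
        ivals.sort()
        merged = [list(ivals[0])]
        for lo, hi in ivals[1:]:
            if lo <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        lens = np.array([hi - lo + 1 for lo, hi in merged], dtype=np.int64)
        cum = np.concatenate([[0], np.cumsum(lens)])
        picks = rng.integers(0, cum[-1], size=n)
        idx = np.searchsorted(cum, picks, side="right") - 1
        starts = np.array([merged[j][0] + (p - cum[j]) for j, p in zip(idx, picks)])
    return [
        GenomicRegion(chrom, int(s), int(s) + region_size - 1, name=f"rand{k}")
        for k, s in enumerate(starts)
    ]


def read_statistic_track(path) -> "pd.DataFrame":
    """Read a per-window statistic track (TSV: chrom, start, end, value),
    e.g. externally computed iHS/XP-EHH/XP-CLR values to be compared with
    an empirical null via :func:`empirical_null_test`."""
    import pandas as pd
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    return df


def empirical_null_test(
    target_values: Sequence[float], null_values: Sequence[float]
) -> tuple[float, float]:
    """Compare a target statistic track against an empirical null.

    Returns ``(percentile of the target median within the null, two-sided
    Wilcoxon rank-sum p with continuity correction)``."""
    target = np.asarray(target_values, dtype=float)
    null = np.asarray(null_values, dtype=float)
    if target.size == 0 or null.size == 0:
        raise ValueError("both samples must be non-empty")
    pct = float(percentileofscore(null, float(np.median(target)), kind="mean"))
    stat = mannwhitneyu(
        target, null, alternative="two-sided", use_continuity=True,
        method="asymptotic",
    )
    return pct, float(stat.pvalue)


# ---------------------------------------------------------------------------
# simulated, frequency-matched nulls
# ---------------------------------------------------------------------------

def _matched_sites(freqs: np.ndarray, window: FreqWindow, match_rule: str,
                   round_digits: Optional[int]) -> np.ndarray:
    if match_rule == "derived":
        return window.contains(freqs, round_digits)
    if match_rule == "either":
        return window.contains(freqs, round_digits) | window.contains(
            1.0 - freqs, round_digits
        )
    raise ValueError(f"unknown match_rule {match_rule!r}")


def freq_matched_fst_null(
    model: DemographicModel,
    window: FreqWindow,
    focal_deme: int = 1,
    other_deme: int = 0,
    seed: int = 0,
    n_reps: Optional[int] = None,
    match_rule: str = "either",
    round_digits: Optional[int] = None,
) -> NullDistribution:
    """Frequency-matched per-site Weir-Cockerham FST null.

    Runs the simulation model and retains the FST (between focal and other
    deme) of every segregating site whose allele frequency in the focal
    deme falls in the matching window."""
    if model.n_pop < 2:
        raise ValueError("FST null requires >= 2 demes")
    reps = model.n_reps if n_reps is None else n_reps
    values: list[float] = []
    for rep in simulate(model, seed=seed, n_reps=reps):
        if rep.n_sites == 0:
            continue
        foc = rep.alleles[rep.demes == focal_deme]
        oth = rep.alleles[rep.demes == other_deme]
        freqs = foc.mean(axis=0)
        for s in np.flatnonzero(_matched_sites(freqs, window, match_rule, round_digits)):
            v = fst_per_site(
                (int(foc[:, s].sum()), foc.shape[0]),
                (int(oth[:, s].sum()), oth.shape[0]),
            )
            if v is not None:
                values.append(v)
    if not values:
        import warnings
        warnings.warn("frequency window matched no simulated sites")
    return NullDistribution(
        np.asarray(values), source="simulated", matching=window, n_inputs=reps,
        meta={"statistic": "fst_wc84", "seed": seed, "match_rule": match_rule,
              "round_digits": round_digits},
    )


def freq_matched_pi_null(
    model: DemographicModel,
    window: FreqWindow,
    focal_deme: int = 1,
    seed: int = 0,
    n_reps: Optional[int] = None,
    match_rule: str = "derived",
    round_digits: Optional[int] = 2,
    span_bp: Optional[int] = None,
    carrier_scope: str = "all",
) -> NullDistribution:
    """Frequency-matched carrier-diversity null.

    Sites are matched on the focal deme's allele frequency; the diversity
    value is computed among the carriers of the matched allele — over the
    whole sample by default (a haplogroup is defined by its defining
    alleles, not by a population boundary), or within the focal deme only
    with ``carrier_scope="focal"``.  Per region, or per site when
    ``span_bp`` is given."""
    if carrier_scope not in ("all", "focal"):
        raise ValueError("carrier_scope must be 'all' or 'focal'")
    reps = model.n_reps if n_reps is None else n_reps
    values: list[float] = []
    for rep in simulate(model, seed=seed, n_reps=reps):
        if rep.n_sites == 0:
            continue
        foc = rep.alleles[rep.demes == focal_deme]
        freqs = foc.mean(axis=0)
        for s in np.flatnonzero(_matched_sites(freqs, window, match_rule, round_digits)):
            sub = foc if carrier_scope == "focal" else rep.alleles
            if match_rule == "either" and not window.contains(
                freqs[s], round_digits
            ):
                sub = 1 - sub  # carrier class is the ancestral allele
            v = carrier_pi(sub, s, span_bp=span_bp)
            if v is not None:
                values.append(v)
    if not values:
        import warnings
        warnings.warn("frequency window matched no simulated sites")
    return NullDistribution(
        np.asarray(values), source="simulated", matching=window, n_inputs=reps,
        meta={"statistic": "carrier_pi", "seed": seed, "match_rule": match_rule,
              "round_digits": round_digits},
    )


def roh_null(
    model: DemographicModel,
    focal_window: FreqWindow,
    focal_deme: int = 0,
    other_deme: int = 1,
    seed: int = 0,
    n_reps: Optional[int] = None,
    side: str = "both",
    one_core_per_rep: bool = True,
) -> NullDistribution:
    """Core-site-conditioned ROH null.

    A replicate contributes when it contains a core site whose derived
    frequency in the focal deme lies in the window while the other deme
    carries zero derived copies.  One qualifying core site per replicate is
    used by default (yielding the expected ~1-1.7% of replicates); the
    focal-deme carrier haplotypes are paired in shuffled order into
    homozygous diploid constructs and the ROH around the core is measured
    in bp for each construct."""
    if model.rho <= 0 and model.n_sites < 2:
        raise ValueError("ROH null needs a recombination map (n_sites)")
    reps = model.n_reps if n_reps is None else n_reps
    region_len = model.n_sites
    lengths: list[float] = []
    n_core = 0
    root = np.random.SeedSequence(seed)
    pair_rng = np.random.Generator(np.random.PCG64(root.spawn(1)[0]))
    for rep in simulate(model, seed=seed, n_reps=reps):
        if rep.n_sites == 0:
            continue
        foc = rep.alleles[rep.demes == focal_deme]
        oth = rep.alleles[rep.demes == other_deme]
        f = foc.mean(axis=0)
        qual = np.flatnonzero(
            focal_window.contains(f) & (oth.sum(axis=0) == 0)
        )
        if qual.size == 0:
            continue
        if one_core_per_rep:
            qual = qual[[int(pair_rng.integers(qual.size))]]
        pos_bp = fractional_to_bp(rep.positions, region_len)
        for s in qual:
            n_core += 1
            carriers = np.flatnonzero(foc[:, s] == 1)
            order = pair_rng.permutation(carriers)
            core_pos = pos_bp[s]
            for k in range(0, len(order) - 1, 2):
                h1, h2 = foc[order[k]], foc[order[k + 1]]
                lengths.append(
                    roh_from_core(h1, h2, pos_bp, core_pos, side=side,
                                  region_start=1, region_end=region_len)
                )
    return NullDistribution(
        np.asarray(lengths), source="simulated", matching=focal_window,
        n_inputs=reps,
        meta={"statistic": f"roh_{side}_bp", "n_core_sites": n_core,
              "seed": seed},
    )


# ---------------------------------------------------------------------------
# bootstrap sampling-bias check
# ---------------------------------------------------------------------------

def bootstrap_homozygotes(
    member_alleles: np.ndarray,
    positions: np.ndarray,
    core_position: float,
    n_individuals: int = 238,
    n_boot: int = 500,
    rng: Optional[np.random.Generator] = None,
    side: str = "downstream",
    region_start: Optional[float] = None,
    region_end: Optional[float] = None,
    observed: Optional[float] = None,
) -> tuple[np.ndarray, Optional[float]]:
    """Resample haplogroup haplotypes into homozygous constructs.

    Each of ``n_boot`` datasets draws ``2 x n_individuals`` member
    haplotypes with replacement, pairs them into homozygous diploid
    constructs and records the mean one-sided ROH.  Returns the bootstrap
    means and, if ``observed`` is given, its percentile within them."""
    member_alleles = np.asarray(member_alleles, dtype=np.uint8)
    if member_alleles.shape[0] < 2:
        raise ValueError("need >= 2 member haplotypes")
    rng = np.random.default_rng() if rng is None else rng
    means = np.empty(n_boot)
    n_hap = member_alleles.shape[0]
    for b in range(n_boot):
        picks = rng.integers(0, n_hap, size=2 * n_individuals)
        total = 0.0
        for k in range(0, 2 * n_individuals, 2):
            total += roh_from_core(
                member_alleles[picks[k]], member_alleles[picks[k + 1]],
                positions, core_position, side=side,
                region_start=region_start, region_end=region_end,
            )
        means[b] = total / n_individuals
    pct = float(percentileofscore(means, observed, kind="mean")) \
        if observed is not None else None
    return means, pct


# ---------------------------------------------------------------------------
# haplogroup identification
# ---------------------------------------------------------------------------

@dataclass
class Haplogroup:
    core_sites: np.ndarray            # site indices into the panel
    core_positions: np.ndarray        # bp
    member: np.ndarray                # bool per haplotype
    full_match: np.ndarray            # bool: derived at ALL core sites
    min_pairwise_r2: float


def identify_haplogroup(
    panel: HaplotypePanel,
    differentiation: Optional[np.ndarray] = None,
    pop_a: Optional[str] = None,
    pop_b: Optional[str] = None,
    r2_threshold: float = 0.84,
    top_fraction: float = 0.95,
) -> Haplogroup:
    """Identify a haplogroup from the most population-differentiated sites.

    Sites with differentiation within ``top_fraction`` of the maximum form
    the candidate core set; all pairwise r-squared values among them must
    exceed ``r2_threshold`` (else an error names the worst pair).
    Membership = carrying the derived allele at at least half the core
    sites; haplotypes that are not full matches are flagged as recombinant
    via ``full_match``."""
    if differentiation is None:
        if pop_a is None or pop_b is None:
            pops = panel.populations()
            if len(pops) < 2:
                raise ValueError("need two populations or a differentiation track")
            pop_a, pop_b = pops[0], pops[1]
        differentiation = fst_between(panel, pop_a, pop_b)
    differentiation = np.asarray(differentiation, dtype=float)
    if not np.isfinite(differentiation).any():
        raise ValueError("no defined differentiation values")
    dmax = np.nanmax(differentiation)
    core = np.flatnonzero(differentiation >= top_fraction * dmax)
    # mutual-LD check
    min_r2 = 1.0
    worst = None
    for i in range(len(core)):
        for j in range(i + 1, len(core)):
            r2 = r_squared(panel.alleles[:, core[i]], panel.alleles[:, core[j]])
            r2 = 0.0 if r2 is None else r2
            if r2 < min_r2:
                min_r2 = r2
                worst = (int(core[i]), int(core[j]))
    if len(core) >= 2 and min_r2 <= r2_threshold:
        raise ValueError(
            f"top-differentiated sites are not a single haplogroup: sites "
            f"{worst[0]} and {worst[1]} have r2={min_r2:.3f} <= {r2_threshold}"
        )
    if len(core) < 2 and r2_threshold > 1.0:
        raise ValueError("no site set passes an r2 threshold above 1")
    hits = panel.alleles[:, core].sum(axis=1)
    member = hits >= (len(core) / 2.0)
    full = hits == len(core)
    return Haplogroup(
        core_sites=core,
        core_positions=panel.positions[core],
        member=member,
        full_match=full,
        min_pairwise_r2=min_r2 if len(core) >= 2 else 1.0,
    )
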