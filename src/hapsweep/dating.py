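"""Age estimators for a swept haplogroup.

Three complementary clocks:

* drift time — the expected time for a neutral allele to drift from a
  single copy (1/2Ne) to its present frequency x, using the Kimura-Ohta
  expected-age form t = -4Ne x ln(x) / (1-x) generations (the formula is
  injectable so an alternative neutral-expectation variant can be swapped
  in);
* sequence divergence — the haplogroup's mean per-site distance from a
  root (non-member) haplotype, calibrated by the human-chimpanzee per-site
  divergence and split time;
* ROH decay — the onset of selection from the length of the run of
  homozygosity: recombination breaks the swept haplotype once r*L*t
  reaches 1, so t = 1/(rL) generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional


@dataclass(frozen=True)
class DatingParams:
    ne: float = 1e4                  # effective population size (diploid)
    gen_time: float = 25.0           # years per generation
    rec_rate: float = 1.45e-8        # per bp per generation
    rec_rate_sd: float = 0.05e-8     # uncertainty on rec_rate
    mut_rate: float = 3e-8           # per site per generation (recorded)
    d_hc: float = 0.01747            # human-chimp per-site divergence
    t_hc_low: float = 5e6            # younger human-chimp split (years)
    t_hc_high: float = 12e6          # older human-chimp split (years)

    def __post_init__(self) -> None:
        for name in ("ne", "gen_time", "rec_rate", "mut_rate", "d_hc",
                     "t_hc_low", "t_hc_high"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class AgeEstimate:
    method: str                      # drift-time | divergence | roh-onset
    value: float                     # years
    range: Optional[tuple[float, float]] = None
    params: DatingParams = field(default_factory=DatingParams)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("age must be non-negative")
        if self.range is not None:
            lo, hi = self.range
            if not lo <= self.value <= hi:
                raise ValueError("range must bracket the value")

    def to_dict(self) -> dict:
        d = {"method": self.method, "value_years": self.value}
        if self.range is not None:
            d["range_years"] = list(self.range)
        d["params"] = {k: getattr(self.params, k)
                       for k in self.params.__dataclass_fields__}
        return d


def kimura_ohta_drift_time(x: float, ne: float) -> float:
    """Expected age (generations) of a neutral allele now at frequency x:
    -4 Ne x ln(x) / (1 - x)."""
    import math
    if x >= 1.0:
        raise ValueError("frequency must be < 1")
    return -4.0 * ne * x * math.log(x) / (1.0 - x)


def neutral_time_to_frequency(
    x: float,
    params: DatingParams = DatingParams(),
    formula: Callable[[float, float], float] = kimura_ohta_drift_time,
) -> AgeEstimate:
    """Expected neutral time for a variant starting at 1/(2Ne) to reach
    frequency ``x``, in years.  The generations formula is swappable."""
    if not 0.0 < x < 1.0:
        raise ValueError(f"frequency must lie in (0, 1), got {x}")
    t_gen = formula(x, params.ne)
    return AgeEstimate("drift-time", t_gen * params.gen_time, params=params)


def divergence_age(d: float, params: DatingParams = DatingParams()) -> AgeEstimate:
    """Coalescent age from per-site divergence ``d`` to a root haplotype,
    linear in the human-chimpanzee calibration: t = d / D_hc * T_hc.
    The range spans the younger and older split-time calibrations."""
    if d < 0:
        raise ValueError("divergence must be non-negative")
    lo = d / params.d_hc * params.t_hc_low
    hi = d / params.d_hc * params.t_hc_high
    mid = (lo + hi) / 2.0
    return AgeEstimate("divergence", mid, range=(lo, hi), params=params)


def sweep_onset_from_roh(
    length_bp: float, params: DatingParams = DatingParams()
) -> AgeEstimate:
    """Selection onset from ROH decay: t = 1/(r L) generations, with the
    uncertainty propagated from the recombination-rate interval.

    ``length_bp`` is the per-individual total (both flanks); callers with a
    one-sided mean must double it."""
    if length_bp <= 0:
        raise ValueError("ROH length must be positive")
    t_years = params.gen_time / (params.rec_rate * length_bp)
    r_lo = params.rec_rate - params.rec_rate_sd
    r_hi = params.rec_rate + params.rec_rate_sd
    rng = (params.gen_time / (r_hi * length_bp),
           params.gen_time / (r_lo * length_bp))
    return AgeEstimate("roh-onset", t_years, range=rng, params=params)
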