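# Methods

This note documents the models behind `hapsweep`, the conventions and
defaults that matter for interpreting its output, and the places where the
design was genuinely open and a choice had to be made.

## The coalescent simulator

`hapsweep.coalescent` implements Hudson's coalescent with recombination for
a structured population, restricted to the flag subset used by the two
simulation command lines the pipeline ships as defaults: `-t` (θ = 4N₀μ per
region), `-r` (ρ = 4N₀r per region over a given number of sites), `-I`
(demes with an optional symmetric migration parameter), `-m` (a single
backward migration-matrix entry), `-n` (present-day deme size), `-en`
(timed size change) and `-ej` (deme join).

**Time scale.** Time runs in units of 4N₀ generations. In these units a
lineage pair in a deme of relative size x coalesces at rate 2/x, a lineage
crosses over at rate ρ × (span of its ancestral material, trapped material
included), a lineage in deme i migrates to deme j at rate m_ij (the
familiar "M/2 per lineage" applies when time is measured in 2N₀
generations), and mutations arrive at rate θ per unit span of tracked
ancestral material under the infinite-sites model. These rates were
validated end to end against an independent ms-compatible engine (`mspms`):
mean segregating sites, private-site counts and matched-site counts agree
within Monte Carlo error on both default command lines. A symmetric-rate
variant that halves migration was detectably wrong in that comparison and
is the reason the scale above is spelled out.

**Mechanics.** Ancestral material is a list of intervals over [0, 1), each
carrying the bitmask of sampled haplotypes below it. Intervals that reach
their local MRCA are dropped, so only branches that can produce segregating
sites are tracked. Instead of simulating mutation events in the main loop,
every destroyed lineage logs (duration × interval × descendant set);
mutations are Poisson-dropped on this branch log afterwards, which is
exact and keeps the event loop small. Crossover breakpoints are continuous
in (leftmost, rightmost); the `-r` site count is used only to map
fractional positions to base pairs (floor(pos·L)+1, collisions bumped to
the next free bp) for downstream ROH distances. `-ej t i j` moves all
lineages of deme i to j and zeroes migration into i. A replicate that can
never fully coalesce (isolated demes, no pending events) raises a guarded
error rather than looping forever.

**Reproducibility.** One root seed spawns per-replicate generators through
`numpy.random.SeedSequence`, so replicate k is bit-identical no matter how
the stream is consumed.

## Statistics

π is the mean pairwise Hamming distance, computed through the
site-frequency identity Σ 2c(n−c)/(n(n−1)) (an O(nS) form that equals the
pairwise enumeration exactly); per-site values divide by the physical span
of the region, not the count of segregating sites. Watterson's θ̂ and
Tajima's D use the standard coefficient chain; D is reported as a flagged 0
when S = 0 so windowed tracks stay numeric. Per-site FST is Weir &
Cockerham's (1984) estimator in its haploid form (no within-individual
component); it can be negative, is exactly 1 at a fixed difference, and is
flagged undefined (and excluded from nulls) at sites monomorphic across
both samples. r² uses phased haplotypes with the deletion coded as a
per-haplotype binary allele. Hierarchical clustering of haplotypes uses
complete linkage on Hamming distance; with tied merge heights the
dendrogram follows the input order, so only order-free summaries (cluster
memberships, cophenetic distances) are contract-stable. Deletion imputation
is a nearest-haplotype vote with ties broken toward the lowest training
index; it exists mainly to demonstrate that a partially linked deletion
(r² ≈ 0.47) cannot be imputed accurately.

**ROH convention.** The run of homozygosity of a diploid around a core site
is the distance from the core to the first site where its two haplotypes
differ, per direction, extending to the region edge when no discordance
exists; `both` sums the two one-sided lengths. The length is the distance
to the discordant site itself, not to the midpoint of the flanking
interval — a simpler convention that slightly overestimates runs, uniformly
across observed and simulated data.

## Frequency-matched null distributions

The matching window (default [0.69, 0.70], the standard-deviation range of
the haplogroup-defining variants' frequency) is applied to the focal deme
of the simulated model (the 206-haplotype, bottlenecked deme).

Two conventions deserve explanation because the simulated derived/ancestral
labels have no counterpart in the reference/alternative labels of real
VCFs:

* **FST null** (default `match_rule="either"`): a site is matched when
  either allele class falls in the window. FST is invariant under allele
  relabeling, so class-symmetric matching is the natural simulation analog
  of matching on reference-relative alternative-allele frequencies. Under
  this rule 1000 replicates of the default model retain ≈650 ± 50 sites.
* **Carrier-diversity null** (default `match_rule="derived"`, frequencies
  compared at the two decimals in which the window is stated): here the
  carrier class must be identified, so the derived class is matched, and π
  is computed over **all** carriers of the matched allele, not only the
  focal deme's (a haplogroup is defined by its alleles, not by a population
  boundary). Under this rule 1000 replicates retain ≈330 ± 30 values.
  Restricting carriers to the focal deme instead places a large fraction of
  the null at or near zero (bottleneck-era carrier clades are often
  identical) and destroys the contrast with a swept haplogroup; the pooled
  scope reproduces the reported behaviour, with the observed swept value
  below essentially the whole null. Both the rule and the scope are
  options (`match_rule`, `round_digits`, `carrier_scope`).

No single convention we could justify reproduces both of the two
historically reported matched counts (≈603 for the FST null and ≈389 for
the carrier-π null) from the same 1000-replicate run: the class-symmetric
rule brackets the former and the derived-at-printed-precision rule comes
within ~10–15% of the latter. The counts are seed-stable (CV < 10%) and
linear in replicate count under every rule; the residual discrepancy is
recorded as unresolved rather than hidden.

A percentile claim as extreme as "below the 1st percentile" needs enough
null values to resolve: matched sites arrive in linked clusters of 2–4 per
replicate (same carrier set, near-identical π), so a ~225-value null puts
lumpy mass in the tail. The true neutral fraction of matched haplogroups as
homogeneous as a swept one is ≈0.2–0.4% (measured on a 6000-replicate run);
comparisons at the 1st percentile should use ≥3000 replicates.

**ROH null.** A replicate qualifies when it contains a core site whose
derived frequency in the focal (East-Asian-like) deme lies in
0.69 ± 0.031 (a binomial standard deviation) with zero derived copies in
the other deme; by default one qualifying site per replicate contributes
(≈1–1.7% of replicates do), the focal carriers are paired in shuffled order
into homozygous diploid constructs, and both-side ROH is measured around
the core in bp. Counting every qualifying site instead of one per replicate
inflates the yield several-fold through within-replicate linkage and is
available via `one_core_per_rep=False`.

**θ calibration.** The default pipeline runs the two command lines
verbatim, including their stated θ values — that is how the original
analysis was performed, even though the FST-model θ exceeds the observed
Watterson estimate of the target region roughly tenfold, an oddity this
package reproduces rather than resolves (the carrier-π contrast in fact
depends on it). `calibrate_to_panel=True` replaces θ with the focal
population's θ̂\_W and rescales the models to the panel's span as a
sensitivity analysis; under that calibration the bottleneck demography
makes neutral matched carriers nearly as homogeneous as a swept haplogroup
and the π and ROH contrasts largely vanish — a caveat worth knowing before
interpreting a default-model verdict.

**Verdict flags.** A panel is called a sweep candidate when (i) the
core-site FST exceeds the 99th percentile of its matched null, (ii) the
within-haplogroup π falls below the 1st percentile of the carrier null, and
(iii) the observed ROH lengths differ from the core-conditioned null by a
two-sided Wilcoxon rank-sum test at p < 0.01. The ROH flag is deliberately
direction-free: on a short observed region the runs are edge-limited and
sit *below* a 200 kb simulated null even for a sweep, while on full-scale
data the expected direction is above; the report always carries the
percentile so the direction is visible. All p-values are raw; no
multiple-testing correction is applied, and the report says so.

## The synthetic-panel generator

`generate_sweep_panel` emulates the haplotype architecture the analysis
assumes, with ground truth: two populations (defaults 206 and 216 phased
haplotypes over 8,787 bp); a haplogroup at frequency 0.70 in the focal
population and 0 in the other, built as copies of a single founder plus
Poisson-sparse private mutations with rate tuned so the within-haplogroup π
is 1.2×10⁻⁴ per site (a star genealogy — most members identical, matching
the observed pattern); a neutral-coalescent background at 7.6×10⁻⁴ per
site; a set of fully linked core SNVs (default 5) derived in members only;
a deletion assigned with P(del | member) = 0.91 and P(del | non-member)
solved in closed form so the member–deletion r² in the focal population is
0.47 (requests beyond the feasible bound r²\_max = (1−f)q₁/(1−fq₁) raise an
error naming the bound); and an optional upstream hotspot realized by
shuffling the right-of-hotspot blocks of a 1−e^(−intensity) fraction of
background haplotypes.

What the generator does **not** emulate: the background has no
two-population demographic structure (differentiation comes entirely from
the haplogroup), the star genealogy has no internal substructure or
recombinant members, private mutations are uniform in rate (so member
identity does not extend over hundreds of kb the way real haplotype
identity decays), and there is no genotyping error or allele-frequency
ascertainment. Passing tests on these panels therefore demonstrates that
the machinery detects the intended structure and does not false-alarm on
its absence — not that the pipeline's power or calibration transfers to
any particular real cohort.

## Dating

Three clocks, all selection-free by construction:

* **Drift time**: t = −4Nₑ x ln(x)/(1−x) generations for an allele now at
  frequency x (defaults Nₑ = 10⁴, 25 years/generation). This is the
  expected *age of an allele observed at x*, which forward Wright–Fisher
  simulation confirms within 15% (sojourn-weighted age near x, N = 500); it
  is roughly three times the conditional first-passage time to x, so the
  two must not be conflated. The formula is injectable
  (`neutral_time_to_frequency(..., formula=...)`) because more than one
  neutral-expectation variant exists in the literature.
* **Divergence**: t = d/D_hc × T_hc with d the haplogroup's mean per-site
  distance from a root (non-member) haplotype; the reported range spans the
  5 and 12 My calibrations of the human–chimpanzee split, with D_hc =
  0.01747 per site.
* **ROH onset**: recombination breaks a swept haplotype once r·L·t ≈ 1, so
  t = 1/(rL) generations with r = (1.45 ± 0.05)×10⁻⁸ per bp per generation
  (the uncertainty interval is propagated to the estimate); L is the
  per-individual total across both flanks — one-sided means must be
  doubled (`--side one` in the CLI does this).

## Problem sizes in the test suite

The suite exercises the full-size study conditions where they are cheap
(1000-replicate null counts, five seeds) and scaled-down sizes elsewhere,
chosen so the checks retain power on one CPU: the ROH core-site yield is
checked at 1500 replicates against the implied per-replicate rate; the
recombination ladder (ρ = 20, 200, 2000 per 200 kb) uses 250/200/100
replicates with a widened matching window to supply enough independent
cores — at the model's mutation density the ρ = 20 and ρ = 200 length
distributions are both mutation-limited and statistically
indistinguishable, so the non-increase is tested step-wise and the strict
decrease across the full ladder; and the Wright–Fisher dating oracle uses
60,000–120,000 forward trajectories.

## Known limitations

Growth (`-G/-g`), gene conversion, population splits (`-es`) and tree
output are unsupported (unused by the target analysis). The simulator is
pure Python; at ρ = 2000 over 200 kb a replicate takes ~1.5 s, so very
large recombination-heavy runs are the practical bottleneck. Real-VCF
support assumes phased, biallelic records with the reference allele
ancestral unless an ancestral annotation is supplied; unphased data are
rejected rather than phased. The iHS/XP-EHH/XP-CLR class of statistics is
consumed as external per-window tracks (`empirical_null_test`), never
computed here.
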