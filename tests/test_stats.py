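"""Statistics checked against enumeration, textbook second implementations,
and invariance properties."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hapsweep.coalescent import DemographicModel, simulate
from hapsweep.panel import HaplotypePanel
from hapsweep.regions import GenomicRegion
from hapsweep.stats import carrier_pi, cluster_haplotypes, fst_per_site, \
    hudson_fst, imputation_accuracy, impute_deletion, mean_divergence, \
    nucleotide_diversity, r_squared, roh_from_core, tajimas_d, watterson_theta


def _panel(alleles, positions=None, pops=None, region_len=None, deletion=None):
    alleles = np.asarray(alleles, dtype=np.uint8)
    n, s = alleles.shape
    if positions is None:
        positions = np.arange(1, s + 1)
    region = GenomicRegion("1", 1, region_len) if region_len else None
    return HaplotypePanel(
        alleles=alleles, positions=np.asarray(positions),
        pop_labels=np.asarray(pops if pops is not None else ["P"] * n),
        sample_ids=np.array([f"s{i // 2}" for i in range(n)]),
        hap_index=np.array([i % 2 for i in range(n)]),
        region=region, deletion_status=deletion,
    )


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def test_pi_monomorphic_is_zero():
    p = _panel(np.zeros((4, 3)), region_len=10)
    assert nucleotide_diversity(p).pi_region == 0.0


def test_pi_enumeration_single_site():
    # 4 haplotypes, one site with derived count 2 -> 4 discordant pairs of 6
    p = _panel([[1, ], [1, ], [0, ], [0, ]], region_len=10)
    d = nucleotide_diversity(p)
    assert d.pi_region == pytest.approx(4 / 6)
    assert d.pi_per_site == pytest.approx(4 / 6 / 10)


def test_pi_matches_brute_force_pair_enumeration(toy_rng):
    alleles = toy_rng.integers(0, 2, size=(8, 30))
    p = _panel(alleles, region_len=100)
    brute = np.mean([
        (alleles[i] != alleles[j]).sum()
        for i, j in itertools.combinations(range(8), 2)
    ])
    assert nucleotide_diversity(p).pi_region == pytest.approx(brute)


@pytest.mark.parametrize("S,n,expected", [(0, 5, 0.0), (10, 5, 10 / (1 + 1/2 + 1/3 + 1/4))])
def test_watterson_examples(S, n, expected):
    assert watterson_theta(S, n) == pytest.approx(expected)


def test_watterson_recovers_simulated_theta():
    theta, n, reps = 4.0, 12, 1500
    model = DemographicModel(n_sam=n, n_reps=reps, theta=theta)
    est = [watterson_theta(rep.n_sites, n) for rep in simulate(model, seed=21)]
    h1 = sum(1 / i for i in range(1, n))
    h2 = sum(1 / i**2 for i in range(1, n))
    sd = np.sqrt((theta * h1 + theta**2 * h2)) / h1
    assert abs(np.mean(est) - theta) < 3 * sd / np.sqrt(reps)


def _tajima_reference(alleles):
    """Independent textbook evaluation of Tajima's D."""
    n, _ = alleles.shape
    c = alleles.sum(axis=0)
    seg = (c > 0) & (c < n)
    S = int(seg.sum())
    if S == 0:
        return None
    pi = np.mean([
        (alleles[i] != alleles[j]).sum()
        for i, j in itertools.combinations(range(n), 2)
    ])
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def test_tajimas_d_matches_independent_formula(toy_rng):
    alleles = toy_rng.integers(0, 2, size=(6, 25)).astype(np.uint8)
    d, defined = tajimas_d(alleles)
    assert defined
    assert d == pytest.approx(_tajima_reference(alleles))


def test_tajimas_d_flagged_zero_when_no_segregation():
    d, defined = tajimas_d(np.zeros((6, 4), dtype=np.uint8))
    assert (d, defined) == (0.0, False)


def test_tajimas_d_near_zero_under_neutral_equilibrium():
    model = DemographicModel(n_sam=20, n_reps=1000, theta=8.0)
    vals = [tajimas_d(rep.alleles)[0] for rep in simulate(model, seed=31)]
    assert abs(np.mean(vals)) < 0.2


# ---------------------------------------------------------------------------
# FST and LD
# ---------------------------------------------------------------------------

def test_fst_fixed_difference_is_one():
    assert fst_per_site((20, 20), (0, 20)) == pytest.approx(1.0)


def test_fst_equal_frequencies_not_positive():
    assert fst_per_site((10, 20), (10, 20)) <= 0.0


def test_fst_monomorphic_flagged_undefined():
    assert fst_per_site((0, 20), (0, 20)) is None
    assert fst_per_site((20, 20), (20, 20)) is None


def test_fst_matches_direct_wc84_evaluation():
    # independent hand evaluation of the haploid WC84 estimator
    da, na, db, nb = 15, 20, 3, 30
    pa, pb = da / na, db / nb
    n_bar = (na + nb) / 2
    n_c = (na + nb - (na**2 + nb**2) / (na + nb))
    p_bar = (da + db) / (na + nb)
    s2 = (na * (pa - p_bar) ** 2 + nb * (pb - p_bar) ** 2) / n_bar
    a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - s2 / 2) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - s2 / 2)
    assert fst_per_site((da, na), (db, nb)) == pytest.approx(a / (a + b))


def test_fst_decreases_with_migration():
    """Island-model trend: stronger migration, lower mean FST."""
    means = []
    for mig in (0.5, 2.0, 8.0):
        model = DemographicModel(n_sam=24, n_reps=150, theta=5.0, n_pop=2,
                                 subsizes=(12, 12), symmetric_mig=mig)
        vals = []
        for rep in simulate(model, seed=41):
            a = rep.alleles[rep.demes == 0]
            b = rep.alleles[rep.demes == 1]
            for s in range(rep.n_sites):
                v = fst_per_site((int(a[:, s].sum()), 12), (int(b[:, s].sum()), 12))
                if v is not None:
                    vals.append(v)
        means.append(np.mean(vals))
    assert means[0] > means[1] > means[2]


@settings(deadline=None, max_examples=40, derandomize=True)
@given(da=st.integers(0, 20), db=st.integers(0, 30))
def test_fst_invariant_under_allele_label_swap(da, db):
    v1 = fst_per_site((da, 20), (db, 30))
    v2 = fst_per_site((20 - da, 20), (30 - db, 30))
    if v1 is None:
        assert v2 is None
    else:
        assert v1 == pytest.approx(v2)
    h1, h2 = hudson_fst((da, 20), (db, 30)), hudson_fst((20 - da, 20), (30 - db, 30))
    if h1 is not None:
        assert h1 == pytest.approx(h2)


def test_r_squared_examples():
    assert r_squared([1, 1, 0, 0], [1, 1, 0, 0]) == pytest.approx(1.0)
    # p_A = p_B = 0.5, p_AB = 0.25 -> independence
    assert r_squared([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(0.0)
    assert r_squared([1, 1, 1, 1], [1, 0, 1, 0]) is None


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                min_size=4, max_size=40))
def test_r_squared_symmetric_and_label_invariant(pairs):
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    v = r_squared(x, y)
    if v is None:
        return
    assert v == pytest.approx(r_squared(y, x))
    assert v == pytest.approx(r_squared(1 - x, y))
    assert 0.0 <= v <= 1.0 + 1e-12


def test_carrier_pi_enumeration():
    alleles = np.array([
        [1, 0, 1, 0],
        [1, 1, 0, 0],
        [1, 0, 0, 0],
        [0, 1, 1, 1],
    ], dtype=np.uint8)
    # carriers at site 0: rows 0-2; pairwise diffs: (0,1)->2 (0,2)->1 (1,2)->1
    assert carrier_pi(alleles, 0) == pytest.approx((2 + 1 + 1) / 3)
    assert carrier_pi(alleles, 3) is None          # single carrier
    ident = np.array([[1, 0], [1, 0], [0, 1]], dtype=np.uint8)
    assert carrier_pi(ident, 0) == 0.0             # identical carriers


def test_mean_divergence_examples():
    ref = np.zeros(1000, dtype=np.uint8)
    subset = np.zeros((2, 1000), dtype=np.uint8)
    subset[0, [3, 50, 700]] = 1
    subset[1, [3, 50, 700]] = 1
    assert mean_divergence(subset, ref, 1000) == pytest.approx(0.003)
    assert mean_divergence(ref[None, :], ref, 1000) == 0.0


# ---------------------------------------------------------------------------
# runs of homozygosity
# ---------------------------------------------------------------------------

def test_roh_boundary_definitions():
    positions = np.array([100, 500, 5500, 9000])
    h1 = np.array([1, 1, 1, 0], dtype=np.uint8)
    h2 = np.array([1, 1, 0, 0], dtype=np.uint8)   # mismatch at 5500
    # core at 500; first downstream discordance at 5500
    assert roh_from_core(h1, h2, positions, 500, "downstream",
                         region_start=1, region_end=10000) == 5000
    assert roh_from_core(h1, h2, positions, 500, "upstream",
                         region_start=1, region_end=10000) == 499
    assert roh_from_core(h1, h2, positions, 500, "both",
                         region_start=1, region_end=10000) == 5499


def test_roh_extends_to_region_edge_without_discordance():
    positions = np.array([100, 500])
    h = np.array([1, 1], dtype=np.uint8)
    assert roh_from_core(h, h, positions, 500, "downstream",
                         region_start=1, region_end=8787) == 8287


def test_roh_heterozygous_core_rejected():
    positions = np.array([100, 500])
    h1 = np.array([1, 1], dtype=np.uint8)
    h2 = np.array([1, 0], dtype=np.uint8)
    with pytest.raises(ValueError, match="heterozygous"):
        roh_from_core(h1, h2, positions, 500, "downstream")


@settings(deadline=None, max_examples=30, derandomize=True)
@given(new_pos=st.integers(501, 5499))
def test_roh_monotone_under_inserted_heterozygous_site(new_pos):
    """Adding a discordant site between the core and the old boundary never
    lengthens the run."""
    positions = np.array([100, 500, 5500, 9000])
    h1 = np.array([1, 1, 1, 0], dtype=np.uint8)
    h2 = np.array([1, 1, 0, 0], dtype=np.uint8)
    base = roh_from_core(h1, h2, positions, 500, "downstream",
                         region_start=1, region_end=10000)
    idx = np.searchsorted(positions, new_pos)
    p2 = np.insert(positions, idx, new_pos)
    g1 = np.insert(h1, idx, 1)
    g2 = np.insert(h2, idx, 0)
    longer = roh_from_core(g1, g2, p2, 500, "downstream",
                           region_start=1, region_end=10000)
    assert longer <= base


def test_statistics_invariant_under_haplotype_reordering(toy_rng):
    alleles = toy_rng.integers(0, 2, size=(10, 40)).astype(np.uint8)
    perm = toy_rng.permutation(10)
    p1 = _panel(alleles, region_len=100)
    p2 = _panel(alleles[perm], region_len=100)
    d1, d2 = nucleotide_diversity(p1), nucleotide_diversity(p2)
    assert d1.pi_region == pytest.approx(d2.pi_region)
    assert d1.tajima_d == pytest.approx(d2.tajima_d)
    assert d1.S == d2.S


# ---------------------------------------------------------------------------
# clustering and imputation
# ---------------------------------------------------------------------------

def test_clustering_separates_two_identical_blocks():
    block_a = np.tile([1, 1, 1, 0, 0, 0], (5, 1))
    block_b = np.tile([0, 0, 0, 1, 1, 1], (5, 1))
    p = _panel(np.vstack([block_a, block_b]), region_len=10)
    _, order = cluster_haplotypes(p)
    groups = [set(order[:5]), set(order[5:])]
    assert {frozenset(g) for g in groups} == {
        frozenset(range(5)), frozenset(range(5, 10))
    }


def test_clustering_topology_invariant_under_permutation(toy_rng):
    """The cophenetic distance between two haplotypes does not depend on the
    input order of the panel."""
    from scipy.cluster.hierarchy import cophenet
    from scipy.spatial.distance import squareform
    # enough sites that merge heights are untied; with tied distances the
    # complete-linkage dendrogram legitimately depends on input order
    alleles = toy_rng.integers(0, 2, size=(9, 200))
    perm = toy_rng.permutation(9)
    z1, _ = cluster_haplotypes(_panel(alleles, region_len=300))
    z2, _ = cluster_haplotypes(_panel(alleles[perm], region_len=300))
    c1 = squareform(cophenet(z1))
    c2 = squareform(cophenet(z2))
    # haplotype i sits at row perm.index(i) of the permuted panel
    inv = np.argsort(perm)
    assert np.allclose(c1, c2[np.ix_(inv, inv)])


def test_impute_deletion_perfect_tag():
    alleles = np.array([[1, 0], [1, 1], [0, 0], [0, 1]], dtype=np.uint8)
    deletion = np.array([1, 1, 0, 0], dtype=np.uint8)  # tagged by site 0
    train = _panel(alleles, region_len=10, deletion=deletion)
    pred = impute_deletion(train, alleles)
    assert np.array_equal(pred, deletion)
    assert imputation_accuracy(train, n_folds=2, seed=0) == 1.0


def test_impute_deletion_independent_of_snvs_matches_null_accuracy(toy_rng):
    n = 200
    alleles = toy_rng.integers(0, 2, size=(n, 12)).astype(np.uint8)
    p_del = 0.3
    deletion = (toy_rng.random(n) < p_del).astype(np.uint8)
    train = _panel(alleles, region_len=50, deletion=deletion)
    acc = imputation_accuracy(train, n_folds=5, seed=1)
    # nearest-haplotype vote cannot beat the majority class by much
    assert acc < max(p_del, 1 - p_del) + 0.12


def test_impute_requires_both_deletion_states():
    alleles = np.zeros((4, 3), dtype=np.uint8)
    train = _panel(alleles, region_len=10,
                   deletion=np.ones(4, dtype=np.uint8))
    with pytest.raises(ValueError, match="monomorphic"):
        impute_deletion(train, alleles)
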