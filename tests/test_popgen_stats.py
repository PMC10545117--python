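import numpy as np
import pandas as pd
import pytest

from surfload.core_io import MISSING, GenotypeMatrix, PopulationMap, VariantSite
from surfload.popgen_stats import (
    beta_st,
    fst_tree,
    ld_decay,
    observed_heterozygosity,
    tajimas_d,
    tajimas_d_window,
    wc_fst,
)


def _gm(geno, positions=None, chrom="chr1"):
    geno = np.asarray(geno, dtype=np.int8)
    n, m = geno.shape
    positions = positions or [j + 1 for j in range(m)]
    sites = [VariantSite(chrom, p, "A", "G") for p in positions]
    return GenotypeMatrix([f"s{i}" for i in range(n)], sites, geno)


def _pm(gm, split=None):
    if split is None:
        return PopulationMap({s: "p1" for s in gm.samples})
    return PopulationMap(
        {s: ("p1" if i < split else "p2") for i, s in enumerate(gm.samples)}
    )


# --- Ho -------------------------------------------------------------------


def test_ho_all_het_is_one():
    gm = _gm([[1], [1], [1], [1]])
    assert observed_heterozygosity(gm, _pm(gm)).iloc[0] == 1.0


def test_ho_all_hom_is_zero():
    gm = _gm([[0], [2], [2], [0]])
    assert observed_heterozygosity(gm, _pm(gm)).iloc[0] == 0.0


def test_ho_matches_hand_recount():
    rng = np.random.default_rng(11)
    geno = rng.integers(-1, 3, size=(6, 30)).astype(np.int8)
    gm = _gm(geno)
    got = observed_heterozygosity(gm, _pm(gm)).iloc[0]
    fracs = []
    for j in range(30):
        het = nm = 0
        for i in range(6):
            if geno[i, j] != MISSING:
                nm += 1
                het += geno[i, j] == 1
        if nm:
            fracs.append(het / nm)
    assert got == pytest.approx(np.mean(fracs), abs=1e-12)


# --- betaST ---------------------------------------------------------------


def test_beta_st_near_zero_for_identical_allele_frequencies():
    # the distinct-draw within-matching is unbiased while cross-matching is a
    # plugin product, so beta is exactly 0 only in expectation; with many
    # individuals and sites it must sit at the sampling floor
    rng = np.random.default_rng(1)
    p = rng.uniform(0.1, 0.9, size=2000)
    geno = rng.binomial(2, np.tile(p, (100, 1))).astype(np.int8)
    gm = _gm(geno)
    b = beta_st(gm, _pm(gm, split=50))
    assert np.abs(b.to_numpy()).max() < 0.02


def test_beta_st_matches_matching_proportion_enumeration():
    """Two pops, two sites: enumerate allele-draw pairs by hand."""
    geno = np.array([[2, 0], [2, 1], [0, 0], [1, 1]], dtype=np.int8)
    gm = _gm(geno)
    pm = _pm(gm, split=2)
    got = beta_st(gm, pm)

    def matching_within(rows, j):
        alleles = []
        for i in rows:
            alleles += [1] * geno[i, j] + [0] * (2 - geno[i, j])
        n = len(alleles)
        same = sum(
            alleles[a] == alleles[b] for a in range(n) for b in range(n) if a != b
        )
        return same / (n * (n - 1))

    def matching_between(j):
        p1 = geno[:2, j].sum() / 4.0
        p2 = geno[2:, j].sum() / 4.0
        return p1 * p2 + (1 - p1) * (1 - p2)

    mb = np.mean([matching_between(j) for j in range(2)])
    for pop, rows in (("p1", [0, 1]), ("p2", [2, 3])):
        mii = np.mean([matching_within(rows, j) for j in range(2)])
        assert got[pop] == pytest.approx((mii - mb) / (1 - mb), abs=1e-12)


def test_beta_st_invariant_to_allele_relabeling():
    rng = np.random.default_rng(5)
    geno = rng.integers(0, 3, size=(8, 25)).astype(np.int8)
    gm1 = _gm(geno)
    gm2 = _gm(2 - geno)
    pm = _pm(gm1, split=4)
    pd.testing.assert_series_equal(beta_st(gm1, pm), beta_st(gm2, pm))


# --- Tajima's D -----------------------------------------------------------


def _tajima_oracle(geno):
    """Literal textbook formula, scalar arithmetic only."""
    n = 2 * geno.shape[0]
    p = geno.sum(axis=0) / n
    seg = (p > 0) & (p < 1)
    S = int(seg.sum())
    if S == 0:
        return np.nan
    pi = sum(2 * q * (1 - q) * n / (n - 1) for q in p[seg])
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def test_tajima_missing_when_no_segregating_sites():
    assert np.isnan(tajimas_d_window(np.zeros((4, 5), dtype=np.int8)))


def test_tajima_negative_for_singleton_only_windows():
    # n=4 diploids (8 haplotypes), 3 segregating sites, all singletons
    geno = np.zeros((4, 3), dtype=np.int8)
    geno[0, 0] = geno[1, 1] = geno[2, 2] = 1
    d = tajimas_d_window(geno)
    assert d < 0
    assert d == pytest.approx(_tajima_oracle(geno), abs=1e-9)


def test_tajima_formula_oracle_on_random_windows():
    rng = np.random.default_rng(2)
    for _ in range(100):
        geno = rng.integers(0, 3, size=(5, rng.integers(2, 20))).astype(np.int8)
        got = tajimas_d_window(geno)
        want = _tajima_oracle(geno)
        if np.isnan(want):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-9)


def test_tajima_windowing_uses_complete_genotypes_only():
    geno = np.array([[1, MISSING], [0, 1], [1, 0], [0, 1]], dtype=np.int8)
    gm = _gm(geno, positions=[10, 20])
    table, _ = tajimas_d(gm, _pm(gm), window_bp=1000, min_s=1)
    assert table.S.iloc[0] == 1  # second site dropped (incomplete)


def test_neutral_equilibrium_mean_tajima_near_zero():
    """Single-deme neutral simulations: mean D across replicates within 0.3
    of zero."""
    from tests.conftest import small_config
    from surfload.simulate import simulate_expansion

    means = []
    for rep in range(20):
        cfg = small_config(
            seed=400 + rep,
            n_demes=1,
            deme_size=80,
            burn_in_generations=30,
            generations_after_last_founding=0,
            dfe_mean_s=-1e-9,   # effectively neutral
            p_beneficial=0.0,
            sample_per_deme=10,
        )
        ds = simulate_expansion(cfg)
        _, d = tajimas_d(ds.gm, ds.popmap, window_bp=50_000, min_s=3)
        if len(d):
            means.append(d.iloc[0])
    assert abs(np.mean(means)) < 0.3


# --- Weir-Cockerham FST ---------------------------------------------------


def test_fst_fixed_difference_is_one():
    geno = np.array([[2]] * 4 + [[0]] * 4, dtype=np.int8)
    gm = _gm(geno)
    f = wc_fst(gm, _pm(gm, split=4))
    assert f.loc["p1", "p2"] == pytest.approx(1.0)


def test_fst_identical_frequencies_near_zero():
    rng = np.random.default_rng(8)
    p = rng.uniform(0.2, 0.8, size=1000)
    geno = rng.binomial(2, p, size=(40, 1000)).astype(np.int8)
    gm = _gm(geno)
    f = wc_fst(gm, _pm(gm, split=20))
    assert abs(f.loc["p1", "p2"]) < 0.02


def _wc_oracle(g1, g2):
    """Literal per-site variance components (diploid, two populations)."""
    num = den = 0.0
    r = 2
    for j in range(g1.shape[1]):
        a1 = g1[:, j][g1[:, j] != MISSING]
        a2 = g2[:, j][g2[:, j] != MISSING]
        n1, n2 = len(a1), len(a2)
        if n1 < 2 or n2 < 2:
            continue
        p1, p2 = a1.sum() / (2 * n1), a2.sum() / (2 * n2)
        h1, h2 = (a1 == 1).mean(), (a2 == 1).mean()
        nbar = (n1 + n2) / 2
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        if pbar <= 0 or pbar >= 1:
            continue
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


def test_fst_matches_variance_component_bruteforce():
    rng = np.random.default_rng(3)
    geno = rng.integers(-1, 3, size=(10, 50)).astype(np.int8)
    gm = _gm(geno)
    f = wc_fst(gm, _pm(gm, split=5))
    want = _wc_oracle(geno[:5], geno[5:])
    assert f.loc["p1", "p2"] == pytest.approx(want, abs=1e-9)


# --- LD -------------------------------------------------------------------


def test_duplicated_site_has_r2_one():
    rng = np.random.default_rng(4)
    col = rng.binomial(2, 0.4, size=20).astype(np.int8)
    geno = np.column_stack([col, col])
    gm = _gm(geno, positions=[100, 600])
    curve, _ = ld_decay(gm, gm.samples, maf=0.05, max_dist_bp=10_000, n_bins=5)
    assert curve.mean_r2.max() == pytest.approx(1.0)


def test_independent_sites_r2_near_sampling_floor():
    rng = np.random.default_rng(6)
    n = 50
    geno = rng.binomial(2, 0.5, size=(n, 200)).astype(np.int8)
    gm = _gm(geno)
    curve, _ = ld_decay(gm, gm.samples, maf=0.05, max_dist_bp=500, n_bins=4)
    pooled = np.average(curve.mean_r2, weights=curve.n_pairs)
    assert pooled < 3.0 / n  # expectation ~ 1/n for independent sites


def test_bottlenecked_deme_has_longer_ld_than_source():
    """A deme held at founder size keeps r2 elevated over much longer
    distances than the equilibrium source deme."""
    from tests.conftest import small_config
    from surfload.pipeline import bundle_from_simulation
    from surfload.simulate import simulate_expansion

    ok = 0
    for rep in range(6):
        cfg = small_config(
            seed=700 + rep, n_demes=2, deme_size=100, founder_size=12,
            growth_rate=1.0, migration_rate=0.002,
            generations_between_founding=10,
            generations_after_last_founding=5,
            n_genes=40, codons_per_gene=25, sample_per_deme=10,
        )
        b = bundle_from_simulation(simulate_expansion(cfg))
        hm = {}
        for pop in ("pop01", "pop02"):
            _, half = ld_decay(b.gm, b.popmap.samples_of(pop),
                               max_dist_bp=150_000, n_bins=10)
            hm[pop] = half
        if np.isnan(hm["pop01"]) or np.isnan(hm["pop02"]):
            continue
        ok += hm["pop02"] >= hm["pop01"]
    assert ok >= 4


# --- FST tree -------------------------------------------------------------


def test_ultrametric_three_populations_equal_root_distances():
    d = pd.DataFrame(
        [[0, 0.2, 0.2], [0.2, 0, 0.2], [0.2, 0.2, 0]],
        index=list("ABC"),
        columns=list("ABC"),
    )
    t = fst_tree(d, root_pop="A")
    assert t.root_distance.max() - t.root_distance.min() < 1e-9


def test_nj_recovers_additive_four_taxon_topology():
    # additive tree: ((A:1,B:2):1,(C:3,D:4)) -> pairwise path lengths
    dm = pd.DataFrame(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ],
        index=list("ABCD"),
        columns=list("ABCD"),
        dtype=float,
    )
    t = fst_tree(dm, root_pop="A")
    tips = {x.name for x in t.tree.tips()}
    assert tips == set("ABCD")
    # A and B must be closer in the tree than A and C
    tree = t.tree
    ab = tree.find("A").distance(tree.find("B"))
    ac = tree.find("A").distance(tree.find("C"))
    assert ab == pytest.approx(3.0, abs=1e-6)
    assert ac == pytest.approx(5.0, abs=1e-6)


def test_root_distance_tracks_expansion_order(surfing_replicates):
    """Serial-founder expansion: NJ root-to-tip distance rank-correlates with
    deme founding order when rooted at the minimal-betaST population."""
    from scipy import stats

    good = 0
    for rep in surfing_replicates[:8]:
        gm, pm = rep["bundle"].gm, rep["bundle"].popmap
        b = beta_st(gm, pm)
        f = wc_fst(gm, pm)
        t = fst_tree(f, beta=b)
        rd = t.root_distance.sort_index()
        rho = stats.spearmanr(np.arange(len(rd)), rd.to_numpy()).statistic
        good += rho > 0.8
    assert good >= 5


def test_minimal_beta_st_marks_an_old_deme(surfing_replicates):
    """The minimal-betaST population is one of the oldest demes: with
    Nm = 5 the source region is near-panmictic, so betaST identifies the
    ancestral *pool* (demes 1-4) rather than deme 1 specifically."""
    hits = 0
    for rep in surfing_replicates:
        gm, pm = rep["bundle"].gm, rep["bundle"].popmap
        b = beta_st(gm, pm)
        hits += b.idxmin() in ("pop01", "pop02", "pop03", "pop04")
    assert hits / len(surfing_replicates) >= 0.8
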