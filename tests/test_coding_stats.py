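import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surfload.coding_stats import (
    _CODON_TABLE,
    _STOPS,
    SiteCounts,
    bin_genes_by_gc3,
    classify_codon_sites,
    gc3,
    gc_conservative_filter,
    gene_site_counts,
    pi_n_pi_s,
    window_pinpis,
)
from surfload.core_io import CodingAlignment, VariantSite


def _aln(gene_id, *seqs):
    """Build an alignment from an even number of haplotype sequences."""
    pairs = [(seqs[i], seqs[i + 1]) for i in range(0, len(seqs), 2)]
    return CodingAlignment(gene_id, [f"s{i}" for i in range(len(pairs))], pairs)


# --- NG86 site counting ---------------------------------------------------


def _enumerate_codon_sites(codon):
    """Independent oracle: enumerate the 9 single-base changes per position."""
    aa = _CODON_TABLE[codon]
    syn = []
    for p in range(3):
        counted = n_syn = 0
        for b in "ACGT":
            if b == codon[p]:
                continue
            mut = codon[:p] + b + codon[p + 1 :]
            if mut in _STOPS:
                continue
            counted += 1
            n_syn += _CODON_TABLE[mut] == aa
        syn.append(n_syn / counted if counted else 0.0)
    return syn


@pytest.mark.parametrize(
    "codon", [c for c in map("".join, itertools.product("ACGT", repeat=3)) if c not in _STOPS]
)
def test_codon_site_classification_matches_enumeration(codon):
    syn, nonsyn = classify_codon_sites(codon)
    expected = _enumerate_codon_sites(codon)
    assert syn == pytest.approx(tuple(expected))
    assert [s + n for s, n in zip(syn, nonsyn)] == pytest.approx([1.0] * 3)


def test_phe_and_gly_examples():
    syn_ttt, _ = classify_codon_sites("TTT")
    assert syn_ttt == pytest.approx((0.0, 0.0, 1 / 3))
    syn_ggg, _ = classify_codon_sites("GGG")
    assert syn_ggg[2] == 1.0


def test_stop_codon_excluded():
    with pytest.raises(ValueError):
        classify_codon_sites("TAA")


def test_site_count_conservation_per_gene():
    rng = np.random.default_rng(0)
    codons = [c for c in map("".join, itertools.product("ACGT", repeat=3)) if c not in _STOPS]
    seq = "".join(rng.choice(codons, size=40))
    aln = _aln("g", seq, seq)
    sc = gene_site_counts(aln)
    assert sc.syn_sites + sc.nonsyn_sites == pytest.approx(3 * sc.codon_count, abs=1e-9)


# --- GC3 ------------------------------------------------------------------


def test_gc3_examples():
    assert gc3(_aln("g", "GACGAT", "GACGAT")).gc3 == pytest.approx(0.5)
    assert gc3(_aln("g", "GGGCCC", "GGGCCC")).gc3 == 1.0
    g = gc3(_aln("g", "ATGGAN", "ATGGAN"))
    assert g.gc3 == 1.0 and g.third_positions_used == 1


def test_gc3_all_N_is_missing():
    assert gc3(_aln("g", "AANAAN", "AANAAN")).gc3 is None


# --- pi -------------------------------------------------------------------


def test_two_haplotypes_single_synonymous_difference():
    # GGA->GGG is synonymous (Gly); 100 codons, one syn diff
    base = "GGA" * 100
    var = "GGG" + "GGA" * 99
    sc = gene_site_counts(_aln("g", base, var))
    assert sc.syn_diffs == pytest.approx(1.0)
    assert sc.nonsyn_diffs == 0.0
    assert sc.pi_s == pytest.approx(1.0 / sc.syn_sites)


def test_identical_haplotypes_zero_pi():
    sc = gene_site_counts(_aln("g", "ATGGCT" * 10, "ATGGCT" * 10))
    assert sc.pi_n == 0.0 and sc.pi_s == 0.0


def test_ratio_missing_when_pi_s_zero():
    sc = gene_site_counts(_aln("g", "ATGGCT" * 10, "ATGGCT" * 10))
    assert np.isnan(sc.ratio)


def _pairwise_oracle(aln):
    """All-pairs mean per-site difference counts, split syn/nonsyn by the
    consensus-codon context -- independent of the vectorized path."""
    from surfload.coding_stats import _column_pi, is_stop, is_synonymous_change

    seqs = aln.sequences()
    n = len(seqs)
    syn_d = nonsyn_d = 0.0
    for c0 in range(0, aln.length, 3):
        codons = [s[c0 : c0 + 3] for s in seqs]
        if any(ch not in "ACGT" for cd in codons for ch in cd):
            continue
        cols = [tuple(cd[k] for cd in codons) for k in range(3)]
        consensus = "".join(_column_pi(col)[1] for col in cols)
        if is_stop(consensus):
            continue
        for k in range(3):
            col = [cd[k] for cd in codons]
            diffs = sum(
                col[i] != col[j] for i in range(n) for j in range(i + 1, n)
            )
            if diffs == 0:
                continue
            mean_pair = diffs / (n * (n - 1) / 2)
            alleles = sorted(set(col))
            ctx = consensus
            minor = alleles[0] if alleles[1] == ctx[k] else alleles[1]
            if is_synonymous_change(ctx[:k] + ctx[k] + ctx[k + 1 :], k, minor):
                syn_d += mean_pair
            else:
                nonsyn_d += mean_pair
    return syn_d, nonsyn_d


def test_pi_matches_all_pairs_oracle_on_random_genes():
    rng = np.random.default_rng(3)
    codons = [c for c in map("".join, itertools.product("ACGT", repeat=3)) if c not in _STOPS]
    alns = []
    for g in range(5):
        base = list("".join(rng.choice(codons, size=12)))
        seqs = []
        for _ in range(6):  # 6 haplotypes
            s = base.copy()
            for _ in range(rng.integers(0, 4)):
                i = rng.integers(len(s))
                s[i] = "ACGT"[rng.integers(4)]
            seqs.append("".join(s))
        alns.append(_aln(f"g{g}", *seqs))
    agg = pi_n_pi_s(alns)
    syn_o = nonsyn_o = 0.0
    for a in alns:
        sd, nd = _pairwise_oracle(a)
        syn_o += sd
        nonsyn_o += nd
    assert agg.syn_diffs == pytest.approx(syn_o, abs=1e-12)
    assert agg.nonsyn_diffs == pytest.approx(nonsyn_o, abs=1e-12)


def test_neutral_coding_region_ratio_near_one():
    """Strictly neutral polymorphism (syn and nonsyn changes equally likely)
    gives piN/piS ~ 1 over replicates."""
    rng = np.random.default_rng(9)
    codons = [c for c in map("".join, itertools.product("ACGT", repeat=3)) if c not in _STOPS]
    ratios = []
    for rep in range(20):
        base = list("".join(rng.choice(codons, size=300)))
        seqs = []
        for _ in range(10):
            s = base.copy()
            for _ in range(60):  # neutral: mutations land anywhere
                i = rng.integers(len(s))
                s[i] = "ACGT"[rng.integers(4)]
            seqs.append("".join(s))
        agg = gene_site_counts(_aln("g", *seqs))
        if agg.pi_s > 0:
            ratios.append(agg.ratio)
    mean = np.mean(ratios)
    ci = 1.96 * np.std(ratios, ddof=1) / np.sqrt(len(ratios))
    assert mean - ci < 1.0 < mean + ci


# --- windows and bins -----------------------------------------------------


def _counts(gene_id, codons=10, syn_d=1.0, nonsyn_d=2.0):
    return SiteCounts(gene_id, 7.5, 22.5, syn_d, nonsyn_d, codons)


def test_window_packing():
    genes = [("chr1", i * 100, _counts(f"g{i}", codons=10)) for i in range(10)]
    # each gene contributes 30 bp of gene space; span 120 -> windows of 4,4,2
    w = window_pinpis(genes, window_span=120)
    assert list(w.n_genes) == [4, 4, 2]
    # trailing window is 60 bp = 50% of span, above the 25% partial threshold
    assert not w.partial.iloc[-1]


def test_window_trailing_below_quarter_span_flagged_partial():
    genes = [("chr1", i * 100, _counts(f"g{i}", codons=10)) for i in range(4)]
    genes.append(("chr1", 400, _counts("g4", codons=8)))  # trailing 24 bp < 25% of 120
    w = window_pinpis(genes, window_span=120)
    assert list(w.n_genes) == [4, 1]
    assert w.partial.iloc[-1]


def test_single_gene_larger_than_span_gets_own_window():
    w = window_pinpis([("chr1", 0, _counts("big", codons=100))], window_span=120)
    assert len(w) == 1 and not w.partial.iloc[0]


def test_window_pi_invariant_to_within_window_gene_order():
    genes = [("chr1", i * 100, _counts(f"g{i}", codons=10, syn_d=i)) for i in range(4)]
    w1 = window_pinpis(genes, window_span=120)
    w2 = window_pinpis(list(reversed(genes)), window_span=120)
    assert w1.pi_s.iloc[0] == pytest.approx(w2.pi_s.iloc[0])


def test_gc3_bins_equal_count_and_monotone():
    from surfload.coding_stats import GeneGC

    rng = np.random.default_rng(1)
    genes = [
        (GeneGC(f"g{i}", float(rng.uniform(0.2, 0.8)), 10), _counts(f"g{i}"))
        for i in range(100)
    ]
    b = bin_genes_by_gc3(genes, 10)
    assert list(b.n_genes) == [10] * 10
    assert (np.diff(b.gc3_median) >= 0).all()


def test_gc3_bins_identical_values():
    from surfload.coding_stats import GeneGC

    genes = [(GeneGC(f"g{i}", 0.5, 10), _counts(f"g{i}")) for i in range(10)]
    b = bin_genes_by_gc3(genes, 5)
    assert (b.gc3_median == 0.5).all()


def test_too_many_bins_raises():
    from surfload.coding_stats import GeneGC

    genes = [(GeneGC("g", 0.5, 10), _counts("g"))]
    with pytest.raises(ValueError):
        bin_genes_by_gc3(genes, 2)


# --- GC-conservative filter ----------------------------------------------


@pytest.mark.parametrize(
    "ref,alt,kept",
    [("A", "T", True), ("A", "G", False), ("C", "G", True), ("T", "C", False)],
)
def test_gc_conservative_filter(ref, alt, kept):
    sites = [VariantSite("chr1", 1, ref, alt)]
    assert (len(gc_conservative_filter(sites)) == 1) is kept


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.sampled_from("ACGT"), min_size=2, max_size=2, unique=True))
def test_gc_conservative_filter_keeps_exactly_strand_symmetric_pairs(pair):
    ref, alt = pair
    kept = gc_conservative_filter([VariantSite("chr1", 1, ref, alt)])
    assert bool(kept) == (frozenset(pair) in ({frozenset("AT"), frozenset("CG")}))
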