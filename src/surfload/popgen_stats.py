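"""Classical population statistics for the demographic backdrop: observed
heterozygosity, population-specific betaST, windowed Tajima's D, pairwise
Weir-Cockerham FST, LD decay, and an FST-based neighbor-joining population
tree with root-to-leaf distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import MISSING, GenotypeMatrix, PopulationMap


def _pop_allele_stats(geno: np.ndarray):
    """Per-site non-missing diploid count and alt-allele frequency for one pop."""
    nonmiss = geno != MISSING
    n = nonmiss.sum(axis=0)
    alt = np.where(nonmiss, geno, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
    return n, p


def observed_heterozygosity(gm: GenotypeMatrix, popmap: PopulationMap) -> pd.Series:
    """Per-population Ho: mean over sites of heterozygote fraction among
    non-missing individuals."""
    out = {}
    for pop, rows in popmap.rows_by_pop(gm.samples).items():
        sub = gm.genotypes[rows]
        nonmiss = sub != MISSING
        n = nonmiss.sum(axis=0)
        het = (sub == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(n > 0, het / n, np.nan)
        out[pop] = float(np.nanmean(frac)) if np.isfinite(frac).any() else 0.0
    return pd.Series(out, name="ho")


def beta_st(gm: GenotypeMatrix, popmap: PopulationMap) -> pd.Series:
    """Population-specific differentiation (Weir-Goudet matching proportions).

    beta_i = (M_ii - M_B) / (1 - M_B) with M_ii the within-population
    allele-matching probability for distinct draws and M_B the mean
    cross-population matching, each a ratio of averages over loci.  Negative
    values flag populations closest to the ancestral gene pool.
    """
    pops = list(popmap.rows_by_pop(gm.samples))
    if len(pops) < 2:
        raise ValueError("betaST needs >= 2 populations")
    rows_by_pop = popmap.rows_by_pop(gm.samples)
    n_sites = gm.n_sites
    freqs, within = {}, {}
    for pop in pops:
        sub = gm.genotypes[rows_by_pop[pop]]
        n, p = _pop_allele_stats(sub)
        n_al = 2.0 * n
        alt = np.where(sub != MISSING, sub, 0).sum(axis=0)
        ref = n_al - alt
        with np.errstate(invalid="ignore", divide="ignore"):
            m_ii = np.where(
                n_al > 1,
                (alt * (alt - 1) + ref * (ref - 1)) / (n_al * (n_al - 1)),
                np.nan,
            )
        freqs[pop] = p
        within[pop] = m_ii
    mb = np.zeros(n_sites)
    n_pairs = 0
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            mb += freqs[a] * freqs[b] + (1 - freqs[a]) * (1 - freqs[b])
            n_pairs += 1
    mb /= n_pairs
    mb_mean = np.nanmean(mb)
    if mb_mean >= 1.0:
        return pd.Series({p: np.nan for p in pops}, name="beta_st")
    out = {}
    for pop in pops:
        mii_mean = np.nanmean(within[pop])
        out[pop] = (mii_mean - mb_mean) / (1.0 - mb_mean)
    return pd.Series(out, name="beta_st")


def _tajima_constants(n: int):
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d_window(geno: np.ndarray) -> float:
    """Tajima's D for one population's complete genotypes at one window's sites.

    ``geno`` is (individuals x sites) dosage with no missing values; the
    haploid sample size is 2 x individuals.
    """
    n = 2 * geno.shape[0]
    if n < 4:
        return np.nan
    p = geno.sum(axis=0) / float(n)
    seg = (p > 0) & (p < 1)
    s = int(seg.sum())
    if s == 0:
        return np.nan
    pi = float(np.sum(2.0 * p[seg] * (1 - p[seg]) * n / (n - 1)))
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * s + e2 * s * (s - 1)
    return (pi - s / a1) / np.sqrt(var)


def tajimas_d(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    window_bp: int = 100_000,
    min_s: int = 3,
) -> tuple[pd.DataFrame, pd.Series]:
    """Windowed Tajima's D per population and its mean over windows with at
    least ``min_s`` segregating sites.

    Only sites completely genotyped within the population enter, keeping the
    haploid sample size constant across sites.
    """
    chroms = np.array([s.chrom for s in gm.sites])
    pos = np.array([s.pos for s in gm.sites])
    win = pos // window_bp
    rows = []
    for pop, ridx in popmap.rows_by_pop(gm.samples).items():
        sub = gm.genotypes[ridx]
        complete = (sub != MISSING).all(axis=0)
        for chrom in np.unique(chroms):
            for w in np.unique(win[chroms == chrom]):
                sel = complete & (chroms == chrom) & (win == w)
                if not sel.any():
                    continue
                g = sub[:, sel]
                p = g.sum(axis=0) / (2.0 * g.shape[0])
                s = int(((p > 0) & (p < 1)).sum())
                d = tajimas_d_window(g)
                rows.append(
                    {"population": pop, "chrom": chrom, "window": int(w), "S": s, "D": d}
                )
    table = pd.DataFrame(rows)
    if table.empty:
        return table, pd.Series(dtype=float, name="tajima_d")
    ok = table[(table.S >= min_s) & np.isfinite(table.D)]
    means = ok.groupby("population")["D"].mean()
    means.name = "tajima_d"
    return table, means


def _wc_pair_components(g1: np.ndarray, g2: np.ndarray):
    """Per-site Weir-Cockerham (1984) variance components a, b, c for two pops."""
    r = 2.0
    comp = []
    for g in (g1, g2):
        nonmiss = g != MISSING
        n = nonmiss.sum(axis=0).astype(float)
        alt = np.where(nonmiss, g, 0).sum(axis=0)
        het = np.where(nonmiss, g == 1, False).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2 * n), np.nan)
            h = np.where(n > 0, het / n, np.nan)
        comp.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comp
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    valid = (
        (n1 >= 2) & (n2 >= 2) & np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
        & (pbar > 0) & (pbar < 1)
    )
    return a, b, c, valid


def wc_fst(gm: GenotypeMatrix, popmap: PopulationMap) -> pd.DataFrame:
    """Pairwise multi-locus Weir-Cockerham FST (ratio of averages)."""
    rows_by_pop = popmap.rows_by_pop(gm.samples)
    pops = list(rows_by_pop)
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, pa in enumerate(pops):
        for pb in pops[i + 1 :]:
            a, b, c, valid = _wc_pair_components(
                gm.genotypes[rows_by_pop[pa]], gm.genotypes[rows_by_pop[pb]]
            )
            denom = (a + b + c)[valid].sum()
            fst = a[valid].sum() / denom if valid.any() and denom != 0 else np.nan
            mat.loc[pa, pb] = mat.loc[pb, pa] = fst
    return mat


def ld_decay(
    gm: GenotypeMatrix,
    pop_samples: list[str],
    maf: float = 0.05,
    max_dist_bp: int = 100_000,
    n_bins: int = 20,
) -> tuple[pd.DataFrame, float]:
    """Genotype-dosage r2 versus distance within one population.

    Site pairs on the same chromosome within ``max_dist_bp`` are binned into
    log-spaced distance bins; ``halfmax_bp`` is the smallest bin distance at
    which mean r2 has fallen to half the maximum bin mean, or +inf when r2
    never decays that far within range (LD longer than measurable).  Missing
    dosages are mean-imputed per site before correlation.
    """
    sub = gm.subset_samples(pop_samples)
    geno = sub.genotypes.astype(float)
    geno[geno == MISSING] = np.nan
    n, p = _pop_allele_stats(sub.genotypes)
    ok = np.isfinite(p) & (np.minimum(p, 1 - p) >= maf) & (n >= 2)
    if ok.sum() < 2:
        return pd.DataFrame(), np.nan
    idx = np.flatnonzero(ok)
    chroms = np.array([s.chrom for s in sub.sites])[idx]
    pos = np.array([s.pos for s in sub.sites])[idx]
    g = geno[:, idx]
    col_mean = np.nanmean(g, axis=0)
    fill = np.where(np.isnan(g), col_mean, g)
    dists, r2s = [], []
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        if sel.sum() < 2:
            continue
        gp = fill[:, sel]
        pp = pos[sel]
        std = gp.std(axis=0)
        use = std > 0
        gp, pp = gp[:, use], pp[use]
        if gp.shape[1] < 2:
            continue
        corr = np.corrcoef(gp.T)
        ii, jj = np.triu_indices(len(pp), k=1)
        d = np.abs(pp[jj] - pp[ii])
        keep = d <= max_dist_bp
        dists.append(d[keep])
        r2s.append(corr[ii, jj][keep] ** 2)
    if not dists:
        return pd.DataFrame(), np.nan
    d = np.concatenate(dists).astype(float)
    r2 = np.concatenate(r2s)
    edges = np.logspace(0, np.log10(max_dist_bp + 1), n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            rows.append(
                {
                    "bin": b,
                    "dist_mid": float(np.sqrt(edges[b] * edges[b + 1])),
                    "mean_r2": float(r2[sel].mean()),
                    "n_pairs": int(sel.sum()),
                }
            )
    curve = pd.DataFrame(rows)
    halfmax = np.nan
    if not curve.empty:
        target = curve.mean_r2.max() / 2.0
        below = curve[curve.mean_r2 <= target]
        halfmax = float(below.dist_mid.iloc[0]) if not below.empty else np.inf
    return curve, halfmax


@dataclass
class PopTree:
    tree: "object"  # skbio TreeNode, rooted
    root_population: str
    root_distance: pd.Series  # per population, sum of branch lengths to root


def fst_tree(fst: pd.DataFrame, root_pop: str | None = None, beta: pd.Series | None = None) -> PopTree:
    """Neighbor-joining tree on the FST distance matrix, rooted at the
    putatively ancestral population (minimal betaST unless ``root_pop`` given).

    Negative estimates (FST or NJ branch lengths) are clamped to 0.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    pops = list(fst.index)
    d = fst.to_numpy(dtype=float).copy()
    np.fill_diagonal(d, 0.0)
    if (d < 0).any():
        d = np.maximum(d, 0.0)
    d = (d + d.T) / 2.0
    tree = nj(DistanceMatrix(d, ids=pops))
    neg = [n for n in tree.traverse() if n.length is not None and n.length < 0]
    if neg:
        warnings.warn(f"clamped {len(neg)} negative NJ branch lengths to 0")
        for n in neg:
            n.length = 0.0
    if root_pop is None:
        if beta is None:
            raise ValueError("need root_pop or betaST values for rooting")
        root_pop = beta.idxmin()
    leaf = tree.find(root_pop)
    rooted = leaf.parent.root_at(reset=True) if leaf.parent is not None else tree
    dist = {}
    for tip in rooted.tips():
        dist[tip.name] = float(tip.accumulate_to_ancestor(rooted))
    return PopTree(rooted, root_pop, pd.Series(dist, name="root_distance"))
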