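"""Distribution of fitness effects from the unfolded SFS, and the rate of
adaptive evolution (alpha, omega_A, omega_NA).

The model is a Poisson random field over unfolded site-frequency classes.
Synonymous sites are neutral: E[syn_i] = theta_s * r_i / i.  Nonsynonymous
expectations integrate the diffusion sojourn density

    H(x; S) = (1 - exp(-S(1-x))) / [x(1-x)(1 - exp(-S))],   S = 4*Ne*s,

against a "GammaExpo" DFE: a reflected gamma of deleterious effects (shape
beta, mean mean_Sd < 0) plus, with probability p_b, an exponential tail of
beneficial effects (mean mean_Sb > 0).  Nuisance distortion multipliers r_i
(shared between syn and nonsyn classes, r_1 = 1) absorb demography, linked
selection and genotyping artifacts; eps_anc mixes class i with n-i to absorb
ancestral-state misorientation.

From a fitted DFE, the expected neutral-to-nearly-neutral substitution rate
omega_NA = integral over S<0 of phi(S) * u(S), with relative fixation
probability u(S) = S/(1-exp(-S)); the adaptive component is
omega_A = dN/dS - omega_NA and alpha = omega_A/(dN/dS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize, special, stats

from .coding_stats import (
    _CODON_TABLE,
    _STOPS,
    classify_codon_sites,
    is_stop,
    is_synonymous_change,
)
from .core_io import CodingAlignment

# ---------------------------------------------------------------------------
# quadrature grids

_S_CUTOFF_LO = 1e-4   # |S| below this is treated as exactly neutral
_S_CUTOFF_HI = 1e5    # deleterious integration upper bound
_SB_CUTOFF_HI = 1e4   # beneficial integration upper bound
_N_S_NODES = 160
_N_X_NODES = 400


@lru_cache(maxsize=None)
def _log_s_grid(hi: float) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights on t = log10|S| in [log10(lo), log10(hi)]."""
    t, w = np.polynomial.legendre.leggauss(_N_S_NODES)
    a, b = math.log10(_S_CUTOFF_LO), math.log10(hi)
    tt = 0.5 * (b - a) * t + 0.5 * (b + a)
    ww = 0.5 * (b - a) * w
    return 10.0**tt, ww * 10.0**tt * math.log(10.0)  # weights include dS/dt


def sojourn_density(x: np.ndarray, S: float) -> np.ndarray:
    """H(x; S), the scaled sojourn-time density of a new semidominant
    mutation with scaled coefficient S, numerically stable for |S| large."""
    x = np.asarray(x, dtype=float)
    if S == 0.0:
        return 1.0 / x
    if abs(S) < 1e-8:  # series limit to avoid cancellation
        return 1.0 / x * (1.0 + S * x / 2.0)
    if S < 0:
        num = np.exp(S) - np.exp(S * x)
        den = x * (1.0 - x) * (np.exp(S) - 1.0)
    else:
        num = 1.0 - np.exp(-S * (1.0 - x))
        den = x * (1.0 - x) * (1.0 - np.exp(-S))
    return num / den


def _h_bounded(x: np.ndarray, S: float) -> np.ndarray:
    """x(1-x) * H(x;S) -- the bounded form used on the logistic grid."""
    if S == 0.0:
        return 1.0 - x
    if S < 0:
        return (np.exp(S) - np.exp(S * x)) / (np.exp(S) - 1.0)
    return (1.0 - np.exp(-S * (1.0 - x))) / (1.0 - np.exp(-S))


@lru_cache(maxsize=None)
def _x_grid() -> tuple[np.ndarray, np.ndarray]:
    """Logistic-transformed x grid: x = sigmoid(y), dx = x(1-x) dy."""
    y, w = np.polynomial.legendre.leggauss(_N_X_NODES)
    a, b = -30.0, 30.0
    yy = 0.5 * (b - a) * y + 0.5 * (b + a)
    ww = 0.5 * (b - a) * w
    return special.expit(yy), ww


@lru_cache(maxsize=None)
def _binom_on_x(n: int) -> np.ndarray:
    """binom(n,i) x^i (1-x)^(n-i) for i = 1..n-1 over the x grid."""
    x, _ = _x_grid()
    i = np.arange(1, n)[:, None]
    return special.comb(n, i) * x[None, :] ** i * (1.0 - x[None, :]) ** (n - i)


@lru_cache(maxsize=None)
def _sojourn_basis(n: int, sign: int, hi: float) -> np.ndarray:
    """b_i(S) = int_0^1 H(x;S) binom(n,i) x^i (1-x)^(n-i) dx for the S grid.

    Rows i = 1..n-1, columns the log-spaced |S| nodes with the given sign.
    """
    s_vals, _ = _log_s_grid(hi)
    x, w = _x_grid()
    pmat = _binom_on_x(n)
    out = np.empty((n - 1, len(s_vals)))
    for k, s_mag in enumerate(s_vals):
        h = _h_bounded(x, sign * s_mag)
        out[:, k] = pmat @ (w * h)
    return out


def _neutral_b(n: int) -> np.ndarray:
    return 1.0 / np.arange(1, n)


def fixation_rate(S) -> np.ndarray:
    """Relative fixation probability u(S) = S / (1 - exp(-S)), u(0) = 1."""
    S = np.atleast_1d(np.asarray(S, dtype=float))
    out = np.ones_like(S)
    neg = S < -1e-12
    pos = S > 1e-12
    # stable negative branch: S/(1-e^{-S}) = S e^{S}/(e^{S}-1), exponents <= 0
    out[neg] = S[neg] * np.exp(S[neg]) / (np.exp(S[neg]) - 1.0)
    out[pos] = S[pos] / (1.0 - np.exp(-S[pos]))
    return out


# ---------------------------------------------------------------------------
# model types


@dataclass
class DFEParams:
    shape: float                 # gamma shape beta of deleterious effects
    mean_sd: float               # mean scaled deleterious effect, < 0
    p_b: float = 0.0             # beneficial fraction
    mean_sb: float = 1.0         # mean scaled beneficial effect, > 0
    theta_syn: float = 1.0       # synonymous mutational input per class-1 site
    theta_nonsyn: float = 1.0
    r: np.ndarray | None = None  # distortion multipliers, r[0] = 1
    eps_anc: float = 0.0         # misorientation probability

    def __post_init__(self):
        if self.shape <= 0:
            raise ValueError("shape must be > 0")
        if self.mean_sd >= 0:
            raise ValueError("mean_Sd must be negative")
        if not 0 <= self.p_b < 1:
            raise ValueError("p_b must be in [0, 1)")
        if self.mean_sb <= 0:
            raise ValueError("mean_Sb must be > 0")
        if not 0 <= self.eps_anc < 0.5:
            raise ValueError("eps_anc must be in [0, 0.5)")
        if self.r is not None:
            self.r = np.asarray(self.r, dtype=float)
            if (self.r <= 0).any():
                raise ValueError("r_i must be > 0")

    def r_for(self, n: int) -> np.ndarray:
        if self.r is None:
            return np.ones(n - 1)
        if len(self.r) != n - 1:
            raise ValueError("r has wrong length")
        return self.r

    def deleterious_weights(self) -> tuple[np.ndarray, np.ndarray, float]:
        """(|S| nodes, quadrature masses, neutral point mass) of the
        deleterious gamma; masses sum to ~1 with the tails."""
        s_vals, w = _log_s_grid(_S_CUTOFF_HI)
        scale = abs(self.mean_sd) / self.shape
        dens = stats.gamma.pdf(s_vals, a=self.shape, scale=scale)
        lo_mass = stats.gamma.cdf(_S_CUTOFF_LO, a=self.shape, scale=scale)
        return s_vals, w * dens, lo_mass

    def beneficial_weights(self) -> tuple[np.ndarray, np.ndarray, float]:
        s_vals, w = _log_s_grid(_SB_CUTOFF_HI)
        dens = stats.expon.pdf(s_vals, scale=self.mean_sb)
        lo_mass = stats.expon.cdf(_S_CUTOFF_LO, scale=self.mean_sb)
        return s_vals, w * dens, lo_mass

    def dfe_mass(self) -> float:
        """Total quadrature mass of phi(S); should be 1 (normalization check)."""
        _, wd, lod = self.deleterious_weights()
        hid = stats.gamma.sf(
            _S_CUTOFF_HI, a=self.shape, scale=abs(self.mean_sd) / self.shape
        )
        del_mass = wd.sum() + lod + hid
        if self.p_b == 0:
            return float(del_mass)
        _, wb, lob = self.beneficial_weights()
        hib = stats.expon.sf(_SB_CUTOFF_HI, scale=self.mean_sb)
        return float((1 - self.p_b) * del_mass + self.p_b * (wb.sum() + lob + hib))


@dataclass
class UnfoldedSFSPair:
    n: int
    syn_sfs: np.ndarray      # counts for derived classes 1..n-1
    nonsyn_sfs: np.ndarray
    L_syn: float
    L_nonsyn: float
    D_syn: float = 0.0
    D_nonsyn: float = 0.0
    filter_log: dict = field(default_factory=dict)

    def __post_init__(self):
        self.syn_sfs = np.asarray(self.syn_sfs, dtype=float)
        self.nonsyn_sfs = np.asarray(self.nonsyn_sfs, dtype=float)
        if self.n < 4:
            raise ValueError("need haploid sample size >= 4")
        if len(self.syn_sfs) != self.n - 1 or len(self.nonsyn_sfs) != self.n - 1:
            raise ValueError("SFS length must be n - 1")
        if (self.syn_sfs < 0).any() or (self.nonsyn_sfs < 0).any():
            raise ValueError("negative SFS counts")

    @property
    def dnds_obs(self) -> float:
        if self.D_syn <= 0 or self.L_syn <= 0 or self.L_nonsyn <= 0:
            return np.nan
        return (self.D_nonsyn / self.L_nonsyn) / (self.D_syn / self.L_syn)


def _mix_misorientation(e: np.ndarray, eps: float) -> np.ndarray:
    return (1.0 - eps) * e + eps * e[::-1]


def expected_sfs(params: DFEParams, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Poisson-random-field expected (syn, nonsyn) class counts for i=1..n-1."""
    r = params.r_for(n)
    inv_i = _neutral_b(n)
    e_syn = params.theta_syn * r * inv_i

    s_neg, w_neg, lo_neg = params.deleterious_weights()
    b_neg = _sojourn_basis(n, -1, _S_CUTOFF_HI)
    del_part = b_neg @ w_neg + lo_neg * inv_i
    mix = (1.0 - params.p_b) * del_part
    if params.p_b > 0:
        s_pos, w_pos, lo_pos = params.beneficial_weights()
        b_pos = _sojourn_basis(n, +1, _SB_CUTOFF_HI)
        mix = mix + params.p_b * (b_pos @ w_pos + lo_pos * inv_i)
    e_nonsyn = params.theta_nonsyn * r * mix

    eps = params.eps_anc
    if eps > 0:
        e_syn = _mix_misorientation(e_syn, eps)
        e_nonsyn = _mix_misorientation(e_nonsyn, eps)
    return e_syn, e_nonsyn


def expected_pin_pis(params: DFEParams) -> float:
    """Expected piN/piS under the fitted DFE (ratio of expected per-site
    heterozygosities; the neutral expectation per theta is the same for every
    class, so the ratio is the mean of 2x(1-x)H integrated over the DFE
    divided by its neutral value)."""
    x, w = _x_grid()
    # E[pi] per theta = int 2x(1-x) H(x;S) dx ; neutral value = 1
    def pi_of(S):
        return float(np.sum(w * 2.0 * x * (1.0 - x) * _h_bounded(x, S)))

    neutral = pi_of(0.0)
    s_neg, w_neg, lo_neg = params.deleterious_weights()
    vals = np.array([pi_of(-s) for s in s_neg])
    acc = (1 - params.p_b) * (np.sum(w_neg * vals) + lo_neg * neutral)
    if params.p_b > 0:
        s_pos, w_pos, lo_pos = params.beneficial_weights()
        valsp = np.array([pi_of(s) for s in s_pos])
        acc += params.p_b * (np.sum(w_pos * valsp) + lo_pos * neutral)
    return float(acc / neutral)


# ---------------------------------------------------------------------------
# maximum-likelihood fit


@dataclass
class DFEFit:
    params: DFEParams
    loglik: float
    model: str
    n_free: int
    converged: bool
    n_starts: int

    @property
    def aic(self) -> float:
        return 2.0 * self.n_free - 2.0 * self.loglik


def _poisson_ll(obs: np.ndarray, mu: np.ndarray) -> float:
    mu = np.maximum(mu, 1e-300)
    return float(np.sum(obs * np.log(mu) - mu))


def _unpack(
    x: np.ndarray, n: int, model: str, fit_r: bool, fit_eps: bool,
    theta_ratio: float | None = None,
) -> DFEParams:
    k = 0
    theta_s = math.exp(x[k]); k += 1
    if theta_ratio is None:
        theta_n = math.exp(x[k]); k += 1
    else:
        theta_n = theta_s * theta_ratio
    shape = math.exp(x[k]); k += 1
    mean_sd = -math.exp(x[k]); k += 1
    if model == "GammaExpo":
        p_b = special.expit(x[k]); k += 1
        mean_sb = math.exp(x[k]); k += 1
    else:
        p_b, mean_sb = 0.0, 1.0
    if fit_r:
        r = np.concatenate([[1.0], np.exp(x[k : k + n - 2])]); k += n - 2
    else:
        r = None
    eps = 0.5 * special.expit(x[k]) if fit_eps else 0.0
    return DFEParams(
        shape=min(shape, 50.0),
        mean_sd=mean_sd,
        p_b=min(p_b, 0.999),
        mean_sb=mean_sb,
        theta_syn=theta_s,
        theta_nonsyn=theta_n,
        r=r,
        eps_anc=min(eps, 0.499),
    )


def fit_gamma_expo(
    sfs: UnfoldedSFSPair,
    model: str = "GammaExpo",
    n_starts: int = 5,
    seed: int = 0,
    fit_distortion: bool = True,
    fit_misorientation: bool = True,
    couple_theta: bool = True,
) -> DFEFit:
    """Maximum-likelihood GammaZero/GammaExpo fit to an unfolded SFS pair.

    Independent Poisson likelihood over the 2(n-1) frequency classes;
    multi-start L-BFGS-B over log/logit-transformed parameters with a
    recorded seed.  With ``couple_theta`` (default) a single mutational
    input is shared between classes, theta_n = theta_s * L_nonsyn/L_syn, so
    the overall deficit of nonsynonymous polymorphism informs the DFE scale;
    otherwise theta_n is free and only the SFS shape is fit (the gamma mean
    is then weakly identified).  r_i (r_1 = 1) are shared between classes so
    that demographic distortion cancels from the DFE.
    """
    if model not in ("GammaZero", "GammaExpo"):
        raise ValueError(f"unknown model {model!r}")
    n = sfs.n
    rng = np.random.default_rng(seed)
    theta_ratio = None
    if couple_theta:
        if sfs.L_syn <= 0 or sfs.L_nonsyn <= 0:
            raise ValueError("couple_theta requires positive L_syn and L_nonsyn")
        theta_ratio = sfs.L_nonsyn / sfs.L_syn
    inv_i_sum = float(np.sum(1.0 / np.arange(1, n)))
    theta_s0 = max(sfs.syn_sfs.sum() / inv_i_sum, 1e-3)
    theta_n0 = max(sfs.nonsyn_sfs.sum() / inv_i_sum, 1e-3)

    base = [math.log(theta_s0)]
    if theta_ratio is None:
        base.append(math.log(theta_n0))
    base += [math.log(0.3), math.log(500.0)]
    if model == "GammaExpo":
        base += [special.logit(0.02), math.log(4.0)]
    if fit_distortion:
        base += [0.0] * (n - 2)
    if fit_misorientation:
        base += [special.logit(0.02 / 0.5)]
    base = np.array(base)

    def objective(x):
        try:
            p = _unpack(x, n, model, fit_distortion, fit_misorientation, theta_ratio)
            e_syn, e_nonsyn = expected_sfs(p, n)
        except (ValueError, OverflowError, FloatingPointError):
            return 1e12
        ll = _poisson_ll(sfs.syn_sfs, e_syn) + _poisson_ll(sfs.nonsyn_sfs, e_nonsyn)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    best = None
    any_converged = False
    for start in range(n_starts):
        x0 = base if start == 0 else base + rng.normal(0, 0.7, size=base.shape)
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                options={"maxiter": 2000, "maxfun": 20000})
        if best is None or res.fun < best.fun:
            best = res
        any_converged = any_converged or res.success
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError(f"DFE fit failed to converge from {n_starts} starts")
    params = _unpack(best.x, n, model, fit_distortion, fit_misorientation, theta_ratio)
    return DFEFit(
        params=params,
        loglik=-float(best.fun),
        model=model,
        n_free=len(base),
        converged=any_converged,
        n_starts=n_starts,
    )


def compare_models(sfs: UnfoldedSFSPair, seed: int = 0, **kw) -> dict[str, DFEFit]:
    """Fit GammaZero and GammaExpo; AIC comparison is reported, not enforced."""
    return {
        m: fit_gamma_expo(sfs, model=m, seed=seed, **kw)
        for m in ("GammaZero", "GammaExpo")
    }


# ---------------------------------------------------------------------------
# alpha / omega


@dataclass
class SelectionSummary:
    omega_na: float
    omega_a: float
    alpha: float
    dnds_obs: float


def omega_na(params: DFEParams) -> float:
    """Expected dN/dS of the non-adaptive (S <= 0) part of the DFE."""
    s_neg, w_neg, lo_neg = params.deleterious_weights()
    u = fixation_rate(-s_neg)
    return float((1.0 - params.p_b) * (np.sum(w_neg * u) + lo_neg * 1.0))


def selection_summary(params: DFEParams, sfs: UnfoldedSFSPair) -> SelectionSummary:
    """alpha = omega_A / (dN/dS) with omega_A = dN/dS - omega_NA."""
    dnds = sfs.dnds_obs
    w_na = omega_na(params)
    if not np.isfinite(dnds) or dnds == 0:
        return SelectionSummary(w_na, np.nan, np.nan, dnds)
    w_a = dnds - w_na
    return SelectionSummary(w_na, w_a, w_a / dnds, dnds)


# ---------------------------------------------------------------------------
# SFS construction from coding alignments


def _hypergeom_project(k: int, m: int, n: int) -> np.ndarray:
    """Expected class mass (classes 1..n-1) of a site with k derived among m
    called haplotypes, down-projected to n haploids without replacement."""
    i = np.arange(1, n)
    return stats.hypergeom.pmf(i, m, k, n)


def build_sfs(
    alignments: list[CodingAlignment],
    ancestral_cds: dict[str, str],
    sample_size: int = 8,
    gapN_site: int = 10,
    gapN_seq: float = 0.5,
    min_nb_codon: int = 6,
    tolerance_zone: int = 20,
    allow_internal_stop: bool = False,
    outgroup_cds: dict[str, str] | None = None,
    divergence_classifier=None,
) -> UnfoldedSFSPair:
    """Filtered unfolded synonymous/nonsynonymous SFS pair for one population.

    ``ancestral_cds`` maps gene_id to the ancestral spliced CDS (N where the
    ancestral state is uncallable); ``outgroup_cds`` (default: the ancestral
    sequence) provides the comparator for divergence counts.  Filters follow
    the usual alignment-QC conventions: a site needs >= ``gapN_site`` ungapped
    haplotypes, sequences with more than ``gapN_seq`` gap/N are dropped, genes
    with fewer than ``min_nb_codon`` complete codons are dropped, and internal
    stop codons outside the terminal ``tolerance_zone`` (in codons) disqualify
    a gene.  Sites are hypergeometrically down-projected to ``sample_size``
    haploids with fractional class masses.

    ``divergence_classifier(consensus_codon, position, outgroup_base) ->
    bool`` may override the default synonymous/nonsynonymous call for
    substitution counting (e.g. to apply a Ts/Tv-aware weighting); the
    default is plain single-step classification in the consensus context.
    """
    if outgroup_cds is None:
        outgroup_cds = ancestral_cds
    if divergence_classifier is None:
        divergence_classifier = is_synonymous_change
    n = sample_size
    syn = np.zeros(n - 1)
    nonsyn = np.zeros(n - 1)
    L_syn = L_nonsyn = 0.0
    D_syn = D_nonsyn = 0.0
    log = {"genes_used": 0, "genes_dropped_codons": 0, "genes_dropped_stop": 0,
           "sites_skipped_coverage": 0, "sites_skipped_ancestral": 0,
           "seqs_dropped_gap": 0}
    max_haps = 0
    for aln in alignments:
        anc = ancestral_cds.get(aln.gene_id)
        if anc is None:
            continue
        seqs = []
        for s in aln.sequences():
            gap_frac = sum(c not in "ACGT" for c in s) / max(len(s), 1)
            if gap_frac > gapN_seq:
                log["seqs_dropped_gap"] += 1
            else:
                seqs.append(s)
        max_haps = max(max_haps, len(seqs))
        if len(seqs) < sample_size:
            continue
        length = aln.length
        n_codons = length // 3
        complete = 0
        internal_stop = False
        for c in range(n_codons):
            codons = [s[3 * c : 3 * c + 3] for s in seqs]
            if all(all(ch in "ACGT" for ch in cd) for cd in codons):
                complete += 1
                if (
                    not allow_internal_stop
                    and tolerance_zone <= c < n_codons - tolerance_zone
                    and any(is_stop(cd) for cd in codons)
                ):
                    internal_stop = True
        if complete < min_nb_codon:
            log["genes_dropped_codons"] += 1
            continue
        if internal_stop:
            log["genes_dropped_stop"] += 1
            continue
        log["genes_used"] += 1
        outg = outgroup_cds.get(aln.gene_id, anc)
        for c in range(n_codons):
            codons = [s[3 * c : 3 * c + 3] for s in seqs]
            called = [cd for cd in codons if all(ch in "ACGT" for ch in cd)]
            if len(called) < gapN_site:
                log["sites_skipped_coverage"] += 1
                continue
            # consensus codon (major base per position among called codons)
            cons = "".join(
                max(sorted({b for b in col}), key=[cd[k] for cd in called].count)
                for k, col in enumerate(zip(*called))
            )
            if cons in _STOPS or cons not in _CODON_TABLE:
                continue
            syn_f, nonsyn_f = classify_codon_sites(cons)
            L_syn += sum(syn_f)
            L_nonsyn += sum(nonsyn_f)
            anc_codon = anc[3 * c : 3 * c + 3]
            out_codon = outg[3 * c : 3 * c + 3]
            for k in range(3):
                col = [cd[k] for cd in called]
                alleles = sorted(set(col))
                anc_b = anc_codon[k] if len(anc_codon) == 3 else "N"
                if len(alleles) == 2:
                    if anc_b not in alleles:
                        log["sites_skipped_ancestral"] += 1
                        continue
                    derived = alleles[0] if alleles[1] == anc_b else alleles[1]
                    kcnt = col.count(derived)
                    mass = _hypergeom_project(kcnt, len(col), n)
                    minor = alleles[0] if alleles[1] == cons[k] else alleles[1]
                    if is_synonymous_change(cons, k, minor):
                        syn += mass
                    else:
                        nonsyn += mass
                elif len(alleles) > 2:
                    continue
                # divergence: fixed focal base vs outgroup base
                if len(alleles) == 1 and out_codon and len(out_codon) == 3:
                    ob = out_codon[k]
                    if ob in "ACGT" and ob != alleles[0]:
                        if divergence_classifier(cons, k, ob):
                            D_syn += 1
                        else:
                            D_nonsyn += 1
    if max_haps and max_haps < sample_size:
        raise ValueError(
            f"population has only {max_haps} usable haplotypes, "
            f"need sample_size={sample_size}"
        )
    return UnfoldedSFSPair(n, syn, nonsyn, L_syn, L_nonsyn, D_syn, D_nonsyn, log)


# ---------------------------------------------------------------------------
# dofe-style text format


def write_sfs(sfs: UnfoldedSFSPair, path, name: str = "pop") -> None:
    """Write a Grapes/dofe-style unfolded SFS file."""
    with open(path, "w") as fh:
        fh.write(f"{name}\n#unfolded\n")
        fields = (
            [name, "all", str(sfs.n), f"{sfs.L_nonsyn:.6g}"]
            + [f"{v:.6g}" for v in sfs.nonsyn_sfs]
            + [f"{sfs.L_syn:.6g}"]
            + [f"{v:.6g}" for v in sfs.syn_sfs]
            + [f"{sfs.L_nonsyn:.6g}", f"{sfs.D_nonsyn:.6g}",
               f"{sfs.L_syn:.6g}", f"{sfs.D_syn:.6g}"]
        )
        fh.write("\t".join(fields) + "\n")


def read_sfs(path) -> UnfoldedSFSPair:
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    data = lines[-1].split("\t")
    n = int(data[2])
    L_n = float(data[3])
    nonsyn = np.array([float(v) for v in data[4 : 4 + n - 1]])
    k = 4 + n - 1
    L_s = float(data[k]); k += 1
    syn = np.array([float(v) for v in data[k : k + n - 1]])
    k += n - 1
    _, D_n, _, D_s = (float(v) for v in data[k : k + 4])
    return UnfoldedSFSPair(n, syn, nonsyn, L_s, L_n, D_s, D_n)
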