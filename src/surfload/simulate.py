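"""Synthetic range-expansion data with allele surfing.

A discrete-generation Wright-Fisher forward simulation of a 1-D serial
founder expansion: deme 1 carries equilibrium standing variation (coalescent
seeded, then a forward selection burn-in), and every T generations the next
deme is founded by K individuals from the current front, with symmetric
neighbor migration thereafter.  Mutations arise in coding sequence;
synonymous changes are neutral, nonsynonymous changes draw a selection
coefficient from a gamma DFE with a small exponential beneficial tail;
dominance follows the inverse h-s relationship (mild mutations near-additive,
severe ones nearly recessive).  Outgroup panels diverge from the same ancestor
under a substitution process thinned by the fixation probability u(S), so
divergence counts carry a realistic dN/dS.

The simulation is desk-scale: deme sizes in the hundreds and kilobase-scale
genes, with the per-bp mutation rate rescaled upward so that 4*N*mu (and all
4*N*s products) sit in a realistic range.  Everything is seed-deterministic.

A "low-recombination" gene class models the long-term consequences of
suppressed recombination (as in regions of residual tetraploidy): reduced
crossover probability and a reduced efficacy-of-selection factor applied to
nonsynonymous coefficients, emulating Hill-Robertson interference that a
desk-scale simulation cannot generate mechanistically.  Low-recombination
genes are also written with low GC/GC3, mirroring the loss of GC-biased gene
conversion.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from numba import njit

from .coding_stats import _CODON_TABLE, _STOPS
from .core_io import (
    GeneModel,
    GenotypeMatrix,
    PopulationMap,
    RegionSet,
    VariantSite,
    revcomp,
    write_fasta,
    write_vcf,
)
from .dfe_alpha import DFEParams, UnfoldedSFSPair, expected_sfs, fixation_rate

_BASES = np.array(list("ACGT"))


@dataclass
class ExpansionConfig:
    """Study conditions for the serial-founder expansion."""

    n_demes: int = 10
    deme_size: int = 500            # N diploids per deme at carrying capacity
    founder_size: int = 10          # K founders of each new deme
    generations_between_founding: int = 50
    growth_rate: float = 1.1        # slow regrowth keeps the wavefront small
    migration_rate: float = 0.01    # per-individual per-generation, neighbors
    generations_after_last_founding: int = 25
    burn_in_generations: int = 150  # forward selection burn-in of deme 1

    # genome: many short genes -> many quasi-independent genealogies,
    # which is what tightens per-deme piN/piS at fixed total length
    n_genes: int = 120
    codons_per_gene: int = 33
    gene_spacing_bp: int = 10_000
    tetraploid_fraction: float = 0.25
    low_recomb_tet_fraction: float = 2 / 3   # share of tetraploid genes in the low class
    low_recomb_crossover: float = 0.02   # adjacent-gene crossover, low class
    high_recomb_crossover: float = 0.5
    low_recomb_efficacy: float = 0.15    # multiplier on |s| in low-recomb genes

    # mutation and selection (per-bp rate rescaled for desk-scale N)
    mutation_rate: float = 5e-6
    dfe_shape: float = 0.3
    dfe_mean_s: float = -0.03
    # dominance follows the standard inverse h-s relationship
    # h(s) = h0 / (1 + k*|s|): mild mutations near-additive, severe ones
    # nearly fully recessive
    dominance_intercept: float = 0.45
    dominance_scale: float = 200.0
    p_beneficial: float = 0.005
    mean_s_beneficial: float = 0.01
    # nonsyn draws beyond this gamma quantile are labelled LoF; at the default
    # rescaling the class threshold corresponds to |4Ns| >~ 25 (severe)
    lof_quantile: float = 0.5
    max_s: float = 0.95             # cap on |s| (rescaled-lethality ceiling)

    # outgroups
    outgroup_divergence: tuple[float, ...] = (0.010, 0.014, 0.018)
    outgroup_n_per_species: int = 5
    outgroup_poly_rate: float = 3e-4

    sample_per_deme: int = 20
    seed: int = 1

    def __post_init__(self):
        if self.founder_size > self.deme_size:
            raise ValueError("founder_size K must be <= deme_size N")
        for r in (self.migration_rate, self.tetraploid_fraction, self.dominance_intercept):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        if self.dfe_shape <= 0 or self.dfe_mean_s >= 0:
            raise ValueError("DFE must have shape > 0 and negative mean")

    @property
    def coding_length(self) -> int:
        return self.n_genes * 3 * self.codons_per_gene

    def scaled_S(self, s: float) -> float:
        return 4.0 * self.deme_size * s


# ---------------------------------------------------------------------------
# genome construction


@dataclass
class SimGenome:
    gene_models: list[GeneModel]
    chrom_seqs: dict[str, str]           # ancestral reference
    coding_anc: np.ndarray               # ancestral coding bases, concat, coding orientation
    gene_of: np.ndarray                  # coding coord -> gene index
    genomic_pos_of: np.ndarray           # coding coord -> genomic 1-based position
    gene_offset: np.ndarray              # gene index -> first coding coord
    compartment: list[str]               # per gene: diploid | tetraploid
    recomb_class: list[str]              # per gene: high | low
    cross_p: np.ndarray                  # switch prob at each gene boundary
    efficacy: np.ndarray                 # per gene |s| multiplier


def _random_codon(rng, gc3: float) -> str:
    while True:
        b12 = "".join(rng.choice(_BASES, size=2))
        third = rng.choice(list("GC")) if rng.random() < gc3 else rng.choice(list("AT"))
        codon = b12 + third
        if codon not in _STOPS:
            return codon


def build_genome(cfg: ExpansionConfig, rng: np.random.Generator) -> SimGenome:
    n_tet = int(round(cfg.n_genes * cfg.tetraploid_fraction))
    n_dip = cfg.n_genes - n_tet
    dip_chroms = [f"chr{c}" for c in (1, 2, 3, 4)]
    layout: list[tuple[str, str]] = []  # (chrom, compartment) per gene
    per = max(1, n_dip // len(dip_chroms))
    for i in range(n_dip):
        layout.append((dip_chroms[min(i // per, len(dip_chroms) - 1)], "diploid"))
    layout += [("chr31", "tetraploid")] * n_tet

    gene_models, compartment, recomb_class, gc3_targets = [], [], [], []
    chroms_genes: dict[str, list[int]] = {}
    tet_seen = 0
    for g, (chrom, comp) in enumerate(layout):
        compartment.append(comp)
        if comp == "tetraploid":
            # leading block of chr31 = low-GC/low-recombination
            low = tet_seen < int(round(n_tet * cfg.low_recomb_tet_fraction))
            tet_seen += 1
        else:
            low = False
        recomb_class.append("low" if low else "high")
        gc3_targets.append(0.32 if low else float(rng.uniform(0.45, 0.65)))
        chroms_genes.setdefault(chrom, []).append(g)

    cds_len = 3 * cfg.codons_per_gene
    chrom_parts: dict[str, list[str]] = {}
    chrom_cursor: dict[str, int] = {}
    coding_anc = np.empty(cfg.coding_length, dtype="U1")
    gene_of = np.empty(cfg.coding_length, dtype=np.int32)
    genomic_pos_of = np.empty(cfg.coding_length, dtype=np.int64)
    gene_offset = np.empty(cfg.n_genes, dtype=np.int64)

    def intergenic(chrom: str, length: int, low_gc: bool) -> str:
        gc = 0.34 if low_gc else 0.46
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        return "".join(rng.choice(_BASES, size=length, p=p))

    for g, (chrom, comp) in enumerate(layout):
        low = recomb_class[g] == "low"
        parts = chrom_parts.setdefault(chrom, [])
        cursor = chrom_cursor.get(chrom, 0)
        slot_in = chroms_genes[chrom].index(g)
        slot_start = slot_in * cfg.gene_spacing_bp  # 0-based
        pad = slot_start + 200 - cursor
        parts.append(intergenic(chrom, pad, low))
        cursor += pad
        cds = "".join(_random_codon(rng, gc3_targets[g]) for _ in range(cfg.codons_per_gene))
        strand = "-" if g % 3 == 2 else "+"
        two_exon = g % 5 == 0
        gstart = cursor + 1  # 1-based
        if two_exon:
            half = (cds_len // 2) // 3 * 3
            intron_len = 120
            seg1 = (gstart, gstart + half - 1, 0)
            seg2 = (gstart + half + intron_len, gstart + cds_len + intron_len - 1, 0)
            genomic_cds = cds if strand == "+" else revcomp(cds)
            parts.append(genomic_cds[:half])
            parts.append(intergenic(chrom, intron_len, low))
            parts.append(genomic_cds[half:])
            segs = [seg1, seg2]
            cursor += cds_len + intron_len
        else:
            segs = [(gstart, gstart + cds_len - 1, 0)]
            parts.append(cds if strand == "+" else revcomp(cds))
            cursor += cds_len
        chrom_cursor[chrom] = cursor
        model = GeneModel(f"gene{g:03d}", chrom, strand, segs)
        gene_models.append(model)
        off = g * cds_len
        gene_offset[g] = off
        coding_anc[off : off + cds_len] = list(cds)
        gene_of[off : off + cds_len] = g
        genomic_pos_of[off : off + cds_len] = model.coding_positions()

    chrom_seqs = {}
    for chrom, parts in chrom_parts.items():
        tail = intergenic(chrom, 500, chrom == "chr31")
        chrom_seqs[chrom] = "".join(parts) + tail

    # fix minus-strand CDS: genome holds revcomp, so re-extract to verify is
    # implicit; crossing-over probabilities between adjacent genes:
    cross_p = np.full(cfg.n_genes, cfg.high_recomb_crossover)
    for g in range(1, cfg.n_genes):
        if layout[g][0] != layout[g - 1][0]:
            cross_p[g] = 0.5
        elif recomb_class[g] == "low" and recomb_class[g - 1] == "low":
            cross_p[g] = cfg.low_recomb_crossover
    cross_p[0] = 0.5

    efficacy = np.array(
        [cfg.low_recomb_efficacy if rc == "low" else 1.0 for rc in recomb_class]
    )
    return SimGenome(
        gene_models,
        chrom_seqs,
        coding_anc,
        gene_of,
        genomic_pos_of,
        gene_offset,
        compartment,
        recomb_class,
        cross_p,
        efficacy,
    )


# ---------------------------------------------------------------------------
# mutation machinery


def _codon_context(coding: np.ndarray, pos: int) -> tuple[str, int]:
    c0 = pos - pos % 3
    return "".join(coding[c0 : c0 + 3]), pos % 3


def _classify_mutation(coding: np.ndarray, pos: int, new_base: str) -> str:
    codon, k = _codon_context(coding, pos)
    if codon in _STOPS or codon not in _CODON_TABLE:
        return "synonymous"  # degenerate context; treat as neutral
    mut = codon[:k] + new_base + codon[k + 1 :]
    if mut in _STOPS:
        return "lof"
    return "synonymous" if _CODON_TABLE[mut] == _CODON_TABLE[codon] else "missense"


@dataclass
class SiteRecord:
    coding_pos: int
    anc_base: str
    derived_base: str
    effect_class: str
    s: float
    h: float


class _DFESampler:
    def __init__(self, cfg: ExpansionConfig, rng: np.random.Generator):
        from scipy import stats as st

        self.cfg = cfg
        self.rng = rng
        self.scale = abs(cfg.dfe_mean_s) / cfg.dfe_shape
        self.lof_cut = st.gamma.ppf(cfg.lof_quantile, a=cfg.dfe_shape, scale=self.scale)

    def draw_nonsyn_s(self, stop_gained: bool) -> tuple[float, str]:
        cfg = self.cfg
        if stop_gained:
            s = -min(max(self.lof_cut * 2.0, 0.3), cfg.max_s)
            return s, "lof"
        if self.rng.random() < cfg.p_beneficial:
            s = min(self.rng.exponential(cfg.mean_s_beneficial), cfg.max_s)
            return s, "missense"
        mag = min(self.rng.gamma(cfg.dfe_shape, self.scale), cfg.max_s)
        cls = "lof" if mag >= self.lof_cut else "missense"
        return -mag, cls


# ---------------------------------------------------------------------------
# forward Wright-Fisher core


@njit(cache=True)
def _fitness_kernel(H, sel, log_het, log_hom, lw):  # pragma: no cover - jit
    n = H.shape[0] // 2
    for i in range(n):
        acc = 0.0
        for k in range(sel.size):
            j = sel[k]
            g = H[2 * i, j] + H[2 * i + 1, j]
            if g == 1:
                acc += log_het[j]
            elif g == 2:
                acc += log_hom[j]
        lw[i] = acc


@njit(cache=True)
def _reproduce_kernel(H, par, path, gene_of_col, out, slot):  # pragma: no cover
    n = par.shape[0]
    M = gene_of_col.shape[0]
    for c in range(n):
        base = 2 * par[c]
        row_out = 2 * c + slot
        for j in range(M):
            out[row_out, j] = H[base + path[c, gene_of_col[j]], j]


class _Population:
    """All demes' haplotypes over a shared, growing set of segregating columns.

    Deme matrices are capacity-buffered: physical shape (2N, capacity) with
    only the first ``n_cols`` columns meaningful, so appending new mutations
    rarely reallocates."""

    def __init__(self, genome: SimGenome, cfg: ExpansionConfig, rng):
        self.genome = genome
        self.cfg = cfg
        self.rng = rng
        self.coding_current = genome.coding_anc.copy()
        self.position_used = np.zeros(cfg.coding_length, dtype=bool)
        self.sites: list[SiteRecord] = []
        self.log_het = np.zeros(0)
        self.log_hom = np.zeros(0)
        self.gene_idx_cols = np.zeros(0, dtype=np.int32)
        self.demes: dict[int, np.ndarray] = {}  # deme index -> (2N, capacity) uint8
        self.capacity = 1024
        self.fixed: list[SiteRecord] = []
        self.dfe = _DFESampler(cfg, rng)
        self._gens_since_prune = 0

    @property
    def n_cols(self) -> int:
        return len(self.sites)

    def haplotypes(self, d: int) -> np.ndarray:
        return self.demes[d][:, : self.n_cols]

    def _grow_capacity(self, needed: int):
        while self.capacity < needed:
            self.capacity *= 2
        for d, H in self.demes.items():
            new = np.zeros((H.shape[0], self.capacity), dtype=np.uint8)
            new[:, : self.n_cols] = H[:, : self.n_cols]
            self.demes[d] = new

    def _append_columns(self, records: list[SiteRecord], carriers: list[tuple[int, int]]):
        if not records:
            return
        k = len(records)
        base = self.n_cols
        if base + k > self.capacity:
            self._grow_capacity(base + k)
        for H in self.demes.values():
            H[:, base : base + k] = 0
        self.sites.extend(records)
        lh = np.array([np.log1p(r.h * r.s) for r in records])
        lo = np.array([np.log1p(r.s) for r in records])
        self.log_het = np.concatenate([self.log_het, lh])
        self.log_hom = np.concatenate([self.log_hom, lo])
        self.gene_idx_cols = np.concatenate(
            [self.gene_idx_cols,
             self.genome.gene_of[[r.coding_pos for r in records]].astype(np.int32)]
        )
        for j, (d, row) in enumerate(carriers):
            self.demes[d][row, base + j] = 1

    def make_site(self, pos: int) -> SiteRecord | None:
        if self.position_used[pos]:
            return None
        anc = self.coding_current[pos]
        choices = [b for b in "ACGT" if b != anc]
        new = choices[int(self.rng.integers(3))]
        cls = _classify_mutation(self.coding_current, pos, new)
        if cls == "synonymous":
            s, h = 0.0, 0.5
        else:
            s, cls = self.dfe.draw_nonsyn_s(stop_gained=(cls == "lof"))
            codon, k = _codon_context(self.coding_current, pos)
            mut = codon[:k] + new + codon[k + 1 :]
            if mut in _STOPS:
                cls = "lof"
            if s >= 0:
                h = 0.5
            else:
                # h reflects the mutation's intrinsic molecular severity
                # (pre-interference), so it is set before the efficacy factor
                h = self.cfg.dominance_intercept / (
                    1.0 + self.cfg.dominance_scale * abs(s)
                )
            s *= self.genome.efficacy[self.genome.gene_of[pos]]
        self.position_used[pos] = True
        return SiteRecord(pos, anc, new, cls, s, h)

    def mutate(self, gen_records, gen_carriers):
        mu, L = self.cfg.mutation_rate, self.cfg.coding_length
        for d, H in self.demes.items():
            n_new = self.rng.poisson(H.shape[0] * L * mu)
            if not n_new:
                continue
            for pos in self.rng.integers(L, size=n_new):
                rec = self.make_site(int(pos))
                if rec is None:
                    continue
                gen_records.append(rec)
                gen_carriers.append((d, int(self.rng.integers(H.shape[0]))))

    def step_deme(self, d: int, n_children: int, sel: np.ndarray):
        M = self.n_cols
        H = self.demes[d]
        rng = self.rng
        n_par = H.shape[0] // 2
        if sel.size:
            lw = np.empty(n_par)
            _fitness_kernel(H, sel, self.log_het, self.log_hom, lw)
            lw -= lw.max()
            w = np.exp(lw)
            tot = w.sum()
            if tot <= 0 or not np.isfinite(tot):
                raise RuntimeError(f"deme {d} fitness collapse (extinction)")
            p = w / tot
        else:
            p = None
        mothers = rng.choice(n_par, size=n_children, p=p)
        fathers = rng.choice(n_par, size=n_children, p=p)
        H_new = np.empty((2 * n_children, self.capacity), dtype=np.uint8)
        for slot, par in ((0, mothers), (1, fathers)):
            # which parental haplotype each gene is copied from, per gamete
            path = self._gamete_paths(n_children)
            _reproduce_kernel(
                H, par.astype(np.int64), path, self.gene_idx_cols, H_new, slot
            )
        self.demes[d] = H_new

    def step_all(self):
        """One generation: mutate, migrate, then reproduce every deme."""
        recs: list[SiteRecord] = []
        carr: list[tuple[int, int]] = []
        self.mutate(recs, carr)
        self._append_columns(recs, carr)
        self.migrate()
        sel = np.flatnonzero(self.log_hom != 0.0)
        for d in sorted(self.demes):
            cur = self.demes[d].shape[0] // 2
            n_children = min(
                self.cfg.deme_size,
                max(int(np.ceil(cur * self.cfg.growth_rate)), self.cfg.founder_size),
            )
            self.step_deme(d, n_children, sel)

    def _gamete_paths(self, n: int) -> np.ndarray:
        """Which parental haplotype each gene is copied from, per gamete."""
        g = self.cfg.n_genes
        u = self.rng.random((n, g))
        switch = u < self.genome.cross_p[None, :]
        return (np.cumsum(switch, axis=1, dtype=np.int32) & 1).astype(np.uint8)

    def migrate(self):
        m = self.cfg.migration_rate
        live = sorted(self.demes)
        for a, b in zip(live, live[1:]):
            if b != a + 1:
                continue
            na = self.demes[a].shape[0] // 2
            nb = self.demes[b].shape[0] // 2
            k = self.rng.binomial(min(na, nb), m)
            if k == 0:
                continue
            ia = self.rng.choice(na, size=k, replace=False)
            ib = self.rng.choice(nb, size=k, replace=False)
            ra = np.concatenate([2 * ia, 2 * ia + 1])
            rb = np.concatenate([2 * ib, 2 * ib + 1])
            tmp = self.demes[a][ra].copy()
            self.demes[a][ra] = self.demes[b][rb]
            self.demes[b][rb] = tmp

    def prune(self, force: bool = False, every: int = 6):
        """Drop lost columns, promote globally fixed ones to substitutions.

        Cheap bookkeeping is deferred: a full scan/rebuild runs every
        ``every`` generations (or when forced before sampling/founding)."""
        self._gens_since_prune += 1
        if not force and self._gens_since_prune < every:
            return
        self._gens_since_prune = 0
        M = self.n_cols
        if M == 0:
            return
        total = np.zeros(M, dtype=np.int64)
        haps = 0
        for H in self.demes.values():
            total += H[:, :M].sum(axis=0, dtype=np.int64)
            haps += H.shape[0]
        lost = total == 0
        fixed = total == haps
        if not (lost.any() or fixed.any()):
            return
        for j in np.flatnonzero(fixed):
            rec = self.sites[j]
            self.fixed.append(rec)
            self.coding_current[rec.coding_pos] = rec.derived_base
        for j in np.flatnonzero(lost):
            self.position_used[self.sites[j].coding_pos] = False
        idx = np.flatnonzero(~(lost | fixed))
        # keep columns grouped by gene: the reproduction kernel then reads
        # long same-parent-row runs, which is substantially cache-friendlier
        idx = idx[np.argsort(self.gene_idx_cols[idx], kind="stable")]
        self.sites = [self.sites[j] for j in idx]
        self.log_het = self.log_het[idx]
        self.log_hom = self.log_hom[idx]
        self.gene_idx_cols = self.gene_idx_cols[idx]
        for d, H in self.demes.items():
            new = np.zeros((H.shape[0], self.capacity), dtype=np.uint8)
            new[:, : len(idx)] = H[:, idx]
            self.demes[d] = new


def _coalescent_seed(cfg: ExpansionConfig, genome: SimGenome, pop: _Population, seed: int):
    """Neutral equilibrium standing variation for deme 1 from a coalescent
    sample; selection coefficients are then assigned and purged during the
    forward burn-in."""
    import msprime

    ts = msprime.sim_ancestry(
        samples=cfg.deme_size,
        population_size=cfg.deme_size,
        sequence_length=cfg.coding_length,
        # modest coalescent map; the forward phase applies the full gene-level
        # crossover model, so burn-in linkage only needs rough decorrelation
        recombination_rate=2e-5,
        random_seed=max(seed % (2**31 - 1), 1),
    )
    mts = msprime.sim_mutations(
        ts,
        rate=cfg.mutation_rate,
        random_seed=max((seed + 1) % (2**31 - 1), 1),
        model=msprime.BinaryMutationModel(),
        discrete_genome=True,
    )
    pop.demes[1] = np.zeros((2 * cfg.deme_size, pop.capacity), dtype=np.uint8)
    records, carriers_cols = [], []
    for var in mts.variants():
        p = int(var.site.position)
        rec = pop.make_site(p)
        if rec is None:
            continue
        geno = (np.asarray(var.genotypes) > 0).astype(np.uint8)
        records.append(rec)
        carriers_cols.append(geno)
    if records:
        M = len(records)
        while pop.capacity < 2 * M:
            pop.capacity *= 2
        H = np.zeros((2 * cfg.deme_size, pop.capacity), dtype=np.uint8)
        for j, g in enumerate(carriers_cols):
            H[:, j] = g
        pop.demes[1] = H
        pop.sites = records
        pop.log_het = np.array([np.log1p(r.h * r.s) for r in records])
        pop.log_hom = np.array([np.log1p(r.s) for r in records])
        pop.gene_idx_cols = genome.gene_of[
            [r.coding_pos for r in records]
        ].astype(np.int32)


# ---------------------------------------------------------------------------
# outgroups


def substitution_rate_ratio(cfg: ExpansionConfig) -> float:
    """Expected nonsyn/neutral substitution rate ratio under the configured
    DFE (thins the outgroup substitution process)."""
    params = DFEParams(
        shape=cfg.dfe_shape,
        mean_sd=cfg.scaled_S(cfg.dfe_mean_s),
        p_b=cfg.p_beneficial,
        mean_sb=cfg.scaled_S(cfg.mean_s_beneficial),
    )
    s_neg, w_neg, lo = params.deleterious_weights()
    omega = (1 - params.p_b) * (np.sum(w_neg * fixation_rate(-s_neg)) + lo)
    s_pos, w_pos, lob = params.beneficial_weights()
    omega += params.p_b * (np.sum(w_pos * fixation_rate(s_pos)) + lob)
    return float(omega)


def _evolve_outgroup(
    coding: np.ndarray, n_sub: int, omega: float, rng
) -> np.ndarray:
    seq = coding.copy()
    L = len(seq)
    placed = 0
    attempts = 0
    while placed < n_sub and attempts < 50 * n_sub + 100:
        attempts += 1
        p = int(rng.integers(L))
        anc = seq[p]
        new = [b for b in "ACGT" if b != anc][int(rng.integers(3))]
        cls = _classify_mutation(seq, p, new)
        if cls == "synonymous" or rng.random() < omega:
            if cls == "lof" and rng.random() > 0.05:
                continue  # stop-gains almost never fix
            seq[p] = new
            placed += 1
    return seq


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class SimulatedDataset:
    config: ExpansionConfig
    genome: SimGenome
    gm: GenotypeMatrix                   # sampled focal individuals, derived dosage
    sites: list[VariantSite]
    truth_sites: pd.DataFrame
    popmap: PopulationMap
    outgroup_gm: GenotypeMatrix
    outgroup_consensus: dict[str, str]   # genomic outgroup-consensus FASTA
    outgroup_nearest: dict[str, str]     # nearest outgroup species, genomic
    ancestral_coding: np.ndarray
    deme_table: pd.DataFrame

    @property
    def gene_models(self) -> list[GeneModel]:
        return self.genome.gene_models

    @property
    def reference(self) -> dict[str, str]:
        return self.genome.chrom_seqs


def simulate_expansion(config: ExpansionConfig | None = None) -> SimulatedDataset:
    cfg = config or ExpansionConfig()
    ss = np.random.SeedSequence(cfg.seed)
    child = ss.spawn(4)
    rng_genome = np.random.default_rng(child[0])
    rng_fwd = np.random.default_rng(child[1])
    rng_out = np.random.default_rng(child[2])
    rng_sample = np.random.default_rng(child[3])

    genome = build_genome(cfg, rng_genome)
    pop = _Population(genome, cfg, rng_fwd)
    _coalescent_seed(cfg, genome, pop, cfg.seed)

    T = cfg.generations_between_founding
    total_fwd = (cfg.n_demes - 1) * T + cfg.generations_after_last_founding
    for gen in range(cfg.burn_in_generations):
        pop.step_all()
        pop.prune()
    for gen in range(total_fwd):
        if gen % T == 0 and gen // T + 2 <= cfg.n_demes:
            new_d = gen // T + 2
            front = max(pop.demes)
            nf = pop.demes[front].shape[0] // 2
            founders = rng_fwd.choice(nf, size=min(cfg.founder_size, nf), replace=False)
            rows = np.concatenate([[2 * i, 2 * i + 1] for i in founders])
            pop.demes[new_d] = pop.demes[front][rows].copy()
        pop.step_all()
        pop.prune()
    pop.prune(force=True)

    # --- sample individuals
    samples, sample_rows, s2p = [], [], {}
    for d in sorted(pop.demes):
        n_d = pop.demes[d].shape[0] // 2
        chosen = rng_sample.choice(n_d, size=min(cfg.sample_per_deme, n_d), replace=False)
        for i in chosen:
            sid = f"pop{d:02d}_ind{i:03d}"
            samples.append(sid)
            sample_rows.append((d, i))
            s2p[sid] = f"pop{d:02d}"

    M = pop.n_cols
    dosage = np.zeros((len(samples), M + len(pop.fixed)), dtype=np.int8)
    for r, (d, i) in enumerate(sample_rows):
        H = pop.haplotypes(d)
        dosage[r, :M] = H[2 * i] + H[2 * i + 1]
    dosage[:, M:] = 2  # globally fixed derived sites

    all_records = pop.sites + pop.fixed
    seg = dosage.sum(axis=0) > 0
    keep = np.flatnonzero(seg)
    dosage = dosage[:, keep]
    all_records = [all_records[j] for j in keep]

    sites, truth_rows = [], []
    keys = [
        (
            genome.gene_models[int(genome.gene_of[r.coding_pos])].chrom,
            int(genome.genomic_pos_of[r.coding_pos]),
        )
        for r in all_records
    ]
    order = np.array(sorted(range(len(keys)), key=keys.__getitem__), dtype=int)
    dosage = dosage[:, order] if len(order) else dosage
    all_records = [all_records[j] for j in order]
    for rec in all_records:
        g = int(genome.gene_of[rec.coding_pos])
        model = genome.gene_models[g]
        gpos = int(genome.genomic_pos_of[rec.coding_pos])
        anc_g = rec.anc_base if model.strand == "+" else revcomp(rec.anc_base)
        der_g = rec.derived_base if model.strand == "+" else revcomp(rec.derived_base)
        sites.append(
            VariantSite(model.chrom, gpos, anc_g, der_g, rec.effect_class, model.gene_id)
        )
        truth_rows.append(
            {
                "chrom": model.chrom,
                "pos": gpos,
                "ancestral": anc_g,
                "derived": der_g,
                "effect_class": rec.effect_class,
                "s": rec.s,
                "h": rec.h,
                "gene_id": model.gene_id,
                "coding_pos": rec.coding_pos,
            }
        )
    gm = GenotypeMatrix(samples, sites, dosage)

    # --- outgroups (selection-thinned substitution process from the ancestor)
    omega = substitution_rate_ratio(cfg)
    L = cfg.coding_length
    species_seqs = []
    for div in cfg.outgroup_divergence:
        n_sub = rng_out.poisson(L * div)
        species_seqs.append(_evolve_outgroup(genome.coding_anc, n_sub, omega, rng_out))
    out_samples, out_seqs = [], []
    for k, sp_seq in enumerate(species_seqs):
        for i in range(cfg.outgroup_n_per_species):
            n_sub = rng_out.poisson(L * cfg.outgroup_poly_rate)
            out_samples.append(f"outg{k + 1}_ind{i}")
            out_seqs.append(_evolve_outgroup(sp_seq, n_sub, omega, rng_out))

    out_geno = np.zeros((len(out_samples), len(all_records)), dtype=np.int8)
    for j, rec in enumerate(all_records):
        for r, seq in enumerate(out_seqs):
            b = seq[rec.coding_pos]
            if b == rec.anc_base:
                out_geno[r, j] = 0
            elif b == rec.derived_base:
                out_geno[r, j] = 2
            else:
                out_geno[r, j] = -1
    outgroup_gm = GenotypeMatrix(out_samples, list(sites), out_geno)

    # genome-wide outgroup consensus (majority of the three species, N on ties)
    cons_coding = genome.coding_anc.copy()
    stack = np.stack(species_seqs)
    for p in range(L):
        col = stack[:, p]
        vals, counts = np.unique(col, return_counts=True)
        if counts.max() >= 2:
            cons_coding[p] = vals[counts.argmax()]
        else:
            cons_coding[p] = "N"

    def coding_to_genomic(coding: np.ndarray) -> dict[str, str]:
        mutable = {c: list(s) for c, s in genome.chrom_seqs.items()}
        for p in np.flatnonzero(coding != genome.coding_anc):
            g = int(genome.gene_of[p])
            model = genome.gene_models[g]
            gpos = int(genome.genomic_pos_of[p])
            b = coding[p]
            mutable[model.chrom][gpos - 1] = (
                b if model.strand == "+" or b == "N" else revcomp(b)
            )
        return {c: "".join(s) for c, s in mutable.items()}

    outgroup_consensus = coding_to_genomic(cons_coding)
    outgroup_nearest = coding_to_genomic(species_seqs[0])

    dist_step = 150.0
    cov = pd.DataFrame(
        {
            "distance_south": [(d - 1) * dist_step for d in sorted(pop.demes)],
            "distance_ocean": [20.0 + 10.0 * d for d in sorted(pop.demes)],
            "ne_proxy": [float(cfg.deme_size)] * len(pop.demes),
        },
        index=[f"pop{d:02d}" for d in sorted(pop.demes)],
    )
    cov.index.name = "population"
    popmap = PopulationMap(s2p, cov)
    deme_table = pd.DataFrame(
        {
            "deme": sorted(pop.demes),
            "population": [f"pop{d:02d}" for d in sorted(pop.demes)],
            "founded_gen": [0 if d == 1 else (d - 2) * T + cfg.burn_in_generations
                            for d in sorted(pop.demes)],
            "distance_south": cov["distance_south"].to_numpy(),
        }
    )
    return SimulatedDataset(
        cfg,
        genome,
        gm,
        sites,
        pd.DataFrame(truth_rows),
        popmap,
        outgroup_gm,
        outgroup_consensus,
        outgroup_nearest,
        genome.coding_anc,
        deme_table,
    )


# ---------------------------------------------------------------------------
# PRF SFS sampler (direct, for DFE unit tests)


def sample_prf_sfs(
    params: DFEParams,
    n: int,
    seed: int = 0,
    L_syn: float = 1e6,
    L_nonsyn: float = 2.5e6,
    D_syn: float = 0.0,
    D_nonsyn: float = 0.0,
) -> UnfoldedSFSPair:
    """Poisson draws around the PRF expected SFS (model-inverting sampler)."""
    rng = np.random.default_rng(seed)
    e_syn, e_nonsyn = expected_sfs(params, n)
    return UnfoldedSFSPair(
        n,
        rng.poisson(e_syn).astype(float),
        rng.poisson(e_nonsyn).astype(float),
        L_syn,
        L_nonsyn,
        D_syn,
        D_nonsyn,
    )


# ---------------------------------------------------------------------------
# emission


def _write_gff(models: list[GeneModel], path):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(
                f"{m.chrom}\tsim\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )
            tid = f"{m.gene_id}.t1"
            fh.write(
                f"{m.chrom}\tsim\tmRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t.\tID={tid};Parent={m.gene_id}\n"
            )
            segs = m.cds_segments if m.strand == "+" else list(reversed(m.cds_segments))
            acc = 0
            for s, e, _ in segs:
                phase = (3 - acc % 3) % 3
                fh.write(
                    f"{m.chrom}\tsim\tCDS\t{s}\t{e}\t.\t{m.strand}\t{phase}\tID={tid}.cds;Parent={tid}\n"
                )
                acc += e - s + 1


def _write_te_bed(ds: SimulatedDataset, path, rng):
    cats = ["LINE", "SINE", "LTR", "DNA"]
    with open(path, "w") as fh:
        for chrom, seq in ds.reference.items():
            tet = chrom == "chr31"
            n_te = max(8, len(seq) // 4_000)
            mean_len = 900 if tet else 300
            for _ in range(n_te):
                length = int(rng.exponential(mean_len)) + 50
                start = int(rng.integers(0, max(1, len(seq) - length)))
                cat = cats[int(rng.integers(len(cats)))]
                fh.write(f"{chrom}\t{start}\t{start + length}\t{cat}\n")


def emit_dataset(ds: SimulatedDataset, out_dir) -> dict[str, str]:
    """Write all standard-format files; returns a manifest of sha256 checksums."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ancestral = {s.key(): s.ref_allele for s in ds.sites}  # reference is ancestral
    write_vcf(ds.gm, out / "focal.vcf", ancestral=ancestral)
    write_vcf(ds.outgroup_gm, out / "outgroups.vcf")
    write_fasta(ds.reference, out / "reference.fa")
    write_fasta(ds.outgroup_consensus, out / "outgroup_consensus.fa")
    write_fasta(ds.outgroup_nearest, out / "outgroup_nearest.fa")
    _write_gff(ds.gene_models, out / "genes.gff3")
    with open(out / "effects.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\tclass\n")
        for s in ds.sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref_allele}\t{s.alt_allele}\t{s.effect_class}\n")
    pm = ds.popmap
    with open(out / "popmap.tsv", "w") as fh:
        fh.write("sample\tpopulation\tdistance_south\tdistance_ocean\tne_proxy\n")
        for smp, p in pm.sample_to_pop.items():
            c = pm.covariates.loc[p]
            fh.write(
                f"{smp}\t{p}\t{c.distance_south}\t{c.distance_ocean}\t{c.ne_proxy}\n"
            )
    with open(out / "tetraploid.bed", "w") as fh:
        for chrom, seq in ds.reference.items():
            if chrom == "chr31":
                fh.write(f"{chrom}\t0\t{len(seq)}\n")
    _write_te_bed(ds, out / "te.bed", np.random.default_rng(ds.config.seed + 17))
    ds.truth_sites.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    ds.deme_table.to_csv(out / "truth_demes.tsv", sep="\t", index=False)
    manifest = {}
    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
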