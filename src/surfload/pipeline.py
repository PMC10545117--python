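"""End-to-end orchestration: from a variant bundle (simulated or loaded from
files) to the per-population metric table that the spatial regressions
consume.

The stages mirror the analysis of an expansion-load study: polarize against
outgroups, count deleterious load per individual, compute piN/piS from
reconstructed coding alignments, build filtered unfolded SFS pairs, fit the
DFE and derive alpha/omega per population.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import coding_stats, core_io, dfe_alpha, load_counts, polarize, popgen_stats
from .core_io import CodingAlignment, GeneModel, GenotypeMatrix, PopulationMap


@dataclass
class VariantBundle:
    """Everything the analysis needs, independent of where it came from."""

    gm: GenotypeMatrix
    gene_models: list[GeneModel]
    reference: dict[str, str]
    outgroup_gm: GenotypeMatrix
    outgroup_consensus: dict[str, str]   # ancestral-state source
    outgroup_nearest: dict[str, str]     # divergence comparator
    popmap: PopulationMap


def load_dataset(directory) -> VariantBundle:
    """Read an emitted dataset directory back through the standard readers."""
    d = Path(directory)
    gm, _ = core_io.read_variants(d / "focal.vcf", d / "effects.tsv")
    out_gm, _ = core_io.read_variants(d / "outgroups.vcf")
    genes = core_io.load_gene_models(d / "genes.gff3")
    ref = core_io._load_reference(d / "reference.fa")
    cons = core_io._load_reference(d / "outgroup_consensus.fa")
    near = core_io._load_reference(d / "outgroup_nearest.fa")
    popmap = core_io.read_popmap(d / "popmap.tsv")
    return VariantBundle(gm, genes, ref, out_gm, cons, near, popmap)


def bundle_from_simulation(ds) -> VariantBundle:
    return VariantBundle(
        ds.gm, ds.gene_models, ds.reference, ds.outgroup_gm,
        ds.outgroup_consensus, ds.outgroup_nearest, ds.popmap,
    )


def subset_alignment(aln: CodingAlignment, sample_ids: list[str]) -> CodingAlignment:
    pos = {s: i for i, s in enumerate(aln.samples)}
    return CodingAlignment(
        aln.gene_id, list(sample_ids), [aln.haplotypes[pos[s]] for s in sample_ids]
    )


def _extract_cds(seq_by_chrom: dict[str, str], gene: GeneModel) -> str:
    chrom = seq_by_chrom[gene.chrom]
    out = []
    for p in gene.coding_positions():
        b = chrom[p - 1].upper()
        out.append(b if gene.strand == "+" or b == "N" else core_io.revcomp(b))
    return "".join(out)


def ancestral_cds_tables(
    bundle: VariantBundle,
    assignments: list[polarize.AncestralAssignment],
) -> tuple[dict[str, str], dict[str, str]]:
    """Per-gene ancestral CDS (focal-site ancestral states layered onto the
    outgroup consensus) and outgroup-consensus CDS (divergence comparator)."""
    by_pos = {(a.site.chrom, a.site.pos): a for a in assignments}
    anc_cds, outg_cds = {}, {}
    for gene in bundle.gene_models:
        if not gene.in_frame:
            continue
        cons = _extract_cds(bundle.outgroup_consensus, gene)
        outg_cds[gene.gene_id] = _extract_cds(bundle.outgroup_nearest, gene)
        anc = list(cons)
        for i, p in enumerate(gene.coding_positions()):
            a = by_pos.get((gene.chrom, int(p)))
            if a is None:
                continue
            base = a.ancestral_base
            if base is None:
                anc[i] = "N"
            else:
                anc[i] = base if gene.strand == "+" else core_io.revcomp(base)
        anc_cds[gene.gene_id] = "".join(anc)
    return anc_cds, outg_cds


@dataclass
class AnalysisResult:
    metrics: pd.DataFrame              # one row per population
    assignments: list
    gene_counts_by_pop: dict[str, dict[str, coding_stats.SiteCounts]]
    sfs_by_pop: dict[str, dfe_alpha.UnfoldedSFSPair]
    fits_by_pop: dict[str, dfe_alpha.DFEFit]
    loads_by_class: dict[str, pd.DataFrame] = None  # per-individual load tables


def analyze(
    bundle: VariantBundle,
    seed: int = 0,
    sample_size: int = 8,
    dfe_model: str = "GammaZero",
    dfe_starts: int = 3,
    dfe_distortion: bool = False,
    fit_dfe: bool = True,
    extra_stats: bool = False,
    gapN_site: int = 10,
) -> AnalysisResult:
    """Run the full per-population analysis on one variant bundle."""
    rng = np.random.default_rng(seed)
    gm, popmap = bundle.gm, bundle.popmap
    pops = [p for p in popmap.populations if p in popmap.rows_by_pop(gm.samples)]

    assignments = polarize.infer_ancestral_table(gm, bundle.outgroup_gm)
    polarized, _ = polarize.polarize_genotypes(gm, assignments)

    metrics: dict[str, pd.Series] = {}
    metrics["ho"] = popgen_stats.observed_heterozygosity(gm, popmap)
    loads_by_class: dict[str, pd.DataFrame] = {}
    for cls in ("missense", "lof", "synonymous"):
        loads = load_counts.individual_load(polarized, cls)
        loads_by_class[cls] = load_counts.load_table(loads, popmap)
        summ = load_counts.population_load_summary(loads, popmap).set_index("population")
        metrics[f"additive_{cls}"] = summ["additive_mean"]
        metrics[f"recessive_{cls}"] = summ["recessive_mean"]

    if extra_stats:
        metrics["beta_st"] = popgen_stats.beta_st(gm, popmap)
        _, d_mean = popgen_stats.tajimas_d(gm, popmap)
        metrics["tajima_d"] = d_mean

    in_frame = [g for g in bundle.gene_models if g.in_frame]
    alignments = {
        g.gene_id: core_io.reconstruct_cds_alignment(g, gm, bundle.reference, rng)
        for g in in_frame
    }
    gene_counts_by_pop: dict[str, dict[str, coding_stats.SiteCounts]] = {}
    pin_pis, pi_s = {}, {}
    pop_alignments: dict[str, list[CodingAlignment]] = {}
    for pop in pops:
        samp = [s for s in popmap.samples_of(pop) if s in gm.samples]
        alns = [subset_alignment(alignments[g.gene_id], samp) for g in in_frame]
        pop_alignments[pop] = alns
        counts = {a.gene_id: coding_stats.gene_site_counts(a) for a in alns}
        gene_counts_by_pop[pop] = counts
        agg = coding_stats.pi_n_pi_s(alns, per_gene=counts)
        pin_pis[pop] = agg.ratio
        pi_s[pop] = agg.pi_s
    metrics["pin_pis"] = pd.Series(pin_pis)
    metrics["pi_s"] = pd.Series(pi_s)

    sfs_by_pop: dict[str, dfe_alpha.UnfoldedSFSPair] = {}
    fits_by_pop: dict[str, dfe_alpha.DFEFit] = {}
    if fit_dfe:
        anc_cds, outg_cds = ancestral_cds_tables(bundle, assignments)
        alpha, w_na, w_a = {}, {}, {}
        for pop in pops:
            try:
                sfs = dfe_alpha.build_sfs(
                    pop_alignments[pop], anc_cds,
                    sample_size=sample_size, gapN_site=gapN_site,
                    outgroup_cds=outg_cds,
                )
                fit = dfe_alpha.fit_gamma_expo(
                    sfs, model=dfe_model, n_starts=dfe_starts,
                    seed=int(rng.integers(2**31 - 1)),
                    fit_distortion=dfe_distortion,
                    fit_misorientation=False,
                )
            except (ValueError, RuntimeError):
                continue
            sfs_by_pop[pop] = sfs
            fits_by_pop[pop] = fit
            summ = dfe_alpha.selection_summary(fit.params, sfs)
            alpha[pop] = summ.alpha
            w_na[pop] = summ.omega_na
            w_a[pop] = summ.omega_a
        metrics["alpha"] = pd.Series(alpha)
        metrics["omega_na"] = pd.Series(w_na)
        metrics["omega_a"] = pd.Series(w_a)

    table = popmap.covariates.copy()
    for name, series in metrics.items():
        table[name] = series.reindex(table.index)
    return AnalysisResult(
        table, assignments, gene_counts_by_pop, sfs_by_pop, fits_by_pop, loads_by_class
    )
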