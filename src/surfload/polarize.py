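"""Ancestral-allele assignment from outgroup panels and derived-allele frequencies.

The ancestral state of a focal SNP is the modal homozygous outgroup allele,
accepted only when (1) at least ``threshold`` (default 90%) of the non-missing
outgroup individuals are homozygous for that allele and (2) it matches one of
the two focal alleles.  Otherwise the site is left unpolarized and excluded
from load analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import MISSING, GenotypeMatrix, PopulationMap, VariantSite


@dataclass(frozen=True)
class AncestralAssignment:
    site: VariantSite
    ancestral: str  # "ref", "alt" or "missing"
    support: float  # fraction of non-missing outgroup individuals hom for the call
    reason: str = "ok"  # ok | below_threshold | allele_mismatch | no_outgroup_data

    def __post_init__(self):
        if self.ancestral not in ("ref", "alt", "missing"):
            raise ValueError(f"bad ancestral {self.ancestral!r}")
        if not 0.0 <= self.support <= 1.0:
            raise ValueError("support out of [0, 1]")

    @property
    def ancestral_base(self) -> str | None:
        if self.ancestral == "ref":
            return self.site.ref_allele
        if self.ancestral == "alt":
            return self.site.alt_allele
        return None


def infer_ancestral(
    site: VariantSite,
    outgroup_genotypes: np.ndarray,
    threshold: float = 0.90,
) -> AncestralAssignment:
    """Infer the ancestral allele of one focal site from outgroup alt dosages.

    ``outgroup_genotypes`` holds alt-allele dosage (0/1/2, -1 missing) of the
    outgroup individuals at the focal site's coordinate, expressed against the
    focal ref/alt pair; outgroup alleles matching neither focal allele must be
    encoded missing by the caller.
    """
    g = np.asarray(outgroup_genotypes)
    g = g[g != MISSING]
    if g.size == 0:
        return AncestralAssignment(site, "missing", 0.0, "no_outgroup_data")
    n_hom_ref = int((g == 0).sum())
    n_hom_alt = int((g == 2).sum())
    if n_hom_alt > n_hom_ref:
        call, n_hom = "alt", n_hom_alt
    else:
        call, n_hom = "ref", n_hom_ref
    support = n_hom / g.size
    if support >= threshold:
        return AncestralAssignment(site, call, support, "ok")
    return AncestralAssignment(site, "missing", support, "below_threshold")


def infer_ancestral_table(
    gm: GenotypeMatrix,
    outgroup_gm: GenotypeMatrix,
    threshold: float = 0.90,
    species_of: dict[str, str] | None = None,
) -> list[AncestralAssignment]:
    """Vectorized :func:`infer_ancestral` over all focal sites.

    Outgroup sites are matched on (chrom, pos); an outgroup record whose
    alleles disagree with the focal ref/alt pair yields an allele-mismatch
    missing call, as does an absent record.

    With ``species_of`` (outgroup sample -> species), the threshold rule is
    applied per species first (each species contributes one consensus call)
    and then across species consensuses, instead of pooling all individuals.
    """
    if species_of is not None:
        return _infer_per_species(gm, outgroup_gm, threshold, species_of)
    out_index = {(s.chrom, s.pos): j for j, s in enumerate(outgroup_gm.sites)}
    assignments = []
    for site in gm.sites:
        j = out_index.get((site.chrom, site.pos))
        if j is None:
            assignments.append(
                AncestralAssignment(site, "missing", 0.0, "no_outgroup_data")
            )
            continue
        osite = outgroup_gm.sites[j]
        col = outgroup_gm.genotypes[:, j].copy()
        if (osite.ref_allele, osite.alt_allele) == (site.ref_allele, site.alt_allele):
            pass
        elif (osite.alt_allele, osite.ref_allele) == (site.ref_allele, site.alt_allele):
            keep = col != MISSING
            col[keep] = 2 - col[keep]
        else:
            # outgroup segregates for other alleles entirely
            assignments.append(
                AncestralAssignment(site, "missing", 0.0, "allele_mismatch")
            )
            continue
        assignments.append(infer_ancestral(site, col, threshold))
    return assignments


def _infer_per_species(gm, outgroup_gm, threshold, species_of):
    species = sorted(set(species_of.values()))
    rows_by_sp = {
        sp: [i for i, s in enumerate(outgroup_gm.samples) if species_of.get(s) == sp]
        for sp in species
    }
    out_index = {(s.chrom, s.pos): j for j, s in enumerate(outgroup_gm.sites)}
    assignments = []
    for site in gm.sites:
        j = out_index.get((site.chrom, site.pos))
        if j is None:
            assignments.append(AncestralAssignment(site, "missing", 0.0, "no_outgroup_data"))
            continue
        osite = outgroup_gm.sites[j]
        col = outgroup_gm.genotypes[:, j].copy()
        if (osite.ref_allele, osite.alt_allele) == (site.alt_allele, site.ref_allele):
            keep = col != MISSING
            col[keep] = 2 - col[keep]
        elif (osite.ref_allele, osite.alt_allele) != (site.ref_allele, site.alt_allele):
            assignments.append(AncestralAssignment(site, "missing", 0.0, "allele_mismatch"))
            continue
        calls = []
        for sp in species:
            sub = col[rows_by_sp[sp]]
            a = infer_ancestral(site, sub, threshold)
            if a.ancestral != "missing":
                calls.append(a.ancestral)
        if not calls:
            assignments.append(AncestralAssignment(site, "missing", 0.0, "no_outgroup_data"))
            continue
        modal = max(sorted(set(calls)), key=calls.count)
        support = calls.count(modal) / len(calls)
        if support >= threshold:
            assignments.append(AncestralAssignment(site, modal, support, "ok"))
        else:
            assignments.append(
                AncestralAssignment(site, "missing", support, "below_threshold")
            )
    return assignments


def polarize_genotypes(
    gm: GenotypeMatrix, assignments: list[AncestralAssignment]
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Re-express genotypes as derived-allele dosages.

    Sites whose ancestral allele is the alt are flipped (dosage 2 - g); sites
    without an ancestral call are dropped.  Returns the polarized matrix and a
    per-site drop log.
    """
    by_key = {a.site.key(): a for a in assignments}
    keep_idx, flip = [], []
    log_rows = []
    for j, site in enumerate(gm.sites):
        a = by_key.get(site.key())
        if a is None or a.ancestral == "missing":
            log_rows.append(
                {
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "kept": False,
                    "reason": a.reason if a else "no_assignment",
                }
            )
            continue
        keep_idx.append(j)
        flip.append(a.ancestral == "alt")
        log_rows.append(
            {"chrom": site.chrom, "pos": site.pos, "kept": True, "reason": "ok"}
        )
    sub = gm.subset_sites(np.array(keep_idx, dtype=int))
    geno = sub.genotypes
    flip = np.array(flip, dtype=bool)
    cols = geno[:, flip]
    nonmiss = cols != MISSING
    cols[nonmiss] = 2 - cols[nonmiss]
    geno[:, flip] = cols
    return sub, pd.DataFrame(log_rows)


def assignment_table(assignments: list[AncestralAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [a.site.chrom for a in assignments],
            "pos": [a.site.pos for a in assignments],
            "ancestral": [a.ancestral_base or "." for a in assignments],
            "support": [a.support for a in assignments],
            "reason": [a.reason for a in assignments],
        }
    )


def derived_frequency_table(
    polarized: GenotypeMatrix,
    popmap: PopulationMap,
    classes: tuple[str, ...] = ("synonymous", "missense", "lof"),
) -> pd.DataFrame:
    """Mean derived allele frequency per (population, effect class).

    Per-site DAF = derived dosage sum / (2 x non-missing diploids); sites with
    no genotyped individual in a population are skipped for that population.
    """
    rows_by_pop = popmap.rows_by_pop(polarized.samples)
    cls = np.array([s.effect_class for s in polarized.sites])
    geno = polarized.genotypes
    records = []
    for pop, rows in rows_by_pop.items():
        sub = geno[rows]
        nonmiss = sub != MISSING
        der = np.where(nonmiss, sub, 0).sum(axis=0).astype(float)
        n_chrom = 2.0 * nonmiss.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            daf = np.where(n_chrom > 0, der / n_chrom, np.nan)
        for c in classes:
            sel = (cls == c) & ~np.isnan(daf)
            records.append(
                {
                    "population": pop,
                    "effect_class": c,
                    "mean_daf": float(np.mean(daf[sel])) if sel.any() else np.nan,
                    "n_sites": int(sel.sum()),
                }
            )
    return pd.DataFrame(records)


def per_site_daf(polarized: GenotypeMatrix, popmap: PopulationMap) -> pd.DataFrame:
    """Per-site DAF matrix (sites x populations), NaN when nothing genotyped."""
    rows_by_pop = popmap.rows_by_pop(polarized.samples)
    out = {}
    for pop, rows in rows_by_pop.items():
        sub = polarized.genotypes[rows]
        nonmiss = sub != MISSING
        der = np.where(nonmiss, sub, 0).sum(axis=0).astype(float)
        n_chrom = 2.0 * nonmiss.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[pop] = np.where(n_chrom > 0, der / n_chrom, np.nan)
    idx = pd.MultiIndex.from_tuples(
        [(s.chrom, s.pos) for s in polarized.sites], names=["chrom", "pos"]
    )
    return pd.DataFrame(out, index=idx)
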