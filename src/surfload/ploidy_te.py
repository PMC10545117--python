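"""Diploid vs residual-tetraploid contrasts.

Salmonid genomes retain chromosome arms that still pair tetrasomically after
the ancestral whole-genome duplication.  These low-recombining compartments
accumulate deleterious variation; the functions here contrast piN/piS between
compartments with gene resampling and GC-matched genomic bins, and compare
transposable-element content corrected for chromosome length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coding_stats import SiteCounts
from .core_io import GeneModel, RegionSet

DEFAULT_TETRAPLOID_CHROMS = tuple(range(31, 39))


@dataclass
class PloidyPartition:
    compartment: dict[str, str]  # gene_id -> "diploid" | "tetraploid"
    source: str
    unassigned: list[str]

    def genes(self, compartment: str) -> list[str]:
        return [g for g, c in self.compartment.items() if c == compartment]


def _chrom_number(chrom: str) -> int | None:
    m = re.search(r"(\d+)$", chrom)
    return int(m.group(1)) if m else None


def assign_ploidy(
    genes: list[GeneModel],
    tetraploid_regions: RegionSet | None = None,
    tetraploid_chroms: tuple[int, ...] = DEFAULT_TETRAPLOID_CHROMS,
) -> PloidyPartition:
    """Assign each gene to the diploid or residual-tetraploid compartment.

    An explicit region BED takes precedence; otherwise the chromosome-number
    rule applies (chromosomes 31-38 tetraploid by default).  Genes matching
    neither are excluded."""
    comp: dict[str, str] = {}
    unassigned: list[str] = []
    for g in genes:
        if tetraploid_regions is not None:
            comp[g.gene_id] = (
                "tetraploid"
                if tetraploid_regions.contains(g.chrom, g.start)
                else "diploid"
            )
            continue
        num = _chrom_number(g.chrom)
        if num is None:
            unassigned.append(g.gene_id)
        elif num in tetraploid_chroms:
            comp[g.gene_id] = "tetraploid"
        else:
            comp[g.gene_id] = "diploid"
    source = "bed" if tetraploid_regions is not None else "chromosome_rule"
    return PloidyPartition(comp, source, unassigned)


@dataclass
class ResampleResult:
    observed_tetraploid: float
    null_values: np.ndarray
    quantile: float  # midrank position of the observed value in the null


def resample_diploid_load(
    partition: PloidyPartition,
    gene_counts: dict[str, SiteCounts],
    n_resamples: int = 200,
    genes_per_set: int = 4000,
    seed: int = 0,
) -> ResampleResult:
    """Null distribution of concatenated piN/piS from random diploid gene
    sets, against the observed tetraploid value.

    Each resample draws ``genes_per_set`` diploid genes without replacement;
    when the pool is smaller than the requested set size, half the pool is
    drawn instead (so the null retains resampling variance) and this is
    logged."""
    import logging

    rng = np.random.default_rng(seed)
    dip = [g for g in partition.genes("diploid") if g in gene_counts]
    tet = [g for g in partition.genes("tetraploid") if g in gene_counts]
    if len(dip) < 10:
        raise ValueError(f"diploid pool of {len(dip)} genes is too small")
    if len(dip) >= genes_per_set:
        k = genes_per_set
    else:
        k = max(2, len(dip) // 2)
        logging.getLogger(__name__).info(
            "diploid pool %d < genes_per_set %d; drawing %d genes per set",
            len(dip), genes_per_set, k,
        )

    def concat_ratio(ids) -> float:
        agg = SiteCounts("resample")
        for g in ids:
            agg += gene_counts[g]
        return agg.ratio

    observed = concat_ratio(tet)
    null = np.array(
        [
            concat_ratio(rng.choice(dip, size=k, replace=False))
            for _ in range(n_resamples)
        ]
    )
    below = float(np.sum(null < observed))
    ties = float(np.sum(null == observed))
    quantile = (below + 0.5 * ties + 0.5) / (len(null) + 1)
    if ties == len(null):  # fully degenerate null
        quantile = 0.5
    elif observed > null.max():
        quantile = 1.0
    elif observed < null.min():
        quantile = 0.0
    return ResampleResult(observed, null, quantile)


def genomic_window_gc(reference: dict[str, str], window_bp: int = 4_000_000) -> pd.DataFrame:
    """GC fraction of fixed genomic windows of the reference."""
    rows = []
    for chrom, seq in reference.items():
        for start in range(0, len(seq), window_bp):
            chunk = seq[start : start + window_bp].upper()
            acgt = sum(chunk.count(b) for b in "ACGT")
            if acgt == 0:
                continue
            gc = (chunk.count("G") + chunk.count("C")) / acgt
            rows.append({"chrom": chrom, "start": start, "end": start + len(chunk), "gc": gc})
    return pd.DataFrame(rows)


def gc_matched_contrast(
    partition: PloidyPartition,
    genes: list[GeneModel],
    gene_counts: dict[str, SiteCounts],
    reference: dict[str, str],
    gc_window_bp: int = 4_000_000,
    lowest_fraction: float = 0.2,
) -> pd.DataFrame:
    """piN/piS per compartment in the lowest-GC genomic windows vs the rest.

    Window GC is computed in fixed ``gc_window_bp`` windows separately per
    compartment; the "lowest" bin is the bottom ``lowest_fraction`` quantile
    of window GC within each compartment (deterministic cut)."""
    windows = genomic_window_gc(reference, gc_window_bp)
    win_by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for _, w in windows.iterrows():
        win_by_chrom.setdefault(w.chrom, []).append((int(w.start), int(w.end), w.gc))
    rows = []
    for g in genes:
        comp = partition.compartment.get(g.gene_id)
        if comp is None or g.gene_id not in gene_counts:
            continue
        for s, e, gc in win_by_chrom.get(g.chrom, []):
            if s <= g.start - 1 < e:
                rows.append({"gene_id": g.gene_id, "compartment": comp, "window_gc": gc})
                break
    df = pd.DataFrame(rows)
    out = []
    for comp, sub in df.groupby("compartment"):
        cut = sub.window_gc.quantile(lowest_fraction)
        for label, sel in (
            ("lowest_gc", sub.window_gc <= cut),
            ("other_gc", sub.window_gc > cut),
        ):
            ids = sub.gene_id[sel]
            agg = SiteCounts(label)
            for gid in ids:
                agg += gene_counts[gid]
            out.append(
                {
                    "compartment": comp,
                    "gc_bin": label,
                    "n_genes": int(sel.sum()),
                    "pi_n": agg.pi_n,
                    "pi_s": agg.pi_s,
                    "ratio": agg.ratio,
                }
            )
    return pd.DataFrame(out)


def te_compare(
    te_regions: RegionSet,
    chrom_lengths: dict[str, int],
    tetraploid_chroms: tuple[int, ...] = DEFAULT_TETRAPLOID_CHROMS,
    tetraploid_regions: RegionSet | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Relative TE length (TE length / chromosome length) per compartment and
    a two-sided Mann-Whitney U test between compartments."""
    rows = []
    for chrom, start, end in te_regions.intervals:
        clen = chrom_lengths.get(chrom)
        if clen is None:
            continue
        if tetraploid_regions is not None:
            comp = (
                "tetraploid"
                if tetraploid_regions.contains(chrom, start + 1)
                else "diploid"
            )
        else:
            num = _chrom_number(chrom)
            if num is None:
                continue
            comp = "tetraploid" if num in tetraploid_chroms else "diploid"
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "compartment": comp,
                "relative_length": (end - start) / clen,
            }
        )
    df = pd.DataFrame(rows)
    groups = {c: g.relative_length.to_numpy() for c, g in df.groupby("compartment")}
    if len(groups) < 2:
        raise ValueError("a compartment has zero TEs; test undefined")
    u, p = stats.mannwhitneyu(
        groups["diploid"], groups["tetraploid"], alternative="two-sided"
    )
    return df, float(u), float(p)
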