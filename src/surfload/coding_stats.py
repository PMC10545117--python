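"""Codon-level diversity statistics: GC3, synonymous/nonsynonymous site
counting (Nei-Gojobori 1986 equal-weight convention), piN and piS over
concatenated gene sets, gene-space windows and GC3 bins.

piN/piS is a classic readout of the efficacy of purifying selection: under
free recombination and large Ne it sits well below 1; relaxed selection
(drift, expansion fronts, low recombination) pushes it up.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .core_io import CodingAlignment, VariantSite

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


def is_stop(codon: str) -> bool:
    return codon in _STOPS


@lru_cache(maxsize=None)
def classify_codon_sites(codon: str) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Per-position synonymous / nonsynonymous site fractions of a codon.

    Equal-weight counting over the three single-base changes at each
    position; changes creating a stop codon are excluded from the
    denominator.  Stop codons raise ValueError (excluded upstream).
    """
    codon = codon.upper()
    if is_stop(codon):
        raise ValueError(f"stop codon {codon} has no site counts")
    if codon not in _CODON_TABLE:
        raise ValueError(f"unrecognized codon {codon!r}")
    aa = _CODON_TABLE[codon]
    syn, nonsyn = [], []
    for p in range(3):
        n_syn = n_counted = 0
        for b in _BASES:
            if b == codon[p]:
                continue
            mut = codon[:p] + b + codon[p + 1 :]
            if is_stop(mut):
                continue
            n_counted += 1
            if _CODON_TABLE[mut] == aa:
                n_syn += 1
        if n_counted == 0:  # cannot happen for sense codons, guard anyway
            syn.append(0.0)
            nonsyn.append(0.0)
        else:
            syn.append(n_syn / n_counted)
            nonsyn.append(1.0 - n_syn / n_counted)
    return tuple(syn), tuple(nonsyn)


def is_synonymous_change(codon: str, position: int, new_base: str) -> bool:
    """Does substituting ``new_base`` at ``position`` (0..2) preserve the amino acid?"""
    mut = codon[:position] + new_base + codon[position + 1 :]
    if codon in _STOPS or mut in _STOPS:
        return False
    return _CODON_TABLE[codon] == _CODON_TABLE[mut]


@dataclass
class GeneGC:
    gene_id: str
    gc3: float | None
    third_positions_used: int


@dataclass
class SiteCounts:
    """Fractional synonymous/nonsynonymous site totals and mean pairwise
    differences for one gene (or an aggregate)."""

    gene_id: str
    syn_sites: float = 0.0
    nonsyn_sites: float = 0.0
    syn_diffs: float = 0.0
    nonsyn_diffs: float = 0.0
    codon_count: int = 0

    @property
    def pi_s(self) -> float:
        return self.syn_diffs / self.syn_sites if self.syn_sites > 0 else np.nan

    @property
    def pi_n(self) -> float:
        return self.nonsyn_diffs / self.nonsyn_sites if self.nonsyn_sites > 0 else np.nan

    @property
    def ratio(self) -> float:
        """piN/piS; missing (NaN) when piS is zero or undefined."""
        ps = self.pi_s
        if not np.isfinite(ps) or ps == 0:
            return np.nan
        return self.pi_n / ps

    def __iadd__(self, other: "SiteCounts") -> "SiteCounts":
        self.syn_sites += other.syn_sites
        self.nonsyn_sites += other.nonsyn_sites
        self.syn_diffs += other.syn_diffs
        self.nonsyn_diffs += other.nonsyn_diffs
        self.codon_count += other.codon_count
        return self


def consensus_sequence(alignment: CodingAlignment) -> str:
    """Column-wise majority base over all haplotypes (ties to the
    alphabetically first base; N only if every haplotype is N)."""
    seqs = alignment.sequences()
    out = []
    for col in zip(*seqs):
        counts: dict[str, int] = {}
        for b in col:
            if b in "ACGT":
                counts[b] = counts.get(b, 0) + 1
        if not counts:
            out.append("N")
        else:
            out.append(max(sorted(counts), key=counts.get))
    return "".join(out)


def gc3(alignment: CodingAlignment, sequence: str | None = None) -> GeneGC:
    """GC fraction at third codon positions of the consensus (or a given) sequence."""
    seq = sequence if sequence is not None else consensus_sequence(alignment)
    thirds = seq[2::3]
    usable = [b for b in thirds if b in "ACGT"]
    if not usable:
        return GeneGC(alignment.gene_id, None, 0)
    gc = sum(b in "GC" for b in usable) / len(usable)
    return GeneGC(alignment.gene_id, gc, len(usable))


def _column_pi(column: tuple[str, ...]) -> tuple[float, str, str | None]:
    """Unbiased per-site diversity of one alignment column.

    Returns (pi, major_base, minor_base).  pi = (n/(n-1)) * (1 - sum p_a^2),
    identical to the mean pairwise difference at the site.
    """
    counts: dict[str, int] = {}
    for b in column:
        counts[b] = counts.get(b, 0) + 1
    n = sum(counts.values())
    alleles = sorted(counts, key=lambda a: (-counts[a], a))
    if len(alleles) == 1 or n < 2:
        return 0.0, alleles[0], None
    sum_p2 = sum((c / n) ** 2 for c in counts.values())
    pi = (1.0 - sum_p2) * n / (n - 1)
    return pi, alleles[0], alleles[1]


def gene_site_counts(alignment: CodingAlignment) -> SiteCounts:
    """NG86 site totals and per-class mean pairwise differences for one gene.

    Codon columns containing N or a gap in any haplotype are excluded
    alignment-wide, so site totals are shared across haplotypes; columns
    whose consensus codon is a stop are excluded too.  Polymorphic positions
    are classified syn/nonsyn by the major/minor allele pair in the context
    of the consensus codon.
    """
    seqs = alignment.sequences()
    out = SiteCounts(alignment.gene_id)
    if not seqs:
        return out
    length = len(seqs[0])
    for c0 in range(0, length - length % 3, 3):
        codons = [s[c0 : c0 + 3] for s in seqs]
        if any(ch not in "ACGT" for cd in codons for ch in cd):
            continue
        cols = [tuple(cd[k] for cd in codons) for k in range(3)]
        consensus = "".join(_column_pi(col)[1] for col in cols)
        if is_stop(consensus) or consensus not in _CODON_TABLE:
            continue
        syn_f, nonsyn_f = classify_codon_sites(consensus)
        out.codon_count += 1
        out.syn_sites += sum(syn_f)
        out.nonsyn_sites += sum(nonsyn_f)
        for k in range(3):
            pi, major, minor = _column_pi(cols[k])
            if minor is None or pi == 0.0:
                continue
            ctx = consensus[:k] + major + consensus[k + 1 :]
            if ctx in _STOPS:
                continue
            if is_synonymous_change(ctx, k, minor):
                out.syn_diffs += pi
            else:
                out.nonsyn_diffs += pi
    return out


def pi_n_pi_s(
    alignments: list[CodingAlignment],
    gene_subset: set[str] | None = None,
    per_gene: dict[str, SiteCounts] | None = None,
) -> SiteCounts:
    """Concatenated piN/piS over a gene set (ratio of summed diffs to summed sites).

    ``per_gene`` may carry precomputed :func:`gene_site_counts` results to
    avoid recomputation when many subsets are evaluated.
    """
    agg = SiteCounts("aggregate")
    for aln in alignments:
        if gene_subset is not None and aln.gene_id not in gene_subset:
            continue
        sc = (
            per_gene[aln.gene_id]
            if per_gene is not None and aln.gene_id in per_gene
            else gene_site_counts(aln)
        )
        agg += sc
    return agg


def window_pinpis(
    gene_counts: list[tuple[str, int, SiteCounts]],
    window_span: int = 4_000_000,
) -> pd.DataFrame:
    """Pack genes (given as (chrom, start, counts), any order) in genomic
    order into windows of concatenated CDS ("gene space") length reaching
    ``window_span``; per-window piN/piS.

    A trailing window shorter than 25% of the span is flagged partial.
    """
    ordered = sorted(gene_counts, key=lambda t: (t[0], t[1]))
    rows = []
    agg = SiteCounts("window")
    members: list[str] = []
    span = 0

    def close(partial: bool):
        rows.append(
            {
                "window": len(rows),
                "n_genes": len(members),
                "cds_span": span,
                "pi_n": agg.pi_n,
                "pi_s": agg.pi_s,
                "ratio": agg.ratio,
                "partial": partial,
            }
        )

    for _, _, sc in ordered:
        agg += sc
        members.append(sc.gene_id)
        span += 3 * sc.codon_count
        if span >= window_span:
            close(False)
            agg, members, span = SiteCounts("window"), [], 0
    if members:
        close(span < 0.25 * window_span)
    return pd.DataFrame(rows)


def bin_genes_by_gc3(
    genes: list[tuple[GeneGC, SiteCounts]], n_bins: int
) -> pd.DataFrame:
    """Equal-count bins of genes sorted by ascending GC3; concatenated
    piN/piS and median GC3 per bin.  Remainder genes go to the first bins."""
    usable = [(g, sc) for g, sc in genes if g.gc3 is not None]
    if n_bins > len(usable):
        raise ValueError(f"n_bins={n_bins} exceeds {len(usable)} genes with GC3")
    usable.sort(key=lambda t: (t[0].gc3, t[0].gene_id))
    base, rem = divmod(len(usable), n_bins)
    rows = []
    i = 0
    for b in range(n_bins):
        size = base + (1 if b < rem else 0)
        chunk = usable[i : i + size]
        i += size
        agg = SiteCounts(f"bin{b}")
        for _, sc in chunk:
            agg += sc
        rows.append(
            {
                "bin": b,
                "n_genes": size,
                "gc3_median": float(np.median([g.gc3 for g, _ in chunk])),
                "pi_n": agg.pi_n,
                "pi_s": agg.pi_s,
                "ratio": agg.ratio,
            }
        )
    return pd.DataFrame(rows)


def gc_conservative_filter(sites: list[VariantSite]) -> list[VariantSite]:
    """Keep only A<->T and C<->G polymorphisms (unaffected by GC-biased gene
    conversion)."""
    keep_pairs = {frozenset("AT"), frozenset("CG")}
    return [
        s for s in sites if frozenset((s.ref_allele, s.alt_allele)) in keep_pairs
    ]
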