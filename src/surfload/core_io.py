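"""Readers/writers for the standard formats the pipeline touches.

Variant data are held in a :class:`GenotypeMatrix` (samples x biallelic SNVs,
alt-allele dosage with missing coded as -1).  Gene models come from GFF3 CDS
features; per-individual coding sequences are reconstructed from the reference
FASTA plus the genotype matrix ("vcf2fasta"), producing a
:class:`CodingAlignment` of two pseudo-haplotypes per individual.

Coordinate conventions: VCF/GFF are 1-based inclusive, BED is 0-based
half-open; all internal interval logic is half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MISSING = -1  # genotype code for ./. -- distinct from 0 (hom ref)

EFFECT_CLASSES = ("synonymous", "missense", "lof", "noncoding", "unknown")

_NT = set("ACGT")
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNV with an optional functional effect class."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    effect_class: str = "unknown"
    gene_id: str | None = None

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_allele not in _NT or self.alt_allele not in _NT:
            raise ValueError(f"non-SNV alleles at {self.chrom}:{self.pos}")
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class!r}")

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class GenotypeMatrix:
    """Alt-allele dosage per (sample, site); missing genotypes are -1."""

    samples: list[str]
    sites: list[VariantSite]
    genotypes: np.ndarray  # int8, shape (n_samples, n_sites)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.sites)):
            raise ValueError("genotype matrix shape inconsistent with samples/sites")
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype values must be in {-1, 0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_index(self) -> dict[tuple[str, int, str, str], int]:
        return {s.key(): j for j, s in enumerate(self.sites)}

    def subset_sites(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=[self.sites[j] for j in idx],
            genotypes=self.genotypes[:, idx].copy(),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        rows = [pos[s] for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), list(self.sites), self.genotypes[rows])


@dataclass
class GeneModel:
    """Spliced CDS of one representative transcript of a gene.

    ``cds_segments`` are (start, end, phase) in 1-based inclusive GFF
    coordinates, stored in ascending genomic order regardless of strand.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_segments: list[tuple[int, int, int]]
    in_frame: bool = True  # False => excluded from codon statistics

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        segs = sorted(self.cds_segments)
        for (s1, e1, _), (s2, _, _) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping CDS segments in {self.gene_id}")
        self.cds_segments = segs

    @property
    def start(self) -> int:
        return self.cds_segments[0][0]

    @property
    def end(self) -> int:
        return self.cds_segments[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds_segments)

    @property
    def first_phase(self) -> int:
        """Phase of the first segment in coding order."""
        seg = self.cds_segments[0] if self.strand == "+" else self.cds_segments[-1]
        return seg[2]

    def coding_positions(self) -> np.ndarray:
        """Genomic 1-based positions in coding (5'->3' mRNA) order, phase-trimmed."""
        if self.strand == "+":
            pos = np.concatenate(
                [np.arange(s, e + 1) for s, e, _ in self.cds_segments]
            )
        else:
            pos = np.concatenate(
                [np.arange(e, s - 1, -1) for s, e, _ in reversed(self.cds_segments)]
            )
        trim = self.first_phase
        n = len(pos) - trim
        n -= n % 3
        return pos[trim : trim + n]


@dataclass
class CodingAlignment:
    """Two phase-trimmed CDS haplotype sequences per individual, coding orientation."""

    gene_id: str
    samples: list[str]
    haplotypes: list[tuple[str, str]]  # parallel to samples

    def __post_init__(self):
        lengths = {len(h) for pair in self.haplotypes for h in pair}
        if len(lengths) > 1:
            raise ValueError("haplotype sequences differ in length")
        if lengths and next(iter(lengths)) % 3:
            raise ValueError("alignment length not divisible by 3")

    @property
    def length(self) -> int:
        return len(self.haplotypes[0][0]) if self.haplotypes else 0

    @property
    def codon_count(self) -> int:
        return self.length // 3

    def sequences(self) -> list[str]:
        return [h for pair in self.haplotypes for h in pair]


@dataclass
class PopulationMap:
    sample_to_pop: dict[str, str]
    covariates: "object" = None  # pandas DataFrame indexed by population

    def __post_init__(self):
        import pandas as pd

        if self.covariates is None:
            self.covariates = pd.DataFrame(
                index=sorted(set(self.sample_to_pop.values()))
            )

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.sample_to_pop.values():
            seen.setdefault(p)
        return list(seen)

    def samples_of(self, pop: str) -> list[str]:
        return [s for s, p in self.sample_to_pop.items() if p == pop]

    def rows_by_pop(self, samples: Sequence[str]) -> dict[str, np.ndarray]:
        """Row indices into ``samples`` per population (samples absent from the map ignored)."""
        out: dict[str, list[int]] = {}
        for i, s in enumerate(samples):
            p = self.sample_to_pop.get(s)
            if p is not None:
                out.setdefault(p, []).append(i)
        return {p: np.array(v) for p, v in out.items()}


@dataclass
class RegionSet:
    """Labelled genomic intervals, 0-based half-open, normalized (sorted+merged)."""

    label: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.intervals = self._normalize(self.intervals)

    @staticmethod
    def _normalize(ivals):
        merged: list[tuple[str, int, int]] = []
        for chrom, start, end in sorted(ivals):
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
                c, s, e = merged[-1]
                merged[-1] = (c, s, max(e, end))
            else:
                merged.append((chrom, start, end))
        return merged

    def contains(self, chrom: str, pos: int) -> bool:
        """pos is 1-based; membership uses half-open [start, end)."""
        import bisect

        keys = [(c, s) for c, s, _ in self.intervals]
        i = bisect.bisect_right(keys, (chrom, pos - 1)) - 1
        if i < 0:
            return False
        c, s, e = self.intervals[i]
        return c == chrom and s <= pos - 1 < e

    def total_length(self) -> int:
        return sum(e - s for _, s, e in self.intervals)


# ---------------------------------------------------------------------------
# readers


def read_effect_table(path) -> dict[tuple[str, int, str, str], str]:
    """TSV with columns chrom, pos, ref, alt, class (header optional)."""
    effects = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts[0] in ("", "chrom", "#chrom"):
                continue
            chrom, pos, ref, alt, cls = parts[:5]
            effects[(chrom, int(pos), ref, alt)] = cls
    return effects


def read_variants(vcf_path, effect_table_path=None) -> tuple[GenotypeMatrix, list[VariantSite]]:
    """Load diploid genotypes from a VCF, keeping biallelic SNVs only.

    Multiallelic records and indels are dropped (and counted); an optional
    effect table assigns effect classes on (chrom, pos, ref, alt), defaulting
    to "unknown".
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    rows = []
    dropped = {"multiallelic": 0, "indel": 0}
    for rec in vcf:
        if len(rec.ALT) != 1:
            dropped["multiallelic"] += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1 or rec.REF not in _NT or rec.ALT[0] not in _NT:
            dropped["indel"] += 1
            continue
        sites.append(VariantSite(rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        g = rec.gt_types.astype(np.int8)  # gts012: 0,1,2, 3=missing
        g[g == 3] = MISSING
        rows.append(g)
    vcf.close()
    if dropped["multiallelic"] or dropped["indel"]:
        logger.info("read_variants dropped %s", dropped)
    geno = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    if effect_table_path is not None:
        effects = read_effect_table(effect_table_path)
        index = {s.key(): j for j, s in enumerate(sites)}
        matched = set()
        for key, cls in effects.items():
            j = index.get(key)
            if j is None:
                warnings.warn(f"effect row {key} matches no variant; skipped")
                continue
            matched.add(key)
            s = sites[j]
            sites[j] = VariantSite(s.chrom, s.pos, s.ref_allele, s.alt_allele, cls, s.gene_id)
    gm = GenotypeMatrix(samples, sites, geno)
    return gm, sites


def write_vcf(gm: GenotypeMatrix, path, ancestral: Mapping | None = None) -> None:
    """Write a minimal VCF v4.2; ``ancestral`` maps site key -> ancestral base (AA tag)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = {s.chrom: None for s in gm.sites}
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        gt_str = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        order = np.lexsort(
            ([s.pos for s in gm.sites], [s.chrom for s in gm.sites])
        )
        for j in order:
            s = gm.sites[j]
            info = "."
            if ancestral is not None:
                aa = ancestral.get(s.key())
                if aa is not None:
                    info = f"AA={aa}"
            gts = "\t".join(gt_str[int(g)] for g in gm.genotypes[:, j])
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref_allele}\t{s.alt_allele}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


def load_gene_models(gff_path) -> list[GeneModel]:
    """Parse GFF3 CDS features into one GeneModel per gene.

    When a gene has several mRNAs the longest CDS wins (ties broken by
    lexicographic transcript id).  Genes whose phase-trimmed spliced length is
    not a multiple of 3 are kept but flagged ``in_frame=False``.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        candidates = []  # (cds_len, transcript_id, segments, strand)
        for mrna in db.children(gene, featuretype="mRNA"):
            segs = [
                (c.start, c.end, int(c.frame) if c.frame in "012" else 0)
                for c in db.children(mrna, featuretype="CDS")
            ]
            if segs:
                length = sum(e - s + 1 for s, e, _ in segs)
                candidates.append((length, mrna.id, segs, mrna.strand))
        if not candidates:
            segs = [
                (c.start, c.end, int(c.frame) if c.frame in "012" else 0)
                for c in db.children(gene, featuretype="CDS")
            ]
            if segs:
                length = sum(e - s + 1 for s, e, _ in segs)
                candidates.append((length, gene.id, segs, gene.strand))
        if not candidates:
            continue
        candidates.sort(key=lambda t: (-t[0], t[1]))
        length, _tid, segs, strand = candidates[0]
        gm = GeneModel(gene.id, gene.seqid, strand, segs)
        gm.in_frame = (length - gm.first_phase) % 3 == 0 and length >= 3
        if not gm.in_frame:
            logger.warning("gene %s flagged out-of-frame (len %d)", gene.id, length)
        models.append(gm)
    return models


def _load_reference(reference) -> Mapping[str, str]:
    if isinstance(reference, Mapping):
        return reference
    from pyfaidx import Fasta

    fa = Fasta(str(reference))
    return {name: str(fa[name][:]) for name in fa.keys()}


def reconstruct_cds_alignment(
    gene: GeneModel,
    gm: GenotypeMatrix,
    reference,
    seed: int | np.random.Generator = 0,
) -> CodingAlignment:
    """Substitute variants into the reference CDS for every individual.

    Homozygous genotypes place the allele on both pseudo-haplotypes;
    unphased heterozygotes are assigned to the two haplotypes uniformly at
    random under ``seed`` (allele counts are conserved either way); missing
    genotypes yield N on both haplotypes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ref = _load_reference(reference)
    if gene.chrom not in ref:
        raise KeyError(f"chromosome {gene.chrom} absent from reference")
    chrom_seq = ref[gene.chrom]
    positions = gene.coding_positions()
    bases = [chrom_seq[p - 1] for p in positions]
    if gene.strand == "-":
        bases = [b.translate(_COMP) for b in bases]
    pos_to_idx = {int(p): i for i, p in enumerate(positions)}

    hap_a = [list(bases) for _ in gm.samples]
    hap_b = [list(bases) for _ in gm.samples]
    for j, site in enumerate(gm.sites):
        if site.chrom != gene.chrom:
            continue
        idx = pos_to_idx.get(site.pos)
        if idx is None:
            continue
        genomic_base = chrom_seq[site.pos - 1].upper()
        if genomic_base != site.ref_allele:
            raise ValueError(
                f"reference mismatch at {site.chrom}:{site.pos}: "
                f"FASTA has {genomic_base}, VCF REF is {site.ref_allele}"
            )
        refb, altb = site.ref_allele, site.alt_allele
        if gene.strand == "-":
            refb, altb = refb.translate(_COMP), altb.translate(_COMP)
        col = gm.genotypes[:, j]
        for i, g in enumerate(col):
            if g == 0:
                continue
            if g == MISSING:
                hap_a[i][idx] = "N"
                hap_b[i][idx] = "N"
            elif g == 2:
                hap_a[i][idx] = altb
                hap_b[i][idx] = altb
            else:  # het: coin flip which pseudo-haplotype carries the alt
                if rng.integers(2):
                    hap_a[i][idx] = altb
                else:
                    hap_b[i][idx] = altb
    haps = [("".join(a), "".join(b)) for a, b in zip(hap_a, hap_b)]
    return CodingAlignment(gene.gene_id, list(gm.samples), haps)


def read_region_set(bed_path, label: str) -> RegionSet:
    """BED3+ reader; rows with start >= end are rejected with a warning."""
    ivals = []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                warnings.warn(f"rejected BED record {chrom}:{start}-{end} (start >= end)")
                continue
            ivals.append((chrom, start, end))
    return RegionSet(label, ivals)


def read_popmap(path) -> PopulationMap:
    """TSV: sample, population, then optional covariate columns with a header.

    A header row is required when covariates are present (first column named
    'sample'); two-column files may omit it.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if df.columns[0].lower() not in ("sample", "sample_id"):
        df = pd.read_csv(path, sep="\t", header=None)
        df.columns = ["sample", "population"] + [
            f"cov{k}" for k in range(df.shape[1] - 2)
        ]
    df.columns = [str(c).lower() for c in df.columns]
    s2p = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    cov_cols = [c for c in df.columns[2:]]
    if cov_cols:
        cov = df.groupby(df.columns[1])[cov_cols].first()
        cov.index.name = "population"
    else:
        cov = pd.DataFrame(index=sorted(set(s2p.values())))
    return PopulationMap(s2p, cov)


def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
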