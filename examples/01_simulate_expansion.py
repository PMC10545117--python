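"""Simulate a small serial-founder range expansion and write every standard
input file (VCF, GFF3, FASTA, BED, TSV) plus the truth tables.

The printed summary shows how heterozygosity erodes deme by deme away from
the source - the demographic fingerprint of repeated founder events.
"""

from surfload.popgen_stats import observed_heterozygosity
from surfload.simulate import ExpansionConfig, emit_dataset, simulate_expansion

cfg = ExpansionConfig(
    n_demes=5,
    deme_size=120,
    founder_size=10,
    generations_between_founding=25,
    burn_in_generations=60,
    n_genes=60,
    codons_per_gene=30,
    sample_per_deme=10,
    seed=42,
)
ds = simulate_expansion(cfg)
manifest = emit_dataset(ds, "scratch/example_dataset")

print(f"simulated {ds.gm.n_sites} variant sites in {ds.gm.n_samples} individuals")
print(f"emitted files: {', '.join(sorted(manifest))}")

ho = observed_heterozygosity(ds.gm, ds.popmap).sort_index()
print("\nobserved heterozygosity by deme (pop01 = source):")
for pop, v in ho.items():
    print(f"  {pop}: {v:.4f}")
print("\nThe youngest deme at the wavefront shows the strongest loss of")
print("diversity; older demes partially recover through migration. Each value")
print("is the mean fraction of heterozygous genotypes per variant site.")
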