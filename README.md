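# surfload

Tools for quantifying **expansion load**: the burden of deleterious
mutations that accumulates when a species expands its range through serial
founder events, as in postglacial recolonization by salmonids. At an
expansion front, effective population size is transiently tiny and drift
overwhelms purifying selection, so deleterious alleles can rise in
frequency or fix by *allele surfing*. `surfload` implements the complete
measurement chain used in population-genomic studies of this process, and a
forward simulator that generates data with exactly this structure so every
stage can be validated against known truth.

The package is a library: import it from Python, or start from the short
scripts in `examples/`.

## What it computes

* **Polarization** — ancestral/derived alleles from outgroup genotype
  panels (a site is polarized when ≥ 90% of non-missing outgroup
  individuals are homozygous for an allele that matches one of the focal
  alleles), and derived allele frequencies per population and effect class.
* **Load counts** — per individual and effect class (synonymous, missense,
  loss-of-function): additive load `N_total = 2·N_homo + N_hetero` and
  recessive load `N_homo`, with ANOVA + Tukey HSD (Bonferroni) contrasts
  among populations.
* **πN/πS** — nucleotide diversity at nonsynonymous vs synonymous sites
  from per-individual coding sequences reconstructed off the reference +
  VCF, with Nei–Gojobori site counting; aggregated over concatenated gene
  sets, gene-space windows, GC3 bins, and GC-conservative sites.
* **Classical statistics** — Ho, Weir–Goudet βST (negative values flag
  ancestral populations), windowed Tajima's D, pairwise Weir–Cockerham FST,
  LD decay, and an FST-based NJ population tree with root-to-tip distances.
* **DFE and α** — a maximum-likelihood fit of the GammaExpo distribution of
  fitness effects to unfolded synonymous/nonsynonymous SFS pairs under a
  Poisson random field, with nuisance distortion (`r_i`) and misorientation
  (ε) parameters; from the fit, `ω_NA = ∫ φ(S)·S/(1−e^{−S}) dS`,
  `ω_A = dN/dS − ω_NA`, and `α = ω_A/(dN/dS)`.
* **Recombination and residual tetraploidy** — diploid vs tetraploid
  compartment contrasts with gene resampling nulls and GC-matched bins, and
  chromosome-length-corrected transposable-element comparisons.
* **Synthetic data** — a Wright–Fisher forward simulation of a 1-D
  stepping-stone expansion (gamma DFE, partially recessive dominance,
  neutral synonymous sites, diverged outgroup panels) emitting VCF, GFF3,
  FASTA, BED and TSV files plus truth tables.

## Worked example

```python
from surfload.pipeline import analyze, bundle_from_simulation
from surfload.simulate import ExpansionConfig, simulate_expansion

ds = simulate_expansion(ExpansionConfig(seed=11))   # 10 demes, N=500, K=10
res = analyze(bundle_from_simulation(ds), seed=11)
print(res.metrics[["ho", "recessive_missense", "pin_pis", "alpha"]])
```

Running `examples/02_polarize_and_load.py` (same seed) prints:

```
ancestral allele assigned at 1605/1632 sites (90% outgroup-homozygosity rule)

missense load per deme (mean over individuals):
population  additive_mean  recessive_mean
     pop01          89.50           26.25
     pop02          89.80           26.50
     ...
     pop09          88.85           35.15
     pop10          83.60           33.85

ANOVA across demes (recessive load): F = 35.33, p = 4.11e-36
```

The recessive (homozygous-derived) missense burden climbs ~30% from the
source deme (`pop01`) to the expansion front while the additive burden
barely moves — the signature of founder-event homozygosity exposing
partially recessive deleterious alleles. `examples/05_population_structure.py`
shows the demographic side of the same history: βST lowest in the oldest
demes, FST-tree root-to-tip distances ranking the founding order, and
heterozygosity declining with distance (adjusted R² = 0.94 in that run).

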