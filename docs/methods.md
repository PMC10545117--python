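# Methods

`surfload` quantifies *expansion load*: the accumulation of deleterious
variation in populations that colonized new territory through repeated
founder events. At an expansion front, effective population size is
transiently tiny, drift overwhelms selection, and deleterious alleles can
rise in frequency or fix by "surfing" the wave of colonization. The package
implements the full measurement chain — allele polarization, load counting,
πN/πS, DFE-based selection efficacy — plus a forward simulator that
generates data with exactly this structure for validation.

## Ancestral and derived alleles

A focal SNP's ancestral allele is inferred from outgroup genotype panels:
the modal homozygous outgroup allele is accepted if (i) at least 90% of the
non-missing outgroup individuals are homozygous for it and (ii) it matches
one of the two focal alleles; otherwise the site is left unpolarized and is
excluded from load analyses. "90%" is applied to non-missing individuals,
pooled across outgroup species (a per-species consensus option exists but is
off by default). Genotypes are then re-expressed as derived-allele dosages.

## Load counting

Per individual and effect class (synonymous / missense / loss-of-function,
supplied by an external annotation or by the simulator):

* additive (total) load `N_total = 2*N_homo + N_hetero`,
* recessive (fixed) load `N_homo`,

over non-missing polarized genotypes. Counts are not normalized by
sites-used by default (a `per_site` option exists). Sites where the derived
allele is fixed in every population are included. Among-population
differences use one-way ANOVA followed by Tukey HSD, Bonferroni-corrected
across contrasts.

Note on the neutral control: under pure drift the *additive* neutral load is
a martingale (E[q] constant), so it shows no deme trend; the *recessive*
neutral count tracks E[q²], which rises with drift toward the front. Tests
therefore use additive synonymous load as the flat negative control.

## πN/πS

Per-individual coding sequences are rebuilt from the reference and the
genotype matrix ("vcf2fasta"): two pseudo-haplotypes per individual,
unphased heterozygotes assigned uniformly at random under a recorded seed
(all frequency-based statistics are invariant to this choice; the allele
counts are conserved by construction and tested). Transcript choice is
longest CDS, ties broken lexicographically.

Site counting follows Nei–Gojobori (1986) equal-weight counting with
mutational paths through stop codons excluded from the denominators. Codon
columns containing N or a gap in any haplotype are excluded alignment-wide;
per-site diversity uses the unbiased `2p(1-p)·n/(n-1)` form. πN/πS over a
gene set is a ratio of summed differences to summed site totals
(concatenation, not a mean of per-gene ratios). Aggregations: greedy packing
of genes in genomic order into windows of concatenated CDS ("gene-space")
length, equal-count GC3 bins (ascending GC3, default 20 bins), and a
GC-conservative subset (A↔T, C↔G) immune to GC-biased gene conversion.

## Classical statistics

Ho (heterozygote fraction), Weir–Goudet βST from matching proportions
(within-population matching uses distinct draws; cross-population matching
uses frequency products; ratio of averages over loci — negative values flag
populations closest to the ancestral gene pool), windowed Tajima's D
(100 kb default, complete genotypes only, population mean over windows with
S ≥ 3), pairwise Weir–Cockerham (1984) FST as a multi-locus ratio of
averages, LD decay as dosage r² in log-spaced distance bins (missing
dosages mean-imputed per site) with a half-maximum distance summary, and a
neighbor-joining tree on the FST matrix rooted at the minimal-βST
population, with root-to-tip distances as an expansion-order proxy.

## DFE and the rate of adaptive evolution

The core model is a Poisson random field over the unfolded SFS. Synonymous
classes are neutral, `E[syn_i] = θ_s · r_i / i`. Nonsynonymous classes
integrate the diffusion sojourn density

    H(x; S) = (1 − e^{−S(1−x)}) / [x(1−x)(1 − e^{−S})],  S = 4Ne·s,

against a GammaExpo DFE: reflected gamma (shape β, mean `mean_Sd` < 0) plus
an exponential beneficial tail (fraction `p_b`, mean `mean_Sb`). Nuisance
parameters: per-class distortion multipliers `r_i` (r₁ ≡ 1, shared between
syn and nonsyn so that demography cancels from the DFE) and an ancestral
misorientation probability ε that mixes class i with n−i.

Identifiability: a single mutational input is shared between classes,
`θ_n = θ_s · L_nonsyn/L_syn` (default `couple_theta=True`). This is what
makes the DFE *scale* identifiable — the overall deficit of nonsynonymous
polymorphism relative to mutational opportunity measures how much of the
gamma is effectively invisible. With both θ free, the SFS-only likelihood
is flat in `mean_Sd` over two orders of magnitude and only β is estimable.
Even with coupling, `mean_Sd` is variance-limited: at θ = 5000 the MLE
recovers log10|mean_Sd| within ±0.5 in roughly 85% of replicates; the
remaining misses are genuine maximum-likelihood outcomes on a β↔p_b ridge,
not optimizer failures.

Numerics: the x-integral uses Gauss–Legendre on a logistic grid
(x = σ(y), 400 nodes on y ∈ [−30, 30]), which cancels the x(1−x)
denominator of H and is exact in the neutral limit; the |S|-integral uses
Gauss–Legendre on log10|S| ∈ [−4, 5] (160 nodes) with the gamma mass below
10⁻⁴ treated as exactly neutral. The quadrature mass of φ(S) reproduces 1
to 10⁻⁸. Likelihood: independent Poisson over the 2(n−1) classes,
multi-start L-BFGS-B (≥5 starts, recorded seed) on log/logit-transformed
parameters. GammaZero (p_b = 0) and GammaExpo are compared by AIC
(reported, not enforced).

From a fit, `ω_NA = ∫_{S<0} φ(S)·u(S) dS` with relative fixation rate
`u(S) = S/(1 − e^{−S})`, `ω_A = dN/dS − ω_NA`, `α = ω_A/(dN/dS)`; observed
`dN/dS = (D_n/L_n)/(D_s/L_s)`.

SFS construction applies alignment QC mirroring standard practice: a site
needs ≥10 ungapped haplotypes, sequences with >50% gaps are dropped, genes
need ≥6 complete codons, internal stop codons outside 20-codon terminal
tolerance zones disqualify a gene, and sites are down-projected to n = 8
haploids by expected (fractional) hypergeometric masses for determinism.
Divergence is counted per codon position against an outgroup comparator
sequence by direct substitution classification in the focal consensus codon
context, without a Ts/Tv correction; a hook exists to substitute a corrected
counter. Polarized ancestral states come from the outgroup *consensus*; the
divergence comparator defaults to the *nearest* outgroup sequence, which
carries enough substitutions to estimate dN/dS at desk scale (the consensus
approximates the ancestor and leaves almost none).

For per-population fits inside the pipeline the default is GammaZero
without distortion/misorientation (5 free parameters): at n = 8 the richer
parameterization is underdetermined per population and, importantly, the
demographic distortion of a front deme's SFS *is* part of the relaxed-
selection signal the α gradient measures. The full GammaExpo machinery is
the module-level default and is what the recovery experiments exercise.

## Ploidy and TE contrasts

Genes are partitioned into diploid vs residual-tetraploid compartments by
chromosome rule (31–38 tetraploid) or an explicit BED (BED wins when both
are given). The tetraploid πN/πS is compared to a null of 200 resamples of
4000 diploid genes (without replacement; scaled to half the pool when the
pool is smaller); the observed value is placed as a mid-rank quantile. The
GC-matched contrast computes window GC in fixed genomic windows per
compartment and compares the lowest-GC fraction (default bottom quintile;
the simulation-scale tests use half) against the rest, per compartment —
isolating recombination from ploidy. TE content is compared as TE length
divided by chromosome length, two-sided Mann–Whitney between compartments.

## Spatial regressions

Populations are the unit of analysis; every metric is regressed by OLS on
expansion covariates (distance to the southernmost site, distance to
ocean), with an exclusion list for outlier-sensitivity runs. Both plain and
adjusted R² are reported.

## Synthetic data

The generator is a discrete-generation Wright–Fisher forward simulation of
a 1-D stepping-stone expansion with study-condition defaults: 10 demes of
N = 500 diploids, founder size K = 10, a new deme founded from the front
every T = 50 generations, symmetric neighbor migration m = 0.01, and
sampling 25 generations after the last founding. Two design choices matter
most:

* **Slow regrowth** (factor 1.1/generation after founding). A founded deme
  spends ~40 generations below carrying capacity, which is what sustains
  allele surfing. With instant regrowth the dominant effect of a founder
  event is the *loss of rare deleterious variants*, and the πN/πS gradient
  reverses — a useful reminder that expansion load requires a persistent
  small wavefront, not just a bottleneck.
* **Desk-scale rescaling.** The per-bp mutation rate is 5×10⁻⁶ (a realistic
  8×10⁻⁹ rescaled by ~600 to keep 4Nμ, and all 4Ns products, in a realistic
  range at N = 500). The genome is 120 genes of 33 codons spaced 10 kb on
  five chromosomes — many short genes give many quasi-independent
  genealogies, which is what tightens per-deme πN/πS.

Fitness is multiplicative per site, (1, 1+hs, 1+s). Synonymous changes are
neutral; nonsynonymous coefficients come from a gamma (shape 0.3, mean
s = −0.03, i.e. mean |4Ns| = 60) with a 0.5% exponential beneficial tail
(mean s = +0.01); |s| is capped at 0.95. Dominance: h = 0.3 for missense,
h = 0.02 for the LoF class (stop-gains plus the top 30% of the deleterious
gamma) — severe mutations are nearly fully recessive, which both shelters
them in heterozygotes and lets front-deme homozygosity expose them, the
mechanism behind the recessive-load gradient. Burn-in seeds deme 1 with an
msprime coalescent sample at equilibrium followed by a 150-generation
forward selection burn-in that purges excess deleterious standing
variation. Recombination is modeled between genes (crossover 0.5 between
chromosomes and high-recombination neighbors, 0.02 within the
low-recombination class); low-recombination genes also carry a
selection-efficacy multiplier of 0.15 on |s|, an explicit stand-in for
Hill–Robertson interference that a desk-scale simulation cannot generate
mechanistically, and are written with low GC/GC3 (mirroring absent
GC-biased gene conversion). The tetraploid compartment (chr31, 25% of genes, of which two thirds
form the low-recombination block) differs
from diploid chromosomes only through this recombination class structure —
tetrasomic inheritance itself is not simulated.

Outgroups: three species diverge from the same ancestor at 1.0/1.4/1.8%
with substitutions thinned by the expected fixation rate under the DFE
(synonymous always accepted, nonsynonymous with probability ≈ ω), so
outgroup divergence carries a realistic dN/dS; five individuals per species
with small within-species polymorphism. The emitted reference FASTA carries
the ancestral allele at every site (so REF = ancestral; polarization flips
are exercised by unit tests rather than by the simulation). The per-site
fixation probabilities of the forward kernel match the diffusion u(S)
within Monte-Carlo error (tested on a semidominant S grid; note with
fitnesses (1, 1+s/2, 1+s) the per-copy effect is s/2, so S = 2Ns).

What the generator does *not* emulate: real intron/intergenic variation
(intergenic sequence is random with compartment-specific GC), linked
selection arising mechanistically, gene conversion, tetrasomic genotyping
artifacts, sequencing error and missingness (genotypes are complete), and
real geographic geometry (distance covariates are linear in deme index).
Passing tests therefore demonstrate that the *measurement chain* recovers
known signals of the expected kind and magnitude ordering, not that any
particular real dataset would yield them.

## Problem sizes in the test suite

The acceptance tests run 20 replicates of the default expansion
(~30 s each) shared across criteria through a session fixture; DFE recovery
uses 10 PRF replicates at n = 20, θ = 5000; oracle-equivalence tests use
≤ 50-site toys. The gradients (Ho, recessive missense and LoF load, πN/πS, α,
additive-vs-recessive CV ordering) carry the expected sign in ~85–100% of
replicates; πN/πS is the noisiest (~85%).

## Known limitations

* `mean_Sd` is weakly identified by construction (see above); report it
  with its recovery variance in mind.
* Divergence counting is single-step per codon position; saturated or
  multi-hit codons are approximated through the consensus context.
* The NJ/βST rooting of the population tree is a proxy for ancestry, not an
  inference; use an explicit outgroup root when one exists.
* The simulator's fitness model is monoecious with selfing allowed;
  inbreeding coefficients at tiny founder sizes are slightly higher than in
  a dioecious model.
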