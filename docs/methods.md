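# Methods

## Genotype model and conventions

All stages share one container: an `n_samples × n_variants` dosage matrix
counting copies of `allele2` (0/1/2, −1 missing), a sample table with a
population label, and a variant table (integer autosome, 1-based bp
position, id, two allele codes). Variants are stably sorted by
`(chrom, pos)` on load; all distances are `|pos_i − pos_j|` in bp; only
intra-chromosomal pairs are ever formed. Dosage orientation is arbitrary
for r² but fixes the sign of r, which the phase-persistence statistic
needs; when two cohorts code opposite alleles at a shared variant
(`allele1`/`allele2` swapped), the join flips the r sign of the affected
pairs rather than touching genotypes.

PLINK 1.9 bed/bim/fam (SNP-major) is read and written natively — the format
is a fixed 2-bit code per genotype and the codec is pinned by a
hand-decoded byte-level test. VCF is read through cyvcf2; multiallelic
records are skipped and counted.

## Quality control

Variants are retained when call rate ≥ 0.95, MAF ≥ 0.05 and the exact
Hardy–Weinberg test p ≥ 1e-6 (all thresholds configurable). Removal is
attributed to the first failed filter in the order call rate → MAF → HWE;
the attribution counters depend on that order, the retained set does not.
The HWE test is the exact conditional test: with the minor-allele count
fixed, the p-value sums the conditional probabilities of all heterozygote
counts no more probable than the observed one (no mid-p correction),
computed by the stable ratio recurrence from the distribution mode. An
exhaustive test checks it against exact-rational enumeration for every
table up to n = 100.

## Two-locus EM and r²

Haplotype frequencies come from EM over the 3×3 genotype table. Every cell
except the double heterozygote resolves its two gametes deterministically;
the double-het count splits between coupling (AB/ab) and repulsion (Ab/aB)
in ratio `pAB·pab : pAb·paB` per iteration. Allele frequencies are
recomputed per SNP pair from pairwise-complete samples. Numerical
choices:

- convergence when the largest haplotype-frequency change drops below
  1e-10, with a 10,000-iteration cap (a small fraction of tables crawl
  along a likelihood plateau and need more than ~1e3 iterations to reach
  the fixed point to 1e-4);
- the iteration runs from three starts — linkage equilibrium plus both
  near-boundary phase assignments — and keeps the highest-likelihood fixed
  point, the LE solution winning ties. The LE start alone is not reliable:
  it is exactly the saddle where double heterozygotes split 50:50, and EM
  can stall there at D = 0 while the MLE sits at a phase boundary;
- the estimator is validated against a brute-force profile-likelihood grid
  over `pAB` (1e-5 resolution with local refinement), and against direct
  gamete counting wherever a table has no double heterozygote.

A composite (genotype-correlation) r² is deliberately not used; the EM
estimator matches the standard array-analysis workflow. Pairs where either
locus is monomorphic among the pairwise-complete samples have undefined LD
and are skipped and counted.

Decay curves use half-open bins `[k·w, (k+1)·w)` (default w = 10 kb to
1 Mb); a pair at exactly 10,000 bp falls in the second bin. Co-located
SNPs (distance 0) are excluded with a warning. Reported standard deviations
of binned/adjacent r² are population (divide-by-n) values, matching the
mean ± sd presentation of array summary tables; the phase statistic instead
uses the divide-by-(n−1) convention consistent with a sample correlation.

Subsampling experiments draw individuals without replacement (a size equal
to the cohort is the identity), with a with-replacement bootstrap available
behind a flag; curves are averaged bin-wise across replicates and are
reproducible from a seed.

## Haplotype blocks

|D′| = |D|/D_max with D_max = min(pA·pb, pa·pB) for D > 0, else
min(pA·pB, pa·pb). The 90% CI comes from the normalised likelihood of the
genotype table on a |D′| grid (step 0.001), allele frequencies fixed at
their EM estimates and D carrying the EM sign: `ci_lo` is the smallest grid
value with ≥ 5% cumulative likelihood at or below it, `ci_hi` the largest
with ≥ 5% at or above. Pairs within a 200 kb window are strong-LD when
`ci_lo ≥ 0.70` and `ci_hi ≥ 0.98`, strong-recombination when
`ci_hi < 0.90`; a SNP run is a candidate block when ≥ 95% of its
informative pairs are strong-LD, and candidates are accepted greedily
longest-first (leftmost wins ties) without overlap. The distance-dependent
CI exemptions that Haploview applies to 2–4-marker spans are intentionally
omitted, so block-count parity with PLINK's caller is approximate; the core
CI rule is identical.

## Persistence of phase

Signed-r records of two cohorts are inner-joined on the SNP pair (shared
variant-id space, orientation harmonised as above). Per half-open distance
interval (default 100 kb to 1 Mb) the statistic is the sample
product-moment correlation of the two r vectors — the only normalisation
bounded in [−1, 1]; intervals with < 2 pairs or zero variance are reported
missing. By default all signed r values enter; an option restricts each
interval to pairs with r > 0 in the reference population, since published
descriptions of the statistic vary on this point. Limiting behaviour is
tested: identical inputs give R = 1 exactly, independent simulated
populations stay within ±0.15 in well-filled bins, and an admixed cohort's
correlation with its source declines with distance.

## Effective population size

`N_T = (4·f(c_t))⁻¹ (1/E[r²_adj|c_t] − α)` with `t = 1/(2c_t)`,
`r²_adj = r² − 1/(βn)`. Defaults α = 1 (no mutation correction) and β = 1
(unphased genotypes), both configurable (α ∈ {1, 2, 2.2}, β ∈ {1, 2}).
`f` maps physical to genetic distance: linear at a configurable cM/Mb
(default 1), or Haldane `(1−e^(−2d))/2`, Kosambi `tanh(2d)/2`, Sved
`d/(1+2d)` applied to the linear-map distance. Bins are either explicit
distance intervals or target generations: each target t defines
`c = 1/(2t)` and a ±25% distance window around the mapped distance, which
reproduces recent-vs-historical trajectories without committing to any
tool's undocumented internal bin edges. `c_t` is evaluated at the bin
midpoint; pairs from all autosomes are pooled per bin; bins that are empty
or have non-positive mean adjusted r² are reported missing. No confidence
intervals are attached to N_T.

## The simulator and what it does (not) show

Forward Wright–Fisher on a fixed biallelic site list: 2N haplotypes are
initialised at linkage equilibrium with allele frequencies uniform on a
band (default [0.05, 0.5]), then evolve by random union of gametes. A
gamete copies one of two uniformly chosen parental haplotypes and switches
parent between adjacent sites with probability `(1 − e^(−2·rec·d))/2` — the
probability of an odd Poisson crossover count in the interval, i.e. the
exact crossover process restricted to the observed sites. Optional
symmetric per-site mutation flips alleles; sites fixed during burn-in are
retained and later removed by the MAF filter, exercising QC realistically.
Samples are `2·sample_n` haplotypes drawn without replacement, paired into
diploids. Chromosomes are simulated independently with per-chromosome seed
streams; a burn-in of 4N generations (the default) brings r² to
drift–recombination quasi-equilibrium. The simulator exposes the full
post-burn-in haplotype pool as a truth table, so exact population r² is
available for every pair.

Admixture crosses two source pools: each founder haplotype comes from pool
A with probability `founder_prop`, else B, and the founder population mates
randomly with recombination for a configurable number of generations. The
bundled two-population fixture ("purebred" N = 200 with 4N burn-in and
mutation 1e-4 to keep the MAF spectrum populated; "crossbred" = 45
individuals from a 3-generation cross of an N = 100 purebred descendant
with an independent N = 100 population; 24 chromosomes of 2 Mb with 45
evenly spaced SNPs ≈ 45 kb apart at 1 cM/Mb; 2% missingness) mirrors the
shape of a two-cohort array study at a size small enough for routine
testing.

Deliberate simplifications, hence what passing tests do not show about real
data: no selection, no gene conversion, no sex chromosomes, no site
ascertainment bias (real arrays enrich intermediate frequencies), even
marker spacing, a uniform recombination map, and a recent-admixture
crossbred whose short-range LD is *higher* than the purebred's — the
reverse of a long-established composite breed, where decades of
recombination have eroded admixture LD. Results on the fixture validate the
estimators' internal consistency, not any particular species' LD landscape.

## Validation problem sizes

The acceptance script re-measures every headline quantity at sizes chosen
so Monte-Carlo error does not dominate the estimand: 500 random two-locus
tables for the EM-vs-oracle check; every HWE table to n = 100 (89,725
configurations); 300 replicate 2 Mb chromosomes (N = 100, 2.5 cM/Mb) for
the Sved comparison; 150 replicate chromosomes per N ∈ {50, 100, 200} for
Ne recovery; 60-chromosome cohorts for the phase limits; and 30 replicates
per subsample size for the inflation check. With those sizes the worst
Sved-bin deviation is a stable ≈ 16% (largest in the lowest-recombination
bins, where MAF conditioning and the drift transient bias r² upward
slightly) and Ne medians recover truth within a few percent.
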