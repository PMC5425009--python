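# Methods

`polymap` re-implements, as a tested and reusable pipeline, the two-pronged
strategy used to localize the gene for a completely dominant binary trait —
polydactyly in the Beijing fatty (BF) chicken — from (i) a case/control GWAS
on a three-generation backcross of a purebred polydactylous BF line to the
normal Shiqiza (SZ) breed and (ii) a whole-genome divergence scan between
small trait-fixed and trait-free resequencing panels. Because the original
study deposits no genotype data, the package ships a first-class simulator
that generates cohorts with the statistical structure the analyses assume;
everything downstream is exercised end to end against it.

## The simulated study

### Genetic model

Variant sites are biallelic (SNPs plus a configurable fraction labelled as
InDels, 10% by default — InDels differ from SNPs only in allele strings and
in being tabulated separately by the opposite-homozygote scan). Founder
allele frequencies for the two breeds follow a Balding–Nichols model: an
ancestral frequency π ~ Uniform(0.05, 0.95) per site and, for each breed,
p ~ Beta(π(1−F)/F, (1−π)(1−F)/F) with divergence parameter
F = `founder_fst`. The default F = 0.10 is a typical SNP-level F_st between
distinct indigenous chicken breeds. At F = 0 both breeds share π exactly.

Around the causal position the donor breed is fixed for a "swept" haplotype
(alt alleles across `causal_pos ± sweep_halfwidth`, 200 kb by default, i.e.
a 400 kb fixed region), reflecting the strong artificial selection that
fixed the trait in the purebred line; the recipient breed carries zero
copies of the causal allele. The causal allele is completely dominant with
penetrance 1.0 by default (`penetrance` is a knob; non-carriers are never
affected).

The donor individual entering the cross is drawn fully inbred: one
haplotype sampled from the donor-breed frequencies and duplicated. This
models a closed purebred line maintained by within-line matings for many
generations, which is also the design assumption of the original breeding
program (a line with 100% penetrance, and resequencing animals "presumed
homozygous"). It matters statistically: an outbred donor heterozygous at a
site tightly linked to the causal locus can transmit an allele whose F2
dosage vector is *identical* to the phenotype vector, which would make the
causal site structurally impossible to rank first. Recipient-breed
individuals (the SZ progenitor and the dams) are outbred Hardy–Weinberg
draws, as is the donor breed at large (the resequencing panels).

### Transmission

Meiosis uses the Haldane map: crossover counts per chromosome are Poisson
with mean (length in Mb) × `recomb_rate` / 100 Morgans (default 3 cM/Mb, a
chicken macrochromosome scale), crossover positions uniform, no
interference. The cohort comprises 1 donor male × 1 recipient female → 1 F1
sire, mated to `n_families` recipient dams (11) → `n_f2` offspring (98)
assigned to dams round-robin: 112 individuals in 11 families, mirroring the
mapping population being emulated. The fraction of each F2 genome inherited
from the donor founder is tracked through meiosis and exposed
(`SimulatedCohort.bf_fraction`) for structure diagnostics.

### Genome fixture and random streams

The default genome is a three-chromosome miniature — "1" (20 Mb), "2"
(15 Mb), "9" (5 Mb) — with 1,666 sites per chromosome (~5,000 total) and
the causal site at 8,460,000 bp of chromosome "2", so per-chromosome
count/density comparisons and the candidate-interval logic are exercisable
at desk scale. Random streams are split per stage (sites/frequencies,
founder draws, meiosis, phenotypes, panels) from one seed, so changing the
number of sites does not perturb phenotype draws, and a seed fully
determines every output down to the emitted VCF/FAM bytes.

### What the simulator does not emulate

Genotyping error and missingness (injectable in tests, not generated),
coalescent ancestry within breeds (sites are exchangeable given their
frequencies; background LD within a breed is absent — LD in the cohort
arises only from the cross), sex chromosomes (sex is recorded but
transmission is autosomal; the trait under study is autosomal), and
morphological trait subtypes. Passing tests therefore demonstrate that the
analyses recover the signal their models assume, not that they are robust
to artifacts real data may carry.

## Analysis components

**QC** (`qc`). Sites are retained iff MAF ≥ 0.05, missing rate ≤ 0.5 and
exact-test HWE p ≥ 1e-6 (all thresholds exposed). MAF uses non-missing
alleles only; a fully missing site fails with reason `MISS`. The HWE test
is the exact conditional test: all heterozygote counts compatible with the
observed allele counts are enumerated and the probabilities of tables no
more probable than the observed one are summed (a chi-square variant sits
behind a flag). LD pruning is greedy within sliding windows of 50 sites
advancing by 5: while any retained pair exceeds r² = 0.2 (dosage
correlation, pairwise-complete), the lower-MAF member of the worst pair is
dropped (ties drop the larger index).

**Structure** (`structure`). Identity-by-state similarity (per-site
1 − |gᵢ − gⱼ|/2, averaged over shared called sites) feeds classical MDS of
the distance 1 − IBS: double-centering of −d²/2, top-k eigenpairs,
coordinates scaled by √eigenvalue, eigenvector signs fixed so the
largest-magnitude entry is positive (run-stable output). The first two
components are the association covariates. At desk-scale marker counts
(a few thousand sites) the leading component separates the pedigree groups
(donor ≫ F1 > F2 > dams) but the per-sample correlation with realized
donor-genome fraction is noisy (ρ ≈ 0.4–0.9 across seeds); tens of
thousands of markers, as in a real reduced-representation study, would be
needed for a tight per-sample gradient. Note also that in a two-line cross
LD pruning preferentially removes ancestry-informative sites, since they
are all mutually correlated through ancestry.

**Logistic association** (`assoc.logistic_assoc`). Case status is
regressed on alt dosage plus covariates by maximum likelihood (batched
Newton with step-halving; samples with a missing genotype are dropped per
site). Reported betas/ORs are the ML estimates when the fit converges to a
finite interior optimum; under (quasi-)separation the Firth (Jeffreys
penalty) estimates are reported and flagged. P-values are penalized
likelihood-ratio tests computed uniformly for every site, with the
constrained fit profiling the nuisance parameters under the full-design
penalty. The choice of penalized LRT over Wald is deliberate: with a fully
penetrant dominant locus the causal site separates cases from controls
perfectly, and Wald statistics collapse as separation is approached
(Hauck–Donner), so a near-perfect neighbour would rank above a perfect
one; the penalized LRT is the one scale on which all sites, separated or
not, are comparable — and it preserves the perfect > near-perfect
ordering.

**Mixed linear model** (`assoc.compute_grm`, `reml_fit`, `mlm_assoc`). The
GRM standardizes dosages by 2p(1−p) with sample frequencies (off-diagonals
of unrelated pairs therefore center at −1/(n−1)). The 0/1 phenotype is
treated as quantitative, as the referenced mixed-model software does for
case/control. Variance components of y = Xβ + g + e, g ~ N(0, G σ²_g), are
estimated once on the null model by REML: the GRM is eigendecomposed,
reducing REML to a one-dimensional profile over the heritability ratio
(total variance profiled analytically), scanned on a coarse grid and
polished by bounded scalar minimization — components are non-negative by
construction and the optimum cannot land in a local well. Non-PSD GRMs are
spectrum-shifted with a warning. Per-site effects are GLS with
V = G σ̂²_g + I σ̂²_e fixed (no per-SNP refit, no leave-one-chromosome-out)
and Wald chi-square p-values.

**Significance and annotation.** Bonferroni threshold α/m with strict
inequality. Nearest-gene distance is 0 inside a (0-based half-open) BED
interval, otherwise the bp gap to the closest interval end on the same
chromosome; ties keep the first-listed gene.

**Selection scan** (`selscan`). Per-site Weir–Cockerham (1984)
two-population variance components (a, b, c) from genotype counts,
including the observed-heterozygosity terms — the sample-size correction is
essential at three diploids per group. A Hudson-style frequency-only
estimator is available for comparison. Windows of 100 kb sliding by 10 kb
are anchored at position 0 and truncated at chromosome ends; window F_st is
the ratio of sums Σa / Σ(a+b+c) (per-site averaging would be upward-biased
in sparse windows); sites with a+b+c = 0 contribute nothing. Windows enter
the empirical distribution only with ≥ `min_snps` contributing sites
(default 5; this floor scales with the ~11 sites expected per 100 kb window
at the default marker density — its purpose is only to keep pure-noise
windows out of the tail, and at 3v3 a ≥5-site window cannot reach the
fixed-difference outlier level by chance). The outlier threshold is the
minimum F_st among the top ⌈0.001·N⌉ qualifying windows (the "lower bound
of the highest 0.1%", not an interpolated quantile); outlier windows are
windows at or above it, merged into maximal regions when overlapping or
bookended. The top region has the highest peak F_st, ties resolved toward
more merged windows, then wider span.

**Opposite homozygotes.** A site qualifies when every individual of one
panel is homozygous for one allele and every individual of the other panel
homozygous for the other; by default any missing call disqualifies
(`require_complete`). SNPs and InDels are tabulated separately;
per-chromosome tables report counts and counts per Mb sorted by density.

**Inheritance analytics** (`inheritance`). Per-mating penetrance grouped
by sire (default; dam and pair grouping available), with selection
thresholds read strictly ("above 90%" excludes exactly 0.90). The
reciprocal-cross check pools offspring counts by carrier-parent sex and
applies the two-sided Fisher exact test (sum of hypergeometric
probabilities ≤ observed; no mid-p). Dominance expectations are Mendelian
transmission probabilities times penetrance; segregation fits are exact
two-sided binomial tests. The candidate-site contingency analysis builds
the 2×3 phenotype-by-genotype table, collapses it to carrier/non-carrier,
and reports carrier penetrance and the Fisher p of the collapsed 2×2.

## Numerical and tie-breaking choices

- Genotype codes are alt-allele dosage; "A1" in reports is the alt allele,
  so OR orientation is unambiguous. Phase is ignored.
- Logistic engines: Newton/Firth iterations run on the shrinking set of
  unconverged sites; singular information matrices mark a site dead
  (results NaN) rather than aborting the batch; LRT statistics are clamped
  at 0; p-values lie in (0, 1].
- End-to-end checks of "the minimum p occurs at the causal site" treat
  perfectly collinear proxies (e.g. an allele-flipped fixed difference with
  zero recombinants in the cohort) as ties, using a 1.05 relative
  tolerance on p; genuinely distinct sites differ by orders of magnitude.
- Degenerate inputs: constant phenotypes, empty window distributions,
  all-missing sites, pairs sharing no called site, and singular V all raise
  with specific messages; degenerate (all-equal) F_st distributions warn.

## Problem sizes

Default end-to-end runs use the ~5,000-site, 112-sample cohort and 3v3
panels described above; multi-seed properties use 50 replicates. Parameter
recovery uses 12,000 sites / 50 diploids per breed for divergence (block
jackknife for the SE) and n = 500 with a 1,000-site GRM over 100 replicates
for heritability. Exact-test oracles are enumerated exhaustively for all
tables with n ≤ 30 and logistic odds ratios for all non-degenerate 2×2
tables with n ≤ 40.

## Known limitations

- The genome-scale counts of the original study (hundreds of thousands of
  RAD SNPs, millions of resequencing variants, specific opposite-homozygote
  totals and the F_st threshold 0.72) depend on the unavailable raw data
  and are out of scope; the pipeline reproduces the *logic* at desk scale.
- The MLM treats a binary trait as Gaussian; with 112 samples and a fully
  penetrant locus this is the intended cross-validation device, not a
  calibrated test for small effects.
- The simulator's exchangeable-site model carries no within-breed LD, so
  LD-pruning behaviour on real data (where background LD exists without
  ancestry differences) is only partially represented.
- Window/step robustness holds when `min_snps` scales with expected marker
  count per window; at 50 kb windows and desk-scale density a floor of 10
  would empty the distribution.
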