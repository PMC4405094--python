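# Methods

## The mixed ("animal") model and its estimator

Every variance-partitioning stage fits

    y = X b + sum_k Z_k u_k + e,    u_k ~ N(0, s2_k K_k),   e ~ N(0, s2_e I)

where `y` stacks possibly repeated trait records, `X` codes sex and
age-at-measurement as multilevel factors (treatment contrasts, aliased
columns dropped by a pivoted-QR rank check), and each random term is
either GRM-structured (`K_k` a genomic relatedness matrix over
individuals) or a plain grouping effect (`K_k = I` over birth years,
measurement years, or individual identity for the permanent-environment
term). Maternal effects are deliberately not modelled: in adult
body-size data they explain little variance and requiring maternal
identity would shrink the sample.

REML maximises `-1/2 [log|V| + log|X'V^-1 X| + y'Py]` by
average-information updates with step halving; a move that would take a
component negative is truncated at a floor of `1e-6 * var(y)` and
components pinned there with an outward gradient join an active set
(reported as 0, SE flagged absent). Convergence requires a relative
logL change below 1e-8 and a projected gradient norm below 1e-4 within
200 iterations; a failed fit restarts once from perturbed starting
values (the default start splits `var(y)` equally across components).
At a boundary optimum the logL is re-evaluated with pinned components
at exactly 0 so nested models remain comparable. Standard errors come
from the inverse AI matrix; ratio SEs (h2 and per-unit shares) use the
first-order delta method. An indefinite covariance structure aborts the
fit naming the term — but GCTA-form GRMs built from few markers are
*mildly* indefinite by construction (their diagonal is not the Gram
diagonal), so eigenvalues down to -5% of the largest are tolerated and
a non-positive-definite starting `V` instead shifts starting weight to
the residual.

Nested models (with/without one genomic term) are compared by
`LRT = 2 (logL_full - logL_reduced)`, floored at 0, against
chi-square(1). The plain chi-square(1) reference is used by default —
matching the source analysis — even though the component lies on the
boundary under the null, which makes the test conservative; the
half-half mixture reference is available via
`varcomp.lrt_pvalue(..., boundary_mixture=True)`.

## GRMs, partitioning and the window rule

The GRM is the allele-frequency-weighted (Yang/GCTA) estimator, with
its distinctive diagonal, computed from dosages mean-imputed at
`2 p_i`; allele frequencies default to the full genotyped sample and
are shared between a unit and its complement, which makes the
decomposition `m_tot A_tot = m_unit A_unit + m_comp A_comp` exact (the
complement GRM is derived by this linearity, never recomputed).
Sampling-error shrinkage of off-diagonals
(`beta = var_true / (var_true + c/m)`) is implemented but **off** by
default: in the source analysis adjusted and unadjusted components
differed very little, and the exact adjustment used there is not
documented.

Sliding windows hold 150 adjacent SNPs, start 75 apart, and are
retained only with at least 113 SNPs; indices run in genome order.
Chromosome partitions carry nominal P values (no multiplicity
adjustment, by design); the regional threshold divides alpha by *half*
the converged-model count because consecutive windows overlap by half.
Non-converged units are reported and excluded from sums, never silently
dropped. The length regression is OLS of per-chromosome h2 on physical
length (Mb) with a two-sided slope test; a variance-scale variant is a
flag away.

## Two-stage association

Stage one extracts `e_hat = s2_e P y` from the whole-genome animal
model — i.e. the phenotype minus fixed-effect predictions *and* the
BLUPs of every random term — and averages repeats per individual.
Stage two computes, per SNP, `chi2 = n r^2` between mean residual and
minor-allele dosage (pairwise-complete over missing calls) against
chi-square(1), plus the OLS slope as the residual-scale effect. Because
the polygenic BLUP absorbs part of every SNP's signal, the statistics
are deflated (lambda < 1); lambda is reported as a diagnostic and no
genomic-control rescaling is applied by default. Ties for the top SNP
break by smaller bp then id. Candidate SNPs are refitted inside the
mixed model as a dosage covariate: `a` is the covariate estimate (Wald
test from `(X'V^-1X)^-1`), `V_SNP = 2 p q a^2` with the minor-allele
frequency taken from the full genotyped sample, `h2_SNP = V_SNP / V_P`
and the `V_A` share uses the genomic component of the joint fit.

## Fitness, selection and the gene-drop null

AS is survival past the annual census date; AR counts offspring born
that year that survived their own first census; LR sums AR over life;
LBS counts all offspring but is restricted to a configurable
birth-cohort window so animals still alive (or with sparse late
parentage data) do not bias it. Relative fitness divides genotype means
by the best genotype mean, `s = 1 - w`, with percentile bootstrap CIs
over individuals (default 1000 resamples, fixed seed); genotype classes
under 5 individuals are flagged as unstable. The equilibrium frequency
`q = s1/(s1+s2)` is only defined under heterozygote advantage and the
function refuses otherwise. The Bayesian hierarchical GLMMs of the
source analysis are out of scope; `genotype_fitness_glm` is a clearly
labelled frequentist stand-in (Poisson/binomial GLM with genotype as a
factor) used for synthetic validation only.

The gene-drop null conditions on the realized pedigree: founders
(animals with an unknown parent) keep observed genotypes — ungenotyped
founders draw from the observed founder frequency — descendants
receive one allele per parent by Mendelian sampling, and yearly
frequencies are recomputed over the same membership sets. The one-tailed
P follows the sign of the observed OLS slope; both tails are returned.
Two oracles guard this machinery: the conditional mean of the drop must
equal the closed-form martingale recursion over the pedigree, and the
empirical P under a neutral forward simulation must be uniform. (The
martingale oracle caught a real defect during development: numpy
boolean addition is logical-or, which silently capped het x het
offspring at dosage 1.)

## Haplotype sharing

Cores are the focal SNP plus three upstream and two downstream
neighbours — six SNPs *including* the focal one (the common "six
flanking SNPs" phrasing only reaches six this way). Rare cores are
dropped below a count threshold; the default is 5 observations, but the
threshold must be read relative to panel size (5 of ~11 000 chromosomes
in the source data is ~0.05%; desk-scale panels of ~100 chromosomes use
3). For each pair of carrier chromosomes the scan walks outward from
the core's edges and the HS length is the bp distance between the last
matching SNPs — so an immediate mismatch on both flanks returns the
core's own span and `HS >= core span` is an invariant; with no mismatch
inside the window (default ±5 Mb) the tract truncates at the window's
terminal SNPs. Pairs are never collapsed across cores that differ only
outside the window. The vectorized implementation is tested for exact
equality against a per-pair scalar scan.

## The synthetic-data generator

The generator's job is to produce the *statistical structure* the
analyses assume, at desk scale:

- **Founder LD** comes from a small ancestral pool (default 12
  haplotypes) whose allele assignments are autocorrelated along the
  chromosome; founders are block mosaics of the pool, so LD decays with
  distance mechanistically and descendants share genuine IBD segments.
  Realized founder minor-allele frequencies are clamped into the
  configured MAF range (default 0.05-0.5).
- **Transmission** is Poisson-crossover meiosis on a uniform 1 cM/Mb
  map without interference; demography is yearly overlapping-generation
  breeding with random mating among survivors (sex ratio 1:1, survival
  0.72/yr), with an optional complete-turnover mode for clean
  generation counting.
- **Traits** sum a standardized-SNP polygenic score (effect variance
  proportional to 1/(2pq), the spectrum the frequency-weighted GRM
  assumes) scaled so per-chromosome variance is proportional to
  physical length and the realized total equals the configured
  heritability on a unit phenotypic scale; planted QTLs (low MAF,
  `V_SNP = 2pq a^2` on top), sex and age fixed effects, and birth-year /
  measurement-year / permanent-environment / residual deviations whose
  shares must sum to 1. Defaults mirror the study design: repeat rate
  2.8 measures per measured adult (roughly 2550 records on 900
  animals), h2 = 0.4.
- **Fitness** acts during the simulation (viability on survival,
  fecundity on parent sampling), so derived AS/AR/LBS/LR tables embody
  the configured neutral / additive / overdominant mode.
- **Admixture**: donor immigrants (a breed drawn from the same
  ancestral pool plus private variation) join the breeding pool a
  configurable number of generations before the end at a configurable
  proportion; donor ancestry is painted per SNP and transmitted with
  the *same* crossovers as the alleles. A donor-only QTL allele sits on
  a single donor ancestral background at moderate donor-breed frequency
  — a young haplotype, so focal and donor carriers share long flanks —
  while outgroup breeds are high-switch mosaics of the same pools and
  carry the old haplotypes broken into short tracts. Under complete
  turnover the mean donor tract length follows
  `100 / ((1 - p) g)` cM; the observed mean runs ~10-15% short of that
  because tracts are measured SNP-to-SNP and truncate at chromosome
  ends.

What the generator does **not** emulate: realistic Soay demography and
mating system, selection on the polygenic background, genotyping error,
the X chromosome, or phasing error (haplotypes are generated phased).
Passing tests therefore validate the estimators and their wiring under
the stated model, not robustness to real-data artefacts such as
mis-phasing or pedigree errors.

## Problem sizes and test design

The statistical acceptance checks run on simulated populations sized
for stable power on a single CPU: heritability recovery uses ~500
measured individuals x 1000 SNPs x 50 replicates; scan power uses ~340
founders (~800-1000 measured, matching the study's August-trait sample)
with 1800 SNPs over four chromosomes and a QTL explaining ~15% of
`V_A`, 25 replicates; the length regression uses eight chromosomes
spanning 10-120 Mb; the gene-drop uniformity check runs 200 complete
tests of 400 drops each; haplotype-sharing equivalence uses 100 random
panels and 25 introgression replicates. Published-table arithmetic
(thresholds, sums, window sizes, variance ratios) is recomputed exactly
from the printed inputs shipped in `wildarch.soay`.

## Known limitations

- The REML engine is dense-matrix and O(n^3) per iteration; it is
  comfortable to a few thousand observations but is not an asreml/GCTA
  replacement at biobank scale.
- GRAMMAR deflation is stronger at desk scale (lambda ~0.5) than in the
  source data (0.61-0.82) because the marker:sample ratio is smaller;
  the qualitative contrast (deflated two-stage vs inflated naive scan)
  is the tested property.
- The window-rule region count on the published SNP counts comes out
  slightly above the published "models attempted" figure; the
  discrepancy is an unstated edge rule in the source and region counts
  are therefore always computed from the map, never assumed.
- Selection-coefficient CIs for rare homozygote classes are wide and
  bootstrap resamples can miss a class entirely; such draws are dropped
  from the percentile, mirroring the instability the source reports for
  its rarest genotypes.
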