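# wildarch

Genetic architecture of quantitative traits in SNP-typed, pedigreed wild
populations.

Long-term studies of free-living populations (the Soay sheep of St Kilda
are the motivating system) now genotype thousands of individuals at tens
of thousands of SNPs. `wildarch` implements the analysis chain used to
ask whether a body-size-like trait is polygenic or driven by a few large
QTL, whether those QTL affect fitness, and where their alleles came
from:

- **Genome partitioning / regional heritability.** Univariate animal
  models `y = Xb + Z1 c_i + Z2 ra_i + Z_r u_r + e` are fitted by
  AI-REML, where `c_i` is structured by a genomic relatedness matrix
  (GRM) built from chromosome *i* or a sliding window of 150 adjacent
  SNPs (stepped by 75, windows under 113 SNPs dropped), and `ra_i` by a
  GRM from all remaining SNPs. Significance is a likelihood-ratio test
  against chi-square(1); regional scans use a threshold of
  `0.05 / (n_converged / 2)`. Per-chromosome variance shares are
  regressed on physical length — a positive slope is the signature of a
  polygenic trait.
- **Two-stage association (GRAMMAR).** Residuals from the whole-genome
  animal model (averaged over repeated measures) are score-tested
  against every SNP (`n r^2` vs chi-square(1)); the genomic inflation
  factor lambda diagnoses the deflation this two-stage shortcut causes
  in family-structured data. Top SNPs are refitted inside the mixed
  model as a dosage covariate; a SNP's variance is `V_SNP = 2 p q a^2`
  and is reported as a share of `V_P` and of `V_A`.
- **Selection at QTL.** Annual survival (AS), annual recruits (AR),
  lifetime breeding success (LBS) and lifetime recruits (LR) are derived
  from pedigree + census records; per-genotype relative fitness `w`,
  selection coefficients `s = 1 - w` with bootstrap CIs, and — under
  heterozygote advantage — the equilibrium frequency
  `q = s1 / (s1 + s2)`. Allele-frequency trends are tested against a
  gene-drop null: founders keep their observed genotypes and every
  descendant is re-dropped through the fixed pedigree.
- **Haplotype sharing.** Six-SNP core haplotypes around a focal SNP
  (focal + 3 upstream + 2 downstream) are compared between the focal
  population and labelled reference breeds; the length of unbroken
  sharing around a core, averaged over all carrier-chromosome pairs,
  identifies the breed a haplotype introgressed from.
- **Synthetic data.** A forward simulator produces pedigreed
  populations with founder haplotype-block LD, Mendelian transmission
  with Poisson crossovers (1 cM/Mb), a length-proportional polygenic
  trait with planted QTLs, fitness records with optional heterozygote
  advantage, and a donor-breed admixture scenario — so the entire
  pipeline runs and is testable without any data download.

Standard formats are supported throughout: PLINK bed/bim/fam, phased
VCF, GCTA binary GRM triplets, and TSV tables.

## Worked example

```python
import wildarch.simulate as sim
from wildarch.grm import compute_grm
from wildarch.varcomp import build_model, fit_variance_components, variance_ratios
from wildarch import gwas

cfg = sim.SimConfig(
    n_founders=200, n_years=10,
    chromosomes=[(300, 60.0), (300, 60.0), (300, 60.0)],
    qtl_specs=[sim.QtlSpec(chromosome=1, target_maf=0.08, additive_effect=0.65)],
    polygenic_h2=0.3, random_effect_variances={"residual": 0.7},
    repeat_rate=1.0, seed=42,
)
pop = sim.simulate_population(cfg)
pheno = sim.simulate_trait_and_phenotypes(pop).drop_duplicates("id")
genotypes = pop.genotype_set()

fitm = fit_variance_components(
    build_model(pheno, "trait", grms={"a": compute_grm(genotypes)})
)
h2, se = variance_ratios(fitm, "a")["a"]
print(f"genomic h2 = {h2:.3f} (SE {se:.3f})")

scan = gwas.score_scan(gwas.grammar_residuals(fitm), genotypes)
top = gwas.top_snp(scan)
print(f"lambda = {gwas.inflation_factor(scan['chi2'].to_numpy()):.2f}; "
      f"top SNP {top.snp_id}, chi2 = {top.chi2:.1f}")

eff = gwas.refit_snp_effect(
    build_model(pheno, "trait", grms={"a": compute_grm(genotypes)}),
    genotypes, top.snp_id,
)
print(f"refit a = {eff.a:.3f} (SE {eff.se:.3f}), share of V_A = {eff.share_va:.2f}")
```

prints

```
genomic h2 = 0.327 (SE 0.064)
lambda = 0.51; top SNP c1s94, chi2 = 10.6
refit a = 0.548 (SE 0.132), share of V_A = 0.17
```

The simulated trait has heritability 0.3 plus one low-frequency QTL
(additive effect 0.65 trait SD, MAF ~0.08, `V_SNP = 2pq a^2 ~ 0.06`).
The animal model recovers the heritability; the residual scan is
deflated (lambda 0.51 < 1, the known conservatism of two-stage scans
under family structure) yet ranks the planted QTL `c1s94` top; the
mixed-model refit recovers its effect (truth 0.65 within 1 SE) and
attributes ~17% of the additive variance to it — the same pattern the
leg-length QTL show in the sheep data.

A thin CLI wraps the same functions
(`wildarch simulate|grm|regions|varcomp|gwas|run`); `wildarch run
--config cfg.yaml` executes the full pipeline and writes a manifest with
content hashes so reruns are verifiably reproducible.

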