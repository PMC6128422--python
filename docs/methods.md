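# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical conventions and the open design choices behind `longtraj`.

## Study design and model

The package analyses a cross-sectional cohort partitioned into three age
groups of one population: G1 (adults ≤ 50 years, taken as representative of
the general gene pool), G2 (50–85 years) and G3 (centenarians, ≥ 100 years).
Individuals aged 86–99 are outside the design and are never generated.  The
boundary case "age exactly 50" belongs to G1.

Because the older groups consist of survivors, a variant with an effect on
survival changes frequency across groups (*mortality selection*), and the
direction of change can differ between the mid-life and late-life windows
(*antagonistic pleiotropy / trade-offs*).  The analysis is purely
cross-sectional; no longitudinal, hazard or birth-cohort modelling is
attempted.

### Pairwise association

Per SNP and per group pair, a logistic regression of membership in the older
group on additive effect-allele dosage with sex (F=0, M=1) as covariate,
fitted by Newton–Raphson (statsmodels `Logit`; at most 100 iterations,
tolerance 1e-10) and tested with the two-sided Wald statistic — matching the
convention of the standard GWAS toolchain this pipeline mirrors.  Missing
dosage or covariate values are dropped per SNP (complete-case).  Perfect or
quasi-complete separation (|β| > 20 or se > 100), non-convergence and
constant dosage produce flagged NaN records; the pipeline continues and
excludes flagged p-values from λ and QQ summaries.  The minor-allele
frequency filter (default 0.01, computed over the union of the groups being
compared) is configurable.

Which controls enter the centenarians-vs-controls GWAS is configurable; the
default uses all controls (G1 ∪ G2).

λ is median(χ²)/median(χ²₁) with the denominator computed at full double
precision via the inverse survival function, so a constant p of 0.5 yields
exactly λ = 1.  QQ expected quantiles are −log10(rank/(n+1)); zero p-values
are clamped to the smallest positive double with a warning.

### Trajectory classes

With S_ij ≡ (p_ij < α), α = 0.01 by default, and d_ij the sign of the raw
effect-allele frequency difference:

| class | predicate |
|-------|-----------|
| A | S12 ∧ S23 ∧ ¬S13 ∧ d12=+1 ∧ d23=−1 |
| B | S12 ∧ S23 ∧ ¬S13 ∧ d12=−1 ∧ d23=+1 |
| C | S12 ∧ S13 ∧ d12=+1 ∧ d13=+1 |
| D | S12 ∧ S13 ∧ d12=−1 ∧ d13=−1 |
| E | ¬S12 ∧ S13 ∧ S23 ∧ d13=−1 ∧ d23=−1 |
| F | ¬S12 ∧ S13 ∧ S23 ∧ d13=+1 ∧ d23=+1 |

anything else is UNCLASSIFIED.  Conventions chosen where the verbal class
definitions leave room:

- "Similar frequencies" means *non-significant at the same α* used for
  significance.
- Directions come from raw frequency differences, not regression signs, so
  they are defined even when a fit is flagged; exact ties give d = 0 and
  leave the SNP unclassified.
- C and D constrain only the two contrasts against G1 (the definitions
  compare G2 and centenarians to the general population); E and F require
  both the G1–G3 and G2–G3 contrasts (a centenarian-specific shift must be
  visible against both similar groups).
- The predicates are mutually exclusive by construction (A/B vs C/D differ on
  S13, C/D vs E/F on S12, within pairs the directions conflict), which the
  test suite verifies by exhausting all 2³×3³ = 216 patterns against an
  independently coded transcription of the definitions.

Note that "every contrast significant" does not imply classification: a SNP
with f3 < f1 < f2 and all three contrasts significant satisfies no predicate.
This is intended — such a pattern matches none of the six described
trajectories.

The per-SNP combined p uses Fisher's method over the available contrasts
(−2Σln p ~ χ² with 2k df; inputs clamped at 1e-300; k adjusted when contrasts
are flagged; with k = 1 it reduces to the single p).  The combination method
is a documented assumption — the procedure this mirrors reports combined
p-values without naming a method — and a Stouffer option is provided.  The
procedure is deliberately nominal; Benjamini–Hochberg q-values on the
combined p are emitted for information only and play no role in
classification.

### PCA, least-squares projection, DAPC

PCA is fitted on the reference (control) individuals only.  Dosages are
mean-centred per SNP and divided by √(p̂(1−p̂)) with the shrunk frequency
p̂ = (1+Σd)/(2+2n) (Patterson normalisation; plain centering available);
missing entries are zeroed after centring; monomorphic SNPs are dropped with
a log line.  Loadings come from the SVD of the normalised matrix; each
loading column's largest-magnitude entry is made positive so score signs are
reproducible.

Supplementary individuals (centenarians) are placed by per-individual least
squares of their normalised non-missing dosages on the corresponding loading
rows — with complete data this is exactly ordinary projection; with missing
data it is the row-subset regression that keeps supplementary-specific
variation out of the axes.  Individuals observed at fewer markers than
retained components get NaN scores with a warning.  Supplementary SNP sets
must cover the model's SNPs; allele flips are reconciled as 2−dosage and
extra SNPs are ignored.

DAPC builds linear discriminant axes on the retained reference PCs by
solving the generalized symmetric eigenproblem S_b w = λ S_w w (axes
S_w-orthonormal), models each class as a multivariate normal with shared
within-class covariance in discriminant space, and computes posteriors
proportional to prior × density with priors proportional to class sizes
(normalised, so uniform prior rescaling is a no-op).  Defaults: 10 retained
PCs and K−1 discriminants — the source analyses do not state their retained
counts, so these are package defaults, configurable.  A singular within-class
covariance raises an error advising fewer PCs.

### Ancestry comparisons

`component_enrichment` reports both group means, their difference and a
two-sided p from Welch's unequal-variance t test (default) or the Wilcoxon
rank-sum test; the underlying test used by the analyses this mirrors is
unstated, so Welch is a documented default and both can be emitted.
`informative_snps` scores each SNP by |Pearson r| between dosage and the
component fraction (pairwise-complete); this is a documented stand-in for an
unspecified informative-marker extraction, chosen because it is
allele-flip-invariant, bounded in [0,1] and monotone in ancestry
differentiation.  Gene-level enrichment of the resulting list is out of
scope (it requires an external annotation database).

## The synthetic-data generator

`simulate_cohort` makes the mortality-selection mechanism explicit:

1. genotypes of a birth cohort drawn per SNP in Hardy–Weinberg proportions;
2. survival through the mid window with probability
   `expit(logit(base_surv_mid) + Σ_s beta_mid[s]·g_s + sex_effect·male)` and,
   conditional on that, the late window analogously with `beta_late`;
3. G3 sampled from late-window survivors, G2 from remaining mid-window
   survivors, G1 from the remaining cohort (disjoint, without replacement;
   a pool smaller than the requested size is an error naming the group);
4. ages uniform within (19,50], (50,85], [100,103]; missingness injected
   uniformly at a configurable rate (default 0).

The per-window logistic survival model is this package's choice: it matches
the logistic analysis model downstream and admits closed-form post-selection
frequency expectations (`expected_group_freqs`, an explicit sum over the
three genotypes and two sexes, with the late window weighting the *birth*
genotype distribution by the product of both windows' survival — mid-window
survivors are no longer in HW proportions, so the stages do not factorise).

Two properties of this model matter for experiment design:

- **Asymmetric selection response.** A late-window effect of −β does not
  undo a mid-window effect of +β on the frequency scale.  The class-planting
  helper `planted_class_betas` therefore solves the closed-form two-stage
  map numerically for the reverting late-window effect when planting classes
  A and B (the classes that must return to baseline in centenarians), rather
  than negating the strength.
- **Bounded upward selection.** Survival probabilities cannot exceed 1, so
  the achievable late-window differential is bounded by 1/base_surv_late;
  upward reversion (class B) needs headroom in the baseline late survival.
  The planting studies therefore run at base_surv_mid = 0.5,
  base_surv_late = 0.2 — the regime where one selection window removes a
  substantial fraction of carriers, which is what makes mortality selection
  measurable at cohort-scale sample sizes.

Planted-class simulations use one selected locus per simulated cohort (other
loci neutral): with many loci simultaneously under additive-logit selection,
each locus's marginal selection is attenuated by the polygenic variance of
the rest and no closed form holds; per-locus cohorts keep every locus exactly
at its closed-form expectation.

Defaults emulate the motivating cohort where stated — group sizes
(381, 392, 333), ~1,106 individuals — and are package choices elsewhere:
baseline per-window survivals 0.85/0.2 and a birth cohort of 8,000 (real
human survival to 100 is far rarer; the compression keeps survivor pools at
desk scale without changing the selection mechanism), male log-odds survival
effect −0.4, baseline frequencies uniform on [0.05, 0.95].

`simulate_structured` draws subpopulation frequencies from the
Balding–Nichols distribution Beta(p(1−F)/F, (1−p)(1−F)/F) around a uniform
ancestral frequency (F = 0 reduces to identical frequencies), records the
subpopulation as the recruitment-center label, and is validated against an
independent Hudson-style FST estimator.  `simulate_ancestry` draws rows from
group-wise Dirichlet(concentration × mean) laws.

What the generator does **not** emulate: linkage disequilibrium (no
trajectory claim here depends on it), fertility effects, X-chromosome
dosage, genotyping batch effects, age-assortative sampling within groups,
admixture-LD between structure and survival.  Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to these real-data features.

## Numerical conventions

- Determinism: every generator takes an explicit integer seed
  (`numpy.random.default_rng`); identical config + seed is byte-identical,
  and the `run-all` pipeline derives stage seeds from the config seed.
- p-values are clamped to (0, 1]; Fisher inputs clamped at 1e-300; QQ zeros
  clamped to the smallest positive double.
- Dosage orientation: the effect allele is recorded per SNP and every beta
  and frequency is reported relative to it.  PED input defines it as the
  first non-missing allele in file order (PED carries no reference allele);
  flipping alleles negates betas, maps frequencies to 1−f and swaps
  trajectory classes A↔B, C↔D, E↔F — an exact involution the tests verify.
- PCA rank tolerance: singular values below 1e-9 of the largest count as
  null; requesting more components than the rank is an error.
- Tie-breaks: informative-SNP ranking breaks score ties by SNP id;
  frequency ties give direction 0 (unclassified).

## Problem sizes used in validation

The validation suite runs at sizes chosen to make each statistical check
well-powered at desk scale: 2,000 SNPs for type-I calibration, 50 seeds ×
5,000 p-values for λ, 20 seeds × 60 planted loci (10 per class, groups
2000/2000/1000) for class recovery, 5,000 SNPs at FST 0.1 for
projection/membership, and 500/100 seeds for ancestry calibration/power.

## Known limitations

- The trajectory procedure is nominal by design; class counts at any α
  include the corresponding false-positive load (visible in the worked
  example, where one neutral SNP lands in class E).
- The genomic inflation factor is a scaled sample median; at 5,000 SNPs its
  sampling SD is ≈ 0.032, so single-run λ values in roughly [0.94, 1.06] are
  consistent with a null genome of that size.
- Binary PLINK (BED/BIM/FAM) and VCF input are not supported; PED/MAP text
  only.
- DAPC retains a fixed number of PCs; no cross-validated choice of the
  retained count is implemented.
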