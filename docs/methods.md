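# Methods

## Problem setting

Tumor-only targeted panels yield no germline sample, but their reads cover
thousands of common SNPs at ultra-low depth (≈ 0.5–2×). The package
estimates each patient's continental (African, Asian) and subcontinental
(Ashkenazi Jewish, AJ) ancestry from that evidence and relates the indices
to eight targetable NSCLC driver alterations, adjusting for age,
pack-years of smoking, sex and histology. All quantities are estimated
against synthetic cohorts with known ground truth, because individual-level
patient data of this kind is not shareable.

## Generative model (the synthetic-data module)

The simulator defines the study conditions; its defaults are fixed, not
tuning knobs.

- **Reference panel.** Balding–Nichols: ancestral frequencies
  p ~ Uniform(0.05, 0.95); population k's frequency is
  Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k). Per-population divergences default
  to F = 0.20 (African), 0.12 (Asian), 0.10 (European), so pairwise
  Hudson FST ≈ (F_i+F_j)/2 gives ≈ 0.15 African–European and
  ≈ 0.11 Asian–European, typical continental values. Haplotypes are
  Bernoulli draws from the population frequency (no linkage
  disequilibrium; see Limitations). Default 2000 sites, 60 haplotypes per
  population.
- **AJ-like subpanel.** A weak drift (F = 0.004, 40 haplotypes) from the
  European latent frequencies, reproducing the geometry of a
  subcontinental group sitting just outside the main European cloud.
- **Cohorts.** Ancestry fractions ~ Dirichlet(α = 0.1 per population):
  mostly unadmixed individuals with an admixed minority, matching a
  tertiary-center cohort where most patients report a single race. Each
  allele copy picks a source population from the fractions, then draws
  from that population's empirical panel frequency — so genotype
  frequencies are exactly linear in admixture. A configurable fraction of
  individuals is drawn instead from the AJ-like subpanel. A self-report
  label (the analog of self-reported race) is emitted when the top
  fraction is ≥ 0.8.
- **Reads.** Site-i.i.d. depth ~ Poisson(1.0 by default); alt reads ~
  Binomial(depth, {ε, ½, 1−ε}) with sequencing error ε = 0.01. No
  GC/positional structure — sufficient for dosage and INFO behaviour.
- **Clinical/somatic tables.** Age ~ N(66, 10) clipped to [30, 92]; 60 %
  female; histology mix dominated by adenocarcinoma; 23 % never smokers,
  Gamma(2, 16) pack-years among smokers, 5 % missing; log-normal TMB with
  a lower median (6.1 vs 9.6 mut/Mb) in the AJ-like group. Alteration
  flags are Bernoulli(logistic(β₀ + βᵀx)) with explicit coefficients, so
  refitting recovers the generating odds ratios. `EffectModel.null()`
  (all β = 0) drives calibration checks; `EffectModel.nsclc_default()`
  encodes an NSCLC-like effect structure (Asian→EGFR OR 4.9 over the full
  ancestry range, AJ→MET OR 2.7, smoking↑KRAS G12C, smoking↓EGFR/ALK/ROS1).
- **Fixture cohorts.** `build_fixture_cohort` replays printed contingency
  tables exactly (one row per counted patient). Alteration flags are
  assigned to disjoint patients unless overlap is requested — the eight
  drivers are near-mutually exclusive and published per-histology row sums
  are consistent with that assumption.

## Imputation

Genotype likelihoods are binomial with alt-read probability {ε, ½, 1−ε}
by genotype; zero-depth sites are flat. The imputation model is a diploid
**Li–Stephens haplotype-copying HMM** against the phased panel: the hidden
state is an ordered pair of panel haplotypes; per interval each chromosome
independently switches to a uniformly drawn haplotype with probability
s = 1 − exp(−ρ/H) (default ρ = 1, so ≈ 1 switch per 100 sites at
H = 100); emissions integrate the genotype likelihood over the copied pair
with copying error θ = 0.01. This is the canonical model underlying
low-coverage imputation tools, chosen because its posteriors are exactly
testable by brute-force enumeration. Physical distance is ignored
(uniform switch probability per interval): imputation accuracy, not
genetic-map fidelity, is the goal here.

Numerics: forward and backward messages are renormalised at every site;
a zero normaliser raises instead of propagating NaN. The factorised
transition (row/column sums) makes the cost O(H² m) per individual. When
the panel exceeds `n_hap_used` (default 100) haplotypes, a seeded subsample
is used. Message recursions run in single precision for cohort-scale work
(messages are renormalised per site; agreement with double precision is
~1e-7) and in double precision by default, where enumeration-oracle
agreement is required at 1e-8.

Dosage is E[g] = P(1) + 2P(2); per-site quality is the IMPUTE-style
INFO = 1 − mean_i Var_i(g)/(2p(1−p)), clamped to [0, 1] because the ratio
estimator can exit bounds; p is the panel allele frequency. Monomorphic
panel sites have undefined INFO and are dropped. Sites are retained iff
INFO > 0.4 and minor allele frequency > 0.01, both strict. The frequency
in the filter is the panel minor-allele frequency (the context is germline
imputation, not a somatic variant-allele fraction); a cohort-estimated
frequency could be substituted but is not the default. Individuals with no
reads at any site are short-circuited to the Hardy–Weinberg prior at the
panel frequency, so their dosage is exactly 2p; with copying error θ > 0
the HMM marginal would otherwise be p + θ(1−2p), an unhelpful bias for an
evidence-free individual.

## Ancestry projection

Weights are trained on the panel's diploid genotypes, standardised as
(g − 2p)/√(2p(1−p)). For each axis (axis → contrast populations:
African vs European, Asian vs European, AJ vs European), PCA runs on all
reference individuals — except the AJ axis, which runs within the European
subset (European + AJ-like individuals) because the subcontinental
contrast is invisible to the global components. Axis weights live in the
span of the top principal components (default 10). The AJ axis is the
projected AJ–European centroid contrast. Each continental axis is the
dual basis of all main-population centroid contrasts against the
reference: the direction on which the target population is positive while
every other main population scores exactly like the reference, so the
score is linear in the target admixture fraction alone. Two simpler rules
were evaluated and rejected: a single best-separating component is an
arbitrary rotation whenever top eigenvalues are near-degenerate (with
three populations they routinely are), and a lone centroid contrast picks
up the other populations' unequal divergences through the centering; both
made truth-concordance swing widely across panel realisations, while the
dual-basis contrast holds it near 0.997. Projection averages w·z over non-missing
filtered sites (missing dosages are mean-imputed at 2p and excluded from
the denominator), making scores robust to site-mask changes.

Raw scores have arbitrary scale, so an affine rescaling anchors group
means: self-reported European mean → 0 and self-reported African/Asian
mean → 100 per continental axis; AJ-like anchor mean → 1 against 0 for
other Europeans. The map is affine, hence association statistics are
unaffected. The 4-SD rule (threshold = anchor mean + 4 SD, population SD)
is computed on rescaled units, where anchor variances of the observed
kind put the African/Asian thresholds near the 20 %/15 % defaults; group
calls use strict inequalities, and the AJ rule (> 0.75) is evaluated only
within the European group. Continental scores are not clipped to
[0, 100]: admixture and noise legitimately move individuals past the
anchors.

## Association battery

- **Fisher exact** (2×2): two-sided p by hypergeometric enumeration
  (SciPy); the primary odds-ratio estimate is the sample OR ad/bc, which
  is what published fold-enrichments print; the conditional-MLE OR and its
  exact conditional 95 % CI are reported alongside. Zero cells give OR 0
  or ∞ with the one-sided exact bound.
- **Logistic regression**: maximum-likelihood Newton/IRLS fit
  (statsmodels) with Wald CIs; separation or non-convergence triggers a
  hand-written Firth (Jeffreys-penalised) refit, flagged in the result.
  Ancestry enters as the quantitative index; pack-years enter continuously
  with missing values indicator-coded (they are excluded listwise from
  smoking-stratified frequency contrasts). Histology dummies with fewer
  than 3 members are folded into the reference level to avoid
  quasi-separation.
- **Multiplicity**: q = min(1, p × n_tests) per axis with n_tests
  defaulting to the 8 alterations; significance at q < 0.1, strict. This
  is a literal Bonferroni adjustment reported as a q-value.
- **Smoking bins**: never (0 pack-years), (0,15], (15,30], (30,45],
  (45,60), [60,∞). Upper edges are closed so integer pack-years land in
  their labelled bin; the 46–59 bin is open at 60 so that 60 starts the
  top bin.
- **TMB**: group medians with a two-sided Mann–Whitney p, plus an optional
  pack-year-adjusted contrast from a linear model on log(TMB+1).
- **First-sample rule**: one row per patient, the minimum-age sample, ties
  broken lexicographically by sample id; patients with no aged sample are
  dropped with a warning.

## Default problem sizes

Validation benchmarks run at 3 populations × 2000 sites, 200 individuals
(continental recovery) or 300 Europeans with 60 AJ-like (AJ AUC), depth
1×. The benchmarks disable haplotype subsampling (all 220 panel
haplotypes): the exact computation is affordable at this panel size and
the default cap of 100 would otherwise be the dominant approximation
error in the sparse-vs-dense concordance. A full benchmark run is a few
minutes on one CPU.
Calibration checks use 200 null cohorts of 500 patients (discovery rate at
q < 0.1 stays below 0.1) and 100 replicates of 1500 patients for CI
coverage of a planted Asian-axis effect (OR 4.9).

## What passing tests do and do not show

The simulator has no linkage disequilibrium, no bait-set geometry, no
GC/coverage structure, no genotyping batch effects, and its "self-report"
labels are noise-free functions of true admixture. Passing recovery
benchmarks therefore demonstrate correctness of the inference machinery
under the stated generative model, not field accuracy on real panels.
Two quantitative consequences: (a) with 2000 independent sites and
subpanel drift F = 0.004, the attainable standardised separation of the
AJ-like group is ≈ 4 SD, so the AJ AUC from sparse reads lands just
short of perfect ranking (≈ 0.99, a handful of inverted pairs out of
14 400) rather than the 1.0 achievable with genome-wide data; (b)
sparse-vs-dense score concordance at 1× sits at ≈ 0.99 — real
off-target coverage is less uniform and would lower it.

## Other limitations

- No Hispanic/Native-American axis: such admixture loads on both
  continental indices and needs a dedicated reference.
- Biallelic SNVs only; no phasing output; no EM re-estimation of panel
  haplotypes; no X chromosome.
- The Fisher/logistic battery treats patients as independent; registry
  duplicates must be removed upstream (the first-sample rule handles
  repeat biopsies only).
- TMB is consumed as a precomputed column, never derived from variants.
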