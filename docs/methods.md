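# Methods

This note documents the models the package implements, the defaults it
ships, the design choices made where the design was genuinely open, and
what the synthetic-data experiments do and do not demonstrate.

## Synthetic cohorts (`simcohort`)

**Reference panels.** Ancestral allele frequencies are uniform on
[0.05, 0.95]. Each population draws its frequency per variant from the
Balding–Nichols beta distribution `Beta(p(1−F)/F, (1−p)(1−F)/F)` at its
fixation index F_ST (F = 0 returns the ancestral frequency exactly);
this is the standard parameterization whose realized Hudson F_ST matches
the target. Linkage disequilibrium is induced by founder-segment
copying: each population keeps a pool of founder haplotypes (default
100) per LD block, and every sampled haplotype copies one founder
segment per block. This yields strong within-block and zero
cross-block correlation — sufficient to exercise clumping, region
definition, and credible sets, but it is not coalescent-realistic: there
is no recombination map, no allele-age structure, and the finite founder
pool adds ~1/n_founders of extra drift on top of the target F_ST
(realized Hudson F_ST ≈ 0.11 for a target of 0.10 at the defaults).
Positions are a uniform 1-based grid (default 5 kb spacing) on one
synthetic GRCh37-style chromosome.

**Admixture** is global: each individual draws one admixture proportion
vector (a profile from `SimTruth.admixture`, uniform over the supplied
profiles) and each of its two gametes comes from a single population
chosen by those proportions. There are no local-ancestry tracts; this
matches an analysis design that adjusts for global ancestry only.

**Liability-threshold disease model.** Genetic liability is
`g = Σ_j β_j (x_j − 2p_j)/√(2p_j(1−p_j))` over causal variants, with
`p_j` the admixture-weighted pooled frequency. Because causal variants
can fall in the same LD block (and founder pools add frequency noise),
`Var(g)` exceeds `Σβ²`; the generator therefore rescales `g` to variance
h² using the empirical variance of its first candidate batch and adds
`N(0, 1 − h²)` noise, so total liability is approximately standard
normal and the case threshold `Φ⁻¹(1 − K)` delivers prevalence K. Cases
and controls are ascertained by rejection sampling with a hard cap of
10⁶ candidate draws; exceeding the cap raises an error rather than
silently under-delivering. Defaults follow the disease context the
package targets: prevalence K = 0.01, and test scenarios use h² in
0.3–0.5 with tens of causal variants.

**Imputation-INFO degradation.** INFO is dosage variance over the
binomial variance 2p(1−p). Dosages are blended as
`d = a·g + b·x + (1−a−b)·2p` with `x ~ Binomial(2, p)` independent and
`a² + b² = t` (for target t ≥ ½, `a = (1+√(2t−1))/2`, `b = 1−a`; for
t ≤ ½, `a = b = √(t/2)`). The blend lies in [0, 2] by construction —
no clamping that would bias the realized variance — with `E[d] = 2p`,
`Var(d) = t·2p(1−p)`, and `corr(d, g)² = a²/t`. Monomorphic variants are
passed through with INFO recorded missing.

**Injected pairs.** Duplicates are genotype copies; both members receive
independent missingness masks at rates uniform in 1–3% (so the
resolution rule "drop the member with more missing genotypes" has
something to act on). First-degree relatives are offspring: one gamete
transmitted Mendelianly from an existing parent's genotype, one drawn
from a random mate with the parent's admixture profile. The returned
truth table backs kinship-classification tests.

## QC and kinship (`qc_kinship`)

Variant QC removes variants with missingness > 2% or Hardy–Weinberg
P < 10⁻⁶. HWE uses a 1-df chi-square (deterministic and adequate at
synthetic scale; an exact test would differ only at tiny control
counts) computed **in controls only**, the usual practice since
case-control association itself distorts genotype frequencies in cases.

Kinship is the robust between-family estimator
`φ = (N_het,het − 2·N_opp-hom)/(N_het(i) + N_het(j))` on genotypes
rounded to hard calls, with classification at the standard inference
bins: duplicate φ > 2^(−3/2), first-degree 2^(−5/2) < φ ≤ 2^(−3/2).
Pairs sharing fewer than 100 non-missing variants are flagged rather
than estimated.

Pair resolution is greedy and deterministic (descending φ, ties by
sample ID): within-batch duplicates drop the member with more missing
genotypes; diagnostically discordant pairs keep the case; concordant
pairs keep the less-missing member and consider reassigning it between
the two batches involved, preferring the batch with the smaller
N_eff : N ratio and moving only when the destination's ratio does not
fall ("ameliorative" moves — adding a sample always raises raw N_eff, so
the ratio is the discriminating criterion). When neither move is
ameliorative the original batch is kept and logged. Ledgers
(N_cases, N_controls, N_eff) update after every decision.

## Ancestry (`ancestry_pca`)

The GRM averages standardized-dosage cross-products (center 2p, scale
√(2p(1−p)), mean-impute missing calls); monomorphic variants are
skipped. Note that in-sample frequency centering forces each variant's
scores to sum to ~0, so the off-diagonal mean of a GRM over n unrelated
samples is ≈ −1/(n−1), not exactly 0. PCA is an eigendecomposition with
coordinates scaled by √eigenvalue.

Ancestry proportions are estimated by ordinary least squares of
reference-population membership indicators on the top 10 reference PCs,
applied to study samples, clipped and projected onto the probability
simplex (Euclidean projection). A mixed model with a random reference
effect would be an alternative; OLS plus projection reproduces the
thresholding behavior the assignment rules need and has no tuning
parameters. Assignment uses 25% thresholds — African: AFR ≥ 25% and each
of AMR/EAS/SAS < 25%; Latino: AMR ≥ 25% and AFR/EAS/SAS < 25%; European:
all four < 25%; otherwise unassigned. The EUR proportion is reported but
never thresholded, and the rules are mutually exclusive by construction.

## Association (`assoc`)

Per-variant logistic regression of phenotype on dosage plus covariates
(default six PCs and genotyping-batch indicators), fitted by
Newton/IRLS warm-started at the covariate-only solution, with Wald
tests — the convention the daner summary-statistic format implies.
Fits hitting 50 iterations or |β| > 20 are flagged as
non-converged/separated and excluded downstream; monomorphic dosages are
flagged missing. X-chromosome analysis runs per sex stratum
(`sex_stratum=`) and the strata are recombined in `metastats` exactly
like two studies. Post-association filters: INFO ≥ 0.3 and MAF ≥ 1%
for primary cohort analyses; INFO ≥ 0.6, MAF ≥ 1%, present in a minimum
number of constituent studies for meta-analysis tables. λ is computed
from P-derived 1-df chi-square quantiles (identical to Z²-derived
values).

## Meta-analysis (`metastats`)

Harmonization aligns each variant to the orientation of the first study
reporting it, flipping sign and frequency for swapped alleles and
recognizing strand complements; A/T and C/G variants are dropped when
any study's frequency is within 0.08 of 0.5 (frequency cannot then
resolve strand), and unmatched allele pairs are dropped with a report.
Variants are combined when present in ≥ 2 studies; per-study presence is
recorded in a daner-style direction string with `?` placeholders.

RE2 maximizes the alternative likelihood over (μ, τ² ≥ 0) with a
golden-section search on τ² over [0, 100·max SE²] at tolerance 1e−10
(validated against dense grid evaluation); the statistic is the LRT
against (0, 0) and always dominates the fixed-effects chi-square since
the FE model is nested. Two null distributions are provided: the
asymptotic equal mixture of χ²₁ and χ²₂, and a seeded simulated null
table (`re2_null_table`). The boundary LRT converges slowly to its
asymptotic mixture: under exactly-normal null effects the asymptotic
P values are **conservative** (empirical type-I ≈ 0.03 at nominal 0.05
for k = 5, still ≈ 0.035–0.04 at k = 200), which is why the original
method's authors tabulate small-k nulls. The package defaults to the
asymptotic null (conservative is the safe direction for discovery) and
uses the tabulated option where exact calibration matters; the
calibration experiment draws its evaluation replicates from a different
seed than the table, so it tests the table rather than echoing it.

## Clumping, sign tests, polygenic scores (`prs_clump`)

Clumping is greedy: visit variants by increasing P (ties by position
then id), open a clump at each unassigned variant, absorb unassigned
variants within 500 kb at r² ≥ the ceiling (default 0.1). Variants
missing from the LD reference — or monomorphic in it, which carries no
LD information — are treated as unlinked. Raising the ceiling
(0.1 → 0.5 → 0.8) can only merge fewer variants, so the number of scored
index SNPs is non-decreasing.

The sign test clumps the training statistics (restricted to SNPs shared
with the test study after harmonization), counts direction agreement
among index SNPs below the training threshold (exact-zero effects are
dropped as ties), and uses the exact one-sided binomial tail at 0.5.

Score evaluation fits logistic models with and without the standardized
score. Nagelkerke R² is computed on the score's increment over the
covariate-only model: `(1 − e^{−LR/n})/(1 − e^{2ℓ₀/n})`. The liability
R² applies the ascertainment-adjusted transformation (threshold model
with prevalence K and sample case proportion P, including the θ
correction term) to the **observed-scale linear-model incremental R²**,
not to Nagelkerke R² — the two pseudo-R² chains differ, so published
values produced by other chains are not exactly recomputable; both are
reported. The association P is the 1-df likelihood-ratio test.
Leave-one-out training re-runs association and meta-analysis without the
target cohort and audits sample-ID disjointness. The joint-model test
compares covariates + score_A against covariates + both scores by a 1-df
LRT, refusing collinear scores (|r| > 0.999). The default P_T grid is
{5e−8, 1e−6, 1e−4, 5e−4, 1e−3, 0.01, 0.05, 0.1, 0.5, 1}.

## Fine-mapping (`finemap`)

Regions form around independent index SNPs (clump indices at r² < 0.1 /
500 kb among variants with P < 10⁻⁶): members lie within a 3 Mb window,
have r² ≥ 0.6 to the index, and P < 10⁻⁴. Evidence per member is the
Wakefield approximate Bayes factor with prior effect-size variance
W = 0.04 on the log-odds scale (prior SD 0.2, the conventional choice
for binary-trait fine-mapping; configurable). Posteriors assume a single
causal variant per region and normalize BFs over the region (computed in
log space with a max-shift, so extreme z scores cannot overflow). The
credible set accumulates SNPs in decreasing posterior order (ties by
smaller P, then position) until the mass **strictly exceeds** the target
(0.99), making the set minimal: dropping its last member falls to or
below the target. Intervals are the positional span of the set with
length (end − start)/1000 kb rounded **half-up** to 2 decimals — the
end-minus-start convention and tie-rounding validated against published
credible-set tables. Meta-analysis posteriors use the fixed-effects
beta/SE; RE2 results never feed the ABF, which assumes one shared
effect. A region is "fine-mapped" when the follow-up analysis is more
significant, its credible interval is shorter, and that interval is also
shorter than the span of SNPs at r² ≥ 0.6 with the index in the base
reference.

## Validation experiments (`validation`) and their scope

Problem sizes were chosen to exercise each property at desk scale:
RE2 calibration uses 10,000 null replicates at k = 5; credible-set
coverage 500 single-causal regions simulated at summary level
(bhat ~ N(R e_c β_c, SE²R) with β_c ~ N(0, W), SE = 0.05, R taken from
panel LD blocks); the polygenic-score transfer experiment runs 20
replicates of an 800-SNP, 40-causal, h² = 0.5, K = 0.01 design with
1200 + 1200 training and 400 + 400 target individuals per population
pair at F_ST 0.1; kinship classification injects 5 duplicate and 5
first-degree pairs at 10,000 SNPs; clumping is checked against a naive
brute-force evaluation on 300 random ≤ 6-variant instances; the IRLS
solver is checked against statsmodels on a fixed 200-sample cohort.

Passing these experiments shows the pipeline's statistics behave as
designed under the generator's assumptions — Balding–Nichols drift,
block LD, global admixture, exactly normal effect estimates. They do not
demonstrate robustness to features real cohorts add: fine-scale and
local-ancestry structure, genotyping batch artifacts correlated with
phenotype, imputation error that varies along the genome, allele
frequencies near fixation in one population, or case ascertainment that
is not a clean liability threshold. Magnitudes (e.g. liability R² of a
simulated score) are specific to the simulated architecture and should
be read as qualitative directions, not calibrated predictions for any
real trait.

## Known limitations

* Segment-copy LD has no recombination map; r² decays in blocks, not
  with distance, so window-based rules are exercised only coarsely.
* One synthetic chromosome; no X-specific dosage generator (male 0/2
  coding is supported by the association layer, not the simulator).
* Single-causal ABF fine-mapping; no multi-causal models or functional
  priors.
* The ancestry "mixed model" is OLS + simplex projection, not a formal
  random-effects fit.
* Binary phenotypes only; no covariate selection or mixed-model
  association.
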