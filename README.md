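# transgwas

A toolkit for **trans-ancestry case-control genome-wide association
analysis**, built around the workflow used for multi-ancestry psychiatric
GWAS: cohort quality control and kinship-based duplicate/relative
resolution, PCA-based continental ancestry assignment, per-ancestry
logistic dosage association with genomic control, fixed-effects and
Han–Eskin RE2 random-effects meta-analysis, LD clumping with
cross-ancestry sign tests, polygenic risk scores evaluated on the
liability scale, and approximate-Bayes-factor credible-set fine-mapping.

It is aimed at statistical geneticists who want the individual pieces of
that pipeline as tested, composable functions — together with a
synthetic-data module that generates multi-population cohorts with known
truth (Balding–Nichols allele-frequency divergence, block LD, global
admixture, liability-threshold ascertainment, imputation-INFO
degradation, injected duplicates and relatives), so every stage can be
validated end to end without access to restricted genotype data.

## The statistics at the core

* **Effective sample size** of an imbalanced case-control study:
  `N_eff = 4 / (1/N_cases + 1/N_controls)`.
* **Genomic control**: `λ = median(χ²)/0.4549`, rescaled for
  comparability as `λ_1000 = 1 + (λ − 1)(1/N_ca + 1/N_co)/(2/1000)`.
* **Fixed-effects meta-analysis**: inverse-variance weights `w_i = 1/SE_i²`,
  `β_FE = Σwβ/Σw`, `SE_FE = (Σw)^{-1/2}`; heterogeneity by Cochran's
  `Q = Σw(β − β_FE)²` (χ², k−1 df) and `I² = max(0, (Q−df)/Q)·100`.
* **RE2**: the likelihood-ratio statistic of `(μ=0, τ²=0)` against a free
  mean with non-negative between-study variance, with the asymptotic
  `½χ²₁ + ½χ²₂` null or a seeded simulated small-k null table.
* **KING-robust kinship**:
  `φ = (N_het,het − 2·N_opp-hom) / (N_het(i) + N_het(j))`, with duplicate
  and first-degree thresholds at `2^{-3/2}` and `2^{-5/2}`.
* **Polygenic scores**: `score_i = Σ_j dosage_ij · log(OR_j)` over clumped
  index SNPs below a training P threshold; evaluated by Nagelkerke
  pseudo-R² and by liability-scale R² via the ascertainment-adjusted
  transformation (population prevalence K, sample case proportion P).
* **Fine-mapping**: Wakefield approximate Bayes factors
  `BF = √(V/(V+W)) · exp(z²W / 2(V+W))` with prior effect variance
  `W = 0.04`, normalized to single-causal posteriors; 99% credible sets
  accumulate SNPs until the posterior mass exceeds 0.99.

See `docs/methods.md` for assumptions, defaults, and numerical choices.

## Worked example

Simulate a two-population panel, ascertain EUR and AFR case-control
cohorts sharing 30 causal variants (h² = 0.5, prevalence 1%), run both
GWAS, meta-analyze, and score a held-out AFR cohort:

```python
import numpy as np
from transgwas import simcohort as sc, assoc, metastats as ms, prs_clump as pc

panel = sc.simulate_reference_panel(n_snps=1000, populations=["AFR", "EUR"],
                                    fst=0.1, n_blocks=40, seed=7)
rng = np.random.default_rng(7)
causal = rng.choice(panel.variants["SNP"], 30, replace=False).tolist()
truth = sc.SimTruth(causal_ids=causal, effects=rng.normal(0, 1, 30),
                    h2=0.5, prevalence=0.01, admixture=[0, 1], seed=7)
eur = sc.simulate_cohort(panel, 1000, 1000, truth, seed=8)

stats = assoc.filter_stats(assoc.logistic_gwas(eur, n_pcs=2))

afr_truth = sc.SimTruth(causal, truth.effects, 0.5, 0.01, [1, 0], seed=7)
afr = sc.simulate_cohort(panel, 1000, 1000, afr_truth, seed=9, id_prefix="afr")
meta = ms.meta_analyze({"eur": stats,
                        "afr": assoc.filter_stats(assoc.logistic_gwas(afr, n_pcs=2))})
top = meta.sort_values("P").iloc[0]
print(f"top meta hit: {top.SNP}  OR = {top.OR:.3f}  P_FE = {top.P:.2e}  "
      f"P_RE2 = {top.P_RE2:.2e}  I2 = {top.I2:.1f}%  dir = {top.DIR}")

ld = pc.LDReference.from_panel(panel, "AFR")
target = sc.simulate_cohort(panel, 400, 400, afr_truth, seed=10, id_prefix="t")
model = pc.model_from_stats(meta, ld, p_threshold=0.05)
scores, n_used = pc.build_prs(model, target)
ev = pc.evaluate_prs(scores, target.phenotype01(), None, prevalence=0.01)
print(f"PRS ({n_used} SNPs, P_T < 0.05): Nagelkerke R2 = {ev.nagelkerke_r2:.3f}, "
      f"liability R2 = {ev.liability_r2:.3f}, P = {ev.p_value:.2e}")
```

Output:

```
top meta hit: rs1_645001  OR = 2.499  P_FE = 1.18e-71  P_RE2 = 1.35e-70  I2 = 60.0%  dir = ++
PRS (123 SNPs, P_T < 0.05): Nagelkerke R2 = 0.616, liability R2 = 0.380, P = 7.01e-110
```

The top trans-ancestry hit is genome-wide significant under both the
fixed-effects and RE2 models with the same effect direction in both
cohorts (`dir = ++`); the meta-trained score explains 38% of liability
variance in the held-out cohort — of the same order as the simulated
h² = 0.5 given 30 strongly powered causal variants and matched-ancestry
LD. On an otherwise identical cohort simulated with h² = 0 the same
pipeline prints `λ = 1.078, λ_1000 = 1.078`, i.e. no systematic
test-statistic inflation (λ carries sampling noise of a few percent at
1,000 SNPs).

A thin CLI mirrors the library (`transgwas simulate panel|cohort`, `qc`,
`kinship`, `gwas`, `meta`, `signtest`); run `transgwas --help`.

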