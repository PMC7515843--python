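"""LD clumping, cross-ancestry sign tests, and polygenic risk scoring.

Clumping greedily picks the most significant unassigned variant as an
index and absorbs every unassigned variant within the window (default
500 kb) whose LD r^2 with the index reaches the ceiling (default 0.1),
so surviving index SNPs are approximately independent.

The sign test asks whether effect directions for independent training
SNPs below a P threshold replicate in a second study more often than
chance: an exact one-sided binomial tail at 0.5.

Polygenic scores sum dosages times training log-odds weights. Score
performance is reported as (i) Nagelkerke pseudo-R^2 of the score's
increment over a covariate-only logistic model, (ii) variance explained
on the liability scale via the ascertainment-adjusted transformation of
the observed-scale linear-model increment (Lee et al.), given population
prevalence K and sample case proportion, and (iii) the 1-df
likelihood-ratio P value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import log_likelihood, logistic_irls
from .metastats import harmonize
from .simcohort import CohortPanel, ReferencePanel

__all__ = [
    "Clump",
    "PRSModel",
    "PRSEvaluation",
    "LDReference",
    "ld_r2",
    "clump",
    "sign_test",
    "build_prs",
    "evaluate_prs",
    "liability_r2",
    "loo_training",
    "joint_model_test",
    "P_T_GRID",
]

#: default training P-value threshold grid
P_T_GRID = (5e-8, 1e-6, 1e-4, 5e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0)


@dataclass
class Clump:
    """One LD clump: index SNP plus absorbed members with their r^2."""

    index_snp: str
    index_p: float
    members: list[tuple[str, float]] = field(default_factory=list)  # (snp, r2 to index)

    @property
    def snps(self) -> list[str]:
        return [self.index_snp] + [s for s, _ in self.members]


@dataclass
class PRSModel:
    """Scoring weights: SNP -> (effect allele, log-odds weight)."""

    weights: pd.DataFrame  # columns SNP, A1, weight
    p_threshold: float
    r2_ceiling: float
    training: str = ""


@dataclass
class PRSEvaluation:
    nagelkerke_r2: float
    liability_r2: float
    p_value: float
    case_proportion: float
    prevalence: float
    n: int


class LDReference:
    """LD backend over a reference dosage matrix.

    ``genotypes`` is (n_variants, n_samples); ``variants`` carries SNP,
    CHR, BP aligned to its rows.
    """

    def __init__(self, genotypes: np.ndarray, variants: pd.DataFrame):
        self.genotypes = np.asarray(genotypes, dtype=float)
        self.variants = variants.reset_index(drop=True)
        self._idx = {s: i for i, s in enumerate(variants["SNP"])}
        centered = self.genotypes - self.genotypes.mean(axis=1, keepdims=True)
        self._centered = centered
        self._norm = np.sqrt((centered**2).sum(axis=1))

    @classmethod
    def from_panel(cls, panel: ReferencePanel, population: str) -> "LDReference":
        return cls(panel.genotypes(population), panel.variants)

    def __contains__(self, snp: str) -> bool:
        return snp in self._idx

    def has_ld(self, snp: str) -> bool:
        """Present in the reference and polymorphic (usable for LD)."""
        i = self._idx.get(snp)
        return i is not None and self._norm[i] > 0

    def position(self, snp: str) -> int:
        return int(self.variants["BP"].iloc[self._idx[snp]])

    def r2(self, snp_i: str, snp_j: str) -> float:
        i, j = self._idx[snp_i], self._idx[snp_j]
        if self._norm[i] == 0 or self._norm[j] == 0:
            raise ValueError("monomorphic variant in LD reference")
        r = (self._centered[i] @ self._centered[j]) / (self._norm[i] * self._norm[j])
        return float(r * r)

    def r2_with(self, index_snp: str, snps: list[str]) -> np.ndarray:
        """Vector of r^2 of ``index_snp`` with each of ``snps``."""
        i = self._idx[index_snp]
        if self._norm[i] == 0:
            raise ValueError("monomorphic index variant in LD reference")
        out = np.zeros(len(snps))
        for k, s in enumerate(snps):
            j = self._idx[s]
            if self._norm[j] == 0:
                continue
            r = (self._centered[i] @ self._centered[j]) / (self._norm[i] * self._norm[j])
            out[k] = r * r
        return out


def ld_r2(ld: LDReference, snp_i: str, snp_j: str) -> float:
    """Squared Pearson correlation of reference dosages."""
    return ld.r2(snp_i, snp_j)


def clump(
    stats_df: pd.DataFrame,
    ld: LDReference,
    r2_max: float = 0.1,
    window_kb: float = 500.0,
) -> list[Clump]:
    """Greedy LD clumping of an association table.

    Variants are visited in order of increasing P (ties: position, then
    id). Each unassigned visit opens a clump and absorbs unassigned
    variants within ``window_kb`` of the index with r^2 >= ``r2_max``.
    Variants absent from the LD reference (or monomorphic in it, hence
    carrying no LD information) are treated as unlinked.
    """
    df = stats_df.dropna(subset=["P"]).sort_values(["P", "BP", "SNP"]).reset_index(drop=True)
    assigned: set[str] = set()
    clumps: list[Clump] = []
    snps = df["SNP"].tolist()
    pos = dict(zip(df["SNP"], df["BP"].astype(int)))
    pvals = dict(zip(df["SNP"], df["P"]))
    window = window_kb * 1000.0
    for snp in snps:
        if snp in assigned:
            continue
        assigned.add(snp)
        cl = Clump(index_snp=snp, index_p=float(pvals[snp]))
        if ld.has_ld(snp):
            near = [
                s
                for s in snps
                if s not in assigned and ld.has_ld(s) and abs(pos[s] - pos[snp]) <= window
            ]
            if near:
                r2s = ld.r2_with(snp, near)
                for s, r2 in zip(near, r2s):
                    if r2 >= r2_max:
                        assigned.add(s)
                        cl.members.append((s, float(r2)))
        clumps.append(cl)
    return clumps


def sign_test(
    train: pd.DataFrame,
    test: pd.DataFrame,
    p_threshold: float,
    ld: LDReference,
    r2_max: float = 0.1,
    window_kb: float = 500.0,
) -> tuple[float, float, int, int]:
    """Direction concordance of independent training SNPs in a test study.

    Training stats are clumped (restricted to SNPs present in both
    studies, after allele harmonization); among index SNPs with training
    P < ``p_threshold``, effect-sign agreement with the test study is
    counted (exact zero betas dropped as ties) and tested with the exact
    one-sided binomial tail at 0.5. Returns
    (fraction concordant, P, n eligible, n concordant).
    """
    aligned, _ = harmonize({"train": train, "test": test})
    tr, te = aligned["train"], aligned["test"]
    common = set(tr["SNP"]) & set(te["SNP"])
    tr = tr[tr["SNP"].isin(common)].reset_index(drop=True)
    te_beta = dict(zip(te["SNP"], te["BETA"]))
    clumps = clump(tr, ld, r2_max=r2_max, window_kb=window_kb)
    n = k = 0
    for cl in clumps:
        if cl.index_p >= p_threshold:
            continue
        b_tr = float(tr.loc[tr["SNP"] == cl.index_snp, "BETA"].iloc[0])
        b_te = float(te_beta[cl.index_snp])
        if b_tr == 0.0 or b_te == 0.0:
            continue
        n += 1
        if np.sign(b_tr) == np.sign(b_te):
            k += 1
    if n == 0:
        raise ValueError("no eligible SNPs below the training threshold")
    p = float(stats.binom.sf(k - 1, n, 0.5))
    return k / n, p, n, k


def build_prs(model: PRSModel, cohort: CohortPanel) -> tuple[np.ndarray, int]:
    """Per-individual score: sum of dosage x weight over model variants.

    Model variants are matched to cohort alleles: counted-allele matches
    use the dosage, swapped matches use 2 - dosage, anything else is
    skipped. Missing dosages are mean-imputed. Returns
    (scores, n variants used); raises if no model variant is usable.
    """
    var = cohort.variants.set_index("SNP")
    scores = np.zeros(cohort.n_samples)
    used = 0
    for snp, a1, w in zip(model.weights["SNP"], model.weights["A1"], model.weights["weight"]):
        if snp not in var.index:
            continue
        row = var.loc[snp]
        j = var.index.get_loc(snp)
        d = cohort.dosages[j]
        d = np.where(np.isnan(d), np.nanmean(d), d)
        if a1 == row["A1"]:
            scores += w * d
        elif a1 == row["A2"]:
            scores += w * (2.0 - d)
        else:
            continue
        used += 1
    if used == 0:
        raise ValueError("no model variants present in the cohort")
    return scores, used


def nagelkerke_r2(lr_stat: float, ll_null: float, n: int) -> float:
    """Nagelkerke pseudo-R^2 from an LR statistic and the null log-likelihood."""
    cox_snell = 1.0 - np.exp(-lr_stat / n)
    max_r2 = 1.0 - np.exp(2.0 * ll_null / n)
    return float(cox_snell / max_r2) if max_r2 > 0 else np.nan


def liability_r2(r2_observed: float, prevalence: float, case_proportion: float) -> float:
    """Ascertainment-adjusted liability-scale R^2 (Lee et al. transformation).

    ``r2_observed`` is the observed-scale (linear model, 0/1 outcome)
    incremental R^2 in a sample with case proportion P drawn from a
    population with prevalence K.
    """
    K, P = prevalence, case_proportion
    if not 0 < K < 1:
        raise ValueError("prevalence must be in (0, 1)")
    thd = stats.norm.isf(K)
    z = stats.norm.pdf(thd)
    m = z / K
    theta = m * (P - K) / (1 - K) * (m * (P - K) / (1 - K) - thd)
    c = K * (1 - K) / z**2 * K * (1 - K) / (P * (1 - P))
    return float(r2_observed * c / (1.0 + r2_observed * theta * c))


def evaluate_prs(
    scores: np.ndarray,
    phenotype01: np.ndarray,
    covariates: np.ndarray | None,
    prevalence: float,
) -> PRSEvaluation:
    """Score-phenotype association with Nagelkerke and liability R^2.

    Fits logistic models with and without the (standardized) score on
    top of the covariates; Nagelkerke R^2 is computed on the score's
    increment, the association P from the 1-df likelihood-ratio test,
    and the liability R^2 from the observed-scale linear increment via
    :func:`liability_r2`.
    """
    y = np.asarray(phenotype01, dtype=float)
    n = y.size
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype is degenerate")
    s = np.asarray(scores, dtype=float)
    if s.std() > 0:
        s = (s - s.mean()) / s.std()
    X0 = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    X1 = np.column_stack([X0, s])

    b0, _, _, _ = logistic_irls(X0, y)
    b1, _, _, _ = logistic_irls(X1, y)
    ll0 = log_likelihood(X0, y, b0)
    ll1 = log_likelihood(X1, y, b1)
    lr = max(0.0, 2.0 * (ll1 - ll0))
    p = float(stats.chi2.sf(lr, 1))
    nk = nagelkerke_r2(lr, ll0, n)

    # observed-scale incremental R^2 from linear fits
    def _rss(X):
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        return float(resid @ resid)

    tss = float(((y - y.mean()) ** 2).sum())
    r2_obs = max(0.0, (_rss(X0) - _rss(X1)) / tss)
    case_prop = float(y.mean())
    liab = liability_r2(r2_obs, prevalence, case_prop)
    return PRSEvaluation(
        nagelkerke_r2=nk,
        liability_r2=liab,
        p_value=p,
        case_proportion=case_prop,
        prevalence=prevalence,
        n=n,
    )


def model_from_stats(
    stats_df: pd.DataFrame,
    ld: LDReference,
    p_threshold: float,
    r2_ceiling: float = 0.1,
    window_kb: float = 500.0,
    training: str = "",
) -> PRSModel:
    """Clump a training table and keep index-SNP weights below a threshold."""
    clumps = clump(stats_df, ld, r2_max=r2_ceiling, window_kb=window_kb)
    idx = [c.index_snp for c in clumps if c.index_p < p_threshold]
    sub = stats_df[stats_df["SNP"].isin(idx)]
    weights = sub[["SNP", "A1", "BETA"]].rename(columns={"BETA": "weight"}).reset_index(drop=True)
    return PRSModel(weights=weights, p_threshold=p_threshold, r2_ceiling=r2_ceiling, training=training)


def loo_training(
    cohorts: dict[str, CohortPanel],
    target: str,
    gwas_fn,
    meta_fn=None,
) -> pd.DataFrame:
    """Leave-one-out training stats: re-analyze every cohort except the target.

    ``gwas_fn(cohort)`` must return an association table; with more than
    one remaining cohort the tables are meta-analyzed (``meta_fn`` or the
    package fixed-effects/RE2 combination). Training and target sample
    IDs are audited to be disjoint.
    """
    if target not in cohorts:
        raise ValueError(f"target {target!r} not among cohorts")
    rest = {name: c for name, c in cohorts.items() if name != target}
    if not rest:
        raise ValueError("leave-one-out requires at least two cohorts")
    target_ids = set(cohorts[target].samples["ID"])
    for name, c in rest.items():
        overlap = target_ids & set(c.samples["ID"])
        if overlap:
            raise ValueError(f"sample overlap between target and {name}: {sorted(overlap)[:3]}")
    tables = {name: gwas_fn(c) for name, c in rest.items()}
    if len(tables) == 1:
        return next(iter(tables.values()))
    if meta_fn is None:
        from .metastats import meta_analyze

        meta_fn = meta_analyze
    return meta_fn(tables)


def joint_model_test(
    score_a: np.ndarray,
    score_b: np.ndarray,
    phenotype01: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """1-df LRT of adding score_b to a baseline with score_a.

    Returns (P value, LR statistic). Collinear scores (|r| > 0.999) are
    rejected.
    """
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    y = np.asarray(phenotype01, dtype=float)
    if a.std() == 0 or b.std() == 0 or abs(np.corrcoef(a, b)[0, 1]) > 0.999:
        raise ValueError("scores are collinear")
    n = y.size
    base_cols = [np.ones(n)]
    if covariates is not None:
        base_cols.append(covariates)
    X0 = np.column_stack(base_cols + [a])
    X1 = np.column_stack(base_cols + [a, b])
    b0, _, _, _ = logistic_irls(X0, y)
    b1, _, _, _ = logistic_irls(X1, y)
    lr = max(0.0, 2.0 * (log_likelihood(X1, y, b1) - log_likelihood(X0, y, b0)))
    return float(stats.chi2.sf(lr, 1)), lr
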