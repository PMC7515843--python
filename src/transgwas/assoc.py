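"""Per-ancestry logistic dosage GWAS, filtering, and genomic control.

Each variant is tested by logistic regression of case/control status on
its imputed dosage plus covariates (ancestry PCs, default six, and
genotyping-batch indicator variables), fitted by iteratively reweighted
least squares with Wald tests. Non-converged or separated fits are
flagged and excluded from downstream combination.

Genomic control: lambda is the median association chi-square divided by
the 1-df chi-square median (~0.4549); its rescaling to a hypothetical
1000-case/1000-control study is

    lambda_1000 = 1 + (lambda - 1) * (1/Nca + 1/Nco) / (2/1000).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import ancestry_pca
from .simcohort import CohortPanel

__all__ = [
    "GCReport",
    "logistic_irls",
    "logistic_gwas",
    "filter_stats",
    "genomic_control",
    "lambda_1000",
]

MAX_ITER = 50
SEPARATION_BETA = 20.0


@dataclass
class GCReport:
    lam: float
    lam_1000: float
    n_cases: int
    n_controls: int


def logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = MAX_ITER,
    tol: float = 1e-10,
    start: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, bool, bool]:
    """Newton/IRLS logistic fit; returns (beta, se, converged, separated)."""
    n, p = X.shape
    beta = np.zeros(p) if start is None else start.copy()
    converged = separated = False
    XtWX = None
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        XtWX = X.T @ (X * w[:, None])
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            return beta, np.full(p, np.nan), False, True
        beta = beta + step
        if np.abs(beta).max() > SEPARATION_BETA:
            separated = True
            break
        if np.abs(step).max() < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    XtWX = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(XtWX)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return beta, se, converged, separated


def log_likelihood(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = np.clip(X @ beta, -30, 30)
    return float((y * eta - np.log1p(np.exp(eta))).sum())


def _covariate_matrix(
    cohort: CohortPanel, n_pcs: int, cohort_indicators: bool, pcs: np.ndarray | None
) -> np.ndarray:
    n = cohort.n_samples
    cols = [np.ones(n)]
    if n_pcs > 0:
        if pcs is None:
            grm = ancestry_pca.compute_grm(cohort.dosages)
            pcs, _ = ancestry_pca.pca(grm, min(n_pcs, n))
        cols.append(pcs[:, :n_pcs])
    if cohort_indicators:
        batches = pd.get_dummies(cohort.samples["batch"], drop_first=True)
        if batches.shape[1]:
            cols.append(batches.to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    return X


def logistic_gwas(
    cohort: CohortPanel,
    n_pcs: int = 6,
    cohort_indicators: bool = True,
    pcs: np.ndarray | None = None,
    sex_stratum: int | None = None,
) -> pd.DataFrame:
    """Per-variant logistic dosage association; daner-style output.

    Columns: CHR SNP BP A1 A2 FRQ INFO BETA SE P OR Nca Nco DIR flag.
    ``flag`` is 'ok', 'monomorphic', or 'nonconverged' (separation or
    iteration-limit fits; excluded by downstream filters). When
    ``sex_stratum`` is 1 or 2 only samples of that sex are analyzed
    (X-chromosome convention: males coded 0/2 upstream).
    """
    samples = cohort.samples
    mask = np.ones(cohort.n_samples, dtype=bool)
    if sex_stratum is not None:
        mask = samples["sex"].to_numpy() == sex_stratum
    y = cohort.phenotype01()[mask]
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("phenotype must be binary 1/2")
    sub = CohortPanel(cohort.variants, cohort.dosages[:, mask], samples.loc[mask].reset_index(drop=True), cohort.info)
    X_cov = _covariate_matrix(sub, n_pcs, cohort_indicators, pcs[mask] if pcs is not None else None)
    n_cases = int(y.sum())
    n_controls = int((1 - y).sum())

    beta0, _, _, _ = logistic_irls(X_cov, y)
    start = np.concatenate([beta0, [0.0]])
    X = np.column_stack([X_cov, np.zeros(len(y))])
    dcol = X.shape[1] - 1

    rows = []
    info_arr = sub.info if sub.info is not None else np.ones(sub.n_snps)
    for j in range(sub.n_snps):
        d = sub.dosages[j]
        p_j = np.nanmean(d) / 2.0
        rec = {
            "CHR": sub.variants["CHR"].iloc[j],
            "SNP": sub.variants["SNP"].iloc[j],
            "BP": sub.variants["BP"].iloc[j],
            "A1": sub.variants["A1"].iloc[j],
            "A2": sub.variants["A2"].iloc[j],
            "FRQ": p_j,
            "INFO": float(info_arr[j]) if np.isfinite(info_arr[j]) else np.nan,
            "Nca": n_cases,
            "Nco": n_controls,
        }
        if not np.isfinite(p_j) or p_j <= 0 or p_j >= 1 or np.nanvar(d) == 0:
            rec.update(BETA=np.nan, SE=np.nan, P=np.nan, OR=np.nan, DIR="?", flag="monomorphic")
            rows.append(rec)
            continue
        X[:, dcol] = np.where(np.isnan(d), 2 * p_j, d)
        beta, se, converged, separated = logistic_irls(X, y, start=start)
        if separated or not converged or not np.isfinite(se[dcol]) or se[dcol] <= 0:
            rec.update(BETA=np.nan, SE=np.nan, P=np.nan, OR=np.nan, DIR="?", flag="nonconverged")
            rows.append(rec)
            continue
        b, s = float(beta[dcol]), float(se[dcol])
        p = float(2.0 * stats.norm.sf(abs(b / s)))
        rec.update(
            BETA=b, SE=s, P=p, OR=float(np.exp(b)),
            DIR="+" if b > 0 else ("-" if b < 0 else "0"), flag="ok",
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def filter_stats(
    stats_df: pd.DataFrame,
    info_min: float = 0.3,
    maf_min: float = 0.01,
    min_studies: int | None = None,
) -> pd.DataFrame:
    """Post-association filters: INFO >= info_min, MAF >= maf_min.

    MAF folds the effect-allele frequency: min(FRQ, 1-FRQ). When
    ``min_studies`` is given, a DIR column is required and records must
    be present (non-'?') in at least that many constituent studies.
    Flagged (non-'ok') records are removed when a flag column exists.
    """
    if not (0 <= info_min <= 1 and 0 <= maf_min <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    df = stats_df
    keep = pd.Series(True, index=df.index)
    if "flag" in df.columns:
        keep &= df["flag"] == "ok"
    if "INFO" in df.columns:
        keep &= df["INFO"].fillna(-1) >= info_min
    maf = np.minimum(df["FRQ"], 1 - df["FRQ"])
    keep &= maf >= maf_min
    if min_studies is not None:
        n_present = df["DIR"].astype(str).str.replace("?", "", regex=False).str.len()
        keep &= n_present >= min_studies
    return df.loc[keep].reset_index(drop=True)


_CHI2_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.454936...


def genomic_control(pvals) -> float:
    """Genomic-control inflation factor lambda from association P values."""
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no P values supplied")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("P values must lie in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / _CHI2_MEDIAN)


def lambda_1000(lam: float, n_cases: int, n_controls: int) -> float:
    """Rescale lambda to a 1000-case/1000-control equivalent study."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if n_cases < 1 or n_controls < 1:
        raise ValueError("counts must be >= 1")
    return 1.0 + (lam - 1.0) * (1.0 / n_cases + 1.0 / n_controls) / (2.0 / 1000.0)
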