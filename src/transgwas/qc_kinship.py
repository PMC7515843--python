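"""Variant QC, robust kinship estimation, and duplicate/relative resolution.

Variant QC removes variants with call-rate failures (missingness above a
ceiling, default 2%) or Hardy-Weinberg disequilibrium in controls
(1-df chi-square P below a floor, default 1e-6).

Kinship uses the robust between-family estimator popularized by the KING
software: for a sample pair (i, j) over shared non-missing variants,

    phi = (N_het,het - 2 * N_opp_hom) / (N_het(i) + N_het(j))

where N_het,het counts variants heterozygous in both, N_opp_hom counts
opposite homozygotes, and N_het(i) counts heterozygous variants of i
among the shared sites. Duplicates satisfy phi > 2^(-3/2) ~ 0.354,
first-degree relatives 2^(-5/2) < phi <= 2^(-3/2).

Pair resolution follows greedy, deterministic bookkeeping on batch
ledgers of effective sample size N_eff = 4/(1/N_cases + 1/N_controls):
within-batch duplicates drop the member with more missing genotypes;
case-control pairs keep the case; diagnostically concordant pairs keep
one member and may reassign it to the candidate batch with the smaller
N_eff:N ratio when that raises the destination's N_eff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metastats import effective_sample_size
from .simcohort import CohortPanel

__all__ = [
    "KinshipPair",
    "BatchLedger",
    "DUPLICATE_PHI",
    "FIRST_DEGREE_PHI",
    "hwe_chisq_p",
    "filter_variants_qc",
    "estimate_kinship",
    "resolve_pairs",
    "make_ledgers",
]

DUPLICATE_PHI = 2.0 ** (-3.0 / 2.0)  # 0.3536
FIRST_DEGREE_PHI = 2.0 ** (-5.0 / 2.0)  # 0.1768


@dataclass
class KinshipPair:
    id1: str
    id2: str
    n_snps: int
    phi: float
    relationship: str  # duplicate | first-degree | other
    same_batch: bool


@dataclass
class BatchLedger:
    """Case/control bookkeeping for one genotyping batch."""

    batch: str
    n_cases: int
    n_controls: int

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def n_eff(self) -> float:
        if self.n_cases <= 0 or self.n_controls <= 0:
            return 0.0
        return effective_sample_size(self.n_cases, self.n_controls)

    @property
    def ratio(self) -> float:
        return self.n_eff / self.n if self.n else 0.0


def make_ledgers(samples: pd.DataFrame) -> dict[str, BatchLedger]:
    """Build per-batch ledgers from a sample table (phenotype 1/2)."""
    out = {}
    for batch, grp in samples.groupby("batch"):
        out[str(batch)] = BatchLedger(
            batch=str(batch),
            n_cases=int((grp["phenotype"] == 2).sum()),
            n_controls=int((grp["phenotype"] == 1).sum()),
        )
    return out


def hwe_chisq_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> tuple[float, float]:
    """1-df chi-square Hardy-Weinberg test; returns (chi2, P).

    P is exactly 1 when observed genotype counts equal their
    Hardy-Weinberg expectation.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return np.nan, np.nan
    p = (2 * n_hom_alt + n_het) / (2 * n)
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    nz = exp > 0
    chi2 = float(((obs[nz] - exp[nz]) ** 2 / exp[nz]).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def filter_variants_qc(
    cohort: CohortPanel,
    max_missing: float = 0.02,
    hwe_p_min: float = 1e-6,
) -> tuple[CohortPanel, pd.DataFrame]:
    """Drop variants failing missingness or control-HWE filters.

    Returns the filtered cohort and an exclusion report with one row per
    removed variant (SNP, reason, value). HWE is computed in controls on
    genotypes rounded to the nearest integer call.
    """
    if not (0 < max_missing < 1 and 0 < hwe_p_min < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    if cohort.n_samples == 0 or cohort.n_snps == 0:
        raise ValueError("empty cohort")

    d = cohort.dosages
    missing = np.isnan(d).mean(axis=1)
    controls = cohort.samples["phenotype"].to_numpy() == 1
    records = []
    keep = np.ones(cohort.n_snps, dtype=bool)
    geno = np.rint(np.clip(d[:, controls], 0, 2))
    for j in range(cohort.n_snps):
        if missing[j] > max_missing:
            keep[j] = False
            records.append(
                {"SNP": cohort.variants["SNP"].iloc[j], "reason": "missingness", "value": missing[j]}
            )
            continue
        gj = geno[j][~np.isnan(geno[j])]
        if gj.size == 0:
            continue
        counts = [(gj == k).sum() for k in (0, 1, 2)]
        _, p_hwe = hwe_chisq_p(*counts)
        if np.isfinite(p_hwe) and p_hwe < hwe_p_min:
            keep[j] = False
            records.append(
                {"SNP": cohort.variants["SNP"].iloc[j], "reason": "hwe", "value": p_hwe}
            )

    filtered = CohortPanel(
        variants=cohort.variants.loc[keep].reset_index(drop=True),
        dosages=d[keep],
        samples=cohort.samples.copy(),
        info=None if cohort.info is None else cohort.info[keep],
    )
    report = pd.DataFrame(records, columns=["SNP", "reason", "value"])
    return filtered, report


def estimate_kinship(cohort: CohortPanel, min_shared: int = 100) -> pd.DataFrame:
    """KING-robust kinship for every sample pair.

    Genotypes are dosages rounded to the nearest call. Pairs with fewer
    than ``min_shared`` shared non-missing variants get a missing phi and
    relationship 'insufficient'. Output columns: ID1, ID2, N_SNPs, phi,
    relationship, same_batch.
    """
    if cohort.n_samples < 2:
        raise ValueError("need at least 2 samples")
    g = np.rint(np.clip(cohort.dosages, 0, 2))  # (m, n), NaN for missing
    valid = ~np.isnan(g)
    het = (g == 1) & valid
    hom0 = (g == 0) & valid
    hom2 = (g == 2) & valid

    H = het.astype(np.float64)
    A0 = hom0.astype(np.float64)
    A2 = hom2.astype(np.float64)
    V = valid.astype(np.float64)

    n_hh = H.T @ H
    n_opp = A0.T @ A2 + A2.T @ A0
    n_shared = V.T @ V
    het_shared = H.T @ V  # het in row-sample among sites valid in col-sample

    ids = cohort.samples["ID"].tolist()
    batches = cohort.samples["batch"].tolist()
    rows = []
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            shared = int(n_shared[i, j])
            denom = het_shared[i, j] + het_shared[j, i]
            if shared < min_shared or denom == 0:
                phi, rel = np.nan, "insufficient"
            else:
                phi = (n_hh[i, j] - 2.0 * n_opp[i, j]) / denom
                if phi > DUPLICATE_PHI:
                    rel = "duplicate"
                elif phi > FIRST_DEGREE_PHI:
                    rel = "first-degree"
                else:
                    rel = "other"
            rows.append(
                {
                    "ID1": ids[i],
                    "ID2": ids[j],
                    "N_SNPs": shared,
                    "phi": phi,
                    "relationship": rel,
                    "same_batch": batches[i] == batches[j],
                }
            )
    return pd.DataFrame(rows)


def _missing_rate(cohort: CohortPanel) -> dict[str, float]:
    rates = np.isnan(cohort.dosages).mean(axis=0)
    return dict(zip(cohort.samples["ID"], rates))


def resolve_pairs(
    pairs: pd.DataFrame,
    samples: pd.DataFrame,
    ledgers: dict[str, BatchLedger],
    missing_rates: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, BatchLedger]]:
    """Greedy keep/drop resolution of duplicate and first-degree pairs.

    Pairs are processed in descending phi order (ties broken on sample
    IDs). Within-batch duplicates drop the member with the larger missing
    fraction. Diagnostically discordant pairs keep the case. Concordant
    pairs keep the member with less missingness and may reassign it to
    whichever of the two batches has the smaller N_eff:N ratio, when the
    move does not decrease that batch's N_eff; otherwise the original
    batch is kept. Ledgers are updated after every decision.

    Returns (decisions, updated ledgers); decisions columns are
    ID_kept, ID_dropped, relationship, rule, batch_assigned.
    """
    if samples["ID"].duplicated().any():
        raise ValueError("sample appears more than once in the sample table")
    missing_rates = missing_rates or {}
    meta = samples.set_index("ID")
    ledgers = {b: BatchLedger(v.batch, v.n_cases, v.n_controls) for b, v in ledgers.items()}

    todo = pairs[pairs["relationship"].isin(["duplicate", "first-degree"])].copy()
    todo = todo.sort_values(["phi", "ID1", "ID2"], ascending=[False, True, True])

    dropped: set[str] = set()
    current_batch = dict(zip(samples["ID"], samples["batch"].astype(str)))
    decisions = []

    def _drop(sample_id: str) -> None:
        b = current_batch[sample_id]
        is_case = meta.loc[sample_id, "phenotype"] == 2
        if is_case:
            ledgers[b].n_cases -= 1
        else:
            ledgers[b].n_controls -= 1
        dropped.add(sample_id)

    for _, pr in todo.iterrows():
        i, j = pr["ID1"], pr["ID2"]
        if i in dropped or j in dropped:
            continue
        pheno_i, pheno_j = meta.loc[i, "phenotype"], meta.loc[j, "phenotype"]
        miss_i = missing_rates.get(i, 0.0)
        miss_j = missing_rates.get(j, 0.0)

        if pr["relationship"] == "duplicate" and current_batch[i] == current_batch[j]:
            if miss_i > miss_j or (miss_i == miss_j and i > j):
                keep, drop = j, i
            else:
                keep, drop = i, j
            rule = "within-batch duplicate: larger missingness dropped"
            _drop(drop)
            decisions.append(
                {"ID_kept": keep, "ID_dropped": drop, "relationship": pr["relationship"],
                 "rule": rule, "batch_assigned": current_batch[keep]}
            )
            continue

        if pheno_i != pheno_j:
            keep, drop = (i, j) if pheno_i == 2 else (j, i)
            rule = "discordant pair: case retained"
            _drop(drop)
            decisions.append(
                {"ID_kept": keep, "ID_dropped": drop, "relationship": pr["relationship"],
                 "rule": rule, "batch_assigned": current_batch[keep]}
            )
            continue

        # concordant pair: keep less-missing member, consider batch reassignment
        if miss_i > miss_j or (miss_i == miss_j and i > j):
            keep, drop = j, i
        else:
            keep, drop = i, j
        batch_keep, batch_drop = current_batch[keep], current_batch[drop]
        _drop(drop)
        assigned = batch_keep
        if batch_keep != batch_drop:
            is_case = meta.loc[keep, "phenotype"] == 2
            # a move is ameliorative when the destination's N_eff:N ratio does
            # not fall; keeping the current batch is always admissible
            scored = []
            for b in {batch_keep, batch_drop}:
                trial = BatchLedger(ledgers[b].batch, ledgers[b].n_cases, ledgers[b].n_controls)
                if b != batch_keep:
                    if is_case:
                        trial.n_cases += 1
                    else:
                        trial.n_controls += 1
                post = trial.ratio
                if b == batch_keep or post >= ledgers[b].ratio:
                    # prefer smaller prior ratio, then larger post ratio,
                    # then stay put (deterministic tie-break)
                    scored.append((ledgers[b].ratio, -post, b != batch_keep, b))
            preferred = min(scored)[3]
            if preferred != batch_keep:
                if is_case:
                    ledgers[batch_keep].n_cases -= 1
                    ledgers[preferred].n_cases += 1
                else:
                    ledgers[batch_keep].n_controls -= 1
                    ledgers[preferred].n_controls += 1
                assigned = preferred
                current_batch[keep] = preferred
        decisions.append(
            {"ID_kept": keep, "ID_dropped": drop, "relationship": pr["relationship"],
             "rule": "concordant pair: less-missing member retained", "batch_assigned": assigned}
        )

    cols = ["ID_kept", "ID_dropped", "relationship", "rule", "batch_assigned"]
    return pd.DataFrame(decisions, columns=cols), ledgers
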