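"""Fixed-effects and Han-Eskin RE2 meta-analysis with heterogeneity statistics.

Per variant, study effects (log-odds betas with standard errors) are
combined by inverse-variance weighting:

    w_i = 1/SE_i^2,  beta_FE = sum(w b)/sum(w),  SE_FE = 1/sqrt(sum(w)).

Between-study heterogeneity is summarized by Cochran's Q (chi-square with
k-1 df) and I^2 = max(0, (Q - df)/Q) * 100.

The RE2 statistic is the likelihood-ratio test of (mu = 0, tau^2 = 0)
against a free mean and non-negative between-study variance,

    S = 2 [ max_{mu, tau^2 >= 0} sum_i log N(b_i; mu, V_i + tau^2)
            - sum_i log N(b_i; 0, V_i) ],

whose asymptotic null is the equal mixture of chi-square(1) and
chi-square(2) (one parameter tested on the boundary). A simulated
small-k null table is available as an alternative reference
distribution.

Effective sample size for an imbalanced case-control study is
N_eff = 4 / (1/N_cases + 1/N_controls).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "effective_sample_size",
    "harmonize",
    "fixed_effects",
    "heterogeneity",
    "re2",
    "re2_null_table",
    "meta_analyze",
    "combine_sex_stratified",
    "GENOME_WIDE_P",
    "FOLLOW_UP_P",
]

GENOME_WIDE_P = 5e-8  # genome-wide significance
FOLLOW_UP_P = 1e-6  # replication follow-up threshold

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS = ({"A", "T"}, {"C", "G"})
AMBIGUOUS_FREQ_BAND = 0.08  # |freq - 0.5| below this -> uninformative


def effective_sample_size(n_cases: int, n_controls: int) -> float:
    """N_eff = 4/(1/N_cases + 1/N_controls)."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def _is_ambiguous(a1: str, a2: str) -> bool:
    return {a1, a2} in _AMBIGUOUS


def harmonize(
    stats_by_study: dict[str, pd.DataFrame],
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Align per-study effects to a common effect allele.

    The first study reporting a variant fixes the reference orientation.
    Swapped alleles flip the beta sign and complement the frequency;
    strand flips (complementary alleles) are recognized. Strand-ambiguous
    A/T and C/G variants are dropped whenever any study's frequency is
    within ``AMBIGUOUS_FREQ_BAND`` of 0.5; allele pairs matching neither
    orientation are dropped. Returns (aligned studies, drop report).
    """
    reference: dict[str, tuple[str, str]] = {}
    dropped: dict[str, str] = {}
    report_rows = []

    for study, df in stats_by_study.items():
        if df["SNP"].duplicated().any():
            dups = df.loc[df["SNP"].duplicated(), "SNP"].iloc[0]
            raise ValueError(f"duplicate variant id {dups!r} within study {study!r}")

    for study, df in stats_by_study.items():
        for snp, a1, a2, frq in zip(df["SNP"], df["A1"], df["A2"], df["FRQ"]):
            if snp in dropped:
                continue
            if _is_ambiguous(a1, a2) and abs(frq - 0.5) < AMBIGUOUS_FREQ_BAND:
                dropped[snp] = "ambiguous"
                report_rows.append({"SNP": snp, "study": study, "reason": "strand-ambiguous"})
                continue
            if snp not in reference:
                reference[snp] = (a1, a2)

    aligned: dict[str, pd.DataFrame] = {}
    for study, df in stats_by_study.items():
        df = df.copy()
        flip = np.zeros(len(df), dtype=bool)
        keep = np.ones(len(df), dtype=bool)
        for r, (snp, a1, a2) in enumerate(zip(df["SNP"], df["A1"], df["A2"])):
            if snp in dropped:
                keep[r] = False
                continue
            ref_a1, ref_a2 = reference[snp]
            ca1, ca2 = _COMPLEMENT.get(a1, "?"), _COMPLEMENT.get(a2, "?")
            if (a1, a2) == (ref_a1, ref_a2) or (ca1, ca2) == (ref_a1, ref_a2):
                continue
            if (a2, a1) == (ref_a1, ref_a2) or (ca2, ca1) == (ref_a1, ref_a2):
                flip[r] = True
            else:
                keep[r] = False
                report_rows.append({"SNP": snp, "study": study, "reason": "allele-mismatch"})
        if flip.any():
            df.loc[flip, "BETA"] = -df.loc[flip, "BETA"]
            df.loc[flip, "FRQ"] = 1.0 - df.loc[flip, "FRQ"]
            df.loc[flip, ["A1", "A2"]] = df.loc[flip, ["A2", "A1"]].to_numpy()
            if "OR" in df.columns:
                df.loc[flip, "OR"] = np.exp(df.loc[flip, "BETA"])
        aligned[study] = df.loc[keep].reset_index(drop=True)

    report = pd.DataFrame(report_rows, columns=["SNP", "study", "reason"])
    return aligned, report


def fixed_effects(betas, ses) -> tuple[float, float, float]:
    """Inverse-variance weighted combined effect: (beta_FE, SE_FE, P_FE)."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size < 1:
        raise ValueError("need at least one study")
    if (s <= 0).any():
        raise ValueError("standard errors must be positive")
    w = 1.0 / s**2
    beta = float((w * b).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return beta, se, p


def heterogeneity(betas, ses) -> tuple[float, float, float]:
    """Cochran's Q, its chi-square P (k-1 df), and I^2 in percent."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    k = b.size
    if k < 2:
        raise ValueError("heterogeneity requires at least two studies")
    w = 1.0 / s**2
    beta_fe = (w * b).sum() / w.sum()
    q = float((w * (b - beta_fe) ** 2).sum())
    df = k - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = float(max(0.0, (q - df) / q) * 100.0) if q > 0 else 0.0
    return q, p_q, i2


def heterogeneity_from_q(q: float, k: int) -> tuple[float, float]:
    """(P, I^2 %) for a reported Cochran's Q with k studies."""
    df = k - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = float(max(0.0, (q - df) / q) * 100.0) if q > 0 else 0.0
    return p_q, i2


def _re2_profile_nll(tau2: float, b: np.ndarray, v: np.ndarray) -> float:
    """Negative profile log-likelihood over mu at fixed tau^2 (constants dropped)."""
    var = v + tau2
    w = 1.0 / var
    mu = (w * b).sum() / w.sum()
    return 0.5 * (np.log(var).sum() + (w * (b - mu) ** 2).sum())


def _golden_min(f, lo: float, hi: float, tol: float = 1e-10) -> float:
    """Golden-section minimizer on [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while abs(b - a) > tol * max(1.0, abs(a) + abs(b)):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def re2_statistic(betas, ses) -> float:
    """Han-Eskin RE2 likelihood-ratio statistic (always >= the FE chi-square)."""
    b = np.asarray(betas, dtype=float)
    v = np.asarray(ses, dtype=float) ** 2
    if b.size < 2:
        raise ValueError("RE2 requires at least two studies")
    if (v <= 0).any():
        raise ValueError("standard errors must be positive")
    ll_null = -0.5 * (np.log(v).sum() + (b**2 / v).sum())
    hi = 100.0 * float(v.max())
    tau2 = _golden_min(lambda t: _re2_profile_nll(t, b, v), 0.0, hi)
    cand = [0.0, tau2]
    nll = min(_re2_profile_nll(t, b, v) for t in cand)
    stat = 2.0 * (-nll - ll_null)
    return float(max(stat, 0.0))


def re2_pvalue(stat: float, null: str = "asymptotic", table: np.ndarray | None = None) -> float:
    """P value for the RE2 statistic.

    ``asymptotic`` uses the equal chi-square(1)/chi-square(2) mixture;
    ``table`` uses an empirical null sample from :func:`re2_null_table`.
    """
    if null == "asymptotic":
        return float(0.5 * stats.chi2.sf(stat, 1) + 0.5 * stats.chi2.sf(stat, 2))
    if null == "table":
        if table is None:
            raise ValueError("null='table' requires a simulated null sample")
        n = table.size
        return float((np.count_nonzero(table >= stat) + 1) / (n + 1))
    raise ValueError(f"unknown null {null!r}")


def re2(betas, ses, null: str = "asymptotic", table: np.ndarray | None = None) -> tuple[float, float]:
    """(RE2 statistic, P value)."""
    s = re2_statistic(betas, ses)
    return s, re2_pvalue(s, null=null, table=table)


def re2_null_table(k: int, n_sim: int = 10_000, seed: int = 0, ses=None) -> np.ndarray:
    """Simulate the RE2 null distribution for k studies.

    Study effects are drawn from N(0, SE_i^2) (unit SEs by default) and
    the statistic recomputed; the returned sample backs the small-k
    empirical null option of :func:`re2_pvalue`.
    """
    rng = np.random.default_rng(seed)
    s = np.ones(k) if ses is None else np.asarray(ses, dtype=float)
    out = np.empty(n_sim)
    for i in range(n_sim):
        b = rng.normal(0.0, s)
        out[i] = re2_statistic(b, s)
    return out


def _direction_char(beta: float) -> str:
    return "+" if beta > 0 else ("-" if beta < 0 else "0")


def meta_analyze(
    stats_by_study: dict[str, pd.DataFrame],
    min_present: int = 2,
    null: str = "asymptotic",
    null_tables: dict[int, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Harmonize studies and combine every variant present in >= min_present.

    Output columns follow the daner meta convention: CHR SNP BP A1 A2 FRQ
    BETA SE P (fixed effects), OR, STAT_RE2 P_RE2, Q P_Q I2, DIR (one
    character per study in input order, '?' when absent), NCA NCO NEFF.
    """
    aligned, _ = harmonize(stats_by_study)
    studies = list(aligned)
    frames = {s: df.set_index("SNP") for s, df in aligned.items()}
    all_snps: list[str] = []
    seen = set()
    for df in aligned.values():
        for snp in df["SNP"]:
            if snp not in seen:
                seen.add(snp)
                all_snps.append(snp)

    rows = []
    for snp in all_snps:
        present = [s for s in studies if snp in frames[s].index]
        if len(present) < max(min_present, 1):
            continue
        recs = [frames[s].loc[snp] for s in present]
        b = np.array([r["BETA"] for r in recs], dtype=float)
        se = np.array([r["SE"] for r in recs], dtype=float)
        beta_fe, se_fe, p_fe = fixed_effects(b, se)
        if len(present) >= 2:
            q, p_q, i2 = heterogeneity(b, se)
            table = (null_tables or {}).get(len(present))
            stat_re2, p_re2 = re2(b, se, null=null if table is None else "table", table=table)
        else:
            q = p_q = i2 = stat_re2 = p_re2 = np.nan
        direction = "".join(
            _direction_char(float(frames[s].loc[snp, "BETA"])) if s in present else "?"
            for s in studies
        )
        nca = int(sum(r.get("Nca", 0) for r in recs))
        nco = int(sum(r.get("Nco", 0) for r in recs))
        neff = sum(
            effective_sample_size(int(r["Nca"]), int(r["Nco"]))
            for r in recs
            if r.get("Nca", 0) and r.get("Nco", 0)
        )
        w = 1.0 / se**2
        frq = float((w * np.array([r["FRQ"] for r in recs])).sum() / w.sum())
        first = recs[0]
        rows.append(
            {
                "CHR": first.get("CHR", "NA"),
                "SNP": snp,
                "BP": first.get("BP", -1),
                "A1": first["A1"],
                "A2": first["A2"],
                "FRQ": frq,
                "BETA": beta_fe,
                "SE": se_fe,
                "P": p_fe,
                "OR": float(np.exp(beta_fe)),
                "STAT_RE2": stat_re2,
                "P_RE2": p_re2,
                "Q": q,
                "P_Q": p_q,
                "I2": i2,
                "DIR": direction,
                "NCA": nca,
                "NCO": nco,
                "NEFF": neff,
            }
        )
    return pd.DataFrame(rows)


def combine_sex_stratified(
    male_stats: pd.DataFrame, female_stats: pd.DataFrame, null: str = "asymptotic"
) -> pd.DataFrame:
    """Combine male and female X-chromosome strata exactly like two studies.

    Variants present in only one stratum are passed through with
    ``one_stratum`` flagged and no heterogeneity/RE2 statistics.
    """
    combined = meta_analyze(
        {"male": male_stats, "female": female_stats}, min_present=1, null=null
    )
    combined["one_stratum"] = combined["DIR"].str.contains(r"\?")
    return combined
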