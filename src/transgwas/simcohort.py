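"""Synthetic multi-ancestry cohorts, reference panels, and dosage degradation.

The generator produces the statistical structure a trans-ancestry
case-control GWAS assumes, with known truth for every downstream stage:

* multi-population allele-frequency divergence via the Balding-Nichols
  model: population frequencies drawn from Beta(p(1-F)/F, (1-p)(1-F)/F)
  around a shared ancestral frequency p, where F is the per-population
  fixation index F_ST;
* block linkage disequilibrium induced by copying founder haplotype
  segments within fixed block boundaries (no recombination map);
* global (per-individual, not per-locus) admixture: each gamete is drawn
  from one continental population chosen by the individual's admixture
  proportions;
* a liability-threshold disease model: liability is the sum of
  standardized causal dosages times their effects plus Gaussian noise
  scaled so the genetic variance fraction equals the target h2; cases
  are individuals whose liability exceeds the threshold Phi^-1(1-K)
  for prevalence K, ascertained by rejection sampling;
* imputation-quality degradation to a target INFO score, and injection
  of duplicate samples and first-degree relatives for kinship QC tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReferencePanel",
    "SimTruth",
    "CohortPanel",
    "simulate_reference_panel",
    "simulate_cohort",
    "emulate_imputation",
    "inject_duplicates_relatives",
]

#: populations in the reference-panel sense (1000 Genomes continental labels)
DEFAULT_POPULATIONS = ("AFR", "EUR", "AMR", "EAS", "SAS")

REJECTION_CAP = 1_000_000  # liability-threshold ascertainment draw budget


@dataclass
class ReferencePanel:
    """Haplotype reference panel with per-population allele frequencies.

    ``freqs[k, j]`` is the Balding-Nichols model frequency of the counted
    (alternate) allele of variant ``j`` in population ``k``. ``founders``
    hold the haplotype pool segments are copied from; ``haplotypes`` are
    realized reference individuals (2 per individual) used as the LD
    reference downstream. ``blocks`` are the LD block start indices
    (first element 0, strictly increasing).
    """

    variants: pd.DataFrame
    populations: list[str]
    freqs: np.ndarray
    ancestral: np.ndarray
    founders: dict[str, np.ndarray]
    haplotypes: dict[str, np.ndarray]
    blocks: np.ndarray
    fst: dict[str, float]

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    def block_slices(self) -> list[slice]:
        bounds = list(self.blocks) + [self.n_snps]
        return [slice(bounds[i], bounds[i + 1]) for i in range(len(self.blocks))]

    def genotypes(self, population: str) -> np.ndarray:
        """Reference genotype dosages (n_snps, n_individuals) for one population."""
        haps = self.haplotypes[population]
        return (haps[0::2] + haps[1::2]).T.astype(float)


@dataclass
class SimTruth:
    """Ground-truth record for one simulated disease architecture.

    ``admixture`` is a (n_profiles, n_populations) array of admixture
    proportion profiles; each simulated individual draws one profile
    uniformly (one global proportion vector per individual, no local
    ancestry). ``effects`` are liability-scale effects per causal variant
    applied to standardized dosages.
    """

    causal_ids: list[str]
    effects: np.ndarray
    h2: float
    prevalence: float
    admixture: np.ndarray
    seed: int = 0
    fst: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        self.admixture = np.atleast_2d(np.asarray(self.admixture, dtype=float))
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"h2 must be in [0, 1], got {self.h2}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if not np.allclose(self.admixture.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("admixture proportions must sum to 1 per profile")
        if len(self.causal_ids) != len(self.effects):
            raise ValueError("causal_ids and effects length mismatch")


@dataclass
class CohortPanel:
    """Dosage matrix plus sample table for one cohort.

    ``dosages`` is (n_variants, n_samples) with NaN for missing calls.
    ``samples`` carries ID, sex (1/2), phenotype (1 control / 2 case),
    batch, and — for simulated cohorts — admixture proportions and the
    true genetic liability (columns prefixed ``truth_``). ``info`` is the
    per-variant imputation INFO score (NaN where undefined).
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    samples: pd.DataFrame
    info: np.ndarray | None = None

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def copy(self) -> "CohortPanel":
        return CohortPanel(
            variants=self.variants.copy(),
            dosages=self.dosages.copy(),
            samples=self.samples.copy(),
            info=None if self.info is None else self.info.copy(),
        )

    def phenotype01(self) -> np.ndarray:
        return self.samples["phenotype"].to_numpy() - 1


def _balding_nichols(ancestral: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    if fst == 0.0:
        return ancestral.copy()
    a = ancestral * (1.0 - fst) / fst
    b = (1.0 - ancestral) * (1.0 - fst) / fst
    return rng.beta(a, b)


def _haplotypes_from_founders(
    founders: np.ndarray, n_haps: int, block_slices: list[slice], rng: np.random.Generator
) -> np.ndarray:
    n_founders, n_snps = founders.shape
    out = np.empty((n_haps, n_snps), dtype=np.int8)
    for sl in block_slices:
        pick = rng.integers(0, n_founders, size=n_haps)
        out[:, sl] = founders[pick][:, sl]
    return out


def simulate_reference_panel(
    n_snps: int,
    populations: list[str] | tuple[str, ...] = DEFAULT_POPULATIONS,
    fst: float | dict[str, float] = 0.1,
    n_blocks: int = 50,
    seed: int = 0,
    n_founders: int = 100,
    n_ref: int = 100,
    chrom: str = "1",
    bp_spacing: int = 5_000,
) -> ReferencePanel:
    """Simulate a Balding-Nichols reference panel with block LD.

    Ancestral frequencies are uniform on [0.05, 0.95]; each population's
    frequencies are Balding-Nichols draws at its F_ST. Haplotypes copy
    founder segments within blocks, which induces LD inside blocks and
    none across block boundaries. Positions are a uniform 1-based grid
    on a single synthetic GRCh37-style chromosome.
    """
    if n_snps < 1 or n_blocks < 1 or n_snps < n_blocks:
        raise ValueError(f"need n_snps >= n_blocks >= 1, got {n_snps}, {n_blocks}")
    if n_founders < 2 or n_ref < 1:
        raise ValueError("n_founders must be >= 2 and n_ref >= 1")
    populations = list(populations)
    if isinstance(fst, dict):
        fst_map = {p: float(fst[p]) for p in populations}
    else:
        fst_map = {p: float(fst) for p in populations}
    for pop, f in fst_map.items():
        if not 0.0 <= f <= 0.5:
            raise ValueError(f"F_ST for {pop} must be in [0, 0.5], got {f}")

    rng = np.random.default_rng(seed)
    ancestral = rng.uniform(0.05, 0.95, size=n_snps)
    freqs = np.vstack([_balding_nichols(ancestral, fst_map[p], rng) for p in populations])

    positions = 1 + bp_spacing * np.arange(n_snps, dtype=np.int64)
    variants = pd.DataFrame(
        {
            "CHR": chrom,
            "SNP": [f"rs{chrom}_{pos}" for pos in positions],
            "BP": positions,
            "A1": "A",  # counted (alternate) allele
            "A2": "G",
        }
    )
    blocks = np.linspace(0, n_snps, n_blocks + 1)[:-1].astype(int)
    blocks = np.unique(blocks)
    bounds = list(blocks) + [n_snps]
    block_slices = [slice(bounds[i], bounds[i + 1]) for i in range(len(blocks))]

    founders: dict[str, np.ndarray] = {}
    haplotypes: dict[str, np.ndarray] = {}
    for k, pop in enumerate(populations):
        founders[pop] = (rng.random((n_founders, n_snps)) < freqs[k]).astype(np.int8)
        haplotypes[pop] = _haplotypes_from_founders(founders[pop], 2 * n_ref, block_slices, rng)

    return ReferencePanel(
        variants=variants,
        populations=populations,
        freqs=freqs,
        ancestral=ancestral,
        founders=founders,
        haplotypes=haplotypes,
        blocks=blocks,
        fst=fst_map,
    )


def _draw_genotypes(
    panel: ReferencePanel,
    pop_idx: np.ndarray,  # (n, 2) population index per gamete
    founder_idx: np.ndarray,  # (n, 2, n_blocks)
    snp_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Materialize genotypes for candidates given gamete population/founder picks."""
    slices = panel.block_slices()
    if snp_idx is None:
        cols = panel.n_snps
        col_of = None
    else:
        cols = len(snp_idx)
        col_of = snp_idx
    n = pop_idx.shape[0]
    geno = np.zeros((n, cols), dtype=np.int8)
    for g in (0, 1):
        for k, pop in enumerate(panel.populations):
            rows = np.flatnonzero(pop_idx[:, g] == k)
            if rows.size == 0:
                continue
            fnd = panel.founders[pop]
            for b, sl in enumerate(slices):
                if col_of is None:
                    geno[rows, sl] += fnd[founder_idx[rows, g, b], sl]
                else:
                    in_block = np.flatnonzero((col_of >= sl.start) & (col_of < sl.stop))
                    if in_block.size == 0:
                        continue
                    sub = col_of[in_block]
                    geno[np.ix_(rows, in_block)] += fnd[founder_idx[rows, g, b]][:, sub]
    return geno


def _mixture_freqs(panel: ReferencePanel, truth: SimTruth) -> np.ndarray:
    """Expected pooled allele frequency under the admixture profile mixture."""
    profile_mean = truth.admixture.mean(axis=0)  # profiles drawn uniformly
    return profile_mean @ panel.freqs


def simulate_cohort(
    panel: ReferencePanel,
    n_cases: int,
    n_controls: int,
    truth: SimTruth,
    batches: list[str] = ("batch1",),
    seed: int = 0,
    id_prefix: str = "S",
) -> CohortPanel:
    """Draw a liability-threshold ascertained case-control cohort.

    Each candidate individual draws an admixture profile, then two gametes
    (each from one population chosen by the profile, composed of founder
    segments per LD block). Genetic liability is the effect-weighted sum
    of standardized causal dosages; environmental noise is scaled so the
    genetic fraction of liability variance equals ``truth.h2``. Cases are
    candidates above the liability threshold Phi^-1(1 - K); rejection
    sampling stops with an error after ``REJECTION_CAP`` draws.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("n_cases and n_controls must be >= 1")
    if truth.admixture.shape[1] != len(panel.populations):
        raise ValueError("admixture profile width must match panel populations")
    snp_index = pd.Index(panel.variants["SNP"])
    causal_pos = snp_index.get_indexer(truth.causal_ids)
    if (causal_pos < 0).any():
        missing = [s for s, i in zip(truth.causal_ids, causal_pos) if i < 0]
        raise ValueError(f"causal variants absent from panel: {missing[:5]}")

    rng = np.random.default_rng(seed)
    n_blocks = len(panel.blocks)
    K = truth.prevalence
    thresh = stats.norm.isf(K)
    pooled = _mixture_freqs(panel, truth)
    p_c = pooled[causal_pos]
    sd_c = np.sqrt(np.maximum(2 * p_c * (1 - p_c), 1e-12))

    # liability is standardized to unit total variance so the threshold
    # Phi^-1(1-K) yields prevalence K: the genetic component is rescaled to
    # variance h2 using the empirical variance of the first candidate batch
    # (LD between causal variants and founder-pool frequency noise make the
    # realized genetic variance exceed sum(beta^2), so an analytic scale
    # would miss the h2 target), and noise has variance 1 - h2
    if truth.h2 > 0 and float(np.sum(truth.effects**2)) == 0:
        raise ValueError("h2 > 0 requires at least one nonzero causal effect")
    sigma_e = np.sqrt(1.0 - truth.h2) if truth.h2 > 0 else 1.0
    g_scale = 1.0  # set from the calibration batch when h2 > 0

    kept: list[dict[str, np.ndarray]] = []
    need_cases, need_controls = n_cases, n_controls
    drawn = 0
    batch_size = int(min(100_000, max(2_000, 4 * (n_cases / max(K, 1e-3) + n_controls))))
    while need_cases > 0 or need_controls > 0:
        if drawn >= REJECTION_CAP:
            raise RuntimeError(
                f"case ascertainment failed: {drawn} candidates drawn, still need "
                f"{need_cases} cases / {need_controls} controls (prevalence {K})"
            )
        m = int(min(batch_size, REJECTION_CAP - drawn))
        drawn += m
        prof = rng.integers(0, truth.admixture.shape[0], size=m)
        q = truth.admixture[prof]
        cum = np.cumsum(q, axis=1)
        u = rng.random((m, 2))
        pop_idx = (u[:, :, None] > cum[:, None, :]).sum(axis=2)
        founder_idx = rng.integers(
            0, min(f.shape[0] for f in panel.founders.values()), size=(m, 2, n_blocks)
        )
        if truth.h2 > 0:
            gc = _draw_genotypes(panel, pop_idx, founder_idx, snp_idx=causal_pos)
            g_liab = ((gc - 2 * p_c) / sd_c) @ truth.effects
            if drawn == m:  # calibration on the first batch
                var_g = float(np.var(g_liab)) if m > 1 else 1.0
                g_scale = np.sqrt(truth.h2 / max(var_g, 1e-12))
            g_liab = g_liab * g_scale
        else:
            g_liab = np.zeros(m)
        liab = g_liab + rng.normal(0.0, sigma_e, size=m)
        is_case = liab > thresh

        take_case = np.flatnonzero(is_case)[:need_cases]
        take_ctrl = np.flatnonzero(~is_case)[:need_controls]
        need_cases -= take_case.size
        need_controls -= take_ctrl.size
        take = np.concatenate([take_case, take_ctrl])
        if take.size:
            kept.append(
                {
                    "pop_idx": pop_idx[take],
                    "founder_idx": founder_idx[take],
                    "admix": q[take],
                    "g_liab": g_liab[take],
                    "liab": liab[take],
                    "case": is_case[take],
                }
            )

    pop_idx = np.concatenate([k["pop_idx"] for k in kept])
    founder_idx = np.concatenate([k["founder_idx"] for k in kept])
    admix = np.concatenate([k["admix"] for k in kept])
    g_liab = np.concatenate([k["g_liab"] for k in kept])
    liab = np.concatenate([k["liab"] for k in kept])
    case = np.concatenate([k["case"] for k in kept])

    order = np.argsort(~case, kind="stable")  # cases first, drawing order within
    geno = _draw_genotypes(panel, pop_idx[order], founder_idx[order]).astype(float)

    n = len(order)
    batches = list(batches)
    samples = pd.DataFrame(
        {
            "ID": [f"{id_prefix}{i:06d}" for i in range(n)],
            "sex": rng.integers(1, 3, size=n),
            "phenotype": np.where(case[order], 2, 1),
            "batch": [batches[i % len(batches)] for i in range(n)],
        }
    )
    for k, pop in enumerate(panel.populations):
        samples[f"Q_{pop}"] = admix[order, k]
    samples["truth_g_liab"] = g_liab[order]
    samples["truth_liability"] = liab[order]

    return CohortPanel(
        variants=panel.variants.copy(),
        dosages=geno.T,
        samples=samples,
        info=np.ones(panel.n_snps),
    )


def emulate_imputation(
    cohort: CohortPanel, target_info: float, seed: int = 0
) -> CohortPanel:
    """Degrade hard genotypes into dosages with a target INFO score.

    INFO is defined as dosage variance over the binomial variance
    2p(1-p). Output dosages blend the true genotype g with an independent
    frequency-matched genotype draw x ~ Binomial(2, p) and the
    frequency-conditioned expectation 2p:

        d = a*g + b*x + (1 - a - b)*2p,     t = target INFO,

    with (a, b) chosen so a^2 + b^2 = t: for t >= 1/2,
    a = (1 + sqrt(2t - 1))/2 and b = 1 - a; for t <= 1/2,
    a = b = sqrt(t/2). Either way d lies in [0, 2] by construction (no
    clamping that would distort the variance), E[d] = 2p, Var(d) =
    t * 2p(1-p) so the realized INFO approximates t, and corr(d, g)^2 =
    a^2/t. Monomorphic variants are left unchanged with INFO missing.
    """
    if not 0.0 < target_info <= 1.0:
        raise ValueError(f"target_info must be in (0, 1], got {target_info}")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    d = out.dosages
    p = np.nanmean(d, axis=1) / 2.0
    var = np.nanvar(d, axis=1)
    mono = (p <= 0) | (p >= 1) | (var == 0)
    info = np.full(cohort.n_snps, np.nan)
    t = target_info
    if t >= 0.5:
        a = (1.0 + np.sqrt(2.0 * t - 1.0)) / 2.0
        b = 1.0 - a
    else:
        a = b = np.sqrt(t / 2.0)
    poly = ~mono
    if poly.any():
        g = d[poly]
        pp = p[poly][:, None]
        x = rng.binomial(2, np.broadcast_to(pp, g.shape)).astype(float)
        noisy = a * g + b * x + (1.0 - a - b) * 2.0 * pp
        noisy[np.isnan(g)] = np.nan
        d[poly] = noisy
        p_out = np.nanmean(d[poly], axis=1) / 2.0
        denom = 2 * p_out * (1 - p_out)
        with np.errstate(invalid="ignore", divide="ignore"):
            info[poly] = np.nanvar(d[poly], axis=1) / denom
    out.info = info
    return out


def inject_duplicates_relatives(
    cohort: CohortPanel,
    n_duplicates: int,
    n_first_degree: int,
    seed: int = 0,
    panel: ReferencePanel | None = None,
) -> tuple[CohortPanel, pd.DataFrame]:
    """Append duplicate samples and first-degree offspring; return truth pairs.

    Duplicates are genotype copies; both members of a duplicate pair get
    independent random missingness masks (rate uniform in 1-3%).
    First-degree relatives are offspring of an existing parent: one gamete
    transmitted from the parent's genotype (Mendelian per variant), one
    drawn from a random mate with the parent's admixture profile (from
    ``panel`` founders when given, else allele frequencies implied by the
    cohort). The truth table lists (ID1, ID2, relationship).
    """
    if n_duplicates < 0 or n_first_degree < 0:
        raise ValueError("pair counts must be non-negative")
    if n_duplicates + n_first_degree == 0:
        return cohort, pd.DataFrame(columns=["ID1", "ID2", "relationship"])
    if n_duplicates + n_first_degree > cohort.n_samples:
        raise ValueError("requested pairs exceed cohort size")

    rng = np.random.default_rng(seed)
    out = cohort.copy()
    m = out.n_snps
    sources = rng.choice(out.n_samples, size=n_duplicates + n_first_degree, replace=False)
    dup_src, rel_src = sources[:n_duplicates], sources[n_duplicates:]
    batches = out.samples["batch"].unique().tolist()

    new_cols: list[np.ndarray] = []
    new_rows: list[dict] = []
    pairs: list[dict] = []

    for j, src in enumerate(dup_src):
        copy = out.dosages[:, src].copy()
        for vec in (out.dosages[:, src], copy):
            rate = rng.uniform(0.01, 0.03)
            mask = rng.random(m) < rate
            vec[mask] = np.nan
        row = out.samples.iloc[src].to_dict()
        src_id = row["ID"]
        row["ID"] = f"DUP{j:04d}_{src_id}"
        row["batch"] = batches[rng.integers(0, len(batches))]
        new_cols.append(copy)
        new_rows.append(row)
        pairs.append({"ID1": src_id, "ID2": row["ID"], "relationship": "duplicate"})

    for j, src in enumerate(rel_src):
        parent = out.dosages[:, src]
        g = np.where(np.isnan(parent), rng.integers(0, 3, size=m), np.rint(parent))
        g = np.clip(g, 0, 2)
        transmitted = (rng.random(m) < g / 2.0).astype(np.int8)
        if panel is not None:
            qcols = [f"Q_{p}" for p in panel.populations]
            q = out.samples.iloc[src][qcols].to_numpy(dtype=float)
            q = q / q.sum()
            pop = int(rng.choice(len(panel.populations), p=q))
            slices = panel.block_slices()
            mate_g = np.empty(m, dtype=np.int8)
            fnd = panel.founders[panel.populations[pop]]
            for sl in slices:
                mate_g[sl] = fnd[rng.integers(0, fnd.shape[0]), sl]
        else:
            p_hat = np.nanmean(out.dosages, axis=1) / 2.0
            mate_g = (rng.random(m) < p_hat).astype(np.int8)
        child = (transmitted + mate_g).astype(float)
        row = out.samples.iloc[src].to_dict()
        src_id = row["ID"]
        row["ID"] = f"REL{j:04d}_{src_id}"
        row["sex"] = int(rng.integers(1, 3))
        row["phenotype"] = int(rng.integers(1, 3))
        row["batch"] = batches[rng.integers(0, len(batches))]
        new_cols.append(child)
        new_rows.append(row)
        pairs.append({"ID1": src_id, "ID2": row["ID"], "relationship": "first-degree"})

    out.dosages = np.column_stack([out.dosages] + new_cols)
    out.samples = pd.concat([out.samples, pd.DataFrame(new_rows)], ignore_index=True)
    if out.info is not None:
        out.info = out.info.copy()
    return out, pd.DataFrame(pairs)
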