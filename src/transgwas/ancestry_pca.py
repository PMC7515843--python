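"""Relatedness matrix, principal components, and ancestry assignment.

The genetic relatedness matrix (GRM) averages standardized-dosage
cross-products over variants: dosages are centered at 2p and scaled by
sqrt(2p(1-p)), so unrelated outbred samples have expected diagonal 1 and
off-diagonal 0. Principal components are eigenvectors of the GRM scaled
by the square root of their eigenvalues.

Continental ancestry proportions (AFR/EUR/AMR/EAS/SAS) are estimated by
regressing reference-sample population membership indicators on top PCs,
applying the fitted model to study samples, and projecting the result
onto the probability simplex. Group assignment uses 25% thresholds:
African requires >= 25% AFR with < 25% of each of AMR/EAS/SAS; Latino
>= 25% AMR with < 25% AFR/EAS/SAS; European < 25% of all four; anything
else is unassigned (the EUR proportion itself is reported but never
thresholded).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg

from .simcohort import CohortPanel, ReferencePanel

__all__ = [
    "compute_grm",
    "pca",
    "estimate_proportions",
    "assign_group",
    "ancestry_pipeline",
    "simplex_project",
]

THRESHOLD = 0.25


def compute_grm(dosages: np.ndarray) -> np.ndarray:
    """GRM from a (n_variants, n_samples) dosage matrix.

    Monomorphic variants are skipped; missing dosages are mean-imputed
    before standardization. Raises if every variant is monomorphic or
    fewer than two samples are given.
    """
    d = np.asarray(dosages, dtype=float)
    if d.ndim != 2 or d.shape[1] < 2:
        raise ValueError("need a (n_variants, n_samples) matrix with >= 2 samples")
    p = np.nanmean(d, axis=1) / 2.0
    poly = (p > 0) & (p < 1) & (np.nanvar(d, axis=1) > 0)
    if not poly.any():
        raise ValueError("all variants are monomorphic")
    d = d[poly]
    p = p[poly][:, None]
    d = np.where(np.isnan(d), 2 * p, d)
    x = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
    return (x.T @ x) / x.shape[0]


def pca(grm: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k principal components of a GRM.

    Returns (coordinates, eigenvalues): coordinates are eigenvectors
    scaled by sqrt(eigenvalue) (clipped at zero), eigenvalues sorted
    non-increasing.
    """
    grm = np.asarray(grm, dtype=float)
    if grm.shape[0] != grm.shape[1] or not np.allclose(grm, grm.T, atol=1e-8):
        raise ValueError("GRM must be symmetric")
    if k > grm.shape[0]:
        raise ValueError("k exceeds sample count")
    vals, vecs = linalg.eigh(grm)
    order = np.argsort(vals)[::-1][:k]
    vals = vals[order]
    vecs = vecs[:, order]
    coords = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return coords, vals


def simplex_project(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    v = np.atleast_2d(np.asarray(v, dtype=float))
    u = np.sort(v, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    idx = np.arange(1, v.shape[1] + 1)
    cond = u - css / idx > 0
    rho = cond.sum(axis=1)
    theta = css[np.arange(v.shape[0]), rho - 1] / rho
    return np.maximum(v - theta[:, None], 0.0)


def estimate_proportions(
    sample_pcs: np.ndarray,
    ref_pcs: np.ndarray,
    ref_labels: list[str] | np.ndarray,
    populations: list[str] | None = None,
) -> pd.DataFrame:
    """Ancestry proportions by indicator regression on reference PCs.

    Fits ordinary least squares of one-hot population membership on the
    reference PCs (with intercept), applies the model to sample PCs, and
    projects each row onto the simplex. Output columns are the population
    labels in ``populations`` order (default: order of first appearance).
    """
    ref_labels = np.asarray(ref_labels)
    if populations is None:
        populations = list(dict.fromkeys(ref_labels.tolist()))
    if len(populations) < 2:
        raise ValueError("reference must span at least two populations")
    if len(ref_labels) < len(populations):
        raise ValueError("fewer reference samples than populations")
    if ref_pcs.shape[1] < len(populations) - 1:
        raise ValueError("PC dimension must be >= populations - 1")
    X_ref = np.column_stack([np.ones(len(ref_labels)), ref_pcs])
    Y = np.column_stack([(ref_labels == p).astype(float) for p in populations])
    coef, *_ = np.linalg.lstsq(X_ref, Y, rcond=None)
    X_s = np.column_stack([np.ones(sample_pcs.shape[0]), sample_pcs])
    raw = np.clip(X_s @ coef, 0.0, 1.0)
    props = simplex_project(raw)
    return pd.DataFrame(props, columns=populations)


def assign_group(profile) -> str:
    """25%-threshold broad ancestry group for one proportions record.

    ``profile`` is a mapping with keys AFR, AMR, EAS, SAS (EUR may be
    present but is not used by the rules).
    """
    afr, amr = profile["AFR"], profile["AMR"]
    eas, sas = profile["EAS"], profile["SAS"]
    t = THRESHOLD
    if afr >= t and amr < t and eas < t and sas < t:
        return "African"
    if amr >= t and afr < t and eas < t and sas < t:
        return "Latino"
    if afr < t and amr < t and eas < t and sas < t:
        return "European"
    return "unassigned"


def ancestry_pipeline(
    cohort: CohortPanel, panel: ReferencePanel, k_pcs: int = 10
) -> pd.DataFrame:
    """GRM -> PCA -> proportions -> group for a cohort against a panel.

    Reference individuals (panel haplotype pairs) and cohort samples are
    pooled into one GRM; proportions are fitted on the reference rows and
    applied to the cohort. Returns a table with ID, per-population
    proportions, top PCs, and the assigned group.
    """
    ref_mats, ref_labels = [], []
    for pop in panel.populations:
        g = panel.genotypes(pop)
        ref_mats.append(g)
        ref_labels.extend([pop] * g.shape[1])
    ref = np.hstack(ref_mats)
    combined = np.hstack([ref, cohort.dosages])
    grm = compute_grm(combined)
    coords, _ = pca(grm, min(k_pcs, combined.shape[1]))
    n_ref = ref.shape[1]
    props = estimate_proportions(
        coords[n_ref:], coords[:n_ref], ref_labels, populations=panel.populations
    )
    props.insert(0, "ID", cohort.samples["ID"].to_numpy())
    props["group"] = [assign_group(row) for _, row in props.iterrows()]
    for j in range(min(2, coords.shape[1])):
        props[f"PC{j + 1}"] = coords[n_ref:, j]
    return props
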