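"""Shared simulated fixtures: reference panels and liability-threshold cohorts."""

import numpy as np
import pytest

from transgwas import simcohort as sc


@pytest.fixture(scope="session")
def panel2():
    """Two-population (AFR/EUR) panel with block LD, F_ST 0.1."""
    return sc.simulate_reference_panel(
        n_snps=1500, populations=["AFR", "EUR"], fst=0.1, n_blocks=60, seed=11, n_ref=150
    )


@pytest.fixture(scope="session")
def panel5():
    """Five-population continental panel, F_ST 0.1."""
    return sc.simulate_reference_panel(
        n_snps=2500, populations=["AFR", "EUR", "AMR", "EAS", "SAS"], fst=0.1,
        n_blocks=60, seed=7, n_ref=80,
    )


def make_truth(panel, n_causal, h2, prevalence, admixture, seed):
    rng = np.random.default_rng(seed)
    causal = rng.choice(panel.variants["SNP"], size=n_causal, replace=False).tolist()
    effects = rng.normal(0.0, 1.0, size=n_causal)
    return sc.SimTruth(
        causal_ids=causal, effects=effects, h2=h2, prevalence=prevalence,
        admixture=admixture, seed=seed,
    )


@pytest.fixture(scope="session")
def eur_cohort(panel2):
    """EUR cohort, 500 cases / 500 controls, h2 = 0.5, prevalence 10%."""
    truth = make_truth(panel2, n_causal=40, h2=0.5, prevalence=0.1, admixture=[0, 1], seed=23)
    return sc.simulate_cohort(panel2, 500, 500, truth, batches=["b1", "b2"], seed=24)
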