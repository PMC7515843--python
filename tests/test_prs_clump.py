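"""Clumping vs brute force, sign tests, scoring, and liability-scale R^2."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from transgwas import prs_clump as pc, simcohort as sc
from conftest import make_truth


def brute_force_clump(snps, positions, pvals, r2_matrix, r2_max, window_bp):
    """Independent naive evaluation of the greedy clumping definition."""
    order = sorted(range(len(snps)), key=lambda i: (pvals[i], positions[i], snps[i]))
    assigned = {}
    clumps = {}
    for i in order:
        if snps[i] in assigned:
            continue
        assigned[snps[i]] = snps[i]
        clumps[snps[i]] = []
        for j in order:
            if snps[j] in assigned:
                continue
            if abs(positions[j] - positions[i]) <= window_bp and r2_matrix[i][j] >= r2_max:
                assigned[snps[j]] = snps[i]
                clumps[snps[i]].append(snps[j])
    return clumps


def ld_from_genotypes(geno, snps, positions):
    variants = pd.DataFrame({"SNP": snps, "CHR": "1", "BP": positions})
    return pc.LDReference(geno, variants)


def random_instance(rng, n):
    """Random <=6-variant instance with block-correlated genotypes."""
    base = rng.binomial(2, 0.4, size=(1, 400)).astype(float)
    geno = np.empty((n, 400))
    for i in range(n):
        mix = rng.uniform(0, 1)
        noise = rng.binomial(2, 0.4, size=400)
        geno[i] = np.where(rng.random(400) < mix, base[0], noise)
    snps = [f"v{i}" for i in range(n)]
    positions = np.sort(rng.choice(2_000_000, size=n, replace=False))
    pvals = rng.uniform(1e-12, 1, size=n)
    return geno, snps, positions, pvals


class TestClump:
    def test_matches_bruteforce_on_small_instances(self):
        rng = np.random.default_rng(5)
        for trial in range(60):
            n = int(rng.integers(1, 7))
            geno, snps, positions, pvals = random_instance(rng, n)
            ld = ld_from_genotypes(geno, snps, positions)
            stats_df = pd.DataFrame({"SNP": snps, "CHR": "1", "BP": positions, "P": pvals})
            got = {c.index_snp: sorted(s for s, _ in c.members)
                   for c in pc.clump(stats_df, ld, r2_max=0.1, window_kb=500)}
            r2m = [[ld.r2(a, b) for b in snps] for a in snps]
            want = {k: sorted(v) for k, v in
                    brute_force_clump(snps, positions, pvals, r2m, 0.1, 500_000).items()}
            assert got == want

    def test_three_variant_example(self):
        # r2(v0,v1)=1 within window; v2 independent
        rng = np.random.default_rng(0)
        a = rng.binomial(2, 0.5, 200).astype(float)
        c = rng.binomial(2, 0.5, 200).astype(float)
        geno = np.vstack([a, a, c])
        ld = ld_from_genotypes(geno, ["v0", "v1", "v2"], [100_000, 200_000, 300_000])
        stats_df = pd.DataFrame(
            {"SNP": ["v0", "v1", "v2"], "CHR": "1",
             "BP": [100_000, 200_000, 300_000], "P": [1e-10, 1e-8, 1e-5]}
        )
        clumps = pc.clump(stats_df, ld, r2_max=0.1, window_kb=500)
        assert [c.index_snp for c in clumps] == ["v0", "v2"]
        assert clumps[0].snps == ["v0", "v1"]

    def test_window_rule_separates_distant_pairs(self):
        rng = np.random.default_rng(1)
        a = rng.binomial(2, 0.5, 200).astype(float)
        geno = np.vstack([a, a])  # r2 = 1 but 600 kb apart
        ld = ld_from_genotypes(geno, ["v0", "v1"], [100_000, 700_000])
        stats_df = pd.DataFrame(
            {"SNP": ["v0", "v1"], "CHR": "1", "BP": [100_000, 700_000], "P": [1e-8, 1e-6]}
        )
        clumps = pc.clump(stats_df, ld, r2_max=0.1, window_kb=500)
        assert len(clumps) == 2

    def test_index_independence_invariant(self):
        rng = np.random.default_rng(2)
        geno, snps, positions, pvals = random_instance(rng, 6)
        ld = ld_from_genotypes(geno, snps, positions)
        stats_df = pd.DataFrame({"SNP": snps, "CHR": "1", "BP": positions, "P": pvals})
        clumps = pc.clump(stats_df, ld, r2_max=0.1, window_kb=500)
        pos = dict(zip(snps, positions))
        for i, a in enumerate(clumps):
            for b in clumps[i + 1 :]:
                if abs(pos[a.index_snp] - pos[b.index_snp]) <= 500_000:
                    assert ld.r2(a.index_snp, b.index_snp) < 0.1

    def test_higher_r2_ceiling_never_scores_fewer_snps(self, panel2, eur_cohort):
        from transgwas import assoc

        stats_df = assoc.logistic_gwas(eur_cohort, n_pcs=0, cohort_indicators=False)
        stats_df = stats_df[stats_df["flag"] == "ok"]
        ld = pc.LDReference.from_panel(panel2, "EUR")
        counts = [
            len(pc.model_from_stats(stats_df, ld, p_threshold=0.5, r2_ceiling=r).weights)
            for r in (0.1, 0.5, 0.8)
        ]
        assert counts[0] <= counts[1] <= counts[2]


class TestLdR2:
    def test_self_and_anticorrelated(self):
        rng = np.random.default_rng(3)
        a = rng.binomial(2, 0.5, 500).astype(float)
        ld = ld_from_genotypes(np.vstack([a, 2 - a]), ["x", "y"], [1, 2])
        assert ld.r2("x", "x") == pytest.approx(1.0)
        assert ld.r2("x", "y") == pytest.approx(1.0)

    def test_independent_variants_near_zero(self):
        rng = np.random.default_rng(4)
        geno = rng.binomial(2, 0.5, size=(40, 5000)).astype(float)
        ld = ld_from_genotypes(geno, [f"v{i}" for i in range(40)], np.arange(40))
        vals = [ld.r2(f"v{2*i}", f"v{2*i+1}") for i in range(20)]
        assert np.mean(vals) < 0.01

    def test_monomorphic_rejected(self):
        geno = np.vstack([np.ones(100), np.zeros(100)])
        ld = ld_from_genotypes(geno, ["x", "y"], [1, 2])
        with pytest.raises(ValueError):
            pc.ld_r2(ld, "x", "y")


class TestSignTest:
    def _stats(self, n, flips, seed=0):
        rng = np.random.default_rng(seed)
        snps = [f"v{i}" for i in range(n)]
        betas = rng.uniform(0.05, 0.3, n)
        train = pd.DataFrame(
            {"SNP": snps, "CHR": "1", "BP": np.arange(n) * 1_000_000,
             "A1": "A", "A2": "G", "FRQ": 0.3, "BETA": betas, "SE": 0.05,
             "P": 1e-8, "Nca": 100, "Nco": 100}
        )
        test = train.copy()
        test["BETA"] = [(-b if i in flips else b) for i, b in enumerate(betas)]
        geno = np.random.default_rng(1).binomial(2, 0.4, size=(n, 300)).astype(float)
        ld = ld_from_genotypes(geno, snps, train["BP"])
        return train, test, ld

    def test_perfect_concordance_tail(self):
        train, test, ld = self._stats(10, flips=set())
        frac, p, n, k = pc.sign_test(train, test, 0.05, ld)
        assert (n, k) == (10, 10)
        assert p == pytest.approx(0.5**10)
        assert p == pytest.approx(9.77e-4, rel=1e-3)

    def test_half_concordance_tail(self):
        train, test, ld = self._stats(10, flips={0, 1, 2, 3, 4})
        frac, p, n, k = pc.sign_test(train, test, 0.05, ld)
        assert (n, k) == (10, 5)
        assert p == pytest.approx(0.623046875)

    def test_reciprocal_roles_swap_cleanly(self):
        train, test, ld = self._stats(10, flips={0, 1})
        f1, p1, n1, k1 = pc.sign_test(train, test, 0.05, ld)
        f2, p2, n2, k2 = pc.sign_test(test, train, 0.05, ld)
        assert (n1, k1) == (n2, k2)

    def test_no_eligible_snps_rejected(self):
        train, test, ld = self._stats(5, flips=set())
        with pytest.raises(ValueError):
            pc.sign_test(train, test, 1e-30, ld)


class TestBuildPrs:
    def _cohort(self, dosage_rows):
        d = np.array(dosage_rows, dtype=float)
        m, n = d.shape
        variants = pd.DataFrame(
            {"CHR": "1", "SNP": [f"v{i}" for i in range(m)], "BP": np.arange(m),
             "A1": "A", "A2": "G"}
        )
        samples = pd.DataFrame(
            {"ID": [f"I{i}" for i in range(n)], "sex": 1, "phenotype": 1, "batch": "b"}
        )
        return sc.CohortPanel(variants, d, samples)

    def test_zero_weights_zero_scores(self):
        coh = self._cohort([[0, 1, 2], [2, 1, 0]])
        model = pc.PRSModel(
            weights=pd.DataFrame({"SNP": ["v0", "v1"], "A1": "A", "weight": [0.0, 0.0]}),
            p_threshold=1.0, r2_ceiling=0.1,
        )
        scores, used = pc.build_prs(model, coh)
        assert used == 2
        assert np.allclose(scores, 0.0)

    def test_hand_computed_dot_product(self):
        coh = self._cohort([[2.0], [1.0]])
        model = pc.PRSModel(
            weights=pd.DataFrame({"SNP": ["v0", "v1"], "A1": "A", "weight": [0.1, -0.2]}),
            p_threshold=1.0, r2_ceiling=0.1,
        )
        scores, _ = pc.build_prs(model, coh)
        assert scores[0] == pytest.approx(0.0)

    def test_allele_flip_shifts_scores_by_constant(self):
        rng = np.random.default_rng(5)
        coh = self._cohort(rng.binomial(2, 0.4, size=(3, 50)))
        w = pd.DataFrame({"SNP": ["v0", "v1", "v2"], "A1": "A", "weight": [0.1, -0.2, 0.3]})
        base, _ = pc.build_prs(pc.PRSModel(w, 1.0, 0.1), coh)
        w_flip = w.copy()
        w_flip.loc[0, "A1"] = "G"
        w_flip.loc[0, "weight"] = -0.1
        flipped, _ = pc.build_prs(pc.PRSModel(w_flip, 1.0, 0.1), coh)
        diff = flipped - base
        assert np.allclose(diff, diff[0])

    def test_all_absent_rejected(self):
        coh = self._cohort([[0, 1, 2]])
        model = pc.PRSModel(
            weights=pd.DataFrame({"SNP": ["zz"], "A1": "A", "weight": [0.1]}),
            p_threshold=1.0, r2_ceiling=0.1,
        )
        with pytest.raises(ValueError):
            pc.build_prs(model, coh)


class TestEvaluatePrs:
    def test_null_score_explains_nothing(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 2000)
        score = rng.normal(0, 1, 2000)
        ev = pc.evaluate_prs(score, y, None, 0.01)
        assert ev.nagelkerke_r2 < 0.005
        assert ev.p_value > 1e-4

    def test_null_pvalues_uniform_across_replicates(self):
        rng = np.random.default_rng(7)
        pvals = [
            pc.evaluate_prs(rng.normal(0, 1, 400), rng.integers(0, 2, 400), None, 0.01).p_value
            for _ in range(40)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_true_liability_recovers_h2_scale(self, panel2):
        r2s = []
        for rep in range(5):
            truth = make_truth(panel2, 30, 0.3, 0.01, [0, 1], seed=300 + rep)
            coh = sc.simulate_cohort(panel2, 600, 600, truth, seed=400 + rep)
            score = coh.samples["truth_g_liab"].to_numpy()
            ev = pc.evaluate_prs(score, coh.phenotype01(), None, 0.01)
            r2s.append(ev.liability_r2)
        assert 0.2 <= float(np.median(r2s)) <= 0.4

    def test_liability_r2_robust_to_ascertainment_ratio(self, panel2):
        truth = make_truth(panel2, 30, 0.3, 0.01, [0, 1], seed=310)
        r2 = {}
        for label, (nca, nco) in {"1:1": (800, 800), "1:3": (500, 1500)}.items():
            coh = sc.simulate_cohort(panel2, nca, nco, truth, seed=311)
            score = coh.samples["truth_g_liab"].to_numpy()
            r2[label] = pc.evaluate_prs(score, coh.phenotype01(), None, 0.01).liability_r2
        assert abs(r2["1:1"] - r2["1:3"]) / r2["1:1"] < 0.25

    def test_degenerate_phenotype_rejected(self):
        with pytest.raises(ValueError):
            pc.evaluate_prs(np.zeros(10), np.zeros(10), None, 0.01)


class TestLiabilityTransform:
    def test_unascertained_balanced_identity_region(self):
        # with P == K the transformation reduces to the classic K(1-K)/z^2 factor
        K = 0.25
        z = stats.norm.pdf(stats.norm.isf(K))
        expected = 0.1 * K * (1 - K) / z**2 * K * (1 - K) / (K * (1 - K))
        assert pc.liability_r2(0.1, K, K) == pytest.approx(expected / (1 + 0.1 * 0 * 1), rel=1e-6)

    def test_zero_maps_to_zero(self):
        assert pc.liability_r2(0.0, 0.01, 0.5) == 0.0


class TestLooAndJointModels:
    def _two_cohorts(self, panel2, seed):
        truth = make_truth(panel2, 30, 0.5, 0.1, [0, 1], seed=seed)
        a = sc.simulate_cohort(panel2, 300, 300, truth, seed=seed + 1, id_prefix="A")
        b = sc.simulate_cohort(panel2, 300, 300, truth, seed=seed + 2, id_prefix="B")
        return a, b

    def test_two_cohorts_training_is_other_gwas(self, panel2):
        from transgwas import assoc

        a, b = self._two_cohorts(panel2, 500)
        gwas_fn = lambda c: assoc.logistic_gwas(c, n_pcs=0, cohort_indicators=False)
        train = pc.loo_training({"A": a, "B": b}, target="B", gwas_fn=gwas_fn)
        direct = gwas_fn(a)
        assert np.allclose(
            train["BETA"].to_numpy(), direct["BETA"].to_numpy(), equal_nan=True
        )

    def test_target_missing_rejected(self, panel2):
        a, b = self._two_cohorts(panel2, 510)
        with pytest.raises(ValueError):
            pc.loo_training({"A": a, "B": b}, target="C", gwas_fn=lambda c: None)

    def test_sample_overlap_rejected(self, panel2):
        a, b = self._two_cohorts(panel2, 520)
        b.samples.loc[0, "ID"] = a.samples["ID"].iloc[0]
        with pytest.raises(ValueError, match="overlap"):
            pc.loo_training({"A": a, "B": b}, target="B", gwas_fn=lambda c: None)

    def test_joint_model_collinear_rejected(self):
        rng = np.random.default_rng(8)
        s = rng.normal(0, 1, 200)
        with pytest.raises(ValueError):
            pc.joint_model_test(s, s.copy(), rng.integers(0, 2, 200))

    def test_joint_model_detects_independent_signal(self, panel2):
        rng = np.random.default_rng(9)
        truth = make_truth(panel2, 30, 0.5, 0.1, [0, 1], seed=530)
        coh = sc.simulate_cohort(panel2, 500, 500, truth, seed=531)
        y = coh.phenotype01()
        g = coh.samples["truth_g_liab"].to_numpy()
        half_a = g / 2 + rng.normal(0, g.std(), len(g))
        informative = g + rng.normal(0, 0.3 * g.std(), len(g))
        noise = rng.normal(0, 1, len(g))
        p_signal, _ = pc.joint_model_test(half_a, informative, y)
        p_noise, _ = pc.joint_model_test(half_a, noise, y)
        assert p_signal < p_noise
        assert p_signal < 1e-3
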