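"""Risk predictors: association scan, clumping, BLUP prediction, evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from h2atlas.cohort import PhenotypeSet, SimScenario, simulate_genotypes, simulate_phenotype
from h2atlas.kinship import GRMSet, compute_grm, cross_grm, grms_from_partition
from h2atlas.prediction import (
    assoc_scan,
    build_grs,
    clump_best_per_window,
    cross_validate_predictors,
    evaluate_prediction,
    predict_multiblup,
)
from h2atlas.reml import VarianceComponentModel

from test_cohort import two_component_partition
from test_qc import geno_from_dosages


class TestAssocScan:
    def test_log_odds_matches_contingency_table(self):
        # cases: 30 alt / 70 ref; controls: 10 alt / 90 ref (0/1 dosages)
        d = np.zeros((200, 1))
        d[:30, 0] = 1      # cases with alt
        d[100:110, 0] = 1  # controls with alt
        y = np.zeros(200)
        y[:100] = 1
        g = geno_from_dosages(d)
        ph = PhenotypeSet(values=y, trait_type="binary")
        scan = assoc_scan(g, ph)
        expect = np.log(30 * 90 / (70 * 10))
        assert scan["beta"][0] == pytest.approx(expect, abs=1e-3)

    def test_no_difference_gives_null_effect(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.3, size=(400, 1)).astype(float)
        y = np.zeros(400)
        y[:200] = 1
        scan = assoc_scan(geno_from_dosages(d), PhenotypeSet(values=y, trait_type="binary"))
        assert abs(scan["beta"][0]) < 0.5
        assert scan["p"][0] > 0.01

    def test_permuted_phenotype_uniform_pvalues(self):
        rng = np.random.default_rng(3)
        g = simulate_genotypes(300, 150, seed=3)
        y = rng.permutation(np.repeat([0.0, 1.0], 150))
        scan = assoc_scan(g, PhenotypeSet(values=y, trait_type="binary"))
        ks = stats.kstest(scan["p"].dropna(), "uniform")
        assert ks.pvalue > 0.01


class TestGrs:
    def scan_frame(self, pos, p, beta=None):
        m = len(pos)
        return pd.DataFrame(
            {
                "snp_id": [f"s{j}" for j in range(m)],
                "chrom": np.ones(m, dtype=int),
                "pos": np.asarray(pos),
                "beta": np.ones(m) if beta is None else np.asarray(beta, float),
                "p": np.asarray(p),
            }
        )

    def test_one_per_megabase(self):
        scan = self.scan_frame([1_000_000, 1_500_000], [1e-10, 1e-9])
        kept = clump_best_per_window(scan, 5e-8, 1_000_000)
        assert len(kept) == 1
        assert kept["snp_id"].iloc[0] == "s0"  # smaller p wins

    def test_distant_hits_both_kept(self):
        scan = self.scan_frame([1_000_000, 2_500_000], [1e-10, 1e-9])
        assert len(clump_best_per_window(scan, 5e-8, 1_000_000)) == 2

    def test_score_arithmetic(self):
        d = np.array([[2.0, 1.0], [0.0, 1.0], [1.0, 1.0], [1.0, 0.0]])
        g = geno_from_dosages(d)
        scan = self.scan_frame([1000, 2_000_000], [1e-10, 1e-10], beta=[0.1, -0.2])
        scores = build_grs(scan, g, p_threshold=5e-8)
        assert scores[0] == pytest.approx(2 * 0.1 + 1 * -0.2, abs=1e-12)
        assert scores[0] == pytest.approx(0.0, abs=1e-12)

    def test_no_passing_snp_zero_scores(self):
        g = geno_from_dosages(np.array([[0.0], [1.0], [2.0]]))
        scan = self.scan_frame([1000], [0.5])
        assert np.all(build_grs(scan, g, p_threshold=1e-300) == 0)


class TestMultiBlup:
    def make(self, seed=5, n=200, m=800):
        g = simulate_genotypes(n, m, seed=seed)
        part = two_component_partition(m, 0.3, seed=seed)
        scen = SimScenario(
            n_samples=n, n_snps=m, n_causal=150, h2=0.6, seed=seed + 1,
            causal_source={"focal": 0.7, "rest": 0.3},
        )
        ph = simulate_phenotype(g, part, scen)
        grms = grms_from_partition(g, part)
        fit = VarianceComponentModel(ph.values, grms).fit()
        return g, part, ph, grms, fit

    def test_single_component_proportional_to_blup(self):
        g, part, ph, grms, _ = self.make()
        K, m_used = compute_grm(g)
        single = GRMSet(matrices=[K], snp_counts=[m_used], component_names=["all"])
        fit = VarianceComponentModel(ph.values, single).fit()
        test = g.subset_samples(np.arange(40))
        Kx, mx = cross_grm(g, test)
        cross = GRMSet(matrices=[Kx], snp_counts=[mx], component_names=["all"])
        weighted = predict_multiblup(fit, cross, weights="pct_h2g")
        plain = predict_multiblup(fit, cross, weights="unit")
        # single-component %h2g is 1, so the weighted score equals the BLUP
        assert np.allclose(weighted, plain, atol=1e-12)

    def test_degenerate_weight_concentration(self):
        g, part, ph, grms, fit = self.make()
        fit.params[:2] = [0.5, 0.0]  # all genetic variance in the focal slot
        test = g.subset_samples(np.arange(30))
        mats, cnts = [], []
        for name in grms.component_names:
            Kx, mc = cross_grm(g, test, part.snp_indices(name))
            mats.append(Kx)
            cnts.append(mc)
        cross = GRMSet(matrices=mats, snp_counts=cnts, component_names=list(grms.component_names))
        score = predict_multiblup(fit, cross, weights="pct_h2g")
        focal_only = fit.blup(cross=cross)["focal"]
        assert np.allclose(score, focal_only, atol=1e-12)


class TestEvaluate:
    def test_perfect_score(self):
        rng = np.random.default_rng(7)
        y = rng.standard_normal(300)
        ph = PhenotypeSet(values=y)
        scores = pd.DataFrame({"oracle": y})
        res = evaluate_prediction(ph, scores)
        assert res.r2_net["oracle"] == pytest.approx(1.0, abs=1e-10)

    def test_independent_score_near_zero(self):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(2000)
        scores = pd.DataFrame({"noise": rng.standard_normal(2000)})
        res = evaluate_prediction(PhenotypeSet(values=y), scores)
        assert abs(res.r2_net["noise"]) < 3 / np.sqrt(2000)

    def test_constant_score_flagged_zero(self):
        rng = np.random.default_rng(9)
        y = rng.standard_normal(100)
        res = evaluate_prediction(PhenotypeSet(values=y), pd.DataFrame({"c": np.ones(100)}))
        assert res.r2_net["c"] == 0.0

    def test_joint_regression_prefers_informative_predictor(self):
        rng = np.random.default_rng(10)
        g_true = rng.standard_normal(1000)
        y = g_true + rng.standard_normal(1000)
        blup = g_true + 0.3 * rng.standard_normal(1000)
        grs = blup + 2.0 * rng.standard_normal(1000)  # nested, noisier
        res = evaluate_prediction(
            PhenotypeSet(values=y), pd.DataFrame({"grs": grs, "blup": blup})
        )
        assert res.joint_p["blup"] < 1e-10
        assert res.joint_p["blup"] < res.joint_p["grs"]

    def test_r2_net_of_covariate_baseline(self):
        rng = np.random.default_rng(11)
        cov = rng.standard_normal(500)
        y = cov + rng.standard_normal(500)
        scores = pd.DataFrame({"cov_copy": cov})
        res = evaluate_prediction(PhenotypeSet(values=y), scores, covariates=cov)
        assert res.baseline_r2 > 0.3
        assert abs(res.r2_net["cov_copy"]) < 1e-10


class TestCrossValidation:
    def test_no_leakage_from_test_phenotypes(self):
        g = simulate_genotypes(120, 300, seed=15)
        part = two_component_partition(300, 0.3, seed=15)
        scen = SimScenario(n_samples=120, n_snps=300, n_causal=60, seed=16)
        ph = simulate_phenotype(g, part, scen)
        y2 = ph.values.copy()
        y2[:40] = np.random.default_rng(0).permutation(y2[:40])  # first fold shuffled
        ph2 = PhenotypeSet(values=y2)
        s1 = cross_validate_predictors(g, ph, part, fold_size=40, grs=False)
        s2 = cross_validate_predictors(g, ph2, part, fold_size=40, grs=False)
        # fold-1 scores are trained on folds 2-3, whose phenotypes are identical
        assert np.allclose(
            s1.loc[:39, ["blup", "multi_blup"]], s2.loc[:39, ["blup", "multi_blup"]]
        )
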