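"""AI-REML: likelihood identities, oracles, BLUP algebra, SE calibration."""

import numpy as np
import pytest

from h2atlas.cohort import SimScenario, simulate_genotypes, simulate_phenotype
from h2atlas.kinship import GRMSet, compute_grm, cross_grm, grms_from_partition
from h2atlas.partition import PartitionAssignment
from h2atlas.reml import VarianceComponentModel, blup_components, fit_reml, restricted_loglik

from test_cohort import two_component_partition


def make_fixture(n=120, m=600, h2=0.5, seed=1, focal_fraction=0.3):
    g = simulate_genotypes(n, m, seed=seed)
    part = two_component_partition(m, focal_fraction, seed=seed)
    scen = SimScenario(n_samples=n, n_snps=m, n_causal=m // 5, h2=h2, seed=seed + 1)
    ph = simulate_phenotype(g, part, scen)
    grms = grms_from_partition(g, part)
    return g, part, ph, grms


class TestLikelihood:
    def test_scaling_jacobian(self):
        # y -> c y with sigma2 -> c^2 sigma2 shifts l_R by -(n - p) log c
        g, part, ph, grms = make_fixture()
        sigma2 = np.array([0.2, 0.2, 0.6])
        c = 1.7
        n, p = 120, 1
        l0 = restricted_loglik(sigma2, grms, ph.values)
        l1 = restricted_loglik(c**2 * sigma2, grms, c * ph.values)
        assert l1 - l0 == pytest.approx(-(n - p) * np.log(c), abs=1e-8)

    def test_optimum_beats_random_perturbations(self):
        g, part, ph, grms = make_fixture()
        fit = fit_reml(grms, ph.values)
        rng = np.random.default_rng(5)
        l_opt = restricted_loglik(fit.params, grms, ph.values)
        for _ in range(100):
            pert = fit.params * np.exp(rng.uniform(-0.15, 0.15, size=3))
            pert = np.maximum(pert, 1e-8)
            assert restricted_loglik(pert, grms, ph.values) <= l_opt + 1e-8

    def test_balanced_single_component_closed_form(self):
        # K = J/n with no fixed effects: V has eigenvalues (e + a) on the mean
        # direction and e elsewhere, giving a hand-derived log-likelihood
        rng = np.random.default_rng(8)
        n = 40
        y = rng.standard_normal(n)
        K = np.ones((n, n)) / n
        grms = GRMSet(matrices=[K], snp_counts=[10], component_names=["mean"])
        a, e = 0.4, 0.8
        model = VarianceComponentModel(y, grms, exog=np.zeros((n, 0)))
        got = model.loglike([a, e])
        s1 = y.sum() ** 2 / n
        ss_dev = (y**2).sum() - s1
        expect = -0.5 * (np.log(e + a) + (n - 1) * np.log(e) + s1 / (e + a) + ss_dev / e)
        assert got == pytest.approx(expect, abs=1e-8)

    def test_non_pd_rejected(self):
        g, part, ph, grms = make_fixture()
        with pytest.raises(ValueError):
            restricted_loglik([-5.0, -5.0, 1e-12], grms, ph.values)


class TestFit:
    def test_null_recovery_within_analytic_se(self):
        # pure noise: unconstrained genetic estimates stay within 3 SE of zero
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            g = simulate_genotypes(150, 800, seed=seed)
            part = two_component_partition(800, 0.3, seed=seed)
            grms = grms_from_partition(g, part)
            y = rng.standard_normal(150)
            fit = VarianceComponentModel(y, grms).fit(constrain_nonnegative=False)
            se = fit.bse()
            for i in range(2):
                assert abs(fit.params[i]) < 3 * se[i]

    def test_identity_grm_flags_degeneracy(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(60)
        grms = GRMSet(matrices=[np.eye(60)], snp_counts=[5], component_names=["iid"])
        fit = VarianceComponentModel(y, grms).fit()
        assert fit.degenerate

    def test_loglik_trace_monotone(self):
        g, part, ph, grms = make_fixture(seed=9)
        fit = fit_reml(grms, ph.values)
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs > -1e-7)

    def test_ai_and_pure_em_agree(self):
        # fixture with an interior optimum: both components carry signal
        g = simulate_genotypes(150, 600, seed=4)
        part = two_component_partition(600, 0.5, seed=4)
        scen = SimScenario(
            n_samples=150, n_snps=600, n_causal=200, h2=0.6, seed=5,
            causal_source={"focal": 0.5, "rest": 0.5},
        )
        ph = simulate_phenotype(g, part, scen)
        grms = grms_from_partition(g, part)
        ai_fit = VarianceComponentModel(ph.values, grms).fit()
        em_fit = VarianceComponentModel(ph.values, grms).fit(
            em_burnin=5000, max_iter=5000, tol=1e-12
        )
        assert np.allclose(ai_fit.params, em_fit.params, atol=1e-4)

    def test_constrained_fit_flags_boundary(self):
        rng = np.random.default_rng(11)
        g = simulate_genotypes(100, 500, seed=11)
        part = two_component_partition(500, 0.3, seed=11)
        grms = grms_from_partition(g, part)
        y = rng.standard_normal(100)  # no signal: some component hits the floor
        fit = VarianceComponentModel(y, grms).fit()
        assert np.all(fit.params >= 0)
        assert fit.constrained.dtype == bool


class TestBlup:
    def test_zero_variance_component_zero_blup(self):
        g, part, ph, grms = make_fixture(seed=6)
        fit = fit_reml(grms, ph.values)
        fit.params[0] = 0.0
        preds = blup_components(fit)
        assert np.allclose(preds[grms.component_names[0]], 0.0)

    def test_ridge_equivalence_single_component(self):
        # BLUP sigma2_g K V^-1 (y - X beta) equals ridge on standardized
        # genotypes with penalty M sigma2_e / sigma2_g
        n, m = 30, 10
        g = simulate_genotypes(n, m, seed=13)
        K, m_used = compute_grm(g)
        grms = GRMSet(matrices=[K], snp_counts=[m_used], component_names=["all"])
        ph_rng = np.random.default_rng(14)
        y = ph_rng.standard_normal(n)
        model = VarianceComponentModel(y, grms)
        fit = model.fit()
        s_g, s_e = fit.params
        if s_g < 1e-6:  # force an interior point for the identity check
            fit.params[:] = [0.3, 0.7]
            s_g, s_e = fit.params
        pred = fit.blup()["all"]
        p = g.dosages.mean(0) / 2
        W = (g.dosages - 2 * p) / np.sqrt(2 * p * (1 - p))
        V = s_g * K + s_e * np.eye(n)
        X = np.ones((n, 1))
        beta = np.linalg.solve(X.T @ np.linalg.solve(V, X), X.T @ np.linalg.solve(V, y))
        resid = y - X @ beta
        lam = m_used * s_e / s_g
        ridge = W @ np.linalg.solve(W.T @ W + lam * np.eye(m_used), W.T @ resid)
        assert np.allclose(pred, ridge, atol=1e-8)

    def test_in_sample_mixed_model_identity(self):
        # X beta + sum_i g_i + sigma2_e P y reconstructs y exactly
        g, part, ph, grms = make_fixture(seed=7)
        fit = fit_reml(grms, ph.values)
        preds = fit.blup()
        work = fit.model._work_at(fit.params)
        recon = fit.model.exog @ fit.fe_params + sum(preds.values()) + fit.params[-1] * work.Py
        assert np.allclose(recon, ph.values, atol=1e-8)

    def test_out_of_sample_requires_component(self):
        g, part, ph, grms = make_fixture(seed=8)
        fit = fit_reml(grms, ph.values)
        Kx, mx = cross_grm(g, g.subset_samples(np.arange(10)))
        bad = GRMSet(matrices=[Kx], snp_counts=[mx], component_names=["unknown"])
        with pytest.raises(KeyError):
            fit.blup(cross=bad)


class TestSubsetConsistency:
    def test_split_half_meta_agrees_with_full(self):
        from h2atlas.pipeline import simulate_cohort, fit_joint_model, split_half_meta

        scen = SimScenario(n_samples=400, n_snps=1200, n_causal=200, seed=31)
        sim = simulate_cohort(scen)
        full = fit_joint_model(sim.geno, sim.pheno, sim.partition)
        meta = split_half_meta(sim.geno, sim.pheno, sim.partition)
        se = np.hypot(full.se_h2_total, meta["se_h2_total"])
        assert abs(full.h2_total - meta["h2_total"]) < 2 * se
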