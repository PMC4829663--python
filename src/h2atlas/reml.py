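"""Multi-component restricted maximum likelihood via Average Information.

The model is y = X b + sum_i g_i + e with g_i ~ N(0, sigma2_i K_i) for each
per-annotation genetic relationship matrix K_i and e ~ N(0, sigma2_e I).  The
restricted log-likelihood

    l_R(theta) = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    V = sum_i sigma2_i K_i + sigma2_e I,
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1,

is maximised by Newton steps that use the Average Information matrix
AI_ij = 1/2 y' P K_i P K_j P y in place of the Hessian, with the score
s_i = -1/2 [ tr(P K_i) - y' P K_i P y ].  The first iteration is an EM step
from an equal split of the phenotypic variance, which stabilises the AI
updates; step-halving guards each Newton step and an EM step substitutes
when the AI matrix is singular.  The inverse AI matrix at convergence is the
error covariance of the variance-component estimates.

Estimates are constrained non-negative by default: a component driven to the
boundary is held at a small floor (1e-8 * var(y)) and flagged, mirroring how
reported 0.0% components arise in constrained GREML fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .kinship import GRMSet

logger = logging.getLogger(__name__)

__all__ = ["VarianceComponentModel", "REMLResults", "fit_reml", "restricted_loglik", "blup_components"]


class _Working:
    """Per-iteration REML working quantities at a given theta."""

    __slots__ = ("V_chol", "Vinv", "P", "Py", "loglik", "beta", "xtvix_inv")

    def __init__(self, theta, Ks, y, X):
        n = len(y)
        V = theta[-1] * np.eye(n)
        for s, K in zip(theta[:-1], Ks):
            V += s * K
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        self.V_chol = (c, low)
        Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
        logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
        if X.shape[1] > 0:
            VinvX = Vinv @ X
            xtvix = X.T @ VinvX
            cx = linalg.cho_factor(xtvix, check_finite=False)
            self.xtvix_inv = linalg.cho_solve(cx, np.eye(X.shape[1]), check_finite=False)
            logdet_x = 2.0 * np.sum(np.log(np.diag(cx[0])))
            self.P = Vinv - VinvX @ self.xtvix_inv @ VinvX.T
            self.beta = self.xtvix_inv @ (VinvX.T @ y)
        else:
            self.xtvix_inv = np.zeros((0, 0))
            logdet_x = 0.0
            self.P = Vinv
            self.beta = np.zeros(0)
        self.Vinv = Vinv
        self.Py = self.P @ y
        ytPy = float(y @ self.Py)
        self.loglik = -0.5 * (logdet_V + logdet_x + ytPy)


def _score_and_ai(work: _Working, Ks, y):
    """REML score vector and Average Information matrix at the working point."""
    k = len(Ks) + 1
    Py = work.Py
    t = [K @ Py for K in Ks] + [Py]  # residual component has K = I
    score = np.empty(k)
    for i in range(k):
        tr = float(np.sum(work.P * Ks[i])) if i < k - 1 else float(np.trace(work.P))
        score[i] = -0.5 * (tr - float(Py @ t[i]))
    Pt = [work.P @ ti for ti in t]
    ai = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ai[i, j] = ai[j, i] = 0.5 * float(t[i] @ Pt[j])
    return score, ai


@dataclass
class REMLResults:
    """Variance-component estimates with uncertainty and diagnostics.

    ``params`` holds the genetic components in GRM order followed by the
    residual; ``cov_params`` is the inverse Average Information matrix at
    convergence (rows/columns of boundary-constrained components retained and
    flagged via ``constrained``).
    """

    model: "VarianceComponentModel"
    params: np.ndarray
    cov_params: np.ndarray
    fe_params: np.ndarray
    loglik_trace: list[float]
    converged: bool
    n_iter: int
    constrained: np.ndarray
    degenerate: bool = False

    @property
    def sigma2(self) -> np.ndarray:
        return self.params

    @property
    def component_names(self) -> list[str]:
        return list(self.model.grms.component_names) + ["residual"]

    @property
    def llf(self) -> float:
        return self.loglik_trace[-1]

    @property
    def sigma2_genetic(self) -> np.ndarray:
        return self.params[:-1]

    @property
    def sigma2_residual(self) -> float:
        return float(self.params[-1])

    @property
    def total_phenotypic_variance(self) -> float:
        return float(self.params.sum())

    @property
    def h2_total(self) -> float:
        """Total SNP heritability: genetic variance over all fitted components
        including the environmental term."""
        return float(self.sigma2_genetic.sum() / self.total_phenotypic_variance)

    def bse(self) -> np.ndarray:
        return np.sqrt(np.maximum(np.diag(self.cov_params), 0.0))

    def blup(self, cross: GRMSet | None = None) -> dict[str, np.ndarray]:
        """Per-component genetic-value predictions g_i = sigma2_i K_i P y.

        With ``cross`` (rectangular test x train GRMs) the prediction is made
        into the held-out samples: g_i,new = sigma2_i K_i,cross P y.
        """
        work = self.model._work_at(self.params)
        Py = work.Py
        out = {}
        if cross is None:
            for name, s, K in zip(self.model.grms.component_names, self.params[:-1], self.model.grms):
                out[name] = s * (K @ Py)
        else:
            for name in cross.component_names:
                if name not in self.model.grms.component_names:
                    raise KeyError(f"component {name!r} absent from the fitted model")
            for name, Kc in zip(cross.component_names, cross):
                i = self.model.grms.component_names.index(name)
                out[name] = self.params[i] * (Kc @ Py)
        return out

    def partition_h2(self, pct_snps=None):
        """Heritability partition of this fit (delegates to enrichment)."""
        from .enrichment import partition_h2

        return partition_h2(self, pct_snps=pct_snps)

    def summary(self, pct_snps=None) -> str:
        """Tab-separated per-component table mirroring the field's usual layout:
        component, sigma2, SE, h2_obs, %h2g, %SNPs, Z, p."""
        from .enrichment import partition_h2

        hp = partition_h2(self, pct_snps=pct_snps)
        lines = [
            "component\tsigma2\tse_sigma2\th2_obs\tpct_h2g\tse_pct_h2g\tpct_snps\tz\tp",
        ]
        se = self.bse()
        for i, name in enumerate(self.model.grms.component_names):
            z = hp.z[i] if hp.z is not None else np.nan
            p = hp.p[i] if hp.p is not None else np.nan
            ps = hp.pct_snps[i] if hp.pct_snps is not None else np.nan
            lines.append(
                f"{name}\t{self.params[i]:.6f}\t{se[i]:.6f}\t{hp.h2_obs[i]:.6f}"
                f"\t{100 * hp.pct_h2g[i]:.3f}\t{100 * hp.se_pct_h2g[i]:.3f}"
                f"\t{100 * ps:.3f}\t{z:.3f}\t{p:.3g}"
            )
        lines.append(f"residual\t{self.params[-1]:.6f}\t{se[-1]:.6f}")
        lines.append(
            f"# h2_total={self.h2_total:.6f} loglik={self.llf:.6f} "
            f"converged={self.converged} n_iter={self.n_iter} "
            f"constrained={','.join(np.asarray(self.component_names)[self.constrained]) or 'none'}"
        )
        return "\n".join(lines)


class VarianceComponentModel:
    """Multi-GRM variance-component model of a quantitative phenotype.

    Parameters
    ----------
    endog : (N,) phenotype (case-control status is fitted as 0/1 on the
        observed scale and transformed to liability downstream).
    grms : GRMSet of genetic components.
    exog : (N, p) fixed-effect design; defaults to an intercept.
    """

    def __init__(self, endog, grms: GRMSet, exog=None):
        self.endog = np.asarray(endog, dtype=np.float64)
        n = len(self.endog)
        if exog is None:
            exog = np.ones((n, 1))
        self.exog = np.atleast_2d(np.asarray(exog, dtype=np.float64))
        if self.exog.shape[0] != n:
            raise ValueError("exog rows must match endog")
        if grms.n_samples != n:
            raise ValueError("GRM dimension must match endog")
        if self.endog.var() <= 0:
            raise ValueError("phenotype has zero variance")
        if n <= self.exog.shape[1] + grms.n_components:
            raise ValueError("need N > n_covariates + n_components")
        self.grms = grms

    # -- likelihood ---------------------------------------------------------

    def _work_at(self, theta) -> _Working:
        return _Working(np.asarray(theta, dtype=np.float64), self.grms.matrices, self.endog, self.exog)

    def loglike(self, sigma2) -> float:
        """Restricted log-likelihood (up to the usual constant) at sigma2 =
        (genetic components..., residual)."""
        sigma2 = np.asarray(sigma2, dtype=np.float64)
        if len(sigma2) != self.grms.n_components + 1:
            raise ValueError("sigma2 must have one entry per component plus residual")
        try:
            return self._work_at(sigma2).loglik
        except linalg.LinAlgError as exc:
            raise ValueError("V is not positive definite at sigma2") from exc

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        max_iter: int = 100,
        tol: float = 1e-6,
        constrain_nonnegative: bool = True,
        em_burnin: int = 1,
        start=None,
    ) -> REMLResults:
        """Fit by AI-REML with an EM burn-in from equal-split initialization."""
        y = self.endog
        k = self.grms.n_components + 1
        n = len(y)
        vary = float(y.var())
        floor = 1e-8 * vary
        theta = np.full(k, vary / k) if start is None else np.asarray(start, dtype=np.float64).copy()

        work = self._work_at(theta)
        trace = [work.loglik]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            score, ai = _score_and_ai(work, self.grms.matrices, y)
            # active set: components pinned at the floor whose score pushes
            # them further down are held fixed this iteration
            if constrain_nonnegative:
                free = ~((theta <= floor * (1 + 1e-6)) & (score < 0))
                if not free.any():
                    free = np.ones(k, dtype=bool)
            else:
                free = np.ones(k, dtype=bool)
            if it <= em_burnin:
                # EM update: theta_i <- theta_i + theta_i^2 (y'P K_i P y - tr(P K_i)) / n
                delta = theta**2 * (2.0 * score) / n
            else:
                delta = np.zeros(k)
                try:
                    delta[free] = linalg.solve(
                        ai[np.ix_(free, free)], score[free], assume_a="sym"
                    )
                except linalg.LinAlgError:
                    logger.info("singular AI matrix at iteration %d; EM fallback", it)
                    delta = theta**2 * (2.0 * score) / n
            # step-halving until the restricted likelihood does not decrease
            step = 1.0
            new_work = None
            for _ in range(12):
                prop = theta + step * delta
                if constrain_nonnegative:
                    prop = np.maximum(prop, floor)
                elif prop[-1] <= 0:
                    step *= 0.5
                    continue
                try:
                    cand = self._work_at(prop)
                except linalg.LinAlgError:
                    step *= 0.5
                    continue
                if cand.loglik >= work.loglik - 1e-10:
                    new_work = cand
                    break
                step *= 0.5
            if new_work is None:
                # fall back to a guarded EM step
                prop = theta + theta**2 * (2.0 * score) / n
                if constrain_nonnegative:
                    prop = np.maximum(prop, floor)
                try:
                    new_work = self._work_at(prop)
                except linalg.LinAlgError:
                    logger.warning("REML step failed at iteration %d; stopping", it)
                    break
            rel = np.max(np.abs(prop - theta) / (np.abs(theta) + 1e-8))
            dll = new_work.loglik - work.loglik
            theta, work = prop, new_work
            trace.append(work.loglik)
            if it > em_burnin and rel < tol and abs(dll) < 1e-8:
                converged = True
                break

        score, ai = _score_and_ai(work, self.grms.matrices, y)
        constrained = theta <= floor * (1 + 1e-6)
        degenerate = False
        try:
            cond = np.linalg.cond(ai)
            if not np.isfinite(cond) or cond > 1e12:
                degenerate = True
            cov = np.linalg.pinv(ai) if degenerate else linalg.inv(ai)
        except linalg.LinAlgError:
            degenerate = True
            cov = np.linalg.pinv(ai)
        cov = 0.5 * (cov + cov.T)
        if degenerate:
            logger.warning("AI matrix ill-conditioned at optimum; components may be non-identifiable")
        if not converged:
            logger.warning("REML did not converge after %d iterations", it)
        return REMLResults(
            model=self,
            params=theta,
            cov_params=cov,
            fe_params=work.beta,
            loglik_trace=trace,
            converged=converged,
            n_iter=it,
            constrained=constrained,
            degenerate=degenerate,
        )


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------


def fit_reml(
    grms: GRMSet,
    y,
    X=None,
    max_iter: int = 100,
    tol: float = 1e-6,
    constrain_nonnegative: bool = True,
) -> REMLResults:
    """Fit the multi-component model; see VarianceComponentModel.fit."""
    return VarianceComponentModel(y, grms, exog=X).fit(
        max_iter=max_iter, tol=tol, constrain_nonnegative=constrain_nonnegative
    )


def restricted_loglik(sigma2, grms: GRMSet, y, X=None) -> float:
    """Restricted log-likelihood at fixed variance components (grid oracle)."""
    return VarianceComponentModel(y, grms, exog=X).loglike(sigma2)


def blup_components(fit: REMLResults, cross: GRMSet | None = None) -> dict[str, np.ndarray]:
    """Per-component BLUPs of genetic values (in-sample, or out-of-sample via
    rectangular cross GRMs)."""
    return fit.blup(cross=cross)
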