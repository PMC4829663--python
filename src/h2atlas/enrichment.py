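"""From variance components to reported quantities.

Converts a REML fit into per-component SNP heritability (h2_obs, with the
residual in the denominator), the share of genetic variance per component
(%h2g, genetic-only denominator) with delta-method standard errors, the
enrichment Z-test of %h2g against the component's share of SNPs, the
observed-to-liability-scale transformation for case-control traits,
inverse-variance meta-analysis across studies or study halves, and the
two-stage model-selection workflow (marginal scan -> grouped joint model ->
selected model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .partition import ModelSpec
from .reml import REMLResults

logger = logging.getLogger(__name__)

__all__ = [
    "HeritabilityPartition",
    "partition_h2",
    "enrichment_test",
    "liability_transform",
    "meta_analyze",
    "select_model",
    "conditional_scan",
]


@dataclass
class HeritabilityPartition:
    """Per-component heritability estimates of one fitted model."""

    component_names: list[str]
    h2_obs: np.ndarray  # sigma2_i / sigma2_P (includes residual in denominator)
    pct_h2g: np.ndarray  # sigma2_i / sum of genetic sigma2
    se_pct_h2g: np.ndarray
    pct_snps: np.ndarray | None = None
    z: np.ndarray | None = None
    p: np.ndarray | None = None
    h2_total: float = np.nan
    se_h2_total: float = np.nan
    h2_total_liability: float | None = None
    degenerate: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "component": self.component_names,
                "h2_obs": self.h2_obs,
                "pct_h2g": 100 * self.pct_h2g,
                "se_pct_h2g": 100 * self.se_pct_h2g,
            }
        )
        if self.pct_snps is not None:
            df["pct_snps"] = 100 * self.pct_snps
            df["z"] = self.z
            df["p"] = self.p
        return df


def partition_h2(fit: REMLResults, pct_snps=None) -> HeritabilityPartition:
    """Partition a REML fit into per-component heritability shares.

    The delta-method SE of f(theta) = theta_i / S with S the genetic total uses
    the gradient d f/d theta_i = (S - theta_i)/S^2, d f/d theta_j = -theta_i/S^2
    and the genetic block of the inverse-AI covariance.  The SE of the total
    h2 = S / (S + sigma2_e) is propagated through the full covariance.
    """
    theta = fit.sigma2_genetic
    k = len(theta)
    if k < 1:
        raise ValueError("fit has no genetic component")
    names = fit.component_names[:-1]
    tot = fit.total_phenotypic_variance
    S = float(theta.sum())
    h2_obs = theta / tot
    if S <= 0:
        logger.warning("zero total genetic variance; %%h2g undefined")
        pct = np.full(k, np.nan)
        se = np.full(k, np.nan)
    else:
        pct = theta / S
        cov_g = fit.cov_params[:k, :k]
        se = np.empty(k)
        for i in range(k):
            grad = -theta[i] / S**2 * np.ones(k)
            grad[i] = (S - theta[i]) / S**2
            se[i] = np.sqrt(max(float(grad @ cov_g @ grad), 0.0))
    # total h2 = S / (S + e): gradient e/tot^2 for genetic, -S/tot^2 for residual
    grad_t = np.full(k + 1, fit.sigma2_residual / tot**2)
    grad_t[-1] = -S / tot**2
    se_tot = np.sqrt(max(float(grad_t @ fit.cov_params @ grad_t), 0.0))

    z = p = degenerate = None
    if pct_snps is not None:
        pct_snps = np.asarray(pct_snps, dtype=np.float64)
        if pct_snps.shape != (k,):
            raise ValueError("pct_snps must have one entry per genetic component")
        z = np.full(k, np.nan)
        p = np.full(k, np.nan)
        degenerate = np.zeros(k, dtype=bool)
        for i in range(k):
            z[i], p[i], degenerate[i] = _ztest(pct[i], se[i], pct_snps[i])
    return HeritabilityPartition(
        component_names=list(names),
        h2_obs=h2_obs,
        pct_h2g=pct,
        se_pct_h2g=se,
        pct_snps=pct_snps,
        z=z,
        p=p,
        h2_total=S / tot,
        se_h2_total=se_tot,
        degenerate=degenerate,
    )


def _ztest(pct: float, se: float, expected: float) -> tuple[float, float, bool]:
    if not np.isfinite(pct):
        return np.nan, np.nan, True
    if se <= 0:
        if pct == expected:
            return 0.0, 1.0, False
        logger.warning("zero SE with pct_h2g != pct_snps; degenerate Z-test")
        return np.inf if pct > expected else -np.inf, 0.0, True
    z = (pct - expected) / se
    return z, 2.0 * stats.norm.sf(abs(z)), False


def enrichment_test(result: HeritabilityPartition, component: str) -> tuple[float, float]:
    """Two-sided Z-test of a component's %h2g against its %SNPs."""
    if result.pct_snps is None:
        raise ValueError("partition has no %SNPs; supply pct_snps to partition_h2")
    i = result.component_names.index(component)
    z, p, _ = _ztest(result.pct_h2g[i], result.se_pct_h2g[i], result.pct_snps[i])
    return z, p


def liability_transform(h2_obs: float, prevalence: float, case_fraction: float) -> float:
    """Observed-scale to liability-scale heritability for 0/1 case status.

    h2_liab = h2_obs * K^2 (1-K)^2 / (P (1-P) z^2) with K the population
    prevalence, P the sample case fraction and z the standard normal density
    at the (1-K) quantile.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    if not 0.0 < case_fraction < 1.0:
        raise ValueError("case_fraction must lie in (0, 1)")
    t = stats.norm.isf(prevalence)
    z = stats.norm.pdf(t)
    K, P = prevalence, case_fraction
    return float(h2_obs * K**2 * (1 - K) ** 2 / (P * (1 - P) * z**2))


def meta_analyze(estimates, ses) -> tuple[float, float]:
    """Fixed-effect inverse-variance meta-analysis."""
    estimates = np.asarray(estimates, dtype=np.float64)
    ses = np.asarray(ses, dtype=np.float64)
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / ses**2
    return float(np.sum(w * estimates) / np.sum(w)), float(np.sum(w) ** -0.5)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

_BACKGROUND_COMPONENTS = ("coding", "utr", "promoter")


def select_model(
    marginal_results: pd.DataFrame,
    alpha: float,
    grouping: Mapping[str, str],
    joint_fit: Callable[[Sequence[str]], HeritabilityPartition],
    fallback: str = "all_other",
) -> ModelSpec:
    """Two-stage selection of a joint model from a marginal annotation scan.

    Stage 1 keeps annotations whose marginal p survives Bonferroni across the
    scan; stage 2 fits the supplied biological ``grouping`` of the survivors as
    one joint model (``joint_fit`` maps an ordered group list to a fitted
    partition with Z-tests); stage 3 keeps groups significant at alpha over the
    number of groups, always retaining the coding/UTR/promoter background.
    The grouping is configuration — a user-supplied biological judgment, not
    an inference made here.
    """
    n_tests = len(marginal_results)
    thresh = alpha / max(n_tests, 1)
    sig = marginal_results[marginal_results["p"] < thresh]
    if sig.empty:
        logger.warning("no annotation survives Bonferroni at %g; background-only model", thresh)
        return _assemble("selected_background", [], fallback)
    groups: list[str] = []
    for ann in sig["annotation"]:
        g = grouping.get(ann)
        if g is None:
            raise KeyError(f"annotation {ann!r} missing from the grouping configuration")
        if g not in groups:
            groups.append(g)
    joint = joint_fit(groups)
    kept = []
    g_thresh = alpha / max(len(groups), 1)
    for g in groups:
        if g in joint.component_names:
            i = joint.component_names.index(g)
            if joint.p is not None and joint.p[i] < g_thresh:
                kept.append(g)
    if not kept:
        logger.warning("no group significant in the joint model; background-only model")
    return _assemble("selected", kept, fallback)


def _assemble(name: str, middle: list[str], fallback: str) -> ModelSpec:
    comps = [(c, (c,)) for c in _BACKGROUND_COMPONENTS]
    comps += [(g, (g,)) for g in middle]
    comps += [(fallback, ())]
    return ModelSpec(name=name, components=comps)


def conditional_scan(
    annotations: Sequence[str],
    fit_conditional: Callable[[str], HeritabilityPartition | None],
    slot: str = "focal",
) -> pd.DataFrame:
    """Re-evaluate annotations one at a time conditional on a selected model.

    ``fit_conditional`` inserts the annotation into the interest slot of the
    conditional hierarchy and returns the fitted partition, or None on REML
    non-convergence (those annotations are reported as skipped, not errors).
    """
    rows = []
    for ann in annotations:
        hp = fit_conditional(ann)
        if hp is None:
            logger.warning("conditional model for %r did not converge; skipped", ann)
            rows.append({"annotation": ann, "converged": False})
            continue
        if slot not in hp.component_names:
            # every SNP of the annotation was claimed by an earlier component:
            # the exclusive slot is empty and carries no enrichment
            rows.append(
                {
                    "annotation": ann, "converged": True, "pct_snps": 0.0,
                    "pct_h2g": 0.0, "se_pct_h2g": np.nan, "z": np.nan, "p": np.nan,
                }
            )
            continue
        i = hp.component_names.index(slot)
        rows.append(
            {
                "annotation": ann,
                "converged": True,
                "pct_snps": hp.pct_snps[i] if hp.pct_snps is not None else np.nan,
                "pct_h2g": hp.pct_h2g[i],
                "se_pct_h2g": hp.se_pct_h2g[i],
                "z": hp.z[i] if hp.z is not None else np.nan,
                "p": hp.p[i] if hp.p is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)
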