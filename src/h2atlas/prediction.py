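"""Polygenic risk prediction: GRS, single-component BLUP, multi-component BLUP.

The genetic risk score (GRS) sums dosages weighted by training-sample log
odds-ratios over genome-wide-significant SNPs, thinned to one per 1-Mb locus
by greedy best-p clumping.  BLUP scores come from the fitted variance
components: single-BLUP uses one all-SNP component, multi-BLUP sums the
per-component predictions weighted by their share of SNP heritability, which
amounts to placing a per-annotation prior on effect-size variance.  Accuracy
is assessed by cross-validation with sequential held-out folds, reporting
prediction R^2 net of a covariate-only baseline and per-predictor p-values
from the joint multiple regression of phenotype on all predictors plus
covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import GenotypeMatrix, PhenotypeSet, TraitType
from .kinship import GRMSet, cross_grm, grms_from_partition
from .reml import REMLResults, VarianceComponentModel

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionResult",
    "assoc_scan",
    "build_grs",
    "predict_multiblup",
    "evaluate_prediction",
    "cross_validate_predictors",
]


@dataclass
class PredictionResult:
    """Per-predictor cross-validated scores and accuracy."""

    scores: pd.DataFrame  # one column per predictor
    r2_net: dict[str, float]
    joint_p: dict[str, float]
    baseline_r2: float


# ---------------------------------------------------------------------------
# association scan and GRS
# ---------------------------------------------------------------------------


def assoc_scan(
    geno: GenotypeMatrix,
    pheno: PhenotypeSet,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP regression of phenotype on dosage with covariates.

    Binary traits use logistic regression (effects are log odds-ratios);
    quantitative traits use OLS.  SNPs with separated or non-converging
    logistic fits are skipped with a warning (p = NaN).
    """
    y = pheno.values
    n, m = geno.dosages.shape
    base = [np.ones((n, 1))]
    if covariates is not None and np.size(covariates):
        base.append(np.atleast_2d(np.asarray(covariates, dtype=float)).reshape(n, -1))
    base = np.hstack(base)
    binary = pheno.trait_type is TraitType.BINARY
    beta = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    for j in range(m):
        x = np.column_stack([base, geno.dosages[:, j]])
        try:
            if binary:
                res = sm.Logit(y, x).fit(disp=0, maxiter=50)
                if not res.mle_retvals.get("converged", True):
                    raise RuntimeError("no convergence")
            else:
                res = sm.OLS(y, x).fit()
            beta[j] = res.params[-1]
            pval[j] = res.pvalues[-1]
        except Exception as exc:  # separation, singular design
            logger.warning("association fit skipped for %s: %s", geno.snp_ids[j], exc)
    return pd.DataFrame(
        {
            "snp_id": geno.snp_ids,
            "chrom": geno.chrom,
            "pos": geno.pos,
            "beta": beta,
            "p": pval,
        }
    )


def clump_best_per_window(scan: pd.DataFrame, p_threshold: float, window: int) -> pd.DataFrame:
    """Greedy best-p clumping: take the most significant SNP, discard all
    others within +/- window bp on its chromosome, repeat (ties by lower
    position)."""
    sig = scan[(scan["p"] < p_threshold) & np.isfinite(scan["p"])]
    sig = sig.sort_values(["p", "pos"], kind="mergesort")
    kept_rows = []
    blocked: dict = {}
    for _, row in sig.iterrows():
        spans = blocked.setdefault(row["chrom"], [])
        if any(abs(row["pos"] - c) < window for c in spans):
            continue
        spans.append(row["pos"])
        kept_rows.append(row)
    if not kept_rows:
        return sig.iloc[:0]
    return pd.DataFrame(kept_rows)


def build_grs(
    scan: pd.DataFrame,
    geno: GenotypeMatrix,
    p_threshold: float = 5e-8,
    clump_window: int = 1_000_000,
) -> np.ndarray:
    """Genetic risk score = sum of dosage x log(OR) over clumped significant SNPs."""
    kept = clump_best_per_window(scan, p_threshold, clump_window)
    if kept.empty:
        logger.warning("no SNP passes p < %g; GRS is identically zero", p_threshold)
        return np.zeros(geno.n_samples)
    idx = pd.Index(geno.snp_ids).get_indexer(kept["snp_id"])
    return geno.dosages[:, idx] @ kept["beta"].to_numpy()


# ---------------------------------------------------------------------------
# BLUP predictors
# ---------------------------------------------------------------------------


def predict_multiblup(
    fit: REMLResults,
    cross: GRMSet,
    weights: str | dict = "pct_h2g",
) -> np.ndarray:
    """Weighted sum of per-component out-of-sample BLUPs.

    ``weights='pct_h2g'`` (default) scales each component's prediction by its
    share of SNP heritability; ``weights='unit'`` gives the plain joint
    multi-component BLUP; a dict gives explicit per-component weights.
    """
    preds = fit.blup(cross=cross)
    if weights == "pct_h2g":
        hp = fit.partition_h2()
        w = dict(zip(hp.component_names, hp.pct_h2g))
    elif weights == "unit":
        w = {name: 1.0 for name in preds}
    elif isinstance(weights, dict):
        w = weights
    else:
        raise ValueError("weights must be 'pct_h2g', 'unit' or a dict")
    out = np.zeros(next(iter(preds.values())).shape[0])
    for name, g in preds.items():
        wi = w.get(name, 0.0)
        if np.isfinite(wi):
            out += wi * g
    return out


# ---------------------------------------------------------------------------
# cross-validation and evaluation
# ---------------------------------------------------------------------------


def _fold_bounds(n: int, fold_size: int):
    for lo in range(0, n, fold_size):
        yield lo, min(lo + fold_size, n)


def cross_validate_predictors(
    geno: GenotypeMatrix,
    pheno: PhenotypeSet,
    partition,
    covariates: np.ndarray | None = None,
    fold_size: int = 1000,
    p_threshold: float = 5e-8,
    grs: bool = True,
    weights: str = "pct_h2g",
    relatedness_max: float | None = None,
) -> pd.DataFrame:
    """Out-of-fold GRS / single-BLUP / multi-BLUP scores by sequential folds.

    Each fold's predictors are trained on the remaining samples only: the
    association scan and the REML fits never see the held-out phenotypes.
    ``relatedness_max`` optionally removes training individuals whose
    cross-GRM to any test individual exceeds the threshold (cross-dataset
    leakage guard).
    """
    n = pheno.n_samples
    if fold_size >= n:
        raise ValueError("fold_size must be smaller than the sample size")
    y = pheno.values
    scores = pd.DataFrame(index=np.arange(n), dtype=float)
    for col in (["grs"] if grs else []) + ["blup", "multi_blup"]:
        scores[col] = np.nan
    for lo, hi in _fold_bounds(n, fold_size):
        test = np.arange(lo, hi)
        train = np.setdiff1d(np.arange(n), test)
        g_tr = geno.subset_samples(train)
        g_te = geno.subset_samples(test)
        if relatedness_max is not None:
            Kx, _ = cross_grm(g_tr, g_te)
            ok = np.max(np.abs(Kx), axis=0) <= relatedness_max
            if not ok.all():
                logger.info("fold %d-%d: dropped %d related training samples", lo, hi, int((~ok).sum()))
                train = train[ok]
                g_tr = geno.subset_samples(train)
        ph_tr = PhenotypeSet(
            values=y[train],
            trait_type=pheno.trait_type,
            covariates=None if covariates is None else np.asarray(covariates)[train],
        )
        cov_tr = None if covariates is None else np.asarray(covariates)[train]
        if grs:
            scan = assoc_scan(g_tr, ph_tr, cov_tr)
            kept = clump_best_per_window(scan, p_threshold, 1_000_000)
            if kept.empty:
                scores.loc[test, "grs"] = 0.0
            else:
                idx = pd.Index(geno.snp_ids).get_indexer(kept["snp_id"])
                scores.loc[test, "grs"] = g_te.dosages[:, idx] @ kept["beta"].to_numpy()

        X_tr = np.ones((len(train), 1))
        if cov_tr is not None and np.size(cov_tr):
            X_tr = np.hstack([X_tr, np.atleast_2d(cov_tr).reshape(len(train), -1)])

        # single-component BLUP over all SNPs
        from .kinship import compute_grm

        K_tr, m_all = compute_grm(g_tr)
        single = GRMSet(matrices=[K_tr], snp_counts=[m_all], component_names=["all"])
        fit1 = VarianceComponentModel(y[train], single, exog=X_tr).fit()
        Kx_all, _ = cross_grm(g_tr, g_te)
        cross1 = GRMSet(matrices=[Kx_all], snp_counts=[m_all], component_names=["all"])
        scores.loc[test, "blup"] = predict_multiblup(fit1, cross1, weights="unit")

        # multi-component BLUP over the partition
        grms_tr = grms_from_partition(g_tr, partition)
        fitm = VarianceComponentModel(y[train], grms_tr, exog=X_tr).fit()
        mats, cnts = [], []
        for name in grms_tr.component_names:
            Kx, mc = cross_grm(g_tr, g_te, partition.snp_indices(name))
            mats.append(Kx)
            cnts.append(mc)
        crossm = GRMSet(matrices=mats, snp_counts=cnts, component_names=list(grms_tr.component_names))
        scores.loc[test, "multi_blup"] = predict_multiblup(fitm, crossm, weights=weights)
    return scores


def evaluate_prediction(
    pheno: PhenotypeSet,
    scores: pd.DataFrame,
    covariates: np.ndarray | None = None,
) -> PredictionResult:
    """Prediction R^2 net of the covariate-only baseline, plus joint p-values.

    R^2 per predictor comes from OLS of phenotype on score + covariates minus
    the covariate-only R^2; joint p-values from the multiple regression of
    phenotype on all predictors together with covariates.
    """
    y = pheno.values
    n = len(y)
    base = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        base = np.hstack([base, np.atleast_2d(np.asarray(covariates, dtype=float)).reshape(n, -1)])
    r2_base = sm.OLS(y, base).fit().rsquared if base.shape[1] > 1 else 0.0
    r2_net = {}
    for col in scores.columns:
        s = scores[col].to_numpy()
        if np.std(s) == 0:
            logger.warning("predictor %r is constant; R^2 set to 0", col)
            r2_net[col] = 0.0
            continue
        r2 = sm.OLS(y, np.column_stack([base, s])).fit().rsquared
        r2_net[col] = float(r2 - r2_base)
    X = base
    used = []
    for col in scores.columns:
        s = scores[col].to_numpy()
        if np.std(s) > 0:
            X = np.column_stack([X, s])
            used.append(col)
    joint = sm.OLS(y, X).fit()
    joint_p = {col: float(joint.pvalues[base.shape[1] + i]) for i, col in enumerate(used)}
    return PredictionResult(scores=scores, r2_net=r2_net, joint_p=joint_p, baseline_r2=float(r2_base))
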