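"""Sample and SNP quality control for heritability estimation.

Filters, in order: minor allele frequency < 1%, SNP missingness > 5%,
Hardy-Weinberg equilibrium p < 0.01 (1-df chi-square on hard-called genotypes
in controls), case-control differential missingness p < 0.05 (2x2 chi-square),
and imputation INFO <= 0.30.  Relatedness pruning removes individuals greedily
until no pair exceeds the GRM threshold (default 0.05).  Principal components
of the standardized genotype matrix provide ancestry covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import GenotypeMatrix, PhenotypeSet, TraitType

logger = logging.getLogger(__name__)

__all__ = ["QCThresholds", "QCReport", "snp_qc", "prune_related", "compute_pcs", "hwe_chi2"]


@dataclass
class QCThresholds:
    maf_min: float = 0.01
    snp_missing_max: float = 0.05
    hwe_p_min: float = 0.01
    diff_missing_p_min: float = 0.05
    info_min: float = 0.30
    relatedness_max: float = 0.05

    def __post_init__(self) -> None:
        for f in ("maf_min", "snp_missing_max", "hwe_p_min", "diff_missing_p_min", "info_min", "relatedness_max"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must lie in [0, 1], got {v}")


@dataclass
class QCReport:
    """Per-filter removal counts, applied in the listed order."""

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    surviving_snps: np.ndarray | None = None
    filter_order: list[str] = field(default_factory=list)

    @property
    def n_output(self) -> int:
        return self.n_input - sum(self.removed.values())

    def to_text(self) -> str:
        lines = ["filter\tremoved"]
        for name in self.filter_order:
            lines.append(f"{name}\t{self.removed.get(name, 0)}")
        lines.append(f"# input={self.n_input} output={self.n_output}")
        return "\n".join(lines)


def _hard_call(dosages: np.ndarray) -> np.ndarray:
    """0/1/2 genotype from dosage at 0.5/1.5 cutpoints."""
    g = np.zeros_like(dosages, dtype=np.int8)
    g[dosages >= 0.5] = 1
    g[dosages >= 1.5] = 2
    return g


def hwe_chi2(n0: int, n1: int, n2: int) -> tuple[float, float]:
    """1-df chi-square test of Hardy-Weinberg proportions on genotype counts."""
    n = n0 + n1 + n2
    if n == 0:
        return 0.0, 1.0
    p = (2 * n2 + n1) / (2 * n)
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.array([n0, n1, n2], dtype=float)
    nz = exp > 0
    chi2 = float(np.sum((obs[nz] - exp[nz]) ** 2 / exp[nz]))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def snp_qc(
    geno: GenotypeMatrix,
    pheno: PhenotypeSet | None = None,
    thresholds: QCThresholds | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the SNP exclusion filters in their stated order.

    The HWE and differential-missingness filters need a binary phenotype (HWE
    is computed in controls only); with a quantitative or absent phenotype
    HWE uses all samples and differential missingness is skipped with a log
    message.
    """
    th = thresholds or QCThresholds()
    m = geno.n_snps
    keep = np.ones(m, dtype=bool)
    report = QCReport(n_input=m, filter_order=["maf", "missingness", "hwe", "diff_missingness", "info"])

    binary = pheno is not None and pheno.trait_type is TraitType.BINARY
    case = pheno.values == 1 if binary else None

    # 1. MAF
    maf = geno.computed_maf()
    drop = keep & (maf < th.maf_min)
    report.removed["maf"] = int(drop.sum())
    keep &= ~drop

    # 2. missingness
    miss_rate = geno.missing_mask.mean(axis=0)
    drop = keep & (miss_rate > th.snp_missing_max)
    report.removed["missingness"] = int(drop.sum())
    keep &= ~drop

    # 3. HWE (controls only, hard-called genotypes)
    rows = ~case if binary else np.ones(geno.n_samples, dtype=bool)
    if not binary:
        logger.info("no binary phenotype: HWE tested on all samples")
    g = _hard_call(geno.dosages[rows])
    obs = ~geno.missing_mask[rows]
    drop = np.zeros(m, dtype=bool)
    for j in np.flatnonzero(keep):
        gj = g[obs[:, j], j]
        n0 = int(np.sum(gj == 0)); n1 = int(np.sum(gj == 1)); n2 = int(np.sum(gj == 2))
        _, p = hwe_chi2(n0, n1, n2)
        if p < th.hwe_p_min:
            drop[j] = True
    report.removed["hwe"] = int(drop.sum())
    keep &= ~drop

    # 4. differential missingness (binary phenotype only)
    if binary:
        drop = np.zeros(m, dtype=bool)
        n_case = int(case.sum())
        n_ctrl = len(case) - n_case
        miss_case = geno.missing_mask[case].sum(axis=0)
        miss_ctrl = geno.missing_mask[~case].sum(axis=0)
        for j in np.flatnonzero(keep):
            table = np.array(
                [
                    [miss_case[j], n_case - miss_case[j]],
                    [miss_ctrl[j], n_ctrl - miss_ctrl[j]],
                ]
            )
            if table[:, 0].sum() == 0:
                continue  # no missing calls at all
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            if p < th.diff_missing_p_min:
                drop[j] = True
        report.removed["diff_missingness"] = int(drop.sum())
        keep &= ~drop
    else:
        logger.info("differential-missingness filter skipped (no binary phenotype)")
        report.removed["diff_missingness"] = 0

    # 5. INFO
    drop = keep & (geno.info_score <= th.info_min)
    report.removed["info"] = int(drop.sum())
    keep &= ~drop

    if not keep.any():
        raise ValueError("QC removed all SNPs")
    report.surviving_snps = geno.snp_ids[keep]
    out = geno.subset_snps(keep)
    out.maf = out.computed_maf()
    return out, report


def prune_related(grm: np.ndarray, threshold: float = 0.05) -> np.ndarray:
    """Greedy relatedness pruning; returns retained sample indices.

    Repeatedly drops the individual with the most above-threshold pairs
    (ties broken by higher mean relatedness, then lower sample index) until no
    off-diagonal entry exceeds the threshold.
    """
    grm = np.asarray(grm)
    if grm.ndim != 2 or grm.shape[0] != grm.shape[1]:
        raise ValueError("GRM must be square")
    if not np.allclose(grm, grm.T, atol=1e-8):
        raise ValueError("GRM must be symmetric")
    n = grm.shape[0]
    adj = np.abs(grm) > threshold
    np.fill_diagonal(adj, False)
    active = np.ones(n, dtype=bool)
    mean_rel = (np.abs(grm).sum(axis=1) - np.abs(np.diag(grm))) / max(n - 1, 1)
    while True:
        deg = (adj & active[None, :]).sum(axis=1)
        deg[~active] = 0
        dmax = deg.max()
        if dmax == 0:
            break
        cand = np.flatnonzero(deg == dmax)
        cand = cand[mean_rel[cand] == mean_rel[cand].max()]
        victim = int(cand.min())
        active[victim] = False
        adj[victim, :] = False
        adj[:, victim] = False
    return np.flatnonzero(active)


def compute_pcs(geno: GenotypeMatrix, k: int = 10) -> np.ndarray:
    """Top-k principal components of the standardized genotype covariance.

    Returns an N x k matrix of sample eigenvectors, each sign-fixed so its
    largest-magnitude loading is positive; fewer columns are returned (with a
    warning) when the covariance is rank-deficient.
    """
    n, m = geno.dosages.shape
    if k >= min(n, m):
        raise ValueError("k must be smaller than min(N, M)")
    if k == 0:
        return np.zeros((n, 0))
    from .kinship import compute_grm

    K, _ = compute_grm(geno)
    vals, vecs = np.linalg.eigh(K)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    rank = int(np.sum(vals > 1e-8 * max(vals[0], 1.0)))
    if rank < k:
        logger.warning("genotype covariance rank %d < requested %d PCs", rank, k)
        k = rank
    pcs = vecs[:, :k]
    for j in range(k):
        i = np.argmax(np.abs(pcs[:, j]))
        if pcs[i, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs
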