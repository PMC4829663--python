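"""Genetic relationship matrices from standardized dosages.

K = W W' / M over SNPs standardized to zero mean and unit variance using
in-sample allele frequencies: w_ij = (x_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)).
Missing dosages are mean-imputed (w = 0).  Per-component GRMs built from an
exclusive partition satisfy the exact identity sum_i M_i K_i = M K_total.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["GRMSet", "compute_grm", "cross_grm", "grms_from_partition", "write_grm_text", "read_grm_text"]

_BLOCK = 4096  # SNPs per accumulation block; memory stays O(N * block + N^2)


def _standardized_block(
    dosages: np.ndarray, missing: np.ndarray, p: np.ndarray
) -> np.ndarray:
    het = 2.0 * p * (1.0 - p)
    w = (dosages - 2.0 * p) / np.sqrt(het)
    if missing.any():
        w[missing] = 0.0
    return w


def _subset_freq(dosages: np.ndarray, missing: np.ndarray) -> np.ndarray:
    if missing.any():
        d = np.where(missing, np.nan, dosages)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(d, axis=0) / 2.0
        return p
    return dosages.mean(axis=0) / 2.0


def compute_grm(geno: GenotypeMatrix, snp_subset=None) -> tuple[np.ndarray, int]:
    """GRM over a SNP subset; returns (K, M_used).

    Monomorphic SNPs (in-sample frequency 0 or 1) are excluded from the
    divisor and the accumulation; raises if none remain.
    """
    idx = np.arange(geno.n_snps) if snp_subset is None else np.asarray(snp_subset)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    if idx.size == 0:
        raise ValueError("empty SNP subset")
    n = geno.n_samples
    K = np.zeros((n, n))
    m_used = 0
    for lo in range(0, idx.size, _BLOCK):
        block = idx[lo : lo + _BLOCK]
        d = geno.dosages[:, block]
        miss = geno.missing_mask[:, block]
        p = _subset_freq(d, miss)
        poly = (p > 0) & (p < 1)
        if not poly.all():
            d, miss, p = d[:, poly], miss[:, poly], p[poly]
        if p.size == 0:
            continue
        w = _standardized_block(d, miss, p)
        K += w @ w.T
        m_used += p.size
    if m_used == 0:
        raise ValueError("all SNPs in subset are monomorphic")
    K /= m_used
    return K, m_used


def cross_grm(
    train: GenotypeMatrix, test: GenotypeMatrix, snp_subset=None
) -> tuple[np.ndarray, int]:
    """Rectangular test x train relationship matrix, standardized with
    *training* allele frequencies.  SNPs monomorphic in training are dropped
    with a warning."""
    idx = np.arange(train.n_snps) if snp_subset is None else np.asarray(snp_subset)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    if train.n_snps != test.n_snps:
        raise ValueError("train and test must share a SNP set")
    K = np.zeros((test.n_samples, train.n_samples))
    m_used = 0
    n_dropped = 0
    for lo in range(0, idx.size, _BLOCK):
        block = idx[lo : lo + _BLOCK]
        d_tr = train.dosages[:, block]
        miss_tr = train.missing_mask[:, block]
        p = _subset_freq(d_tr, miss_tr)
        poly = (p > 0) & (p < 1)
        n_dropped += int((~poly).sum())
        if not poly.all():
            block = block[poly]
            d_tr, miss_tr, p = d_tr[:, poly], miss_tr[:, poly], p[poly]
        if p.size == 0:
            continue
        w_tr = _standardized_block(d_tr, miss_tr, p)
        w_te = _standardized_block(test.dosages[:, block], test.missing_mask[:, block], p)
        K += w_te @ w_tr.T
        m_used += p.size
    if n_dropped:
        logger.warning("cross_grm: dropped %d SNPs monomorphic in training", n_dropped)
    if m_used == 0:
        raise ValueError("all SNPs in subset are monomorphic in training")
    K /= m_used
    return K, m_used


@dataclass
class GRMSet:
    """Ordered per-component relationship matrices with SNP counts.

    Holds square kinship matrices (validated symmetric) or rectangular
    test x train cross-relationship blocks for out-of-sample prediction.
    """

    matrices: list[np.ndarray]
    snp_counts: list[int]
    component_names: list[str]

    def __post_init__(self) -> None:
        for name, K, m in zip(self.component_names, self.matrices, self.snp_counts):
            if K.shape[0] == K.shape[1] and not np.allclose(K, K.T, atol=1e-10):
                raise ValueError(f"GRM for {name!r} is not symmetric")
            if m <= 0:
                raise ValueError(f"component {name!r} has no SNPs")

    @property
    def n_components(self) -> int:
        return len(self.matrices)

    @property
    def n_samples(self) -> int:
        return self.matrices[0].shape[0]

    def __iter__(self):
        return iter(self.matrices)

    def subset_samples(self, index: np.ndarray) -> "GRMSet":
        index = np.asarray(index)
        return GRMSet(
            matrices=[K[np.ix_(index, index)] for K in self.matrices],
            snp_counts=list(self.snp_counts),
            component_names=list(self.component_names),
        )


def grms_from_partition(geno: GenotypeMatrix, partition, components=None) -> GRMSet:
    """One GRM per partition component (components with zero SNPs are skipped)."""
    names = partition.component_names if components is None else list(components)
    mats, counts, kept = [], [], []
    for name in names:
        idx = partition.snp_indices(name)
        if idx.size == 0:
            logger.warning("component %r has no SNPs; skipped", name)
            continue
        K, m = compute_grm(geno, idx)
        mats.append(K)
        counts.append(m)
        kept.append(name)
    if not mats:
        raise ValueError("no component has SNPs")
    return GRMSet(matrices=mats, snp_counts=counts, component_names=kept)


# ---------------------------------------------------------------------------
# plain-text persistence (lower-triangle table + id file)
# ---------------------------------------------------------------------------


def write_grm_text(K: np.ndarray, m_snps: int, ids, prefix) -> None:
    """Write a GRM as `<prefix>.grm.txt` (i, j, M, K_ij lower triangle,
    1-based) plus `<prefix>.grm.id` (FID IID), the common mixed-model text
    exchange layout."""
    prefix = Path(prefix)
    n = K.shape[0]
    ii, jj = np.tril_indices(n)
    df = pd.DataFrame({"i": ii + 1, "j": jj + 1, "m": m_snps, "k": K[ii, jj]})
    df.to_csv(Path(str(prefix) + ".grm.txt"), sep="\t", header=False, index=False, float_format="%.10g")
    with open(Path(str(prefix) + ".grm.id"), "w") as fh:
        for s in ids:
            fh.write(f"{s}\t{s}\n")


def write_grm_bin(K: np.ndarray, m_snps: int, ids, prefix) -> None:
    """Binary triangle layout used by the common GREML tools: `<prefix>.grm.bin`
    (float32 row-major lower triangle incl. diagonal), `<prefix>.grm.N.bin`
    (float32 per-pair SNP count) and `<prefix>.grm.id`."""
    prefix = str(prefix)
    n = K.shape[0]
    ii, jj = np.tril_indices(n)
    K[ii, jj].astype("<f4").tofile(prefix + ".grm.bin")
    np.full(ii.size, m_snps, dtype="<f4").tofile(prefix + ".grm.N.bin")
    with open(prefix + ".grm.id", "w") as fh:
        for s in ids:
            fh.write(f"{s}\t{s}\n")


def read_grm_bin(prefix) -> tuple[np.ndarray, int, list[str]]:
    prefix = str(prefix)
    ids = [line.split()[1] for line in open(prefix + ".grm.id")]
    n = len(ids)
    tri = np.fromfile(prefix + ".grm.bin", dtype="<f4").astype(np.float64)
    if tri.size != n * (n + 1) // 2:
        raise ValueError(f"{prefix}.grm.bin has {tri.size} entries; expected {n * (n + 1) // 2}")
    K = np.zeros((n, n))
    ii, jj = np.tril_indices(n)
    K[ii, jj] = tri
    K = K + K.T - np.diag(np.diag(K))
    counts = np.fromfile(prefix + ".grm.N.bin", dtype="<f4")
    m = int(counts[0]) if counts.size else 0
    return K, m, ids


def read_grm_text(prefix) -> tuple[np.ndarray, int, list[str]]:
    prefix = Path(prefix)
    df = pd.read_csv(Path(str(prefix) + ".grm.txt"), sep="\t", header=None, names=["i", "j", "m", "k"])
    n = int(df["i"].max())
    K = np.zeros((n, n))
    K[df["i"] - 1, df["j"] - 1] = df["k"]
    K = K + K.T - np.diag(np.diag(K))
    ids = [line.split()[1] for line in open(Path(str(prefix) + ".grm.id"))]
    return K, int(df["m"].iloc[0]), ids
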