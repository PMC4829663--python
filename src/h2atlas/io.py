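"""Plain-text writers and readers for cohort data.

Genotypes persist as a dosage matrix (TSV, samples x SNPs) plus a SNP map
(chrom, pos, id, a1, a2, maf, typed, info); phenotypes and covariates as
whitespace-delimited (FID, IID, value...) tables, mirroring the conventions
of the common mixed-model tools.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix, PhenotypeSet, TraitType

__all__ = ["write_genotypes", "read_genotypes", "write_phenotypes", "read_phenotypes", "write_covariates"]


def write_genotypes(geno: GenotypeMatrix, prefix) -> None:
    prefix = Path(prefix)
    snp_map = pd.DataFrame(
        {
            "chrom": geno.chrom,
            "pos": geno.pos,
            "id": geno.snp_ids,
            "a1": geno.a1,
            "a2": geno.a2,
            "maf": geno.maf,
            "typed": geno.typed_flag.astype(int),
            "info": geno.info_score,
        }
    )
    snp_map.to_csv(Path(str(prefix) + ".snps.tsv"), sep="\t", index=False, float_format="%.8g")
    d = geno.dosages.copy()
    d[geno.missing_mask] = np.nan
    pd.DataFrame(d, columns=geno.snp_ids).to_csv(
        Path(str(prefix) + ".dosages.tsv"), sep="\t", index=False, float_format="%.6g", na_rep="NA"
    )


def read_genotypes(prefix) -> GenotypeMatrix:
    prefix = Path(prefix)
    snp_map = pd.read_csv(Path(str(prefix) + ".snps.tsv"), sep="\t")
    d = pd.read_csv(Path(str(prefix) + ".dosages.tsv"), sep="\t", na_values="NA").to_numpy(float)
    missing = np.isnan(d)
    d = np.where(missing, 0.0, d)
    g = GenotypeMatrix(
        dosages=d,
        chrom=snp_map["chrom"].to_numpy(),
        pos=snp_map["pos"].to_numpy(),
        maf=snp_map["maf"].to_numpy(float),
        missing_mask=missing,
        typed_flag=snp_map["typed"].to_numpy(bool),
        info_score=snp_map["info"].to_numpy(float),
        snp_ids=snp_map["id"].to_numpy(),
        a1=snp_map["a1"].to_numpy(),
        a2=snp_map["a2"].to_numpy(),
    )
    g.maf = g.computed_maf()
    return g


def write_phenotypes(pheno: PhenotypeSet, path, ids=None) -> None:
    n = pheno.n_samples
    ids = ids if ids is not None else [f"ind{i}" for i in range(n)]
    df = pd.DataFrame({"FID": ids, "IID": ids, "value": pheno.values})
    df.to_csv(path, sep=" ", index=False, header=False, float_format="%.8g")


def read_phenotypes(path, trait_type: TraitType | str = TraitType.QUANTITATIVE) -> PhenotypeSet:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["FID", "IID", "value"])
    return PhenotypeSet(values=df["value"].to_numpy(float), trait_type=TraitType(trait_type))


def write_covariates(covariates: np.ndarray, path, ids=None) -> None:
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] == 1 and cov.shape[1] > 1:
        cov = cov.T
    n = cov.shape[0]
    ids = ids if ids is not None else [f"ind{i}" for i in range(n)]
    df = pd.DataFrame({"FID": ids, "IID": ids})
    for j in range(cov.shape[1]):
        df[f"C{j + 1}"] = cov[:, j]
    df.to_csv(path, sep=" ", index=False, header=False, float_format="%.8g")
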