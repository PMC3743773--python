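"""Plain-text readers and writers for the pipeline's tabular artifacts.

Formats: PLINK text pedigree files (.ped/.map, alleles coded A = minor /
B = major, '0 0' for a missing call, phenotype 1 = control / 2 = case),
a simple genotype TSV (individuals x SNPs of 0/1/2 counts, NA = missing),
phenotype/covariate TSV, BED-like gene annotation TSV (1-based inclusive
start/end), variant TSV and association result TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, Cohort

__all__ = [
    "write_ped_map",
    "read_ped_map",
    "write_genotype_tsv",
    "read_genotype_tsv",
    "write_phenotype_tsv",
    "read_phenotype_tsv",
    "write_annotation_tsv",
    "read_annotation_tsv",
    "write_variants_tsv",
    "read_variants_tsv",
    "write_assoc_tsv",
    "read_assoc_tsv",
    "read_cohort",
]

_GENO_TO_ALLELES = {0: "B B", 1: "A B", 2: "A A", MISSING: "0 0"}


def write_ped_map(cohort: Cohort, variants: pd.DataFrame, prefix: str | Path) -> None:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".ped"), "w") as fh:
        sex = cohort.covariates.get("sex")
        for i in range(cohort.n_individuals):
            sex_code = "0" if sex is None else str(int(sex.iloc[i]) + 1)
            fields = [
                f"FAM{i + 1}", f"IND{i + 1}", "0", "0", sex_code,
                str(int(cohort.phenotype[i]) + 1),
            ]
            fields.extend(_GENO_TO_ALLELES[int(g)] for g in cohort.genotypes[i])
            fh.write(" ".join(fields) + "\n")
    with open(prefix.with_suffix(".map"), "w") as fh:
        for row in variants.itertuples(index=False):
            chrom = str(row.chrom).removeprefix("chr")
            fh.write(f"{chrom} {row.snp_id} 0 {row.pos}\n")


def read_ped_map(prefix: str | Path) -> tuple[Cohort, pd.DataFrame]:
    """Read .ped/.map; genotypes become minor-allele (A) counts."""
    prefix = Path(prefix)
    variants = pd.read_csv(
        prefix.with_suffix(".map"), sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos"], dtype={"chrom": str},
    )[["snp_id", "chrom", "pos"]]
    genos, phenos, sexes = [], [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            sexes.append(max(int(fields[4]) - 1, 0))
            phenos.append(int(fields[5]) - 1)
            alleles = fields[6:]
            row = np.empty(len(alleles) // 2, dtype=np.int8)
            for j in range(row.size):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                row[j] = MISSING if "0" in (a, b) else (a == "A") + (b == "A")
            genos.append(row)
    covars = pd.DataFrame({"sex": sexes})
    return (
        Cohort(
            genotypes=np.vstack(genos),
            phenotype=np.array(phenos, dtype=np.int8),
            covariates=covars,
            snp_ids=variants["snp_id"].to_numpy(),
        ),
        variants,
    )


def write_genotype_tsv(cohort: Cohort, path: str | Path) -> None:
    g = cohort.genotype_matrix()
    df = pd.DataFrame(g, columns=cohort.snp_ids)
    df.insert(0, "iid", [f"IND{i + 1}" for i in range(cohort.n_individuals)])
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%g")


def read_genotype_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Returns (genotypes int8 with -1 missing, snp_ids, individual ids)."""
    df = pd.read_csv(path, sep="\t")
    iids = df["iid"].astype(str).tolist()
    g = df.drop(columns="iid")
    snp_ids = g.columns.to_numpy(dtype=object)
    mat = g.to_numpy(dtype=np.float64)
    out = np.where(np.isnan(mat), MISSING, mat).astype(np.int8)
    return out, snp_ids, iids


def write_phenotype_tsv(cohort: Cohort, path: str | Path) -> None:
    df = cohort.covariates.copy()
    df.insert(0, "iid", [f"IND{i + 1}" for i in range(cohort.n_individuals)])
    df.insert(1, "phenotype", cohort.phenotype)
    df.to_csv(path, sep="\t", index=False)


def read_phenotype_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_cohort(genotype_path: str | Path, phenotype_path: str | Path) -> Cohort:
    """Assemble a cohort from a genotype TSV and a phenotype/covariate TSV."""
    genotypes, snp_ids, iids = read_genotype_tsv(genotype_path)
    pheno = read_phenotype_tsv(phenotype_path).set_index("iid").loc[iids]
    covars = pheno.drop(columns="phenotype").reset_index(drop=True)
    return Cohort(
        genotypes=genotypes,
        phenotype=pheno["phenotype"].to_numpy(dtype=np.int8),
        covariates=covars,
        snp_ids=snp_ids,
    )


def write_annotation_tsv(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation TSV needs columns {sorted(required)}")
    return df


def write_variants_tsv(variants: pd.DataFrame, path: str | Path) -> None:
    variants.to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"snp_id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise ValueError(f"variant TSV needs columns {sorted(required)}")
    return df


def write_assoc_tsv(assoc_table: pd.DataFrame, path: str | Path) -> None:
    assoc_table.to_csv(path, sep="\t", index=False)


def read_assoc_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
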