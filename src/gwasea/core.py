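"""Shared containers for cohorts and simulation ground truth.

Genotypes are stored as an ``individuals x SNPs`` int8 matrix of additive
minor-allele counts (0/1/2) with ``-1`` marking a missing call.  Phenotype is
a 0/1 case indicator; covariates live in a DataFrame aligned to individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class Cohort:
    """Case-control cohort: genotype matrix, phenotype and covariates."""

    genotypes: np.ndarray        # (n_individuals, n_snps) int8, -1 = missing
    phenotype: np.ndarray        # (n_individuals,) 0/1
    covariates: pd.DataFrame     # columns e.g. 'age', 'sex'
    snp_ids: np.ndarray          # (n_snps,) str

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        n = self.genotypes.shape[0]
        if self.phenotype.shape[0] != n or len(self.covariates) != n:
            raise ValueError("phenotype/covariates not aligned to genotypes")
        classes = np.unique(self.phenotype)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError("phenotype must contain both cases and controls")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return self.n_individuals - self.n_cases

    def genotype_matrix(self) -> np.ndarray:
        """Genotypes as float64 with NaN for missing calls."""
        g = self.genotypes.astype(np.float64)
        g[self.genotypes == MISSING] = np.nan
        return g


@dataclass
class TruthSpec:
    """Ground truth of a simulation scenario.

    ``beta`` maps SNP id -> log-odds per minor allele; SNPs absent from the
    mapping are non-causal (beta 0).  ``alpha`` is the disease-model
    intercept, ``gamma`` the log-odds per year of age.
    """

    causal_set_names: list[str] = field(default_factory=list)
    causal_genes: list[str] = field(default_factory=list)
    beta: dict[str, float] = field(default_factory=dict)
    alpha: float = 0.0
    gamma: float = 0.0

    @property
    def is_null(self) -> bool:
        return not self.beta

    def beta_vector(self, snp_ids: np.ndarray) -> np.ndarray:
        return np.array([self.beta.get(s, 0.0) for s in snp_ids])
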