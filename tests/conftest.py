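"""Shared fixtures.

The two session fixtures run the full pipeline once at the scaled study
conditions (2,000 SNPs / 200 genes / 100 sets / 200 permutations) so the
calibration and power assertions across test modules share a single
simulation instead of re-running the permutation engine.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gwasea import genemap, simdata
from gwasea.pipeline import run_study

STUDY_SEED = 1


@pytest.fixture(scope="session")
def null_run() -> dict:
    """Null cohort at the reference shape: 537 cases / 605 controls, no
    causal effects, B = 200 permutation replicates."""
    return run_study(B=200, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def power_run() -> dict:
    """One implanted causal set: 5 causal genes, per-SNP odds ratio 1.6,
    1000 + 1000 individuals, B = 200, tag-SNP density (~3 SNPs per gene)."""
    return run_study(
        n_cases=1000,
        n_controls=1000,
        n_causal_sets=1,
        effect_size=float(np.log(1.6)),
        snps_per_gene_mean=3,
        B=200,
        seed=STUDY_SEED,
    )


@pytest.fixture
def toy_annotation() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": ["GA", "GB", "GC"],
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [100_000, 105_000, 50_000],
            "end": [110_000, 130_000, 60_000],
        }
    )


@pytest.fixture
def toy_variants() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": ["s1", "s2", "s3", "s4", "s5"],
            "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2"],
            "pos": [80_000, 107_000, 150_000, 55_000, 90_000],
            "maf": [0.3, 0.2, 0.4, 0.25, 0.1],
        }
    )


@pytest.fixture
def toy_map(toy_variants, toy_annotation) -> genemap.SnpGeneMap:
    return genemap.map_snps(toy_variants, toy_annotation)


@pytest.fixture
def small_cohort():
    """200-individual, 100-SNP null cohort for permutation-engine tests."""
    annotation = simdata.simulate_annotation(10, seed=5)
    variants = simdata.simulate_variants(annotation, snps_per_gene_mean=10, seed=5)
    variants = variants.iloc[:100].reset_index(drop=True)
    from gwasea.core import TruthSpec

    return variants, simdata.simulate_cohort(
        variants, TruthSpec(), n_cases=100, n_controls=100, seed=5
    )
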