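"""Self-contained enrichment via the ratio of significant SNPs (SNP ratio test).

For a set S, the statistic is ``m_sig / M`` where M counts the distinct SNPs
mapped to any member gene (a SNP shared by two member genes counts once) and
``m_sig`` those with association p strictly below the cutoff.  Significance
comes from case/control label permutations: the ratio is recomputed from
each permuted scan and

    p = (1 + #{b : ratio_b >= ratio_obs}) / (B + 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genemap import SnpGeneMap
from .genesets import GeneSetCollection
from .gwas_assoc import PermutationAssoc

__all__ = ["snp_ratio", "srt_pvalue", "srt_test"]


def snp_ratio(
    assoc_table: pd.DataFrame,
    snp_gene_map: SnpGeneMap,
    gene_set,
    p_threshold: float = 0.05,
) -> tuple[int, int, float]:
    """(m_sig, M, ratio) for one set; raises if no SNP maps to the set."""
    genes = gene_set.genes if hasattr(gene_set, "genes") else list(gene_set)
    snps = snp_gene_map.snps_of_set(genes)
    if not snps:
        raise ValueError("no SNPs mapped to the set")
    p = assoc_table.set_index("snp_id").loc[snps, "P"]
    m_sig = int((p < p_threshold).sum())
    return m_sig, len(snps), m_sig / len(snps)


def srt_pvalue(
    observed_ratio: float,
    permutation: PermutationAssoc,
    snp_indices: np.ndarray,
    p_threshold: float = 0.05,
) -> float:
    """Empirical p from the shared permutation replicates for one set."""
    ratios = (permutation.p_values[:, snp_indices] < p_threshold).mean(axis=1)
    return float((1 + int((ratios >= observed_ratio).sum())) / (permutation.B + 1))


def srt_test(
    assoc_table: pd.DataFrame,
    permutation: PermutationAssoc,
    snp_gene_map: SnpGeneMap,
    collection: GeneSetCollection,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Ratio and permutation p for every set.

    Sets with no mapped SNP are flagged ``no_snps`` and get NaN results.
    Returns columns set, m_sig, M, ratio, raw_p, flag.
    """
    snp_index = {s: i for i, s in enumerate(assoc_table["snp_id"])}
    p_obs = assoc_table["P"].to_numpy()
    sig_obs = p_obs < p_threshold
    sig_perm = permutation.p_values < p_threshold          # (B, L)
    rows = []
    for name in collection.names:
        snps = snp_gene_map.snps_of_set(collection[name].genes)
        if not snps:
            rows.append((name, 0, 0, np.nan, np.nan, "no_snps"))
            continue
        idx = np.array([snp_index[s] for s in snps])
        M = idx.size
        m_sig = int(sig_obs[idx].sum())
        ratio = m_sig / M
        ratios_b = sig_perm[:, idx].mean(axis=1)
        p = (1 + int((ratios_b >= ratio).sum())) / (permutation.B + 1)
        rows.append((name, m_sig, M, ratio, p, "ok"))
    return pd.DataFrame(
        rows, columns=["set", "m_sig", "M", "ratio", "raw_p", "flag"]
    )
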