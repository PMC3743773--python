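"""Competitive enrichment via the weighted KS running-sum score (GSEA-style).

Genes are ranked by their best-SNP chi-square ``r`` in descending order.
For a set S with N_H of the N ranked genes, a running sum walks down the
ranking, rising by ``|r|^tau / N_R`` at member genes (``N_R`` the sum of
those weights, so the hit mass totals 1) and falling by ``1 / (N - N_H)``
at non-members.  The enrichment score ES(S) is the maximum of the running
sum — the positive-deviation convention, since inflation of the set's
statistics is the alternative of interest — and the sum returns to 0 at the
end of the list.  Significance comes from case/control label permutations:
gene statistics, ranking and ES are recomputed per replicate, and

    p = (1 + #{b : ES_b >= ES_obs}) / (B + 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genemap import SnpGeneMap
from .genesets import GeneSetCollection
from .gwas_assoc import PermutationAssoc

__all__ = ["rank_genes", "enrichment_score", "gengen_test"]


def rank_genes(gene_stats: pd.DataFrame) -> pd.DataFrame:
    """Order genes by descending statistic, ties by gene id ascending."""
    if len(gene_stats) < 2:
        raise ValueError("need at least two genes to rank")
    return gene_stats.sort_values(
        ["r", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def _running_sum(r_ranked: np.ndarray, hits: np.ndarray, tau: float) -> np.ndarray:
    """Running sum for one set; ``hits`` is a boolean mask in rank order."""
    N = r_ranked.size
    N_H = int(hits.sum())
    if N_H == 0 or N_H >= N:
        raise ValueError("need 1 <= N_H < N")
    w = np.abs(r_ranked) ** tau
    n_r = w[hits].sum()
    step = np.where(hits, w / n_r if n_r > 0 else 1.0 / N_H, -1.0 / (N - N_H))
    return np.cumsum(step)


def enrichment_score(ranked: pd.DataFrame, gene_set, tau: float = 1.0) -> float:
    """ES for one set against a ranked gene table (as from rank_genes)."""
    members = set(gene_set.genes if hasattr(gene_set, "genes") else gene_set)
    hits = ranked["gene_id"].isin(members).to_numpy()
    return float(_running_sum(ranked["r"].to_numpy(), hits, tau).max())


def _es_matrix(
    r: np.ndarray, gene_order: np.ndarray, membership: np.ndarray, tau: float
) -> np.ndarray:
    """ES for all sets at once.

    r: (N,) statistics in fixed gene-index order; gene_order: ranking
    permutation; membership: (n_sets, N) boolean in fixed gene-index order.
    Sets with N_H == 0 get NaN.
    """
    N = r.size
    w = np.abs(r[gene_order]) ** tau            # (N,) in rank order
    H = membership[:, gene_order]               # (n_sets, N) in rank order
    n_h = H.sum(axis=1)
    n_r = (H * w).sum(axis=1)
    hit_step = np.where(
        n_r[:, None] > 0, H * w / np.where(n_r[:, None] > 0, n_r[:, None], 1.0),
        H / np.maximum(n_h[:, None], 1),
    )
    miss = np.maximum(N - n_h, 1)
    step = hit_step - (~H) / miss[:, None]
    es = np.cumsum(step, axis=1).max(axis=1)
    es[n_h == 0] = np.nan
    return es


def _rank_order(r: np.ndarray) -> np.ndarray:
    # descending r; ties by gene index ascending (gene ids are pre-sorted)
    return np.lexsort((np.arange(r.size), -r))


def gengen_test(
    assoc_table: pd.DataFrame,
    permutation: PermutationAssoc,
    snp_gene_map: SnpGeneMap,
    collection: GeneSetCollection,
    tau: float = 1.0,
) -> pd.DataFrame:
    """ES and permutation p-value per gene set.

    Gene statistics are the best-SNP chi-squares; per replicate they are
    recomputed from the permuted scan so the SNP-gene structure (and any LD
    the genotypes carry) is preserved under the null.  Sets with no gene in
    the ranking are flagged ``no_overlap``; a set covering every ranked gene
    is rejected (the miss decrement is undefined).
    Returns columns set, ES, N_H, raw_p, flag.
    """
    if permutation.B < 1:
        raise ValueError("need at least one permutation replicate")
    genes = snp_gene_map.genes                       # sorted
    gene_index = {g: i for i, g in enumerate(genes)}
    N = len(genes)
    if N < 2:
        raise ValueError("need at least two covered genes")
    snp_index = {s: i for i, s in enumerate(assoc_table["snp_id"])}
    pair_s = np.array([snp_index[s] for s in snp_gene_map.pairs["snp_id"]])
    pair_g = np.array([gene_index[g] for g in snp_gene_map.pairs["gene_id"]])

    names = collection.names
    membership = np.zeros((len(names), N), dtype=bool)
    for i, name in enumerate(names):
        idx = [gene_index[g] for g in collection[name].genes if g in gene_index]
        membership[i, idx] = True
    n_h = membership.sum(axis=1)
    if (n_h == N).any():
        raise ValueError("a gene set covers every ranked gene; ES undefined")

    def gene_r(t_values: np.ndarray) -> np.ndarray:
        r = np.zeros(N)
        np.maximum.at(r, pair_g, t_values[pair_s])
        return r

    r_obs = gene_r(assoc_table["T"].to_numpy())
    es_obs = _es_matrix(r_obs, _rank_order(r_obs), membership, tau)

    exceed = np.zeros(len(names))
    for b in range(permutation.B):
        r_b = gene_r(permutation.t_values[b])
        es_b = _es_matrix(r_b, _rank_order(r_b), membership, tau)
        exceed += (es_b >= es_obs)
    raw_p = (1.0 + exceed) / (permutation.B + 1.0)
    flag = np.where(n_h == 0, "no_overlap", "ok")
    raw_p = np.where(n_h == 0, np.nan, raw_p)
    return pd.DataFrame(
        {"set": names, "ES": es_obs, "N_H": n_h, "raw_p": raw_p, "flag": flag}
    )
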