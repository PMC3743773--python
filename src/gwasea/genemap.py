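"""SNP-to-gene assignment under the +/-20 kb rule and gene-level statistics.

A SNP belongs to a gene when its position falls in the closed window
``[start - flank, end + flank]`` on the same chromosome (1-based,
strand-agnostic); a SNP may belong to several overlapping genes and a gene
typically carries many SNPs.  Each covered gene is then summarized by its
most significant mapped SNP: ``p_best`` is the minimum SNP p-value and ``r``
the Wald chi-square of that SNP.  Genes without any mapped SNP are dropped
everywhere — they can never contribute signal and would bias SNP resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SnpGeneMap", "map_snps", "gene_statistics"]

DEFAULT_FLANK_BP = 20_000


@dataclass
class SnpGeneMap:
    """Many-to-many SNP<->gene assignment."""

    pairs: pd.DataFrame   # columns snp_id, gene_id

    _gene_to_snps: dict[str, list[str]] = field(default=None, repr=False)
    _snp_to_genes: dict[str, list[str]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        g = self.pairs.groupby("gene_id", sort=True)["snp_id"]
        self._gene_to_snps = {k: sorted(v) for k, v in g}
        s = self.pairs.groupby("snp_id", sort=True)["gene_id"]
        self._snp_to_genes = {k: sorted(v) for k, v in s}

    @property
    def genes(self) -> list[str]:
        return list(self._gene_to_snps)

    @property
    def snps(self) -> list[str]:
        return list(self._snp_to_genes)

    def snps_of(self, gene_id: str) -> list[str]:
        return self._gene_to_snps.get(gene_id, [])

    def genes_of(self, snp_id: str) -> list[str]:
        return self._snp_to_genes.get(snp_id, [])

    def snps_of_set(self, gene_ids) -> list[str]:
        """Distinct SNPs mapped to any of the given genes (sorted)."""
        out: set[str] = set()
        for g in gene_ids:
            out.update(self._gene_to_snps.get(g, ()))
        return sorted(out)

    def __len__(self) -> int:
        return len(self.pairs)


def map_snps(
    variants: pd.DataFrame,
    annotation: pd.DataFrame,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> SnpGeneMap:
    """Assign every SNP to every gene whose flanked window contains it."""
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    rows: list[tuple[str, str]] = []
    for chrom, snps in variants.groupby("chrom"):
        genes = annotation[annotation["chrom"] == chrom]
        if genes.empty:
            continue
        pos = snps["pos"].to_numpy()[:, None]
        lo = (genes["start"].to_numpy() - flank_bp)[None, :]
        hi = (genes["end"].to_numpy() + flank_bp)[None, :]
        snp_idx, gene_idx = np.nonzero((pos >= lo) & (pos <= hi))
        snp_ids = snps["snp_id"].to_numpy()
        gene_ids = genes["gene_id"].to_numpy()
        rows.extend(zip(snp_ids[snp_idx], gene_ids[gene_idx]))
    pairs = pd.DataFrame(rows, columns=["snp_id", "gene_id"])
    pairs = pairs.sort_values(["gene_id", "snp_id"], kind="mergesort").reset_index(drop=True)
    return SnpGeneMap(pairs=pairs)


def gene_statistics(assoc_table: pd.DataFrame, snp_gene_map: SnpGeneMap) -> pd.DataFrame:
    """Best-SNP summary per covered gene.

    Ties in the minimum p-value are broken by the larger chi-square, then the
    lexicographically smaller SNP id, so the table is deterministic.
    Returns columns gene_id, r, p_best, best_snp, n_snps.
    """
    if len(snp_gene_map) == 0:
        raise ValueError("empty SNP-gene map")
    merged = snp_gene_map.pairs.merge(
        assoc_table[["snp_id", "T", "P"]], on="snp_id", how="inner"
    )
    merged = merged.sort_values(
        ["gene_id", "P", "T", "snp_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    best = merged.groupby("gene_id", sort=True).first()
    counts = merged.groupby("gene_id", sort=True).size()
    return pd.DataFrame(
        {
            "gene_id": best.index,
            "r": best["T"].to_numpy(),
            "p_best": best["P"].to_numpy(),
            "best_snp": best["snp_id"].to_numpy(),
            "n_snps": counts.to_numpy(),
        }
    ).reset_index(drop=True)
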