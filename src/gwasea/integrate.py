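"""Multiple-testing adjustment, cross-method consensus and reporting tables.

The four set-level tests produce raw p-values on very different statistics;
this layer puts them on a common footing: Benjamini-Hochberg FDR per method
(optionally against the full collection size when only a top list is in
hand), a consensus report that takes the largest per-method count of
FDR-significant sets as K and compares the per-method top-K lists, the
contributing-gene summaries, a leave-one-out sensitivity rerun, and the
cross-set table of recurrently enriched genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genemap import SnpGeneMap
from .genesets import GeneSet, GeneSetCollection

__all__ = [
    "bh_adjust",
    "adjust_results",
    "ConsensusReport",
    "consensus",
    "contributing_genes",
    "set_size_summary",
    "leave_one_out",
    "enriched_gene_table",
]

METHODS = ("gengen", "aligator", "srt", "mixedmodel")


def bh_adjust(pvalues: Sequence[float], m_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    ``m_total`` may exceed the number of supplied p-values, which adjusts a
    printed top list against the full number of tests it came from; the
    step-up minimum then runs over the supplied ranks only.  Results are
    returned in the input order, capped at 1.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size if m_total is None else int(m_total)
    if m < p.size:
        raise ValueError("m_total smaller than the number of p-values")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def adjust_results(
    results: pd.DataFrame, p_col: str = "raw_p", m_total: int | None = None
) -> pd.DataFrame:
    """Return a copy with an ``fdr`` column; flagged NaN rows stay NaN."""
    out = results.copy()
    ok = out[p_col].notna()
    fdr = np.full(len(out), np.nan)
    if m_total is None:
        m_total = int(ok.sum())
    fdr[ok.to_numpy()] = bh_adjust(out.loc[ok, p_col].to_numpy(), m_total)
    out["fdr"] = fdr
    return out


@dataclass
class ConsensusReport:
    K: int
    significant: dict[str, list[str]]            # per method, FDR < threshold
    top_lists: dict[str, pd.DataFrame]           # per method, top-K by raw p
    union: pd.DataFrame                          # set, multiplicity, methods
    median_set_size: dict[str, float] = field(default_factory=dict)


def consensus(
    results_by_method: Mapping[str, pd.DataFrame],
    fdr_threshold: float = 0.05,
    sizes: Mapping[str, int] | None = None,
) -> ConsensusReport:
    """Cross-method candidate report.

    Each per-method frame needs columns ``set``, ``raw_p`` and ``fdr`` (an
    optional ``size`` column, or the ``sizes`` mapping, feeds the median
    set-size summary).  K is the largest per-method count of sets at
    FDR < threshold, floored at 1; each method contributes its top-K sets by
    raw p (ties broken by set name) and the union is annotated with how many
    methods picked each set.
    """
    if not results_by_method:
        raise ValueError("no method results supplied")
    significant: dict[str, list[str]] = {}
    for method, df in results_by_method.items():
        hit = df[df["fdr"] < fdr_threshold]
        significant[method] = sorted(hit["set"])
    K = max(1, max(len(v) for v in significant.values()))

    top_lists: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    found_in: dict[str, list[str]] = {}
    for method, df in results_by_method.items():
        usable = df[df["raw_p"].notna()]
        top = usable.sort_values(["raw_p", "set"], kind="mergesort").head(K)
        top = top.reset_index(drop=True)
        top_lists[method] = top
        for name in top["set"]:
            found_in.setdefault(name, []).append(method)
        if "size" in top.columns:
            medians[method] = float(np.median(top["size"]))
        elif sizes is not None:
            medians[method] = float(np.median([sizes[s] for s in top["set"]]))
    union = pd.DataFrame(
        {
            "set": sorted(found_in),
            "multiplicity": [len(found_in[s]) for s in sorted(found_in)],
            "methods": [",".join(sorted(found_in[s])) for s in sorted(found_in)],
        }
    )
    return ConsensusReport(
        K=K, significant=significant, top_lists=top_lists, union=union,
        median_set_size=medians,
    )


def contributing_genes(
    gene_set,
    assoc_table: pd.DataFrame,
    snp_gene_map: SnpGeneMap,
    p_threshold: float = 0.05,
) -> tuple[list[str], float]:
    """Member genes with >= 1 SNP below the threshold, plus the set-level
    significant-SNP ratio (SNPs deduplicated across member genes)."""
    genes = gene_set.genes if hasattr(gene_set, "genes") else list(gene_set)
    p_of = assoc_table.set_index("snp_id")["P"]
    contributing = []
    for g in genes:
        snps = snp_gene_map.snps_of(g)
        if snps and (p_of.loc[snps] < p_threshold).any():
            contributing.append(g)
    all_snps = snp_gene_map.snps_of_set(genes)
    if not all_snps:
        return [], 0.0
    ratio = float((p_of.loc[all_snps] < p_threshold).sum() / len(all_snps))
    return contributing, ratio


def set_size_summary(top_sizes: Mapping[str, Iterable[int]]) -> dict[str, float]:
    """Median annotated set size per method (even length: mean of the
    central pair)."""
    out = {}
    for method, sizes in top_sizes.items():
        sizes = list(sizes)
        if not sizes:
            raise ValueError(f"empty size list for {method}")
        out[method] = float(np.median(sizes))
    return out


def leave_one_out(
    method: str,
    gene_set: GeneSet,
    gene: str,
    assoc_table: pd.DataFrame,
    snp_gene_map: SnpGeneMap,
    permutation=None,
    p_threshold: float = 0.05,
    tau: float = 1.0,
    B: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rerun one method on the set with one gene removed, all else fixed.

    Returns the method's one-row result frame for the reduced set.
    """
    if gene not in gene_set.genes:
        raise ValueError(f"{gene} is not a member of {gene_set.name}")
    reduced = GeneSet(
        gene_set.name, gene_set.description, [g for g in gene_set.genes if g != gene]
    )
    if not reduced.genes:
        raise ValueError("removal leaves an empty set")
    single = GeneSetCollection()
    single.add(reduced)
    if method == "gengen":
        from .gengen import gengen_test

        if permutation is None:
            raise ValueError("gengen needs the permutation replicates")
        return gengen_test(assoc_table, permutation, snp_gene_map, single, tau=tau)
    if method == "srt":
        from .srt import srt_test

        if permutation is None:
            raise ValueError("srt needs the permutation replicates")
        return srt_test(assoc_table, permutation, snp_gene_map, single, p_threshold)
    if method == "aligator":
        from .aligator import aligator_test

        return aligator_test(assoc_table, snp_gene_map, single, p_threshold, B=B, seed=seed)
    if method == "mixedmodel":
        from .mixedmodel import mixedmodel_test

        covered = [g for g in reduced.genes if snp_gene_map.snps_of(g)]
        if len(covered) < 2:
            raise ValueError("reduced set falls below the mixed model's two-gene minimum")
        return mixedmodel_test(assoc_table, snp_gene_map, single)
    raise ValueError(f"unknown method {method!r}")


def enriched_gene_table(
    top_sets: Iterable[GeneSet],
    assoc_table: pd.DataFrame,
    snp_gene_map: SnpGeneMap,
    min_terms: int = 4,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Genes recurring across the top sets.

    Lists every gene that (a) has at least one mapped SNP below the p
    threshold and (b) belongs to at least ``min_terms`` of the given top
    sets, with its significant/total SNP counts and most significant SNP.
    """
    top_sets = list(top_sets)
    if not top_sets:
        raise ValueError("no top sets supplied")
    term_count: dict[str, int] = {}
    for s in top_sets:
        for g in set(s.genes):
            term_count[g] = term_count.get(g, 0) + 1
    p_of = assoc_table.set_index("snp_id")["P"]
    rows = []
    for g, n_terms in sorted(term_count.items()):
        if n_terms < min_terms:
            continue
        snps = snp_gene_map.snps_of(g)
        if not snps:
            continue
        p = p_of.loc[snps]
        n_sig = int((p < p_threshold).sum())
        if n_sig == 0:
            continue
        best = p.sort_values(kind="mergesort").index[0]
        rows.append((g, n_terms, n_sig, len(snps), best, float(p.min())))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "n_terms", "n_sig_snps", "n_snps", "best_snp", "best_p"],
    )
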