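"""Independent brute-force reference implementations used only by tests.

These deliberately mirror the definitions one step at a time (explicit
loops, no shared code with the package) so they can serve as oracles for
the vectorized implementations.
"""

from __future__ import annotations

import itertools
import math


def brute_enrichment_score(r_by_gene: dict[str, float], members: set[str], tau: float = 1.0) -> float:
    """Running-sum maximum computed gene by gene from the definition."""
    ranked = sorted(r_by_gene.items(), key=lambda kv: (-kv[1], kv[0]))
    n = len(ranked)
    hits = [g for g, _ in ranked if g in members]
    n_h = len(hits)
    assert 1 <= n_h < n
    n_r = sum(abs(r_by_gene[g]) ** tau for g in hits)
    running, best = 0.0, -math.inf
    for g, r in ranked:
        if g in members:
            running += (abs(r) ** tau / n_r) if n_r > 0 else 1.0 / n_h
        else:
            running -= 1.0 / (n - n_h)
        best = max(best, running)
    return best


def brute_significant_genes(
    snp_p: dict[str, float], gene_snps: dict[str, list[str]], threshold: float
) -> list[str]:
    out = []
    for gene, snps in gene_snps.items():
        for s in snps:
            if snp_p[s] < threshold:
                out.append(gene)
                break
    return sorted(out)


def brute_set_count(significant: list[str], members: list[str]) -> int:
    return sum(1 for g in set(members) if g in set(significant))


def brute_snp_ratio(
    snp_p: dict[str, float], gene_snps: dict[str, list[str]], members: list[str],
    threshold: float,
) -> tuple[int, int]:
    snps: set[str] = set()
    for g in members:
        snps.update(gene_snps.get(g, []))
    m_sig = sum(1 for s in snps if snp_p[s] < threshold)
    return m_sig, len(snps)


def enumerate_resample_counts(
    snp_genes: dict[str, list[str]], target: int, members: list[str]
) -> list[int]:
    """Significant-gene count in a set under every SNP draw order."""
    counts = []
    for order in itertools.permutations(snp_genes):
        marked: set[str] = set()
        for s in order:
            if len(marked) >= target:
                break
            marked.update(snp_genes[s])
        counts.append(len(marked & set(members)))
    return counts
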