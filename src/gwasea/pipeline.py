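"""End-to-end drivers: simulate (or load) a study, scan, permute, run the
four set-level tests, adjust, and build the consensus report."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import aligator, gengen, genemap, gwas_assoc, integrate, mixedmodel, simdata, srt
from .genesets import GeneSetCollection, filter_by_size

__all__ = ["run_methods", "run_study"]


def run_methods(
    assoc_table: pd.DataFrame,
    permutation: gwas_assoc.PermutationAssoc,
    snp_gene_map: genemap.SnpGeneMap,
    collection: GeneSetCollection,
    p_threshold: float = 0.05,
    tau: float = 1.0,
    aligator_B: int | None = None,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """All four set-level tests with BH-adjusted p-values.

    Returns per-method frames with columns set, raw_p, fdr, size plus the
    method's own statistics.  ALIGATOR's resampling count defaults to ten
    times the permutation count, mirroring the convention of many cheap SNP
    resamples against fewer expensive label permutations.
    """
    if aligator_B is None:
        aligator_B = 10 * permutation.B
    sizes = collection.sizes()
    out = {
        "gengen": gengen.gengen_test(assoc_table, permutation, snp_gene_map, collection, tau=tau),
        "aligator": aligator.aligator_test(
            assoc_table, snp_gene_map, collection, p_threshold, B=aligator_B, seed=seed
        ),
        "srt": srt.srt_test(assoc_table, permutation, snp_gene_map, collection, p_threshold),
        "mixedmodel": mixedmodel.mixedmodel_test(assoc_table, snp_gene_map, collection),
    }
    for method, df in out.items():
        df = integrate.adjust_results(df, m_total=len(collection))
        df["size"] = df["set"].map(sizes)
        out[method] = df
    return out


def run_study(
    n_cases: int = 537,
    n_controls: int = 605,
    n_genes: int = 200,
    n_sets: int = 100,
    snps_per_gene_mean: float = 10.0,
    n_causal_sets: int = 0,
    n_causal_genes_per_set: int = 5,
    effect_size: float = 0.0,
    B: int = 200,
    p_threshold: float = 0.05,
    tau: float = 1.0,
    flank_bp: int = genemap.DEFAULT_FLANK_BP,
    set_size_filter: tuple[int, int] = (5, 250),
    seed: int | None = None,
    covariates: tuple[str, ...] = ("age",),
    **sim_kwargs,
) -> dict:
    """Simulate a cohort and run the whole analysis.

    Returns a dict with the simulation artifacts plus assoc, lambda,
    permutation, map, per-method results and the consensus report.
    """
    ss = np.random.SeedSequence(seed)
    s_sim, s_perm, s_ali = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    study = simdata.simulate_study(
        n_genes=n_genes,
        n_sets=n_sets,
        snps_per_gene_mean=snps_per_gene_mean,
        n_causal_sets=n_causal_sets,
        n_causal_genes_per_set=n_causal_genes_per_set,
        effect_size=effect_size,
        n_cases=n_cases,
        n_controls=n_controls,
        seed=s_sim,
        **sim_kwargs,
    )
    collection = filter_by_size(study["collection"], *set_size_filter)
    snp_gene_map = genemap.map_snps(study["variants"], study["annotation"], flank_bp)
    assoc = gwas_assoc.run_scan(study["cohort"], covariates, variants=study["variants"])
    permutation = gwas_assoc.permute_assoc(study["cohort"], covariates, B=B, seed=s_perm)
    results = run_methods(
        assoc, permutation, snp_gene_map, collection,
        p_threshold=p_threshold, tau=tau, seed=s_ali,
    )
    report = integrate.consensus(results)
    return {
        **study,
        "collection": collection,
        "map": snp_gene_map,
        "assoc": assoc,
        "lambda": gwas_assoc.genomic_inflation(assoc),
        "permutation": permutation,
        "results": results,
        "consensus": report,
    }
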