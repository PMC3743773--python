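"""Synthetic genomes, cohorts and gene-set collections.

The generator emulates the structure a case-control GWAS enrichment analysis
assumes: a gene annotation laid out along chromosomes, genotyped SNPs dense
enough that every gene is covered under the +/-20 kb assignment window, a
GO-like gene-set collection (sizes bounded, optionally overlapping, some sets
seeded with causal genes), and a cohort sampled from an additive-logit
disease model

    logit P(case) = alpha + sum_i beta_i g_i + gamma * age

with genotypes drawn binomial(2, maf) per SNP (independent SNPs by default;
an optional block-copy mode induces local LD) and rejection sampling into
exact case/control counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core import MISSING, Cohort, TruthSpec
from .genesets import GeneSet, GeneSetCollection

__all__ = [
    "simulate_annotation",
    "simulate_variants",
    "simulate_gene_sets",
    "assign_snp_effects",
    "calibrate_alpha",
    "simulate_cohort",
    "simulate_study",
]


def simulate_annotation(
    n_genes: int,
    n_chroms: int = 1,
    gene_length_range: tuple[int, int] = (5_000, 50_000),
    gap_range: tuple[int, int] = (30_000, 120_000),
    seed: int | None = None,
) -> pd.DataFrame:
    """Lay out ``n_genes`` non-overlapping genes chromosome by chromosome.

    Returns a DataFrame with columns gene_id, chrom, start, end (1-based,
    inclusive).  Lengths and inter-gene gaps are drawn uniformly from the
    given inclusive ranges.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    for lo, hi in (gene_length_range, gap_range):
        if lo <= 0 or hi < lo:
            raise ValueError("ranges must be positive with lo <= hi")
    rng = np.random.default_rng(seed)
    per_chrom = np.array_split(np.arange(n_genes), n_chroms)
    rows = []
    width = len(str(n_genes))
    for c, idx in enumerate(per_chrom, start=1):
        pos = 1
        for i in idx:
            gap = int(rng.integers(gap_range[0], gap_range[1] + 1))
            length = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
            start = pos + gap
            rows.append((f"G{i + 1:0{width}d}", f"chr{c}", start, start + length - 1))
            pos = start + length
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def simulate_variants(
    annotation: pd.DataFrame,
    snps_per_gene_mean: float = 10.0,
    intergenic_fraction: float = 0.1,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | None = None,
    guarantee_coverage: bool = True,
    flank_bp: int = 20_000,
) -> pd.DataFrame:
    """Scatter SNPs over the annotated genome.

    Per gene, a Poisson(snps_per_gene_mean) number of SNPs is placed uniformly
    in [start - flank_bp, end + flank_bp]; with ``guarantee_coverage`` every
    gene gets at least one such SNP.  ``intergenic_fraction`` of the final
    table is additional SNPs placed uniformly across each chromosome span.
    Returns a DataFrame (snp_id, chrom, pos, maf) sorted by chrom then pos.
    """
    if len(annotation) == 0:
        raise ValueError("annotation is empty")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be within (0, 0.5]")
    rng = np.random.default_rng(seed)
    chroms, positions = [], []
    for row in annotation.itertuples(index=False):
        k = int(rng.poisson(snps_per_gene_mean))
        if guarantee_coverage and snps_per_gene_mean >= 1:
            k = max(k, 1)
        if k == 0:
            continue
        win_lo = max(1, row.start - flank_bp)
        win_hi = row.end + flank_bp
        pos = rng.integers(win_lo, win_hi + 1, size=k)
        chroms.extend([row.chrom] * k)
        positions.extend(int(p) for p in pos)
    n_genic = len(positions)
    if intergenic_fraction > 0 and n_genic:
        n_extra = int(round(intergenic_fraction / (1 - intergenic_fraction) * n_genic))
        spans = annotation.groupby("chrom")["end"].max()
        chrom_choice = rng.choice(spans.index.to_numpy(), size=n_extra)
        for c in chrom_choice:
            positions.append(int(rng.integers(1, spans[c] + flank_bp)))
            chroms.append(c)
    df = pd.DataFrame({"chrom": chroms, "pos": positions})
    df["maf"] = rng.uniform(lo, hi, size=len(df))
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    df.insert(0, "snp_id", [f"rs{i + 1:06d}" for i in range(len(df))])
    return df


def simulate_gene_sets(
    annotation: pd.DataFrame,
    n_sets: int = 100,
    size_range: tuple[int, int] = (5, 25),
    n_causal_sets: int = 0,
    n_causal_genes_per_set: int = 5,
    overlap_fraction: float = 0.3,
    causal_size_range: tuple[int, int] | None = None,
    seed: int | None = None,
) -> tuple[GeneSetCollection, TruthSpec]:
    """Draw a GO-like collection over the annotated genes.

    With ``overlap_fraction`` 0 the genes are partitioned so distinct sets
    are pairwise disjoint (an error if the universe is too small).
    Otherwise each set takes ``round(overlap_fraction * size)`` members from
    a small shared pool and the rest uniformly from the remaining universe,
    so genes recur across sets the way GO terms reuse genes (exercising the
    competitive vs self-contained distinction).  The first ``n_causal_sets``
    sets receive ``n_causal_genes_per_set`` designated causal genes drawn
    from their non-shared members; causal genes are withheld from later
    sets' sampling so implanted signal stays confined to the causal sets.

    Causal sets draw their size from ``causal_size_range``, by default
    [n_causal, 2 * n_causal] clipped to ``size_range``'s upper bound: a
    positive control is a set whose membership is substantially causal, not
    a large term with a few causal members.
    """
    genes = annotation["gene_id"].to_numpy()
    n_genes = len(genes)
    lo, hi = size_range
    if not (1 <= lo <= hi <= n_genes):
        raise ValueError("size_range must satisfy 1 <= lo <= hi <= n_genes")
    if n_causal_sets > n_sets:
        raise ValueError("n_causal_sets exceeds n_sets")
    if causal_size_range is None:
        causal_size_range = (
            max(lo, n_causal_genes_per_set),
            min(hi, max(lo, 2 * n_causal_genes_per_set)),
        )
    c_lo, c_hi = causal_size_range
    if n_causal_sets and not (n_causal_genes_per_set <= c_lo <= c_hi <= n_genes):
        raise ValueError("causal_size_range must hold the causal genes")

    def draw_size(k: int) -> int:
        if k < n_causal_sets:
            return int(rng.integers(c_lo, c_hi + 1))
        return int(rng.integers(lo, hi + 1))

    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(genes))

    collection = GeneSetCollection()
    truth = TruthSpec()
    if overlap_fraction == 0:
        pool = shuffled
        for k in range(n_sets):
            size = draw_size(k)
            if size > len(pool):
                raise ValueError(
                    "gene universe too small for disjoint sets; raise overlap_fraction"
                )
            members, pool = pool[:size], pool[size:]
            name = f"SET{k + 1:04d}"
            collection.add(GeneSet(name, f"synthetic set {k + 1}", sorted(members)))
            if k < n_causal_sets:
                _designate_causal(truth, name, members, n_causal_genes_per_set, rng)
        return collection, truth

    pool_size = max(1, min(hi, n_genes // 4))
    shared_pool = shuffled[:pool_size]
    body = shuffled[pool_size:]
    causal_blocked: set[str] = set()
    for k in range(n_sets):
        size = draw_size(k)
        n_shared = min(int(round(overlap_fraction * size)), len(shared_pool))
        if k < n_causal_sets:
            # causal members come from the set's own (non-shared) draw
            n_shared = min(n_shared, size - n_causal_genes_per_set)
        open_body = [g for g in body if g not in causal_blocked]
        n_own = size - n_shared
        if n_own > len(open_body):
            raise ValueError("gene universe too small for the requested set sizes")
        shared = list(rng.choice(shared_pool, size=n_shared, replace=False)) if n_shared else []
        own = list(rng.choice(open_body, size=n_own, replace=False))
        name = f"SET{k + 1:04d}"
        collection.add(GeneSet(name, f"synthetic set {k + 1}", sorted(own + shared)))
        if k < n_causal_sets:
            causal = _designate_causal(truth, name, own, n_causal_genes_per_set, rng)
            causal_blocked.update(causal)
    return collection, truth


def _designate_causal(
    truth: TruthSpec, name: str, candidates: list[str], n_causal: int,
    rng: np.random.Generator,
) -> list[str]:
    if n_causal > len(candidates):
        raise ValueError("not enough non-shared genes for the requested causal genes")
    causal = [str(g) for g in rng.choice(candidates, size=n_causal, replace=False)]
    truth.causal_set_names.append(name)
    truth.causal_genes.extend(causal)
    return causal


def assign_snp_effects(
    truth: TruthSpec,
    annotation: pd.DataFrame,
    variants: pd.DataFrame,
    effect_size: float,
    snps_per_gene: int = 1,
    flank_bp: int = 20_000,
    seed: int | None = None,
) -> TruthSpec:
    """Give ``snps_per_gene`` SNPs mapped to each causal gene a log-odds of
    ``effect_size``; all other SNPs stay null.  Modifies and returns truth."""
    rng = np.random.default_rng(seed)
    ann = annotation.set_index("gene_id")
    for gene in truth.causal_genes:
        row = ann.loc[gene]
        hit = variants[
            (variants["chrom"] == row["chrom"])
            & (variants["pos"] >= row["start"] - flank_bp)
            & (variants["pos"] <= row["end"] + flank_bp)
        ]
        if hit.empty:
            raise ValueError(f"causal gene {gene} has no mapped SNPs")
        take = min(snps_per_gene, len(hit))
        for snp in rng.choice(hit["snp_id"].to_numpy(), size=take, replace=False):
            truth.beta[str(snp)] = effect_size
    return truth


def calibrate_alpha(
    truth: TruthSpec,
    variants: pd.DataFrame,
    gamma: float = 0.0,
    age_range: tuple[float, float] = (3.0, 12.0),
    target_prevalence: float = 0.5,
) -> float:
    """Intercept putting the population mean logit at the target prevalence."""
    maf = variants.set_index("snp_id")["maf"]
    shift = sum(2.0 * maf[s] * b for s, b in truth.beta.items())
    mean_age = 0.5 * (age_range[0] + age_range[1])
    return float(logit(target_prevalence) - shift - gamma * mean_age)


def ld_blocks(variants: pd.DataFrame, span_bp: int = 100_000) -> list[tuple[int, int]]:
    """Positional LD blocks: a new block starts at a chromosome change or
    when a SNP lies more than ``span_bp`` beyond the block's first SNP.
    Returns (start, stop) index pairs over the variant table's row order."""
    blocks = []
    chrom_arr = variants["chrom"].to_numpy()
    pos_arr = variants["pos"].to_numpy()
    start = 0
    for i in range(1, len(variants)):
        if chrom_arr[i] != chrom_arr[start] or pos_arr[i] - pos_arr[start] > span_bp:
            blocks.append((start, i))
            start = i
    if len(variants):
        blocks.append((start, len(variants)))
    return blocks


def _draw_genotypes(
    rng: np.random.Generator,
    maf: np.ndarray,
    n: int,
    blocks: list[tuple[int, int]] | None = None,
    ld_copy_prob: float = 0.0,
) -> np.ndarray:
    g = rng.binomial(2, maf, size=(n, maf.size)).astype(np.int8)
    if blocks and ld_copy_prob > 0:
        # Block-LD mode: within a positional block, each SNP copies the
        # block leader's genotype with probability ld_copy_prob, else keeps
        # its own independent draw (correlation ~ copy probability).
        for start, stop in blocks:
            if stop - start < 2:
                continue
            leader = g[:, start]
            copy = rng.random((n, stop - start - 1)) < ld_copy_prob
            block = g[:, start + 1 : stop]
            block[copy] = np.broadcast_to(leader[:, None], copy.shape)[copy]
    return g


def simulate_cohort(
    variants: pd.DataFrame,
    truth: TruthSpec,
    n_cases: int,
    n_controls: int,
    alpha: float | None = None,
    gamma: float = 0.0,
    age_range: tuple[float, float] = (3.0, 12.0),
    seed: int | None = None,
    missing_rate: float = 0.0,
    ld_copy_prob: float = 0.0,
    ld_span_bp: int = 100_000,
    max_batches: int = 200,
) -> Cohort:
    """Sample a cohort with exactly the requested case/control counts.

    Individuals are drawn in batches (genotypes, age, sex), case status is
    Bernoulli under the logistic disease model, and accepted into whichever
    arm is still unfilled; an error is raised if the counts cannot be reached
    within ``max_batches`` batches (e.g. an extreme intercept).  SNPs are
    independent by default; with ``ld_copy_prob > 0`` genotypes are
    correlated within positional blocks of ``ld_span_bp`` so association
    signal spreads over a locus the way LD spreads it in real data.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("need at least one case and one control")
    rng = np.random.default_rng(seed)
    maf = variants["maf"].to_numpy()
    snp_ids = variants["snp_id"].to_numpy()
    beta = truth.beta_vector(snp_ids)
    if not np.all(np.isfinite(beta)):
        raise ValueError("effect sizes must be finite")
    if alpha is None:
        alpha = truth.alpha
    gamma = gamma if gamma else truth.gamma

    blocks = ld_blocks(variants, ld_span_bp) if ld_copy_prob > 0 else None
    batch = max(256, 2 * (n_cases + n_controls))
    kept_g: list[np.ndarray] = []
    kept_age: list[np.ndarray] = []
    kept_y: list[np.ndarray] = []
    need_cases, need_controls = n_cases, n_controls
    causal_idx = np.flatnonzero(beta != 0.0)
    for _ in range(max_batches):
        if need_cases == 0 and need_controls == 0:
            break
        g = _draw_genotypes(rng, maf, batch, blocks, ld_copy_prob)
        age = rng.uniform(age_range[0], age_range[1], size=batch)
        eta = alpha + gamma * age
        if causal_idx.size:
            eta = eta + g[:, causal_idx].astype(np.float64) @ beta[causal_idx]
        y = (rng.random(batch) < expit(eta)).astype(np.int8)
        take_case = np.flatnonzero(y == 1)[:need_cases]
        take_ctrl = np.flatnonzero(y == 0)[:need_controls]
        take = np.concatenate([take_case, take_ctrl])
        kept_g.append(g[take])
        kept_age.append(age[take])
        kept_y.append(y[take])
        need_cases -= take_case.size
        need_controls -= take_ctrl.size
    if need_cases or need_controls:
        raise RuntimeError(
            "could not reach requested case/control counts; check alpha/beta"
        )
    g = np.concatenate(kept_g)
    age = np.concatenate(kept_age)
    y = np.concatenate(kept_y)
    order = rng.permutation(g.shape[0])   # interleave cases and controls
    g, age, y = g[order], age[order], y[order]
    if missing_rate > 0:
        mask = rng.random(g.shape) < missing_rate
        g[mask] = MISSING
    sex = rng.integers(0, 2, size=g.shape[0]).astype(np.int8)
    covars = pd.DataFrame({"age": age, "sex": sex})
    return Cohort(genotypes=g, phenotype=y, covariates=covars, snp_ids=snp_ids)


def simulate_study(
    n_genes: int = 200,
    n_chroms: int = 4,
    n_sets: int = 100,
    set_size_range: tuple[int, int] = (5, 25),
    snps_per_gene_mean: float = 10.0,
    n_causal_sets: int = 0,
    n_causal_genes_per_set: int = 5,
    causal_size_range: tuple[int, int] | None = None,
    effect_size: float = 0.0,
    causal_snps_per_gene: int = 1,
    n_cases: int = 537,
    n_controls: int = 605,
    overlap_fraction: float = 0.3,
    seed: int | None = None,
    **cohort_kwargs,
) -> dict:
    """End-to-end scenario builder used by tests, the CLI and the pipeline.

    Returns a dict with keys annotation, variants, collection, truth, cohort.
    Defaults mirror the shape of the motivating caries study scaled to desk
    size: 537/605 cases/controls, ages 3-12, GO-like sets of 5-25 genes.
    """
    ss = np.random.SeedSequence(seed)
    s_ann, s_var, s_set, s_eff, s_coh = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)
    )
    annotation = simulate_annotation(n_genes, n_chroms=n_chroms, seed=s_ann)
    variants = simulate_variants(
        annotation, snps_per_gene_mean=snps_per_gene_mean, seed=s_var
    )
    collection, truth = simulate_gene_sets(
        annotation,
        n_sets=n_sets,
        size_range=set_size_range,
        n_causal_sets=n_causal_sets,
        n_causal_genes_per_set=n_causal_genes_per_set,
        causal_size_range=causal_size_range,
        overlap_fraction=overlap_fraction,
        seed=s_set,
    )
    if effect_size and truth.causal_genes:
        assign_snp_effects(
            truth, annotation, variants, effect_size,
            snps_per_gene=causal_snps_per_gene, seed=s_eff,
        )
    prevalence = n_cases / (n_cases + n_controls)
    truth.alpha = calibrate_alpha(truth, variants, target_prevalence=prevalence)
    cohort = simulate_cohort(
        variants, truth, n_cases, n_controls, seed=s_coh, **cohort_kwargs
    )
    return {
        "annotation": annotation,
        "variants": variants,
        "collection": collection,
        "truth": truth,
        "cohort": cohort,
    }
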