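"""Per-SNP logistic association scan and the phenotype-permutation engine.

Each SNP is tested with an additive logistic regression

    logit P(case) = b0 + b_g * g + b' c

where ``g`` is the minor-allele count (0/1/2) and ``c`` the covariates
(age by default).  Significance is the Wald chi-square on ``b_g`` (1 df),
the convention of standard GWAS tooling.  Because the set-level methods need
the full scan refitted under hundreds of case/control label permutations,
the fit is a vectorized iteratively-reweighted least squares across all SNPs
at once rather than a per-SNP model object.

Degenerate SNPs (monomorphic, separated, non-converged) are flagged and
assigned P = 1 / T = 0 so that set-level denominators stay defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2

from .core import Cohort

__all__ = [
    "AssocRecord",
    "PermutationAssoc",
    "fit_snp_logistic",
    "minor_allele_flips",
    "run_scan",
    "genomic_inflation",
    "permute_assoc",
]

#: median of the chi-square distribution with 1 df
CHI2_1_MEDIAN = float(chi2.ppf(0.5, 1))

FLAG_OK = "ok"
FLAG_MONOMORPHIC = "monomorphic"
FLAG_SEPARATION = "separation"
FLAG_NONCONVERGED = "nonconverged"

_MAX_ITER = 100
_TOL = 1e-8
_BETA_DIVERGED = 15.0


@dataclass
class AssocRecord:
    snp_id: str
    beta: float
    se: float
    T: float
    P: float
    flag: str


@dataclass
class PermutationAssoc:
    """Label-permuted rescans shared by the permutation-based set tests."""

    B: int
    p_values: np.ndarray   # (B, L)
    t_values: np.ndarray   # (B, L)
    labels: np.ndarray     # (B, n) permuted phenotype vectors
    seed: int | None


def _minor_allele_code(G: np.ndarray) -> np.ndarray:
    """Recode so genotypes count the cohort-wide minor allele.

    Frequencies are computed over non-missing calls of the whole cohort;
    ties at 0.5 keep the original coding.
    """
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(G, axis=0) / 2.0
    flip = freq > 0.5
    if flip.any():
        G = G.copy()
        G[:, flip] = 2.0 - G[:, flip]
    return G


try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:                                  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]


@_njit(cache=False)
def _irls_kernel(g, valid, y, C, beta0_init, tol, maxiter):  # pragma: no cover
    """Per-SNP Newton fits with fused accumulation (numba fast path).

    g: (L, n) genotypes (invalid entries arbitrary), valid: (L, n) mask,
    y: (n,) phenotype, C: (n, k) centered covariates.  Returns
    (beta_g, se_g, converged).
    """
    L, n = g.shape
    k = C.shape[1]
    p = 2 + k
    beta_g = np.empty(L)
    se_g = np.empty(L)
    conv = np.zeros(L, dtype=np.bool_)
    beta = np.empty(p)
    H = np.empty((p, p))
    A = np.empty((p, p + 2))
    score = np.empty(p)
    x = np.empty(p)
    for i in range(L):
        for a in range(p):
            beta[a] = 0.0
        beta[0] = beta0_init
        converged = False
        singular = False
        cov11 = np.nan
        for _ in range(maxiter):
            for a in range(p):
                score[a] = 0.0
                for b in range(p):
                    H[a, b] = 0.0
            for j in range(n):
                if not valid[i, j]:
                    continue
                gx = g[i, j]
                eta = beta[0] + beta[1] * gx
                for c in range(k):
                    eta += beta[2 + c] * C[j, c]
                mu = 1.0 / (1.0 + np.exp(-eta))
                w = mu * (1.0 - mu)
                s = y[j] - mu
                x[0] = 1.0
                x[1] = gx
                for c in range(k):
                    x[2 + c] = C[j, c]
                for a in range(p):
                    score[a] += s * x[a]
                    wxa = w * x[a]
                    for b in range(a, p):
                        H[a, b] += wxa * x[b]
            for a in range(p):
                for b in range(a):
                    H[a, b] = H[b, a]
                H[a, a] += 1e-10
            # solve [H | score, e1] by Gauss elimination with partial pivot;
            # the e1 column yields (H^-1)[1,1] for the Wald SE.
            for a in range(p):
                for b in range(p):
                    A[a, b] = H[a, b]
                A[a, p] = score[a]
                A[a, p + 1] = 1.0 if a == 1 else 0.0
            singular = False
            for col in range(p):
                piv = col
                big = abs(A[col, col])
                for rr in range(col + 1, p):
                    if abs(A[rr, col]) > big:
                        big = abs(A[rr, col])
                        piv = rr
                if big < 1e-12:
                    singular = True
                    break
                if piv != col:
                    for cc in range(p + 2):
                        tmp = A[col, cc]
                        A[col, cc] = A[piv, cc]
                        A[piv, cc] = tmp
                for rr in range(p):
                    if rr == col:
                        continue
                    f = A[rr, col] / A[col, col]
                    if f != 0.0:
                        for cc in range(col, p + 2):
                            A[rr, cc] -= f * A[col, cc]
            if singular:
                break
            maxd = 0.0
            for a in range(p):
                d = A[a, p] / A[a, a]
                beta[a] += d
                if abs(d) > maxd:
                    maxd = abs(d)
            cov11 = A[1, p + 1] / A[1, 1]
            if maxd < tol:
                converged = True
                break
        beta_g[i] = beta[1]
        se_g[i] = np.sqrt(cov11) if cov11 > 0.0 else np.nan
        conv[i] = converged
    return beta_g, se_g, conv


def _irls_system(
    g: np.ndarray, g2: np.ndarray, C: np.ndarray, CC: np.ndarray,
    w: np.ndarray, s: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Normal equations of the weighted least-squares step without ever
    materializing the (l, n, p) design tensor.

    Columns are [1, g, C]; ``w`` are the IRLS weights, ``s`` the working
    scores (y - mu, missing zeroed).  Covariate blocks go through BLAS
    matvecs since C is shared across SNPs.
    """
    l, n = g.shape
    k = C.shape[1]
    p = 2 + k
    wg = w * g
    H = np.empty((l, p, p))
    H[:, 0, 0] = w.sum(axis=1)
    H[:, 0, 1] = wg.sum(axis=1)
    H[:, 1, 1] = (w * g2).sum(axis=1)
    if k:
        H[:, 0, 2:] = w @ C
        H[:, 1, 2:] = wg @ C
        H[:, 2:, 2:] = (w @ CC).reshape(l, k, k)
        H[:, 2:, 0] = H[:, 0, 2:]
        H[:, 2:, 1] = H[:, 1, 2:]
    H[:, 1, 0] = H[:, 0, 1]
    score = np.empty((l, p))
    score[:, 0] = s.sum(axis=1)
    score[:, 1] = (s * g).sum(axis=1)
    if k:
        score[:, 2:] = s @ C
    H[:, np.arange(p), np.arange(p)] += 1e-10
    return H, score


def _batched_irls(
    G: np.ndarray, y: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit logit(y) ~ 1 + g + C per SNP column of G (NaN = missing).

    Dispatches to the compiled per-SNP Newton kernel when numba is present,
    else to the vectorized numpy path; both honor the same convergence rule
    (max |coefficient change| < 1e-8, at most 100 iterations).
    Returns (beta_g, se_g, converged) arrays of length L.
    """
    if _HAVE_NUMBA:
        g_all = np.ascontiguousarray(G.T)
        valid = np.isfinite(g_all)
        g0 = np.where(valid, g_all, 0.0)
        yf = y.astype(np.float64)
        prev = min(max(yf.mean(), 1e-12), 1 - 1e-12)
        beta0 = float(np.log(prev / (1 - prev)))
        return _irls_kernel(
            g0, valid, yf, np.ascontiguousarray(C), beta0, _TOL, _MAX_ITER
        )
    return _batched_irls_numpy(G, y, C)


def _batched_irls_numpy(
    G: np.ndarray, y: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS over all SNPs; converged SNPs drop out of the
    working set so late iterations only touch the stragglers."""
    n, L = G.shape
    k = C.shape[1]
    p = 2 + k
    g_all = G.T.copy()                               # (L, n)
    valid_all = np.isfinite(g_all)
    any_missing = not valid_all.all()
    if any_missing:
        g_all[~valid_all] = 0.0
    g2_all = g_all * g_all
    CC = (C[:, :, None] * C[:, None, :]).reshape(n, k * k) if k else np.empty((n, 0))
    yf = y.astype(np.float64)

    beta = np.zeros((L, p))
    beta[:, 0] = np.log(max(yf.mean(), 1e-12) / max(1.0 - yf.mean(), 1e-12))
    active = np.arange(L)
    converged = np.zeros(L, dtype=bool)
    for _ in range(_MAX_ITER):
        g = g_all[active]
        eta = beta[active, 0:1] + beta[active, 1:2] * g
        if k:
            eta += beta[active, 2:] @ C.T
        mu = expit(eta)
        if any_missing:
            v = valid_all[active]
            w = mu * (1.0 - mu) * v
            s = (yf[None, :] - mu) * v
        else:
            w = mu * (1.0 - mu)
            s = yf[None, :] - mu
        H, score = _irls_system(g, g2_all[active], C, CC, w, s)
        try:
            delta = np.linalg.solve(H, score[..., None])[..., 0]
        except np.linalg.LinAlgError:
            break
        beta[active] += delta
        done = np.max(np.abs(delta), axis=1) < _TOL
        converged[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break

    # observed information and Wald SE at the final estimates, all SNPs
    se = np.empty(L)
    chunk = 2048
    for start in range(0, L, chunk):
        stop = min(start + chunk, L)
        g = g_all[start:stop]
        eta = beta[start:stop, 0:1] + beta[start:stop, 1:2] * g
        if k:
            eta += beta[start:stop, 2:] @ C.T
        mu = expit(eta)
        w = mu * (1.0 - mu)
        if any_missing:
            w = w * valid_all[start:stop]
        H, _ = _irls_system(g, g2_all[start:stop], C, CC, w, np.zeros_like(w))
        with np.errstate(invalid="ignore"):
            cov = np.linalg.inv(H)
            se[start:stop] = np.sqrt(cov[:, 1, 1])
    return beta[:, 1], se, converged


def _flags(G: np.ndarray, y: np.ndarray, beta: np.ndarray, conv: np.ndarray) -> np.ndarray:
    """Per-SNP degeneracy flags from the data and the fit."""
    L = G.shape[1]
    flags = np.full(L, FLAG_OK, dtype=object)
    with np.errstate(invalid="ignore"):
        gmin = np.nanmin(G, axis=0)
        gmax = np.nanmax(G, axis=0)
    flags[gmin == gmax] = FLAG_MONOMORPHIC
    case = y == 1
    Gc = np.where(np.isfinite(G), G, np.nan)
    with np.errstate(invalid="ignore"):
        case_min = np.nanmin(Gc[case], axis=0)
        case_max = np.nanmax(Gc[case], axis=0)
        ctrl_min = np.nanmin(Gc[~case], axis=0)
        ctrl_max = np.nanmax(Gc[~case], axis=0)
    separated = (case_min > ctrl_max) | (ctrl_min > case_max)
    diverged = np.abs(beta) > _BETA_DIVERGED
    ok = flags == FLAG_OK
    flags[ok & (separated | diverged)] = FLAG_SEPARATION
    ok = flags == FLAG_OK
    flags[ok & ~conv] = FLAG_NONCONVERGED
    return flags


def _scan_arrays(
    G: np.ndarray, y: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    beta, se, conv = _batched_irls(G, y, C)
    flags = _flags(G, y, beta, conv)
    ok = flags == FLAG_OK
    bad = ~ok | ~np.isfinite(se) | (se <= 0)
    flags[ok & (~np.isfinite(se) | (se <= 0))] = FLAG_NONCONVERGED
    T = np.zeros_like(beta)
    with np.errstate(invalid="ignore", divide="ignore"):
        T[~bad] = (beta[~bad] / se[~bad]) ** 2
    P = np.ones_like(beta)
    P[~bad] = chi2.sf(T[~bad], 1)
    beta = np.where(bad, np.nan, beta)
    se = np.where(bad, np.nan, se)
    return beta, se, T, P, flags


def _covariate_matrix(cohort: Cohort, covariates: tuple[str, ...]) -> np.ndarray:
    missing = [c for c in covariates if c not in cohort.covariates.columns]
    if missing:
        raise KeyError(f"unknown covariates: {missing}")
    C = cohort.covariates[list(covariates)].to_numpy(dtype=np.float64)
    # Centering leaves the genotype coefficient untouched, improves IRLS
    # conditioning, and makes a constant covariate an exact no-op column.
    return C - C.mean(axis=0, keepdims=True)


def minor_allele_flips(cohort: Cohort) -> np.ndarray:
    """Boolean mask of SNPs whose coding the scan flips to count the
    cohort-wide minor allele.  A simulated effect on the original coding
    appears with the opposite sign for a flipped SNP."""
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(cohort.genotype_matrix(), axis=0) / 2.0
    return freq > 0.5


def run_scan(
    cohort: Cohort,
    covariates: tuple[str, ...] = ("age",),
    variants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Logistic association scan over all SNPs; one row per SNP in input order.

    Per-SNP degeneracy is reported in the ``flag`` column, never raised.  If
    a variant table is supplied its chrom/pos columns are joined in.
    """
    if cohort.n_snps < 1:
        raise ValueError("cohort has no SNPs")
    G = _minor_allele_code(cohort.genotype_matrix())
    C = _covariate_matrix(cohort, covariates)
    beta, se, T, P, flags = _scan_arrays(G, cohort.phenotype, C)
    table = pd.DataFrame(
        {"snp_id": cohort.snp_ids, "beta": beta, "se": se, "T": T, "P": P, "flag": flags}
    )
    if variants is not None:
        table = table.merge(
            variants[["snp_id", "chrom", "pos"]], on="snp_id", how="left"
        )[["snp_id", "chrom", "pos", "beta", "se", "T", "P", "flag"]]
    return table


def fit_snp_logistic(
    cohort: Cohort, snp_index: int, covariate_names: tuple[str, ...] = ("age",)
) -> AssocRecord:
    """Fit one SNP; individuals with a missing call are dropped for it."""
    G = _minor_allele_code(cohort.genotype_matrix()[:, [snp_index]])
    if np.unique(G[np.isfinite(G)]).size < 2:
        return AssocRecord(
            str(cohort.snp_ids[snp_index]), np.nan, np.nan, 0.0, 1.0, FLAG_MONOMORPHIC
        )
    y_valid = cohort.phenotype[np.isfinite(G[:, 0])]
    if np.unique(y_valid).size < 2:
        raise ValueError("both phenotype classes required among non-missing calls")
    C = _covariate_matrix(cohort, covariate_names)
    beta, se, T, P, flags = _scan_arrays(G, cohort.phenotype, C)
    return AssocRecord(
        str(cohort.snp_ids[snp_index]), beta[0], se[0], float(T[0]), float(P[0]), flags[0]
    )


def genomic_inflation(assoc_table: pd.DataFrame) -> float:
    """Genomic control lambda: median observed Wald chi-square over the
    null chi-square(1) median (0.4549...)."""
    ok = assoc_table["flag"] == FLAG_OK
    if not ok.any():
        raise ValueError("no non-degenerate records")
    return float(np.median(assoc_table.loc[ok, "T"]) / CHI2_1_MEDIAN)


def permute_assoc(
    cohort: Cohort,
    covariates: tuple[str, ...] = ("age",),
    B: int = 1000,
    seed: int | None = None,
    max_B: int = 100_000,
) -> PermutationAssoc:
    """Full logistic rescan under B case/control label permutations.

    Labels are shuffled across all individuals while covariates stay attached
    to their individuals, so every replicate preserves the case count and the
    genotype/covariate correlation structure.  The replicates are shared by
    the GenGen and SNP-ratio permutation tests.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if B > max_B:
        raise ValueError(f"B={B} exceeds the configured maximum {max_B}")
    rng = np.random.default_rng(seed)
    G = _minor_allele_code(cohort.genotype_matrix())
    C = _covariate_matrix(cohort, covariates)
    n, L = cohort.n_individuals, cohort.n_snps
    labels = np.empty((B, n), dtype=np.int8)
    p_values = np.empty((B, L))
    t_values = np.empty((B, L))
    for b in range(B):
        y_perm = cohort.phenotype[rng.permutation(n)]
        labels[b] = y_perm
        _, _, T, P, _ = _scan_arrays(G, y_perm, C)
        p_values[b] = P
        t_values[b] = T
    return PermutationAssoc(B=B, p_values=p_values, t_values=t_values, labels=labels, seed=seed)
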