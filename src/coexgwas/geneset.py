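"""Competitive gene-set (module) enrichment with covariates, gene-gene
correlation, and adaptive-permutation multiple-testing correction.

The competitive test regresses per-gene association Z-scores on a set
membership indicator plus gene-level confounders (gene size and SNP count),
by generalized least squares with error covariance proportional to the
gene-gene correlation implied by shared/linked SNPs.  A positive membership
coefficient means the set's genes carry more association signal than the
rest of the genome; the reported p is the one-sided upper tail of its
t-statistic.

Family-wise correction permutes gene Z-scores across genes (covariates and
correlation stay attached to genes), re-tests every set, and compares each
observed p with the distribution of per-permutation minimum p; per-set early
stopping caps work on clearly non-significant sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneAssignment
from .data_io import GeneLocus
from .gene_assoc import GeneResult, LdPanel, log_p_cov

log = logging.getLogger(__name__)

__all__ = [
    "GeneSetResult",
    "competitive_test",
    "default_covariates",
    "gene_gene_correlation",
    "adaptive_permutation",
]


@dataclass
class GeneSetResult:
    """Competitive enrichment result for one gene set."""

    set_id: str
    n_genes: int
    beta: float
    se: float
    p: float
    p_corr: float | None = None
    n_perm: int | None = None


def _as_design(
    membership: np.ndarray, covariates: np.ndarray | None, n: int
) -> np.ndarray:
    cols = [np.ones(n), membership.astype(float)]
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] == n:
            covariates = covariates.T
        for row in covariates:
            cols.append(row)
    return np.column_stack(cols)


def competitive_test(
    gene_z: Sequence[float],
    membership: Sequence[bool],
    covariates: np.ndarray | pd.DataFrame | None = None,
    gene_corr: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """GLS fit of z on intercept + membership + covariates.

    Returns (beta, se, one-sided p) for the membership coefficient, where the
    one-sided alternative is beta > 0 (competitive enrichment).
    ``gene_corr=None`` (or the identity) reduces to ordinary least squares.
    """
    z = np.asarray(gene_z, dtype=float)
    n = z.size
    member = np.asarray(membership, dtype=bool)
    if member.size != n:
        raise ValueError("gene_z and membership lengths differ")
    k = int(member.sum())
    if k == 0 or k == n:
        raise ValueError("gene set must be a strict, non-empty subset of the universe")

    names = ["intercept", "membership"]
    if isinstance(covariates, pd.DataFrame):
        names += list(covariates.columns)
        covariates = covariates.to_numpy()
    elif covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        ncov = covariates.shape[1] if covariates.ndim == 2 and covariates.shape[0] == n else covariates.shape[0]
        names += [f"cov{i}" for i in range(ncov)]
    X = _as_design(member, covariates, n)

    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify columns that do not increase rank when added
        collinear = []
        rank = 0
        for j in range(X.shape[1]):
            new_rank = np.linalg.matrix_rank(X[:, : j + 1])
            if new_rank == rank:
                collinear.append(names[j] if j < len(names) else f"col{j}")
            rank = new_rank
        raise ValueError(f"singular design; collinear columns: {collinear}")

    if gene_corr is not None:
        import statsmodels.api as sm

        fit = sm.GLS(z, X, sigma=np.asarray(gene_corr, dtype=float)).fit()
    else:
        import statsmodels.api as sm

        fit = sm.OLS(z, X).fit()
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    dof = int(fit.df_resid)
    p = float(stats.t.sf(beta / se, dof))
    return beta, se, p


def default_covariates(results: Sequence[GeneResult]) -> pd.DataFrame:
    """Gene-level confounders for the competitive test: log SNP count and log
    gene length.  SNP density is their ratio, hence exactly collinear on the
    log scale and not included as a third column."""
    return pd.DataFrame(
        {
            "log_n_snps": [np.log(max(r.n_snps, 1)) for r in results],
            "log_length": [
                np.log(r.length_bp) if r.length_bp else 0.0 for r in results
            ],
        },
        index=[r.gene_id for r in results],
    )


def gene_gene_correlation(
    assignments: Sequence[GeneAssignment],
    ld_source: LdPanel,
    genes: Sequence[GeneLocus],
    gene_ids: Sequence[str],
    window_bp: int = 1_000_000,
    tissue: str | None = None,
    cov_model: str = "two-sided",
) -> np.ndarray:
    """Correlation between gene statistics induced by shared or linked SNPs.

    For gene pairs on the same chromosome whose bodies lie within
    ``window_bp`` of each other, the covariance of the two Q statistics is
    the sum of the pairwise log-p covariances over the genes' SNP sets
    (including SNPs shared by both genes); correlations are the normalized
    covariances, zero beyond the window, and the matrix is clipped to
    positive semidefinite with the unit diagonal restored.
    """
    snps_by_gene: dict[str, list[str]] = {}
    for a in assignments:
        if tissue is not None and a.tissue != tissue:
            continue
        lst = snps_by_gene.setdefault(a.gene_id, [])
        if a.snp_id not in lst and a.snp_id in ld_source:
            lst.append(a.snp_id)
    locus = {g.gene_id: g for g in genes}

    G = len(gene_ids)
    corr = np.eye(G)
    variances = np.empty(G)
    for i, gid in enumerate(gene_ids):
        snps = snps_by_gene.get(gid, [])
        if not snps:
            variances[i] = np.nan
            continue
        R = ld_source.ld(snps).r
        C = log_p_cov(R, model=cov_model)
        np.fill_diagonal(C, 4.0)
        variances[i] = C.sum()

    for i in range(G):
        gi = locus.get(gene_ids[i])
        si = snps_by_gene.get(gene_ids[i], [])
        if gi is None or not si or not np.isfinite(variances[i]):
            continue
        for j in range(i + 1, G):
            gj = locus.get(gene_ids[j])
            sj = snps_by_gene.get(gene_ids[j], [])
            if gj is None or not sj or not np.isfinite(variances[j]):
                continue
            if gi.chrom != gj.chrom:
                continue
            gap = max(gi.start, gj.start) - min(gi.end, gj.end)
            if gap > window_bp:
                continue
            union = list(dict.fromkeys(si + sj))
            R = ld_source.ld(union).r
            C = log_p_cov(R, model=cov_model)
            np.fill_diagonal(C, 4.0)
            idx = {s: k for k, s in enumerate(union)}
            ii = [idx[s] for s in si]
            jj = [idx[s] for s in sj]
            cov_ij = float(C[np.ix_(ii, jj)].sum())
            corr[i, j] = corr[j, i] = cov_ij / np.sqrt(variances[i] * variances[j])

    # PSD repair with unit diagonal
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() < -1e-10:
        vals = np.clip(vals, 0.0, None)
        corr = (vecs * vals) @ vecs.T
        d = np.sqrt(np.clip(np.diag(corr), 1e-12, None))
        corr = corr / np.outer(d, d)
        np.fill_diagonal(corr, 1.0)
    return corr


def _whiten(gene_corr: np.ndarray | None, n: int) -> np.ndarray | None:
    if gene_corr is None:
        return None
    C = np.asarray(gene_corr, dtype=float)
    # small ridge keeps a clipped-PSD matrix invertible
    L = np.linalg.cholesky(C + 1e-8 * np.eye(n))
    return L


def _batched_set_pvalues(
    Xbase: np.ndarray,
    set_cols: np.ndarray,
    Y: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-sided membership (p, beta, se) for every set (rows) x response (cols).

    ``Xbase`` is the n x p base design (intercept + covariates), ``set_cols``
    n x K membership indicators, ``Y`` n x B responses.  Inputs are assumed
    already whitened when a gene correlation is in play.
    """
    n, p = Xbase.shape
    Qb, _ = np.linalg.qr(Xbase)
    S = set_cols - Qb @ (Qb.T @ set_cols)
    Yt = Y - Qb @ (Qb.T @ Y)
    ss = (S**2).sum(axis=0)
    if np.any(ss <= 1e-12):
        raise ValueError("singular design: a set column is collinear with the covariates")
    num = S.T @ Yt  # K x B
    beta = num / ss[:, None]
    yss = (Yt**2).sum(axis=0)  # B
    rss = np.clip(yss[None, :] - num**2 / ss[:, None], 1e-300, None)
    dof = n - p - 1
    sigma2 = rss / dof
    se = np.sqrt(sigma2 / ss[:, None])
    t = beta / se
    return stats.t.sf(t, dof), beta, se


def adaptive_permutation(
    sets: Mapping[str, Sequence[str]],
    gene_ids: Sequence[str],
    gene_z: Sequence[float],
    covariates: pd.DataFrame | np.ndarray | None = None,
    gene_corr: np.ndarray | None = None,
    n_max: int = 10_000,
    early_hits: int = 10,
    seed: int = 0,
    chunk: int = 500,
) -> list[GeneSetResult]:
    """Competitive tests for all sets plus empirical family-wise correction.

    Gene Z-scores are permuted across genes (n_max times at most); for each
    permutation all sets are re-tested and the minimum competitive p recorded.
    p_corr(set) = (b + 1) / (k + 1) with b the number of permutation minima at
    or below the observed p after k permutations; a set stops early once
    b >= early_hits.  Fixed ``seed`` makes runs bit-reproducible.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    gene_ids = list(gene_ids)
    z = np.asarray(gene_z, dtype=float)
    n = z.size
    index = {g: i for i, g in enumerate(gene_ids)}

    set_names = list(sets)
    member = np.zeros((n, len(set_names)))
    for k_, name in enumerate(set_names):
        rows = [index[g] for g in sets[name] if g in index]
        if not rows or len(rows) == n:
            raise ValueError(
                f"set {name!r} is empty or equals the gene universe; no contrast"
            )
        member[rows, k_] = 1.0

    if isinstance(covariates, pd.DataFrame):
        covariates = covariates.loc[gene_ids].to_numpy()
    if covariates is not None and not np.all(np.isfinite(covariates)):
        raise ValueError("covariates contain non-finite values")
    Xbase = np.column_stack([np.ones(n)] + ([] if covariates is None else [covariates]))
    # keep only covariate columns that add rank (a constant covariate, say a
    # uniform SNP count, is redundant with the intercept and carries no
    # information for the fit)
    keep = [0]
    for j in range(1, Xbase.shape[1]):
        if np.linalg.matrix_rank(Xbase[:, keep + [j]]) > len(keep):
            keep.append(j)
    if len(keep) < Xbase.shape[1]:
        log.warning(
            "adaptive_permutation: dropped %d redundant covariate column(s)",
            Xbase.shape[1] - len(keep),
        )
        Xbase = Xbase[:, keep]

    L = _whiten(gene_corr, n)
    if L is not None:
        from scipy.linalg import solve_triangular

        Xbase = solve_triangular(L, Xbase, lower=True)
        member_w = solve_triangular(L, member, lower=True)
        z_w = solve_triangular(L, z, lower=True)
    else:
        member_w = member
        z_w = z

    p_obs, beta_obs, se_obs = _batched_set_pvalues(Xbase, member_w, z_w[:, None])
    p_obs = p_obs[:, 0]
    beta_obs = beta_obs[:, 0]
    se_obs = se_obs[:, 0]

    rng = np.random.default_rng(seed)
    K = len(set_names)
    b = np.zeros(K, dtype=int)
    k_done = np.zeros(K, dtype=int)
    active = np.ones(K, dtype=bool)
    total = 0
    while total < n_max and active.any():
        B = min(chunk, n_max - total)
        perm_idx = np.argsort(rng.random((B, n)), axis=1)
        Yp = z[perm_idx.T]  # n x B permuted raw z
        if L is not None:
            from scipy.linalg import solve_triangular

            Yp = solve_triangular(L, Yp, lower=True)
        p_perm, _, _ = _batched_set_pvalues(Xbase, member_w, Yp)
        minp = p_perm.min(axis=0)  # B
        total += B
        for kk in np.nonzero(active)[0]:
            b[kk] += int((minp <= p_obs[kk]).sum())
            k_done[kk] = total
            if b[kk] >= early_hits:
                active[kk] = False

    out = []
    for kk, name in enumerate(set_names):
        out.append(
            GeneSetResult(
                set_id=name,
                n_genes=int(member[:, kk].sum()),
                beta=float(beta_obs[kk]),
                se=float(se_obs[kk]),
                p=float(p_obs[kk]),
                p_corr=float((b[kk] + 1) / (k_done[kk] + 1)),
                n_perm=int(k_done[kk]),
            )
        )
    return out
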