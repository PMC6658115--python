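"""LD-aware gene-based association test.

The gene statistic is the sum of the assigned SNPs' -log10 p-values.  Its
null distribution is evaluated on the equivalent statistic
Q = 2 ln(10) * T = sum_i -2 ln p_i: under the null each term is chi-squared
with 2 degrees of freedom, and terms are dependent through LD.  Q's mean and
variance are matched to a scaled chi-squared c * chi2_f (Brown-style moment
matching), with the pairwise covariance of the -2 ln p terms evaluated as a
function of the SNP dosage correlation r.

GWAS p-values are two-sided, so the covariance depends on |r| only.  The
default covariance model is the Hermite-series expansion of
cov(-2 ln p_i, -2 ln p_j) for two-sided normal p-values,

    cov(r) = sum_{k even} a_k r^k,   a_k = c_k^2 k!,

with c_k the Hermite coefficients of z -> -2 ln(2 Phi(-|z|)); the series is
truncated at order 30 and the (small) remaining mass is carried on the r^32
term so that cov(1) = 4 = Var(chi2_2) exactly.  The widely used cubic fit
3.263|r| + 0.710 r^2 + 0.027 |r|^3 applies to one-sided p-values and is
available as ``cov_model="one-sided"``; with two-sided inputs it overstates
the covariance and makes the test conservative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneAssignment
from .data_io import GeneLocus, SnpRecord

log = logging.getLogger(__name__)

__all__ = [
    "LdMatrix",
    "GeneResult",
    "LdPanel",
    "ld_from_dosages",
    "gene_test",
    "run_gene_tests",
    "bonferroni_thresholds",
    "log_p_cov",
]

LN10_2 = 2.0 * math.log(10.0)
_P_CLAMP = 1e-12

#: Even-series coefficients a_k (k = 2, 4, ..., 32) of the covariance of
#: -2 ln(two-sided p) between unit normals with correlation r.  Derived by
#: adaptive quadrature of the Hermite coefficients of -2 ln(2 Phi(-|z|));
#: the r^32 entry closes the series so the coefficients sum to 4.
_TWO_SIDED_COEF: dict[int, float] = {
    2: 3.9067978924362285,
    4: 0.05061626052918755,
    6: 0.01734929418467153,
    8: 0.00816109391950243,
    10: 0.0045642354185852245,
    12: 0.0028461254777506833,
    14: 0.0019123441598243509,
    16: 0.001356703864044236,
    18: 0.0010031140226276158,
    20: 0.0007661517530026445,
    22: 0.0006006846741124192,
    24: 0.00048121177858377406,
    26: 0.0003925214269088574,
    28: 0.00032512450981439387,
    30: 0.0002728751038007272,
    32: 0.0025543667413541193,
}


def log_p_cov(r: np.ndarray | float, model: str = "two-sided") -> np.ndarray:
    """Covariance of -2 ln p_i and -2 ln p_j for SNPs with dosage
    correlation ``r``, under the chosen p-value sidedness model."""
    r = np.asarray(r, dtype=float)
    if model == "two-sided":
        r2 = r * r
        out = np.zeros_like(r2)
        for k, a in _TWO_SIDED_COEF.items():
            out = out + a * r2 ** (k // 2)
        return out
    if model == "one-sided":
        a = np.abs(r)
        return 3.263 * a + 0.710 * a * a + 0.027 * a * a * a
    raise ValueError(f"unknown covariance model {model!r}")


def _hermite_cov_reference(rho: float, nodes: int = 200) -> float:
    """Direct 2-D Gauss-Hermite evaluation of the two-sided log-p covariance.

    Slow; used as an independent check of the frozen series coefficients.
    """
    x, w = np.polynomial.hermite_e.hermegauss(nodes)
    w = w / np.sqrt(2 * np.pi)
    q = -2 * np.log(np.clip(2 * stats.norm.sf(np.abs(x)), 1e-300, 1.0))
    e1 = w @ q
    z2 = rho * x[:, None] + math.sqrt(max(1 - rho * rho, 0.0)) * x[None, :]
    q2 = -2 * np.log(np.clip(2 * stats.norm.sf(np.abs(z2)), 1e-300, 1.0))
    return float(np.einsum("i,j,i,ij->", w, w, q, q2) - e1 * e1)


@dataclass
class LdMatrix:
    """Pairwise Pearson correlations of allele dosages for an ordered SNP set."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.snp_ids)
        if self.r.shape != (m, m):
            raise ValueError("LD matrix dimension does not match snp_ids")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise ValueError("LD matrix must have unit diagonal")

    @property
    def m(self) -> int:
        return len(self.snp_ids)


@dataclass
class GeneResult:
    """Per-(gene, tissue) combined association result."""

    gene_id: str
    tissue: str
    n_snps: int
    statistic: float  # T = sum of -log10 p
    p_gene: float
    z: float
    length_bp: int | None = None

    @property
    def density(self) -> float | None:
        if self.length_bp is None or self.length_bp <= 0:
            return None
        return self.n_snps / self.length_bp


def ld_from_dosages(dosages: np.ndarray, snp_ids: Sequence[str] | None = None) -> LdMatrix:
    """Pearson correlation of SNP dosage rows (SNPs x samples)."""
    dosages = np.asarray(dosages, dtype=float)
    if dosages.ndim != 2 or dosages.shape[1] < 2:
        raise ValueError("dosage matrix must be SNPs x samples with >= 2 samples")
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(dosages.shape[0])]
    sd = dosages.std(axis=1)
    if np.any(sd == 0):
        bad = [snp_ids[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"monomorphic SNP(s) in panel: {bad[:5]}")
    r = np.corrcoef(dosages)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    return LdMatrix(list(snp_ids), r)


def _repair_psd(r: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues at 0 and restore the unit diagonal."""
    vals, vecs = np.linalg.eigh(r)
    if vals.min() >= -1e-10:
        return r
    vals = np.clip(vals, 0.0, None)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.clip(np.diag(out), 1e-12, None))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def gene_test(
    p_values: Sequence[float],
    ld: LdMatrix,
    gene_id: str = "",
    tissue: str = "",
    length_bp: int | None = None,
    cov_model: str = "two-sided",
) -> GeneResult:
    """Combine assigned SNP p-values into one gene p-value under LD.

    T = sum -log10 p is reported; the null is evaluated on Q = 2 ln10 * T via
    moment matching of Q to c * chi2_f with f = 2 E^2 / Var and c = Var / (2 E),
    where E = 2m and Var = 4m + 2 * sum_{i<j} cov(|r_ij|).
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m < 1:
        raise ValueError("gene_test requires at least one SNP")
    if ld.m != m:
        raise ValueError("p_values and LD matrix dimensions differ")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")

    r = _repair_psd(ld.r)
    if np.linalg.eigvalsh(r).min() < -1e-8:
        raise ValueError("LD matrix is not repairable to positive semidefinite")

    T = float(np.sum(-np.log10(p)))
    Q = LN10_2 * T
    cov = log_p_cov(r, model=cov_model)
    iu = np.triu_indices(m, k=1)
    var = 4.0 * m + 2.0 * float(cov[iu].sum())
    mean = 2.0 * m
    f = 2.0 * mean * mean / var
    c = var / (2.0 * mean)
    p_gene = float(stats.chi2.sf(Q / c, f))
    p_gene = min(max(p_gene, _P_CLAMP), 1.0 - _P_CLAMP)
    z = float(stats.norm.ppf(1.0 - p_gene))
    return GeneResult(
        gene_id=gene_id,
        tissue=tissue,
        n_snps=m,
        statistic=T,
        p_gene=p_gene,
        z=z,
        length_bp=length_bp,
    )


class LdPanel:
    """A reference panel of dosages used to look up LD for arbitrary SNP sets."""

    def __init__(self, snp_ids: Sequence[str], dosages: np.ndarray):
        dosages = np.asarray(dosages, dtype=float)
        if len(snp_ids) != dosages.shape[0]:
            raise ValueError("snp_ids and dosage rows differ")
        self.snp_ids = list(snp_ids)
        self.dosages = dosages
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def ld(self, snp_ids: Sequence[str]) -> LdMatrix:
        idx = [self._index[s] for s in snp_ids]
        return ld_from_dosages(self.dosages[idx], snp_ids)


def run_gene_tests(
    snps: Sequence[SnpRecord],
    assignments: Sequence[GeneAssignment],
    ld_source: LdPanel,
    genes: Sequence[GeneLocus],
    cov_model: str = "two-sided",
) -> list[GeneResult]:
    """One gene test per (gene, tissue) group of assignments.

    SNPs missing from the GWAS input or the LD panel are dropped with a
    logged count; a gene whose SNPs all drop out is skipped with a warning.
    Output is deterministic: groups are processed in sorted order and SNPs
    within a gene in panel order.
    """
    p_by_snp: dict[str, float] = {}
    for s in snps:
        if s.snp_id not in p_by_snp:  # first occurrence wins
            p_by_snp[s.snp_id] = s.p
        else:
            log.warning("duplicate SNP id %s in GWAS input; first occurrence kept", s.snp_id)
    locus_by_gene = {g.gene_id: g for g in genes}

    groups: dict[tuple[str, str], list[str]] = {}
    for a in sorted(assignments, key=lambda a: (a.gene_id, a.tissue, a.snp_id)):
        groups.setdefault((a.gene_id, a.tissue), []).append(a.snp_id)

    n_missing = 0
    results: list[GeneResult] = []
    for (gene_id, tissue), snp_list in sorted(groups.items()):
        usable = []
        seen: set[str] = set()
        for sid in snp_list:
            if sid in seen:
                continue
            seen.add(sid)
            if sid in p_by_snp and sid in ld_source:
                usable.append(sid)
            else:
                n_missing += 1
        if not usable:
            log.warning("gene %s (%s): no SNP with both p-value and panel LD; skipped",
                        gene_id, tissue)
            continue
        ld = ld_source.ld(usable)
        locus = locus_by_gene.get(gene_id)
        results.append(
            gene_test(
                [p_by_snp[s] for s in usable],
                ld,
                gene_id=gene_id,
                tissue=tissue,
                length_bp=locus.length_bp if locus else None,
                cov_model=cov_model,
            )
        )
    if n_missing:
        log.info("run_gene_tests: dropped %d assignments lacking p or panel LD", n_missing)
    return results


def bonferroni_thresholds(
    results: Sequence[GeneResult] | Mapping[str, int],
    scheme: str = "global",
    alpha: float = 0.05,
) -> float | dict[str, float]:
    """Bonferroni significance thresholds for gene tests.

    ``scheme="global"`` divides alpha by the total number of tests (the
    conservative multi-tissue threshold, or the single threshold of a
    proximity-only analysis); ``scheme="per-tissue"`` divides by the number
    of tests within each tissue and returns one threshold per tissue.
    ``results`` may be GeneResult objects or a mapping tissue -> test count.
    Values are exact; round only for display.
    """
    if isinstance(results, Mapping):
        counts = dict(results)
    else:
        counts = {}
        for r in results:
            counts[r.tissue] = counts.get(r.tissue, 0) + 1
    if not counts or any(v <= 0 for v in counts.values()):
        raise ValueError("empty result group")
    if scheme == "global":
        return alpha / sum(counts.values())
    if scheme == "per-tissue":
        return {t: alpha / n for t, n in counts.items()}
    raise ValueError(f"unknown scheme {scheme!r}")
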