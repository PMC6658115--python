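"""Synthetic data generation with known ground truth.

Everything downstream consumes desk-scale versions of the study's real
input types: LD-block genotypes, GWAS summary statistics, tissue eQTL pair
tables, expression matrices with planted co-expression modules, and gene
loci.  The generators are deterministic given a seed.

Genotypes use a latent-normal haplotype model: within an LD block, latent
normals follow an AR(1) process whose parameter is calibrated (by inverting
the tetrachoric attenuation) so that adjacent-SNP *dosage* correlation
matches the requested value; blocks are independent.  This is a simple
correlation-controlled model, not a coalescent simulation.

Expression planted modules are one-factor models: module genes load on a
shared latent factor with loading sqrt(module_cor), so the expected
within-module gene-gene correlation equals module_cor.  A fraction of genes
additionally carry a cis-eQTL effect from one genotyped SNP; loadings are
scaled so total gene variance stays at 1 and within-module correlation is
unchanged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_io import EqtlPair, ExpressionMatrix, GeneLocus, SnpRecord
from .gene_assoc import LdPanel

log = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "StudyData",
    "simulate_genotypes",
    "simulate_gwas",
    "simulate_expression",
    "simulate_gene_loci",
    "simulate_study",
]

SNP_SPACING_BP = 2_000
GENE_SPACING_BP = 2_000
GENE_LENGTH_BP = 1_500
BLOCKS_PER_CHROM = 5


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic data generators."""

    seed: int = 0
    n_samples: int = 200          # expression-cohort donors
    n_snps: int = 300
    ld_block_size: int = 10
    within_block_rho: float = 0.7
    n_genes: int = 300
    n_modules: int = 4
    module_size: int = 50
    module_cor: float = 0.6
    n_causal_snps: int = 20
    effect_size: float = 0.15     # per causal SNP, in phenotype SD per dosage SD
    eqtl_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_snps", "ld_block_size", "n_genes",
                     "n_modules", "module_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.within_block_rho < 1.0):
            raise ValueError("within_block_rho must be in [0, 1)")
        if not (0.0 <= self.module_cor < 1.0):
            raise ValueError("module_cor must be in [0, 1)")
        if not (0.0 <= self.eqtl_fraction <= 1.0):
            raise ValueError("eqtl_fraction must be in [0, 1]")


def _binorm_cdf(z: float, rho: float) -> float:
    """P(Z1 < z, Z2 < z) for standard bivariate normal with correlation rho."""
    return float(
        stats.multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]], allow_singular=True
        ).cdf([z, z])
    )


def _latent_rho(target_phi: float, maf: float) -> float:
    """Latent AR parameter whose thresholded-indicator (phi) correlation at
    allele frequency ``maf`` equals ``target_phi``."""
    if target_phi <= 0:
        return 0.0
    z = stats.norm.ppf(maf)
    denom = maf * (1.0 - maf)

    def gap(rho_l: float) -> float:
        return (_binorm_cdf(z, rho_l) - maf * maf) / denom - target_phi

    if gap(0.999) < 0:
        return 0.999
    return float(optimize.brentq(gap, 0.0, 0.999, xtol=1e-4))


def _snp_position(i: int, cfg: SimulationConfig) -> tuple[str, int]:
    block = i // cfg.ld_block_size
    chrom = str(block // BLOCKS_PER_CHROM + 1)
    within = block % BLOCKS_PER_CHROM * cfg.ld_block_size + i % cfg.ld_block_size
    return chrom, within * SNP_SPACING_BP + 1_000


def snp_table(cfg: SimulationConfig) -> pd.DataFrame:
    """SNP ids and genomic placement implied by the block layout."""
    rows = []
    for i in range(cfg.n_snps):
        chrom, pos = _snp_position(i, cfg)
        rows.append((f"rs{i}", chrom, pos, i // cfg.ld_block_size))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "block"])


def simulate_genotypes(
    cfg: SimulationConfig,
    n_samples: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], np.ndarray]:
    """Draw a SNPs x samples dosage matrix with AR LD blocks.

    Two independent haplotypes per sample; alleles are thresholded latent
    AR(1) normals with per-block allele frequency ~ U(0.05, 0.5); the AR
    parameter is calibrated so adjacent-SNP dosage correlation is close to
    ``within_block_rho``.  Monomorphic draws are re-thresholded at the
    median to keep every SNP polymorphic.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = n_samples if n_samples is not None else cfg.n_samples
    m = cfg.n_snps
    n_blocks = math.ceil(m / cfg.ld_block_size)
    dosages = np.empty((m, n))
    for b in range(n_blocks):
        i0 = b * cfg.ld_block_size
        i1 = min(i0 + cfg.ld_block_size, m)
        size = i1 - i0
        maf = rng.uniform(0.05, 0.5)
        rho_l = _latent_rho(cfg.within_block_rho, maf)
        thr = stats.norm.ppf(maf)
        haps = np.zeros((2, size, n))
        for h in range(2):
            z = rng.standard_normal((size, n))
            for j in range(1, size):
                z[j] = rho_l * z[j - 1] + math.sqrt(1 - rho_l * rho_l) * z[j]
            haps[h] = (z < thr).astype(float)
        block = haps.sum(axis=0)
        dosages[i0:i1] = block
    # guard against monomorphic SNPs at small n
    for i in range(m):
        if dosages[i].std() == 0:
            dosages[i, rng.integers(0, n)] = 1.0 if dosages[i, 0] != 1.0 else 0.0
    ids = [f"rs{i}" for i in range(m)]
    return ids, dosages


def simulate_gwas(
    dosages: np.ndarray,
    snp_ids: Sequence[str],
    causal_snp_ids: Sequence[str] = (),
    effect_size: float = 0.0,
    cfg: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[SnpRecord]:
    """Marginal per-SNP association of a simulated continuous phenotype.

    The phenotype is the sum of standardized causal dosages times
    ``effect_size`` plus unit normal noise; each SNP is tested by simple
    linear regression (two-sided t test on the correlation).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    snp_ids = list(snp_ids)
    unknown = set(causal_snp_ids) - set(snp_ids)
    if unknown:
        raise ValueError(f"causal SNPs absent from genotypes: {sorted(unknown)[:5]}")
    m, n = dosages.shape
    X = np.asarray(dosages, dtype=float)
    Xs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    y = rng.standard_normal(n)
    idx = {s: i for i, s in enumerate(snp_ids)}
    for s in causal_snp_ids:
        y = y + effect_size * Xs[idx[s]]
    yc = (y - y.mean()) / y.std()
    r = Xs @ yc / n
    r = np.clip(r, -0.999999, 0.999999)
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p = np.clip(p, 1e-300, 1.0)
    table = snp_table(cfg) if cfg is not None else None
    records = []
    for i, s in enumerate(snp_ids):
        chrom, pos = (
            (table.chrom.iloc[i], int(table.pos.iloc[i])) if table is not None
            else ("1", i * SNP_SPACING_BP + 1_000)
        )
        records.append(
            SnpRecord(snp_id=s, chrom=str(chrom), pos=pos, allele1="A",
                      allele2="G", p=float(p[i]), n=n)
        )
    return records


def simulate_gene_loci(cfg: SimulationConfig) -> list[GeneLocus]:
    """Place genes alongside the SNP blocks, cycling through chromosomes so
    each gene sits near (and may overlap) genotyped SNPs."""
    n_blocks = math.ceil(cfg.n_snps / cfg.ld_block_size)
    n_chroms = math.ceil(n_blocks / BLOCKS_PER_CHROM)
    chrom_span = BLOCKS_PER_CHROM * cfg.ld_block_size * SNP_SPACING_BP
    genes = []
    per_chrom = math.ceil(cfg.n_genes / n_chroms)
    for i in range(cfg.n_genes):
        chrom = str(i // per_chrom + 1)
        slot = i % per_chrom
        start = 1_000 + (slot * GENE_SPACING_BP) % max(chrom_span, GENE_SPACING_BP)
        genes.append(
            GeneLocus(
                gene_id=f"gene{i}",
                chrom=chrom,
                start=start,
                end=start + GENE_LENGTH_BP - 1,
                strand="+" if i % 2 == 0 else "-",
            )
        )
    return genes


def simulate_expression(
    cfg: SimulationConfig,
    dosages: np.ndarray | None = None,
    snp_ids: Sequence[str] | None = None,
    tissue: str = "TissueA",
    rng: np.random.Generator | None = None,
    eqtl_effect: float = 0.5,
    loading_spread: float = 0.15,
) -> tuple[ExpressionMatrix, np.ndarray, list[EqtlPair]]:
    """Expression with planted modules, true labels, and an eQTL pair table.

    Module genes follow a one-factor model: gene g in a module loads on the
    module factor with loading drawn uniformly in
    sqrt(module_cor) +/- ``loading_spread``, so the expected within-module
    gene-gene correlation equals ``module_cor`` while genes differ in how
    central they are to the module (hub structure, as in real co-expression
    networks).  The remaining genes are independent noise.  For
    ``eqtl_fraction`` of genes a genotyped SNP contributes ``eqtl_effect``
    (in SD units) to the gene's expression, and the pair enters the eQTL
    table with a q-value drawn uniformly below 0.05.  When genotypes are
    supplied, the expression cohort is their sample set.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n = dosages.shape[1] if dosages is not None else cfg.n_samples
    G = cfg.n_genes
    labels = np.zeros(G, dtype=int)
    X = rng.standard_normal((G, n))
    for mdx in range(cfg.n_modules):
        lo = mdx * cfg.module_size
        hi = min(lo + cfg.module_size, G)
        if lo >= G:
            log.warning("simulate_expression: n_genes too small for %d modules", cfg.n_modules)
            break
        factor = rng.standard_normal(n)
        center = math.sqrt(cfg.module_cor)
        spread = min(loading_spread, center, 1.0 - center)
        load = rng.uniform(center - spread, center + spread, hi - lo)
        X[lo:hi] = load[:, None] * factor + np.sqrt(1.0 - load**2)[:, None] * X[lo:hi]
        labels[lo:hi] = mdx + 1

    pairs: list[EqtlPair] = []
    if cfg.eqtl_fraction > 0 and dosages is not None:
        snp_ids = list(snp_ids) if snp_ids is not None else [f"rs{i}" for i in range(dosages.shape[0])]
        Xs = np.asarray(dosages, dtype=float)
        Xs = (Xs - Xs.mean(axis=1, keepdims=True)) / Xs.std(axis=1, keepdims=True)
        n_eqtl = int(round(cfg.eqtl_fraction * G))
        which = rng.choice(G, size=n_eqtl, replace=False)
        gamma = eqtl_effect
        resid_var = 1.0 - gamma * gamma
        if resid_var <= 0:
            raise ValueError("eqtl_effect too large")
        for g in np.sort(which):
            s = int(rng.integers(0, len(snp_ids)))
            X[g] = math.sqrt(resid_var) * X[g] + gamma * Xs[s]
            q = rng.uniform(0.0, 0.05)
            pairs.append(
                EqtlPair(
                    gene_id=f"gene{g}",
                    snp_id=snp_ids[s],
                    tissue=tissue,
                    p_eqtl=q * 0.5,
                    qvalue=q,
                )
            )
    expr = ExpressionMatrix(
        pd.DataFrame(
            X,
            index=[f"gene{i}" for i in range(G)],
            columns=[f"S{j}" for j in range(n)],
        ),
        tissue=tissue,
    )
    return expr, labels, pairs


@dataclass
class StudyData:
    """A complete synthetic study: reference panel, GWAS, expression, eQTLs."""

    config: SimulationConfig
    panel: LdPanel
    gwas: list[SnpRecord]
    expression: ExpressionMatrix
    module_labels: np.ndarray
    eqtl_pairs: list[EqtlPair]
    gene_loci: list[GeneLocus]
    causal_snp_ids: list[str]
    target_module: int | None = None


def simulate_study(
    cfg: SimulationConfig,
    n_gwas_samples: int = 4_000,
    n_panel_samples: int = 500,
    target_module: int | None = None,
    tissue: str = "TissueA",
) -> StudyData:
    """Generate a full synthetic study.

    With ``target_module`` set, the GWAS causal SNPs are the eQTL SNPs of
    that module's genes (an enrichment positive control); otherwise
    ``n_causal_snps`` SNPs are drawn at random with effect ``effect_size``
    (0 causal SNPs when effect_size is 0).
    """
    rng = np.random.default_rng(cfg.seed)
    snp_ids, panel_dos = simulate_genotypes(cfg, n_samples=n_panel_samples, rng=rng)
    _, expr_dos = simulate_genotypes(cfg, n_samples=cfg.n_samples, rng=rng)
    _, gwas_dos = simulate_genotypes(cfg, n_samples=n_gwas_samples, rng=rng)

    expr, labels, pairs = simulate_expression(
        cfg, dosages=expr_dos, snp_ids=snp_ids, tissue=tissue, rng=rng
    )

    if target_module is not None:
        member_genes = {f"gene{i}" for i in np.nonzero(labels == target_module)[0]}
        causal = sorted({p.snp_id for p in pairs if p.gene_id in member_genes})
        if not causal:
            raise ValueError("target module has no eQTL SNPs to plant effects on")
    elif cfg.effect_size > 0 and cfg.n_causal_snps > 0:
        causal = [snp_ids[i] for i in rng.choice(cfg.n_snps, cfg.n_causal_snps, replace=False)]
    else:
        causal = []

    gwas = simulate_gwas(
        gwas_dos, snp_ids, causal_snp_ids=causal,
        effect_size=cfg.effect_size, cfg=cfg, rng=rng,
    )
    return StudyData(
        config=cfg,
        panel=LdPanel(snp_ids, panel_dos),
        gwas=gwas,
        expression=expr,
        module_labels=labels,
        eqtl_pairs=pairs,
        gene_loci=simulate_gene_loci(cfg),
        causal_snp_ids=list(causal),
        target_module=target_module,
    )
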