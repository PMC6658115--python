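"""Readers/writers for the study's external formats and expression preprocessing.

All genomic coordinates are handled 1-based inclusive internally.  BED input
(0-based, half-open) is converted at the reader boundary.  GWAS summary
statistics, gene loci, eQTL pair tables, expression matrices, dosage matrices
and GMT gene sets are all plain delimited text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "SnpRecord",
    "GeneLocus",
    "EqtlPair",
    "ExpressionMatrix",
    "read_gwas_summary",
    "write_gwas_summary",
    "read_gene_loci",
    "write_gene_loci",
    "read_eqtl_pairs",
    "write_eqtl_pairs",
    "read_expression",
    "write_expression",
    "read_dosage_matrix",
    "write_dosage_matrix",
    "read_vcf_dosages",
    "read_gene_sets",
    "write_gene_sets",
    "filter_expressed_genes",
    "normalize_expression",
    "quantile_normalize",
    "exclude_mhc",
    "MHC_REGION",
]

#: Default MHC exclusion window, GRCh37 convention (chr6:26-34 Mb).
MHC_REGION: tuple[str, int, int] = ("6", 26_000_000, 34_000_000)


@dataclass(frozen=True)
class SnpRecord:
    """A GWAS summary-statistics row: one SNP with its association p-value."""

    snp_id: str
    chrom: str
    pos: int
    allele1: str = "N"
    allele2: str = "N"
    p: float = 1.0
    n: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"SNP {self.snp_id}: p={self.p} outside (0, 1]")
        if self.pos < 1:
            raise ValueError(f"SNP {self.snp_id}: pos={self.pos} < 1")


@dataclass(frozen=True)
class GeneLocus:
    """A gene body on a chromosome, 1-based inclusive, with strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class EqtlPair:
    """A significant tissue-specific SNP-gene expression association."""

    gene_id: str
    snp_id: str
    tissue: str
    p_eqtl: float
    qvalue: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.qvalue <= 1.0):
            raise ValueError(
                f"eQTL pair ({self.snp_id}, {self.gene_id}): qvalue outside [0, 1]"
            )


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values for one tissue.

    ``data`` is a pandas DataFrame with gene ids as the index and sample ids
    as columns.
    """

    data: pd.DataFrame
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated gene ids: {dups[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# GWAS summary statistics

_GWAS_DEFAULT_COLUMNS = {
    "snp": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "a1": "A1",
    "a2": "A2",
    "p": "P",
    "n": "N",
}


def read_gwas_summary(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[SnpRecord]:
    """Read whitespace/tab-delimited GWAS summary statistics.

    ``column_map`` maps the logical names snp/chrom/pos/a1/a2/p/n onto the
    file's header names; unspecified entries fall back to the defaults
    SNP/CHR/BP/A1/A2/P/N.  Rows whose p-value does not parse or lies outside
    (0, 1] are dropped and counted in the log rather than clamped.
    """
    cols = dict(_GWAS_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if df.empty:
        raise ValueError(f"empty GWAS summary file: {path}")
    for logical in ("snp", "chrom", "pos", "p"):
        if cols[logical] not in df.columns:
            raise ValueError(
                f"GWAS summary file {path} is missing mandatory column "
                f"{cols[logical]!r} (for {logical})"
            )

    p = pd.to_numeric(df[cols["p"]], errors="coerce")
    pos = pd.to_numeric(df[cols["pos"]], errors="coerce")
    ok = p.notna() & (p > 0) & (p <= 1) & pos.notna() & (pos >= 1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.warning("read_gwas_summary: dropped %d rows with invalid p or position", n_dropped)
    df = df[ok]

    has_alleles = cols["a1"] in df.columns and cols["a2"] in df.columns
    has_n = cols["n"] in df.columns
    records = []
    seen: set[str] = set()
    for row, pval, bp in zip(df.itertuples(index=False), p[ok], pos[ok]):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        snp_id = d[cols["snp"]]
        if snp_id in seen:
            log.warning("read_gwas_summary: duplicate SNP id %s, keeping first", snp_id)
            continue
        seen.add(snp_id)
        records.append(
            SnpRecord(
                snp_id=snp_id,
                chrom=str(d[cols["chrom"]]),
                pos=int(bp),
                allele1=d[cols["a1"]] if has_alleles else "N",
                allele2=d[cols["a2"]] if has_alleles else "N",
                p=float(pval),
                n=int(float(d[cols["n"]])) if has_n and pd.notna(d[cols["n"]]) else None,
            )
        )
    return records


def write_gwas_summary(records: Iterable[SnpRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "SNP": [r.snp_id for r in records],
            "CHR": [r.chrom for r in records],
            "BP": [r.pos for r in records],
            "A1": [r.allele1 for r in records],
            "A2": [r.allele2 for r in records],
            "P": [r.p for r in records],
            "N": [r.n if r.n is not None else "NA" for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene loci


def read_gene_loci(path: str | Path, fmt: str = "tsv") -> list[GeneLocus]:
    """Read gene loci from a 1-based TSV (gene_id chrom start end strand) or
    from BED (0-based half-open; converted here)."""
    if fmt not in ("tsv", "bed"):
        raise ValueError(f"unknown gene locus format {fmt!r}")
    if fmt == "bed":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str},
        )
        return [
            GeneLocus(
                gene_id=str(r.name_),
                chrom=str(r.chrom),
                start=int(r.start) + 1,
                end=int(r.end),
                strand=str(r.strand),
            )
            for r in df.rename(columns={"name": "name_"}).itertuples(index=False)
        ]
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene locus TSV {path} missing columns: {sorted(missing)}")
    return [
        GeneLocus(
            gene_id=str(r.gene_id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
        )
        for r in df.itertuples(index=False)
    ]


def write_gene_loci(genes: Iterable[GeneLocus], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# eQTL pairs


def read_eqtl_pairs(path: str | Path) -> list[EqtlPair]:
    """Read significant SNP-gene pairs: TSV with header
    gene_id, variant_id, tissue, pval, qval."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "variant_id": str, "tissue": str})
    required = {"gene_id", "variant_id", "tissue", "pval", "qval"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"eQTL pair file {path} missing columns: {sorted(missing)}")
    return [
        EqtlPair(
            gene_id=str(r.gene_id),
            snp_id=str(r.variant_id),
            tissue=str(r.tissue),
            p_eqtl=float(r.pval),
            qvalue=float(r.qval),
        )
        for r in df.itertuples(index=False)
    ]


def write_eqtl_pairs(pairs: Iterable[EqtlPair], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [p.gene_id for p in pairs],
            "variant_id": [p.snp_id for p in pairs],
            "tissue": [p.tissue for p in pairs],
            "pval": [p.p_eqtl for p in pairs],
            "qval": [p.qvalue for p in pairs],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression


def read_expression(path: str | Path, tissue: str = "") -> ExpressionMatrix:
    """Read a genes x samples TSV; first column gene_id, remaining columns samples."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    df.index.name = "gene_id"
    return ExpressionMatrix(df.astype(float), tissue=tissue)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Dosages


def read_dosage_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a SNPs x samples dosage TSV (first column snp_id).  Returns the
    SNP ids and the dosage matrix."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    return list(df.index.astype(str)), df.to_numpy(dtype=float)


def write_dosage_matrix(
    snp_ids: Sequence[str], dosages: np.ndarray, path: str | Path
) -> None:
    pd.DataFrame(
        dosages, index=pd.Index(snp_ids, name="snp_id"),
        columns=[f"S{i}" for i in range(dosages.shape[1])],
    ).to_csv(path, sep="\t")


def read_vcf_dosages(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read alternate-allele dosages from a VCF (requires cyvcf2)."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("reading VCF dosages requires the cyvcf2 package") from exc
    ids, rows = [], []
    for var in VCF(str(path)):
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        gt = np.asarray(var.gt_types, dtype=float)  # 0/1/2/3 (3 = unknown)
        gt[gt == 3] = np.nan
        gt[gt == 2] = np.nan  # cyvcf2 encodes UNKNOWN=2 when gts012=False
        rows.append(gt)
    dosages = np.vstack(rows)
    return ids, dosages


# ---------------------------------------------------------------------------
# Gene sets (GMT)


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Read GMT: one set per line, name <tab> description <tab> gene ids."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gene_sets(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# Expression preprocessing


def filter_expressed_genes(
    expr: ExpressionMatrix,
    raw_counts: pd.DataFrame,
    min_donors: int = 10,
    min_rpkm: float = 0.1,
    min_reads: int = 6,
) -> ExpressionMatrix:
    """Keep genes expressed above both thresholds in at least ``min_donors``
    samples: expression (RPKM) > ``min_rpkm`` and read count >= ``min_reads``.
    Gene order is preserved."""
    if expr.data.shape != raw_counts.shape or not expr.data.index.equals(raw_counts.index):
        raise ValueError("expression and raw-count matrices must share genes and samples")
    qualifying = (expr.data.to_numpy() > min_rpkm) & (
        raw_counts.to_numpy() >= min_reads
    )
    keep = qualifying.sum(axis=1) >= min_donors
    if not keep.any():
        log.warning("filter_expressed_genes: no gene passed the expression filter")
    return ExpressionMatrix(expr.data.loc[keep], tissue=expr.tissue)


def quantile_normalize(X: np.ndarray) -> np.ndarray:
    """Between-sample quantile normalization of a genes x samples matrix.

    Each sample's values are replaced by the mean order statistics across
    samples; ties receive the mean of the relevant order statistics.  Samples
    that are permutations of the same values map onto identical multisets.
    """
    X = np.asarray(X, dtype=float)
    ref = np.sort(X, axis=0).mean(axis=1)  # mean order statistics
    Xq = np.empty_like(X)
    for j in range(X.shape[1]):
        ranks = stats.rankdata(X[:, j], method="average") - 1  # 0-based, may be halves
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        Xq[:, j] = 0.5 * (ref[lo] + ref[hi])
    return Xq


def normalize_expression(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Two-step normalization used before network construction.

    Step 1: between-sample quantile normalization (``quantile_normalize``).
    Step 2: per-gene inverse-normal transform — each gene's values are
    replaced by Phi^-1((rank - 0.5) / n) with average ranks for ties.
    Genes constant after step 1 have undefined ranks and are dropped with a
    warning.
    """
    X = expr.data.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        raise ValueError("normalization requires at least 2 samples")

    Xq = quantile_normalize(X)
    keep = np.ptp(Xq, axis=1) > 0
    n_const = int((~keep).sum())
    if n_const:
        log.warning("normalize_expression: dropped %d constant genes", n_const)
    Xq = Xq[keep]

    # step 2: per-gene rank-based inverse normal transform
    ranks = np.apply_along_axis(stats.rankdata, 1, Xq)
    Z = stats.norm.ppf((ranks - 0.5) / n_samples)
    out = pd.DataFrame(Z, index=expr.data.index[keep], columns=expr.data.columns)
    return ExpressionMatrix(out, tissue=expr.tissue)


def exclude_mhc(
    genes: Sequence[GeneLocus],
    region: tuple[str, int, int] = MHC_REGION,
) -> list[GeneLocus]:
    """Drop genes overlapping the MHC window (any overlap counts).

    Chromosome labels are compared after stripping a leading "chr".
    """
    chrom, lo, hi = region
    chrom = chrom.removeprefix("chr")
    return [
        g
        for g in genes
        if not (g.chrom.removeprefix("chr") == chrom and g.start <= hi and g.end >= lo)
    ]
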