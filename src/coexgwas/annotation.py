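"""SNP-to-gene assignment.

Two annotation schemes feed the same downstream gene test:

* proximity — a SNP is assigned to every gene whose body, extended by an
  upstream/downstream window (default 35 kb up, 10 kb down, strand-aware),
  contains the SNP position;
* eQTL — a SNP is assigned to every gene whose expression it is significantly
  associated with in the interrogated tissue (FDR q-value strictly below the
  threshold), regardless of distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import EqtlPair, GeneLocus, SnpRecord

log = logging.getLogger(__name__)

__all__ = [
    "GeneAssignment",
    "assign_proximity",
    "assign_eqtl",
    "annotation_summary",
]

PROXIMITY_TISSUE = "proximity"


@dataclass(frozen=True)
class GeneAssignment:
    """A (SNP, gene, tissue) link produced by an annotation scheme."""

    snp_id: str
    gene_id: str
    tissue: str
    source: str  # "proximity" or "eqtl"


def assign_proximity(
    snps: Sequence[SnpRecord],
    genes: Sequence[GeneLocus],
    upstream_kb: float = 35.0,
    downstream_kb: float = 10.0,
    strand_aware: bool = True,
) -> list[GeneAssignment]:
    """Assign each SNP to every gene whose extended body covers it.

    For a +-strand gene the window is [start - up, end + down]; for a --strand
    gene [start - down, end + up].  With ``strand_aware=False`` the upstream
    extension is applied on the lower-coordinate side for every gene.
    A SNP may land in several overlapping windows and is assigned to each.
    """
    up = int(round(upstream_kb * 1000))
    down = int(round(downstream_kb * 1000))

    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append((s.pos, s.snp_id))
    pos_arrays = {
        c: (np.array([p for p, _ in v]), [i for _, i in v]) for c, v in by_chrom.items()
    }
    for c in pos_arrays:
        order = np.argsort(pos_arrays[c][0], kind="stable")
        pos_arrays[c] = (
            pos_arrays[c][0][order],
            [pos_arrays[c][1][k] for k in order],
        )

    out: list[GeneAssignment] = []
    for g in genes:
        if g.strand not in ("+", "-"):  # GeneLocus already validates; guard anyway
            raise ValueError(f"gene {g.gene_id}: unknown strand {g.strand!r}")
        if not strand_aware or g.strand == "+":
            lo, hi = g.start - up, g.end + down
        else:
            lo, hi = g.start - down, g.end + up
        if g.chrom not in pos_arrays:
            continue
        pos, ids = pos_arrays[g.chrom]
        i0 = int(np.searchsorted(pos, lo, side="left"))
        i1 = int(np.searchsorted(pos, hi, side="right"))
        for k in range(i0, i1):
            out.append(
                GeneAssignment(
                    snp_id=ids[k],
                    gene_id=g.gene_id,
                    tissue=PROXIMITY_TISSUE,
                    source="proximity",
                )
            )
    return out


def assign_eqtl(
    pairs: Sequence[EqtlPair],
    fdr_threshold: float = 0.05,
    tissue: str | None = None,
) -> list[GeneAssignment]:
    """Assign SNPs to their eGenes: pairs with qvalue strictly below
    ``fdr_threshold`` in the requested tissue (all tissues when None)."""
    out = []
    seen: set[tuple[str, str, str]] = set()
    for p in pairs:
        if tissue is not None and p.tissue != tissue:
            continue
        if not p.qvalue < fdr_threshold:
            continue
        key = (p.snp_id, p.gene_id, p.tissue)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            GeneAssignment(snp_id=p.snp_id, gene_id=p.gene_id, tissue=p.tissue, source="eqtl")
        )
    if not out:
        log.warning("assign_eqtl: no pair passed FDR < %g", fdr_threshold)
    return out


def annotation_summary(assignments: Sequence[GeneAssignment]) -> pd.DataFrame:
    """Per-(gene, tissue) SNP counts.  The number of distinct genes per tissue
    (used for per-tissue Bonferroni thresholds) is the number of rows per
    tissue.  Duplicate (snp, gene, tissue) rows are deduplicated first."""
    if not assignments:
        return pd.DataFrame(columns=["gene_id", "tissue", "n_snps"])
    df = pd.DataFrame(
        {
            "snp_id": [a.snp_id for a in assignments],
            "gene_id": [a.gene_id for a in assignments],
            "tissue": [a.tissue for a in assignments],
        }
    ).drop_duplicates()
    out = (
        df.groupby(["gene_id", "tissue"], sort=True)
        .size()
        .rename("n_snps")
        .reset_index()
    )
    return out
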