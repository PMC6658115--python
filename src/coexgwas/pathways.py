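"""Over-representation analysis of module genes against curated gene sets.

One-tailed Fisher / hypergeometric test per set: given a universe of N
genes, a set of K of them, and a module of n genes drawn from the universe,
the p-value is P(X >= observed overlap) for X hypergeometric(N, K, n).
Multiple-testing adjustment is Bonferroni or Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["OraResult", "ora"]


@dataclass
class OraResult:
    set_id: str
    overlap: int
    set_size: int
    module_size: int
    universe_size: int
    p: float
    p_adj: float | None = None


def ora(
    module_genes: Iterable[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Iterable[str],
    adjust: str = "bh",
) -> list[OraResult]:
    """Hypergeometric over-representation of module genes in each gene set.

    Sets are intersected with the universe before testing; ``adjust`` is
    "bonferroni", "bh", or "none".
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    module = set(module_genes)
    if not module <= uni:
        raise ValueError("module genes must be a subset of the universe")
    N, n = len(uni), len(module)
    results = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & uni
        K = len(members)
        k = len(members & module)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        results.append(
            OraResult(
                set_id=name,
                overlap=k,
                set_size=K,
                module_size=n,
                universe_size=N,
                p=min(p, 1.0),
            )
        )
    if adjust != "none" and results:
        method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[adjust]
        padj = multipletests([r.p for r in results], method=method)[1]
        for r, q in zip(results, padj):
            r.p_adj = float(q)
    return results
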