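"""Cross-tissue module preservation (Zsummary / medianRank).

Given a module found in a reference tissue, preservation asks whether its
genes remain densely interconnected (density statistics, computed in the
test tissue) and whether its internal connectivity pattern is reproduced
(connectivity statistics, comparing reference vs test).  Each observed
statistic is standardized against a permutation null built from random gene
sets of the same size drawn from the test network, giving a Z per statistic;
Zsummary is the mean of the density and connectivity composites (medians
within each class).  Categories follow the conventional thresholds:
Zsummary < 2 none, 2-10 weak-to-moderate, > 10 strong.  medianRank ranks
modules by observed preservation (lower = better preserved).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .coexpression import ModulePartition, adjacency, module_eigengene
from .data_io import ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = ["PreservationReport", "preservation_stats", "preservation_z"]

DENSITY_STATS = ("mean_adj", "prop_var_explained")
CONNECTIVITY_STATS = ("cor_kim", "cor_cor")


@dataclass
class PreservationReport:
    module_id: int
    z_density: float
    z_connectivity: float
    z_summary: float
    median_rank: float
    category: str

    @staticmethod
    def categorize(z_summary: float) -> str:
        if z_summary < 2:
            return "none"
        if z_summary <= 10:
            return "weak-moderate"
        return "strong"


def _module_stats(
    ref_X: np.ndarray, test_X: np.ndarray, power: int
) -> dict[str, float]:
    """Raw preservation statistics for one gene set (genes x samples blocks
    aligned on the same genes in reference and test)."""
    # density, computed in the test data
    r_test = np.corrcoef(test_X)
    a_test = np.abs(r_test) ** power
    m = a_test.shape[0]
    iu = np.triu_indices(m, k=1)
    mean_adj = float(a_test[iu].mean())

    sd = test_X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Xs = (test_X - test_X.mean(axis=1, keepdims=True)) / sd
    svals = np.linalg.svd(Xs, compute_uv=False)
    prop_var = float(svals[0] ** 2 / np.sum(svals**2))

    # connectivity, comparing reference vs test
    r_ref = np.corrcoef(ref_X)
    a_ref = np.abs(r_ref) ** power
    k_ref = a_ref.sum(axis=1) - 1.0
    k_test = a_test.sum(axis=1) - 1.0
    cor_kim = _pearson(k_ref, k_test)
    cor_cor = _pearson(r_ref[iu], r_test[iu])
    return {
        "mean_adj": mean_adj,
        "prop_var_explained": prop_var,
        "cor_kim": cor_kim,
        "cor_cor": cor_cor,
    }


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def preservation_stats(
    ref_expr: ExpressionMatrix,
    test_expr: ExpressionMatrix,
    ref_partition: ModulePartition,
    module_id: int,
    power: int = 6,
) -> dict[str, float]:
    """Observed density and connectivity statistics for one reference module,
    computed on the genes shared by both expression matrices."""
    members = ref_partition.members(module_id)
    shared = [g for g in members if g in test_expr.data.index]
    if len(shared) < len(members):
        log.info(
            "module %s: %d/%d genes present in test tissue",
            module_id, len(shared), len(members),
        )
    if len(shared) < 3:
        raise ValueError(f"module {module_id}: fewer than 3 genes shared with test data")
    ref_X = ref_expr.data.loc[shared].to_numpy(dtype=float)
    test_X = test_expr.data.loc[shared].to_numpy(dtype=float)
    return _module_stats(ref_X, test_X, power)


def preservation_z(
    ref_expr: ExpressionMatrix,
    test_expr: ExpressionMatrix,
    ref_partition: ModulePartition,
    n_perm: int = 100,
    seed: int = 0,
    power: int = 6,
) -> list[PreservationReport]:
    """Permutation-standardized preservation per reference module.

    Nulls are built per module size by recomputing every statistic on random
    gene sets of that size drawn from the genes available in the test tissue.
    Density statistics are competitive — their null sets are drawn from all
    genes ("is the module denser than a random gene set of this network?").
    Connectivity statistics test reference/test pattern correspondence, so
    their null sets exclude the evaluated module's members: otherwise sampled
    module genes leak reproducible connectivity into the null and deflate
    the Z.
    """
    rng = np.random.default_rng(seed)
    shared_genes = [g for g in ref_expr.gene_ids if g in test_expr.data.index]
    reports: list[PreservationReport] = []
    all_stats = DENSITY_STATS + CONNECTIVITY_STATS

    observed: dict[int, dict[str, float]] = {}
    zscores: dict[int, dict[str, float]] = {}
    for m in ref_partition.module_ids:
        obs = preservation_stats(ref_expr, test_expr, ref_partition, m, power=power)
        members = set(ref_partition.members(m))
        size = len([g for g in members if g in test_expr.data.index])
        outside = [g for g in shared_genes if g not in members]
        if len(outside) < size:
            log.warning(
                "module %s: null pool smaller than module, sampling all genes", m
            )
            outside = shared_genes
        null = {s: np.empty(n_perm) for s in all_stats}
        for b in range(n_perm):
            for pool, stat_names in ((shared_genes, DENSITY_STATS),
                                     (outside, CONNECTIVITY_STATS)):
                pick = rng.choice(len(pool), size=size, replace=False)
                genes = [pool[i] for i in pick]
                ref_X = ref_expr.data.loc[genes].to_numpy(dtype=float)
                test_X = test_expr.data.loc[genes].to_numpy(dtype=float)
                st = _module_stats(ref_X, test_X, power)
                for s in stat_names:
                    null[s][b] = st[s]
        zs = {}
        for s in all_stats:
            mu = float(null[s].mean())
            sd = float(null[s].std(ddof=1))
            if sd == 0:
                if obs[s] > mu:
                    log.warning("module %s stat %s: null sd 0, Z set to +inf", m, s)
                    zs[s] = math.inf
                else:
                    zs[s] = 0.0
            else:
                zs[s] = (obs[s] - mu) / sd
        observed[m] = obs
        zscores[m] = zs

    # ranks of observed statistics across modules (1 = most preserved)
    mods = list(observed)
    ranks: dict[int, list[float]] = {m: [] for m in mods}
    for s in all_stats:
        vals = np.array([observed[m][s] for m in mods])
        order = (-vals).argsort(kind="stable")
        r = np.empty(len(mods))
        r[order] = np.arange(1, len(mods) + 1)
        for i, m in enumerate(mods):
            ranks[m].append(float(r[i]))

    for m in mods:
        zd = float(np.median([zscores[m][s] for s in DENSITY_STATS]))
        zc = float(np.median([zscores[m][s] for s in CONNECTIVITY_STATS]))
        zsum = (zd + zc) / 2.0
        reports.append(
            PreservationReport(
                module_id=m,
                z_density=zd,
                z_connectivity=zc,
                z_summary=zsum,
                median_rank=float(np.median(ranks[m])),
                category=PreservationReport.categorize(zsum),
            )
        )
    return reports
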