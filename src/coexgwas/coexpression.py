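"""Weighted gene co-expression network construction.

Pipeline: pick a soft-threshold power by the scale-free topology criterion,
raise absolute Pearson correlations to that power (unsigned adjacency),
normalize by topological overlap, cluster genes by average linkage on
1 - TOM, cut the tree into modules, summarize modules by eigengenes, and
merge modules with highly correlated eigengenes.  A permutation stability
check destroys inter-gene correlation while preserving marginals and reruns
the whole detection.

Module detection is a fixed-height branch cut on the 1 - TOM dendrogram with
two acceptance rules: a minimum module size, and a background-calibrated
cohesion guard — a branch only becomes a module if its genes overlap each
other topologically well above the network's background overlap level.  The
guard is what keeps permuted (structure-free) data from yielding spurious
modules: on such data every candidate branch has intra-branch TOM at the
background level and is rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data_io import ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "SoftThresholdScan",
    "ModulePartition",
    "pick_soft_threshold",
    "adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "merge_modules",
    "build_network",
    "stability_check",
]

UNASSIGNED = 0


@dataclass
class SoftThresholdScan:
    """Scale-free fit and mean connectivity per candidate power."""

    powers: list[int]
    fit_r2: list[float]
    mean_connectivity: list[float]
    chosen_power: int
    reached_target: bool


@dataclass
class ModulePartition:
    """Gene -> module labels (0 = unassigned) with module eigengenes."""

    gene_ids: list[str]
    labels: np.ndarray
    eigengenes: pd.DataFrame | None = None  # modules x samples
    tissue: str = ""

    def members(self, module_id: int) -> list[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == module_id]

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels.tolist()) - {UNASSIGNED})

    def sizes(self) -> dict[int, int]:
        return {m: int((self.labels == m).sum()) for m in self.module_ids}


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log10(frequency) ~ log10(connectivity) regression.

    Positive when the connectivity distribution decays (negative slope), the
    signature of approximate scale-free topology.
    """
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        raise ValueError("fewer than 2 distinct connectivity bins")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins).astype(float)
    means = np.bincount(which, weights=k, minlength=n_bins)
    ok = counts > 0
    x = np.log10(means[ok] / counts[ok])
    y = np.log10(counts[ok] / counts.sum())
    if x.size < 3 or np.ptp(x) == 0:
        return 0.0
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ssr = np.sum((y - yhat) ** 2)
    sst = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    return float(-np.sign(slope) * r2)


def pick_soft_threshold(
    expr: ExpressionMatrix,
    powers: range | list[int] | None = None,
    target_r2: float = 0.8,
    n_bins: int = 10,
    min_mean_connectivity: float = 1.0,
) -> SoftThresholdScan:
    """Scan candidate powers and choose the smallest reaching the scale-free
    fit target; if none does, fall back to the best-fitting power with a
    warning.

    Powers whose mean connectivity falls below ``min_mean_connectivity`` are
    ineligible: raising the power always thins the network until the log-log
    frequency fit looks good for the trivial reason that almost no edges
    remain, so the scan is restricted to powers that keep the network
    non-degenerate.
    """
    if powers is None:
        powers = range(2, 21)
    powers = list(powers)
    if min(powers) < 2 or max(powers) > 20:
        log.info("pick_soft_threshold: non-default power range %s", powers)
    if expr.n_genes < 20:
        raise ValueError("soft-threshold scan needs at least 20 genes")
    absr = np.abs(np.corrcoef(expr.values))
    np.fill_diagonal(absr, 0.0)
    fits, conns = [], []
    for b in powers:
        a = absr**b
        k = a.sum(axis=1)
        fits.append(_scale_free_fit(k, n_bins=n_bins))
        conns.append(float(k.mean()))
    fits_arr = np.array(fits)
    conns_arr = np.array(conns)
    eligible = conns_arr >= min_mean_connectivity
    if not eligible.any():
        eligible[:] = True
        log.warning("pick_soft_threshold: all powers below connectivity floor")
    masked = np.where(eligible, fits_arr, -np.inf)
    reached = bool((masked >= target_r2).any())
    if reached:
        chosen = powers[int(np.argmax(masked >= target_r2))]
    else:
        chosen = powers[int(np.argmax(masked))]
        log.warning(
            "pick_soft_threshold: no eligible power reached fit %.2f "
            "(best %.2f at power %d)",
            target_r2, masked.max(), chosen,
        )
    return SoftThresholdScan(powers, fits, conns, chosen, reached)


def adjacency(expr: ExpressionMatrix, power: int) -> np.ndarray:
    """Unsigned adjacency a_ij = |cor(x_i, x_j)|^power with unit diagonal."""
    X = expr.values
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = [expr.gene_ids[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant gene(s): {bad[:5]}")
    a = np.abs(np.corrcoef(X)) ** power
    np.fill_diagonal(a, 1.0)
    return a


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu."""
    a = np.asarray(adj, dtype=float)
    n = a.shape[0]
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    l = a0 @ a0  # includes no i/j terms since diagonal zeroed
    k = a0.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    tom = (l + a0) / (kmin + 1.0 - a0)
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    tom: np.ndarray,
    gene_ids: list[str] | None = None,
    min_module_size: int = 30,
    cut_height: float = 0.99,
    cohesion_ratio: float = 3.0,
    background_quantile: float = 0.1,
    expr: ExpressionMatrix | None = None,
    tissue: str = "",
) -> ModulePartition:
    """Cut the average-linkage dendrogram of 1 - TOM into modules.

    Branches below ``cut_height`` with at least ``min_module_size`` genes
    become candidate modules; a candidate is accepted only if its median
    intra-branch TOM is at least ``cohesion_ratio`` times the network's
    background overlap (the ``background_quantile`` quantile of all
    off-diagonal TOM entries).  Labels are 1..K by decreasing module size;
    0 marks unassigned genes.  When ``expr`` is supplied, eigengenes are
    attached.
    """
    tom = np.asarray(tom, dtype=float)
    n = tom.shape[0]
    if gene_ids is None:
        gene_ids = expr.gene_ids if expr is not None else [f"g{i}" for i in range(n)]
    labels = np.zeros(n, dtype=int)
    if n < min_module_size:
        log.warning("detect_modules: fewer genes (%d) than min module size", n)
        return ModulePartition(gene_ids, labels, tissue=tissue)

    dism = 1.0 - tom
    dism = (dism + dism.T) / 2.0
    np.fill_diagonal(dism, 0.0)
    Z = hierarchy.linkage(squareform(dism, checks=False), method="average")
    raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")

    iu = np.triu_indices(n, k=1)
    background = float(np.quantile(tom[iu], background_quantile))
    floor = max(background, 1e-12) * cohesion_ratio

    accepted = []
    for cl in np.unique(raw):
        idx = np.nonzero(raw == cl)[0]
        if idx.size < min_module_size:
            continue
        sub = tom[np.ix_(idx, idx)]
        med = float(np.median(sub[np.triu_indices(idx.size, k=1)]))
        if med >= floor:
            accepted.append((idx.size, med, idx))
    accepted.sort(key=lambda t: (-t[0], -t[1]))
    for new_label, (_, _, idx) in enumerate(accepted, start=1):
        labels[idx] = new_label

    part = ModulePartition(gene_ids, labels, tissue=tissue)
    if expr is not None:
        attach_eigengenes(part, expr)
    return part


def module_eigengene(expr: ExpressionMatrix, member_gene_ids: list[str]) -> np.ndarray:
    """First principal component (across samples) of the members' expression.

    Member gene profiles are standardized, the leading right singular vector
    is taken, normalized to unit length, and oriented so that its mean
    correlation with the member genes is non-negative.
    """
    if len(member_gene_ids) < 2:
        raise ValueError("eigengene needs at least 2 member genes")
    X = expr.data.loc[member_gene_ids].to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    if not np.any(Xs):
        raise ValueError("rank-0 member submatrix")
    _, _, vt = np.linalg.svd(Xs, full_matrices=False)
    e = vt[0]
    e = e / np.linalg.norm(e)
    cors = _row_cor(Xs, e)
    if np.nanmean(cors) < 0:
        e = -e
    return e


def _row_cor(X: np.ndarray, v: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (vc**2).sum())
    denom[denom == 0] = np.nan
    return (Xc @ vc) / denom


def attach_eigengenes(partition: ModulePartition, expr: ExpressionMatrix) -> None:
    rows = {}
    for m in partition.module_ids:
        rows[m] = module_eigengene(expr, partition.members(m))
    partition.eigengenes = (
        pd.DataFrame.from_dict(rows, orient="index", columns=expr.sample_ids)
        if rows
        else pd.DataFrame(columns=expr.sample_ids)
    )


def merge_modules(
    partition: ModulePartition,
    expr: ExpressionMatrix,
    merge_cor: float = 0.8,
) -> ModulePartition:
    """Iteratively merge the module pair with the highest eigengene
    correlation while it is >= ``merge_cor`` (inclusive), recomputing the
    merged eigengene after each step."""
    labels = partition.labels.copy()
    part = ModulePartition(partition.gene_ids, labels, tissue=partition.tissue)
    attach_eigengenes(part, expr)
    while True:
        mods = part.module_ids
        if len(mods) < 2:
            break
        E = part.eigengenes.loc[mods].to_numpy()
        C = np.corrcoef(E)
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if C[i, j] < merge_cor:
            break
        keep, drop = mods[i], mods[j]
        labels[labels == drop] = keep
        # relabel by decreasing size
        sizes = sorted(
            ((int((labels == m).sum()), m) for m in set(labels) - {UNASSIGNED}),
            key=lambda t: -t[0],
        )
        mapping = {old: new for new, (_, old) in enumerate(sizes, start=1)}
        labels = np.array([mapping.get(l, UNASSIGNED) for l in labels])
        part = ModulePartition(partition.gene_ids, labels, tissue=partition.tissue)
        attach_eigengenes(part, expr)
    return part


def build_network(
    expr: ExpressionMatrix,
    powers: range | list[int] | None = None,
    target_r2: float = 0.8,
    min_module_size: int = 30,
    cut_height: float = 0.99,
    merge_cor: float = 0.8,
    cohesion_ratio: float = 3.0,
) -> tuple[ModulePartition, SoftThresholdScan]:
    """Full construction: soft threshold, adjacency, TOM, tree cut, merge."""
    scan = pick_soft_threshold(expr, powers=powers, target_r2=target_r2)
    adj = adjacency(expr, scan.chosen_power)
    tom = topological_overlap(adj)
    part = detect_modules(
        tom,
        gene_ids=expr.gene_ids,
        min_module_size=min_module_size,
        cut_height=cut_height,
        cohesion_ratio=cohesion_ratio,
        expr=expr,
        tissue=expr.tissue,
    )
    if part.module_ids:
        part = merge_modules(part, expr, merge_cor=merge_cor)
    return part, scan


def stability_check(
    expr: ExpressionMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    **detect_kwargs,
) -> pd.DataFrame:
    """Permutation stability of module detection.

    Each replicate independently permutes every gene's values across samples
    (removing inter-gene correlation, preserving marginals) and reruns the
    full detection pipeline; the module count per replicate is recorded.
    """
    rng = np.random.default_rng(seed)
    X = expr.values
    counts = []
    for _ in range(n_perm):
        Xp = X.copy()
        for i in range(Xp.shape[0]):
            rng.shuffle(Xp[i])
        perm = ExpressionMatrix(
            pd.DataFrame(Xp, index=expr.data.index, columns=expr.data.columns),
            tissue=expr.tissue,
        )
        part, _ = build_network(perm, **detect_kwargs)
        counts.append(len(part.module_ids))
    return pd.DataFrame({"replicate": range(n_perm), "n_modules": counts})
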