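"""Unsigned weighted gene co-expression network construction.

The chain follows the weighted-network convention: Pearson correlation
across samples, an unsigned soft-thresholded adjacency ``a_ij = |r_ij|^beta``
with ``beta`` chosen for approximate scale-free topology, topological
overlap, average-linkage clustering into modules (static cut at the height
that best separates within- from between-cluster overlap, honoring the
minimum module size and the eigengene merge threshold), module eigengenes,
module-trait association, and intramodular connectivity (kWithin).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .de import adjust_fdr

__all__ = [
    "correlation_matrix",
    "pick_soft_threshold",
    "adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengenes",
    "module_trait_association",
    "intramodular_connectivity",
    "SoftThresholdFit",
]

#: module label reserved for genes not assigned to any module
UNASSIGNED = 0


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between genes (rows) across samples (columns).

    Zero-variance genes are dropped with a warning; fewer than 3 samples
    is an error (a correlation over 2 points is vacuous).
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlations")
    x = expr.to_numpy(dtype=float)
    keep = x.std(axis=1) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance genes", stacklevel=2)
        expr = expr.loc[keep]
        x = x[keep]
    r = np.atleast_2d(np.corrcoef(x))
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(np.clip(r, -1.0, 1.0), index=expr.index, columns=expr.index)


def adjacency(corr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned soft-thresholded adjacency ``a_ij = |r_ij|^beta``, diag 1."""
    if int(beta) != beta or beta < 1:
        raise ValueError("beta must be an integer >= 1")
    a = np.abs(corr.to_numpy(dtype=float)) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=corr.index, columns=corr.columns)


@dataclass
class SoftThresholdFit:
    """Chosen soft threshold plus the full scale-free fit table."""

    beta: int
    table: pd.DataFrame
    satisfied: bool


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Scale-free fit index: R^2 of log10(frequency) on log10(mean k).

    Connectivities are discretized into ``n_bins`` equal-width bins; empty
    bins are dropped and the per-bin frequency is regressed on the per-bin
    mean connectivity on the log-log scale (unweighted least squares).
    """
    k = k[k > 0]
    if len(k) < n_bins:
        return np.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k = np.array([k[idx == b].mean() if (idx == b).any() else np.nan
                       for b in range(n_bins)])
    freq = np.array([(idx == b).sum() for b in range(n_bins)], dtype=float) / len(k)
    ok = (freq > 0) & np.isfinite(mean_k) & (mean_k > 0)
    if ok.sum() < 3 or np.ptp(np.log10(mean_k[ok])) == 0 or np.ptp(np.log10(freq[ok])) == 0:
        return np.nan
    res = stats.linregress(np.log10(mean_k[ok]), np.log10(freq[ok]))
    return float(res.rvalue**2)


def pick_soft_threshold(
    corr: pd.DataFrame,
    candidate_betas: list[int] | None = None,
    rsq_cut: float = 0.8,
    mean_k_min: float = 0.7,
) -> SoftThresholdFit:
    """Choose the smallest beta giving an approximately scale-free network.

    For each candidate the connectivity ``k_i = sum_{j != i} a_ij`` is
    computed; its log-log frequency fit (10 equal-count bins, unweighted
    least squares) gives the scale-free R^2.  The smallest beta with
    ``R^2 >= rsq_cut`` and mean connectivity ``>= mean_k_min`` wins; if no
    candidate satisfies both, the argmax-R^2 beta is returned flagged.
    ``mean_k_min`` reflects a minimum-mean-connectivity convention whose
    original intent is ambiguous; the full fit table is always reported.
    """
    if candidate_betas is None:
        candidate_betas = list(range(1, 13))  # includes the conventional beta = 7
    if not candidate_betas:
        raise ValueError("candidate beta list is empty")
    rows = []
    for b in candidate_betas:
        a = adjacency(corr, b).to_numpy()
        k = a.sum(axis=1) - 1.0
        rows.append({"beta": b, "rsq": _scale_free_fit(k), "mean_k": float(k.mean()),
                     "median_k": float(np.median(k)), "max_k": float(k.max())})
    table = pd.DataFrame(rows)
    ok = (table["rsq"] >= rsq_cut) & (table["mean_k"] >= mean_k_min)
    if ok.any():
        beta = int(table.loc[ok, "beta"].iloc[0])
        return SoftThresholdFit(beta=beta, table=table, satisfied=True)
    warnings.warn("no candidate beta satisfies the scale-free criteria", stacklevel=2)
    beta = int(table.loc[table["rsq"].fillna(-np.inf).idxmax(), "beta"])
    return SoftThresholdFit(beta=beta, table=table, satisfied=False)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap ``w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)``.

    ``l_ij = sum_{u != i,j} a_iu a_uj`` counts shared neighbors and
    ``k_i = sum_{u != i} a_iu`` is connectivity.  Diagonal is 1.
    """
    a = adj.to_numpy(dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("adjacency values must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 1.0)
    sq = a @ a
    # remove the u = i and u = j terms (diag(a) = 1 so those are a_ij each)
    l = sq - 2.0 * a
    k = a.sum(axis=1) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > 0, (l + a) / denom, 0.0)
    np.fill_diagonal(w, 1.0)
    w = np.clip(w, 0.0, 1.0)
    return pd.DataFrame(w, index=adj.index, columns=adj.columns)


def _static_cut(link: np.ndarray, tom: np.ndarray) -> np.ndarray:
    """Cut the dendrogram at the height maximizing weighted modularity.

    Candidate heights lie between consecutive merge distances; each cut
    is scored by Newman modularity of the resulting partition on the
    TOM-weighted graph (zero diagonal), which penalizes both the trivial
    one-cluster and the singleton-dominated partitions.  Deterministic
    given the TOM.
    """
    n = tom.shape[0]
    w = tom.copy()
    np.fill_diagonal(w, 0.0)
    two_m = w.sum()
    if two_m <= 0:
        return np.ones(n, dtype=int)
    deg = w.sum(axis=1)
    heights = np.unique(link[:, 2])
    if len(heights) < 2:
        return np.ones(n, dtype=int)
    candidates = (heights[:-1] + heights[1:]) / 2.0
    best_labels, best_score = np.ones(n, dtype=int), 0.0  # one cluster has Q = 0
    for h in candidates:
        labels = hierarchy.fcluster(link, t=h, criterion="distance")
        q = 0.0
        for lab in np.unique(labels):
            mask = labels == lab
            q += w[np.ix_(mask, mask)].sum() / two_m - (deg[mask].sum() / two_m) ** 2
        if q > best_score + 1e-12:
            best_score, best_labels = q, labels
    return best_labels


def detect_modules(
    tom: pd.DataFrame,
    expr: pd.DataFrame | None = None,
    min_size: int = 30,
    merge_threshold: float = 0.2,
) -> pd.Series:
    """Cluster genes into co-expression modules from topological overlap.

    Average-linkage hierarchical clustering on dissimilarity ``1 - w``;
    the tree is cut at the static height maximizing within- vs
    between-cluster overlap separation.  Clusters below ``min_size`` are
    relabeled unassigned (label 0).  If ``expr`` is given, modules whose
    eigengene dissimilarity ``1 - r`` falls below ``merge_threshold`` are
    merged iteratively until stable.  Returns gene -> module label, with
    modules renumbered 1..m by decreasing size.
    """
    n = tom.shape[0]
    if min_size > n:
        warnings.warn("min_size exceeds the number of genes; all unassigned", stacklevel=2)
        return pd.Series(UNASSIGNED, index=tom.index, name="module")
    w = tom.to_numpy(dtype=float)
    diss = 1.0 - w
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(diss, checks=False), method="average")
    labels = _static_cut(link, w)

    # size filter
    out = labels.copy()
    for lab, count in zip(*np.unique(labels, return_counts=True)):
        if count < min_size:
            out[labels == lab] = UNASSIGNED

    modules = pd.Series(out, index=tom.index, name="module")
    if expr is not None:
        modules = _kme_cleanup(modules, expr, min_size)
        modules = _merge_by_eigengene(modules, expr, merge_threshold)
    # renumber 1..m by decreasing size (ties by first appearance)
    labs = [l for l in modules.unique() if l != UNASSIGNED]
    sizes = {l: int((modules == l).sum()) for l in labs}
    order = sorted(labs, key=lambda l: (-sizes[l], l))
    remap = {l: i + 1 for i, l in enumerate(order)}
    remap[UNASSIGNED] = UNASSIGNED
    return modules.map(remap).astype(int)


#: minimum |module membership| (gene-eigengene correlation) to stay assigned
KME_THRESHOLD = 0.6
#: minimum mean member |kME| for a module to count as coherent
MIN_MEAN_KME = 0.7


def _kme_cleanup(modules: pd.Series, expr: pd.DataFrame, min_size: int) -> pd.Series:
    """Reassign genes by module membership (kME) and drop incoherent modules.

    Each gene goes to the module whose eigengene it correlates with most
    strongly in absolute value (the network is unsigned), provided
    |kME| >= 0.6 (well clear of chance correlation at typical sample counts); otherwise it is unassigned.  This strips weakly
    attached genes that average linkage happened to fold into a cluster
    branch.  Modules that fall below ``min_size`` afterwards, or whose
    mean member |kME| stays under 0.7 (clusters of mutually selected
    noise rather than a shared driver), dissolve into the unassigned
    label.
    """
    labs = sorted(l for l in modules.unique() if l != UNASSIGNED)
    if not labs:
        return modules
    eig = module_eigengenes(expr, modules)
    x = expr.to_numpy(dtype=float)
    xz = (x - x.mean(axis=1, keepdims=True))
    sd = xz.std(axis=1)
    kme = np.zeros((len(expr), len(labs)))
    for j, lab in enumerate(labs):
        e = eig.loc[lab].to_numpy()
        ez = e - e.mean()
        denom = sd * ez.std()
        with np.errstate(invalid="ignore", divide="ignore"):
            kme[:, j] = np.where(denom > 0, (xz @ ez) / len(e) / denom, 0.0)
    best = np.argmax(np.abs(kme), axis=1)
    best_val = np.abs(kme)[np.arange(len(expr)), best]
    new = np.where(best_val >= KME_THRESHOLD, np.array(labs)[best], UNASSIGNED)
    out = pd.Series(new, index=modules.index, name="module")
    for j, lab in enumerate(labs):
        members = (out == lab).to_numpy()
        if members.sum() < min_size or np.abs(kme[members, j]).mean() < MIN_MEAN_KME:
            out[out == lab] = UNASSIGNED
    return out


def _merge_by_eigengene(modules: pd.Series, expr: pd.DataFrame, threshold: float) -> pd.Series:
    modules = modules.copy()
    while True:
        labs = sorted(l for l in modules.unique() if l != UNASSIGNED)
        if len(labs) < 2:
            return modules
        eig = module_eigengenes(expr, modules)
        best = None
        for i, li in enumerate(labs):
            for lj in labs[i + 1 :]:
                r = float(np.corrcoef(eig.loc[li], eig.loc[lj])[0, 1])
                d = 1.0 - r
                if d < threshold and (best is None or d < best[0]):
                    best = (d, li, lj)
        if best is None:
            return modules
        _, li, lj = best
        modules[modules == lj] = li


def module_eigengenes(expr: pd.DataFrame, modules: pd.Series) -> pd.DataFrame:
    """First principal component of each module's standardized expression.

    Rows are module labels, columns are samples; each eigengene has unit
    norm and is sign-aligned so its correlation with the module's mean
    expression profile is non-negative.
    """
    out = {}
    for lab in sorted(l for l in modules.unique() if l != UNASSIGNED):
        genes = modules.index[modules == lab]
        sub = expr.loc[genes].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=0)
        if np.any(sd == 0):
            raise ValueError(f"module {lab} contains zero-variance genes")
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        v = vt[0]
        mean_profile = z.mean(axis=0)
        if np.corrcoef(v, mean_profile)[0, 1] < 0:
            v = -v
        out[lab] = v
    return pd.DataFrame(out, index=expr.columns).T


def module_trait_association(
    eigengenes: pd.DataFrame, trait: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Pearson correlation of each eigengene with a 0/1 trait, BH-adjusted."""
    y = np.asarray(trait, dtype=float)
    if eigengenes.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if np.std(y) == 0:
        raise ValueError("trait is constant")
    rows = []
    for lab, e in eigengenes.iterrows():
        res = stats.pearsonr(e.to_numpy(), y)
        rows.append({"module": lab, "r": float(res.statistic), "p": float(res.pvalue)})
    table = pd.DataFrame(rows).set_index("module")
    table["p_adj"] = adjust_fdr(table["p"].to_numpy())
    return table


def intramodular_connectivity(adj: pd.DataFrame, modules: pd.Series) -> pd.Series:
    """kWithin: a gene's summed adjacency to the other genes in its module.

    Unassigned genes get 0; hub ranking by kWithin (descending, ties by
    gene ID) is the module's centrality order.
    """
    a = adj.to_numpy(dtype=float)
    labels = modules.reindex(adj.index).to_numpy()
    k = np.zeros(len(adj))
    for lab in np.unique(labels):
        if lab == UNASSIGNED:
            continue
        mask = labels == lab
        sub = a[np.ix_(mask, mask)]
        k[mask] = sub.sum(axis=1) - np.diag(sub)
    return pd.Series(k, index=adj.index, name="kWithin")
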