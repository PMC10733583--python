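"""Weighted coexpression network construction and module detection.

Implements the signed-hybrid variant: adjacency a_ij = max(cor_ij, 0)^beta
with Pearson correlation of log2 expression across samples, the
topological overlap matrix

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

(with connectivity k excluding the diagonal and TOM_ii = 1), average
linkage (UPGMA) clustering of the TOM dissimilarity 1 - TOM, and a
tree-variant dynamic cut: a static height cut at the 0.99 quantile of the
merge heights followed by a minimum-branch-size filter. Module summaries
are eigengenes (first principal component of the standardized module
expression), kME module memberships with correlation-test p-values, and
per-module hub genes by intramodular connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
from scipy.spatial.distance import squareform

DEFAULT_BETA = 12
MIN_MODULE_SIZE = 30
KME_THRESHOLD = 0.80


def filter_network_genes(
    counts: pd.DataFrame,
    expr: pd.DataFrame,
    min_total_counts: int = 10,
    min_cv: float = 0.2,
) -> pd.Series:
    """Genes retained for network construction.

    Keeps genes with total counts >= ``min_total_counts`` over the course
    and coefficient of variation of expression across all samples strictly
    above ``min_cv`` (low-variation genes carry no coexpression signal).
    """
    totals = counts.sum(axis=1)
    arr = expr.to_numpy(dtype=float)
    m = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(m > 0, sd / m, np.nan)
    cv = pd.Series(cv, index=expr.index)
    keep = (totals.reindex(expr.index) >= min_total_counts) & (cv > min_cv)
    return keep.fillna(False).rename("network_gene")


def signed_hybrid_adjacency(expr: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Adjacency (max(cor, 0))^beta with unit diagonal.

    ``expr`` is genes x samples (log2 scale); needs >= 4 samples. Genes
    with zero variance should have been filtered and raise here.
    """
    if expr.shape[1] < 4:
        raise ValueError("adjacency requires at least 4 samples")
    if beta < 1:
        raise ValueError("soft-threshold beta must be >= 1")
    arr = expr.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    bad = expr.index[sd == 0]
    if len(bad):
        raise ValueError(f"zero-variance gene(s) in expression: {list(bad[:5])}")
    cor = np.corrcoef(arr)
    adj = np.clip(cor, 0.0, None) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=expr.index, columns=expr.index)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit index for a connectivity vector.

    Bins log10(k), regresses log10 of the per-bin frequency on the per-bin
    mean log10(k) and returns (signed R^2, slope). The sign convention
    makes the index positive only for the decreasing degree distributions
    expected of scale-free networks.
    """
    k = connectivity[connectivity > 0]
    if k.size < n_bins:
        raise ValueError("too few positive connectivities for the fit")
    # equal-width bins on the k scale; frequency and mean k per bin
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        raise ValueError("too few occupied bins for the scale-free fit")
    slope, _, r, _, _ = scipy.stats.linregress(xs, ys)
    r2 = r**2
    return (r2 if slope < 0 else -r2), slope


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_betas=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    r2_target: float = 0.8,
    default_beta: float = DEFAULT_BETA,
) -> tuple[float, pd.DataFrame]:
    """Select the smallest beta reaching the scale-free fit target.

    Returns (beta, fit table with columns beta, fit_r2, slope, mean_k,
    median_k, max_k). Falls back to ``default_beta`` with a warning when no
    candidate reaches ``r2_target``.
    """
    if len(candidate_betas) == 0:
        raise ValueError("candidate beta list is empty")
    rows = []
    for beta in candidate_betas:
        adj = signed_hybrid_adjacency(expr, beta).to_numpy()
        k = adj.sum(axis=0) - 1.0  # exclude the unit diagonal
        if np.allclose(k, 0):
            warnings.warn(
                f"all-zero adjacency at beta={beta}; candidate skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        try:
            fit, slope = scale_free_fit(k)
        except ValueError:
            fit, slope = np.nan, np.nan
        rows.append(
            {
                "beta": beta,
                "fit_r2": fit,
                "slope": slope,
                "mean_k": k.mean(),
                "median_k": np.median(k),
                "max_k": k.max(),
            }
        )
    table = pd.DataFrame(rows, columns=["beta", "fit_r2", "slope", "mean_k", "median_k", "max_k"])
    hit = table[table["fit_r2"] >= r2_target]
    if len(hit):
        beta = float(hit["beta"].iloc[0])
    else:
        warnings.warn(
            f"no candidate beta reached scale-free fit R^2 >= {r2_target}; "
            f"falling back to beta={default_beta}",
            RuntimeWarning,
            stacklevel=2,
        )
        beta = float(default_beta)
    return beta, table


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """TOM of a (signed-hybrid, hence non-negative) adjacency matrix."""
    a = adj.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    n = a.shape[0]
    k = a.sum(axis=0) - np.diag(a)  # connectivity excludes the diagonal
    l_mat = a @ a
    diag = np.diag(a)
    # shared-neighbor sums excluding u = i and u = j
    shared = l_mat - diag[:, None] * a - a * diag[None, :]
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, numer / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(0.5 * (tom + tom.T), 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def average_linkage_cluster(diss: pd.DataFrame) -> np.ndarray:
    """UPGMA linkage matrix (scipy format) of a dissimilarity matrix."""
    d = diss.to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError("dissimilarity matrix contains NaN")
    if d.shape[0] < 2:
        return np.empty((0, 4))
    condensed = squareform(0.5 * (d + d.T), checks=False)
    return sch.linkage(condensed, method="average")


def cut_tree_dynamic(
    linkage: np.ndarray,
    n_leaves: int | None = None,
    min_size: int = MIN_MODULE_SIZE,
    cut_height: float = 0.99,
) -> np.ndarray:
    """Tree-variant dynamic cut: static height cut + branch-size filter.

    Cuts the dendrogram at the absolute height ``cut_height`` (on the TOM
    dissimilarity scale, where uncorrelated genes join near 1, the
    conventional tree-cut default is 0.99); branches with >= ``min_size``
    leaves become modules labeled 1..M by decreasing size, remaining
    leaves get label 0 (unassigned).
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if linkage.shape[0] == 0:
        return np.zeros(n_leaves or 1, dtype=int)
    raw = sch.fcluster(linkage, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_size]
    # decreasing size; ties broken by the smallest original cluster id
    ordered = sorted(big.index, key=lambda c: (-big[c], c))
    relabel = {c: i + 1 for i, c in enumerate(ordered)}
    return np.array([relabel.get(c, 0) for c in raw], dtype=int)


@dataclass
class ModuleAssignment:
    """Gene -> module labels with eigengenes, kME and hubs.

    ``labels``: 0 = unassigned, 1..M by decreasing module size.
    ``eigengenes``: modules x samples, unit-norm rows.
    ``kme``: genes x modules Pearson correlations, with ``kme_pvalues``.
    ``featured``: kME > threshold and p < 0.05 for the gene's own module.
    """

    labels: pd.Series
    eigengenes: pd.DataFrame
    variance_explained: pd.Series
    kme: pd.DataFrame
    kme_pvalues: pd.DataFrame
    featured: pd.Series
    hubs: dict[int, str] = field(default_factory=dict)


def module_eigengene(
    expr: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """First principal component per module, over samples.

    Each member gene is z-scored across samples; the eigengene is the
    leading right singular vector (unit norm), sign-oriented so that the
    mean correlation with member genes is positive. Returns (eigengenes,
    fraction of variance explained).
    """
    modules = sorted(set(labels[labels > 0]))
    rows, varex = [], []
    for mod in modules:
        members = labels.index[labels == mod]
        if len(members) < 2:
            raise ValueError(f"module {mod} has fewer than 2 genes")
        sub = expr.loc[members].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=0)
        if (sd == 0).any():
            bad = list(members[sd == 0][:5])
            raise ValueError(f"constant gene(s) inside module {mod}: {bad}")
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        if np.corrcoef(np.vstack([eig, z]))[0, 1:].mean() < 0:
            eig = -eig
        rows.append(eig)
        varex.append(s[0] ** 2 / (s**2).sum())
    eigengenes = pd.DataFrame(
        rows, index=pd.Index(modules, name="module"), columns=expr.columns
    )
    return eigengenes, pd.Series(varex, index=eigengenes.index, name="variance_explained")


def module_membership(
    expr: pd.DataFrame,
    eigengenes: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """kME: Pearson correlation of every gene with every module eigengene.

    p-values come from the t-statistic with n - 2 df. Requires >= 4 samples.
    """
    n = expr.shape[1]
    if n < 4:
        raise ValueError("kME requires at least 4 samples")
    x = expr.to_numpy(dtype=float)
    e = eigengenes.to_numpy(dtype=float)
    xz = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=0, keepdims=True)
    ez = (e - e.mean(axis=1, keepdims=True)) / e.std(axis=1, ddof=0, keepdims=True)
    cor = np.clip(xz @ ez.T / n, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cor * np.sqrt((n - 2) / np.clip(1.0 - cor**2, 1e-300, None))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    kme = pd.DataFrame(cor, index=expr.index, columns=eigengenes.index)
    pvals = pd.DataFrame(p, index=expr.index, columns=eigengenes.index)
    return kme, pvals


def featured_flags(
    kme: pd.DataFrame,
    pvals: pd.DataFrame,
    labels: pd.Series,
    kme_threshold: float = KME_THRESHOLD,
    alpha: float = 0.05,
) -> pd.Series:
    """kME > threshold with p < 0.05 against the gene's own eigengene."""
    out = pd.Series(False, index=labels.index, name="featured")
    for mod in kme.columns:
        members = labels.index[labels == mod]
        out.loc[members] = (kme.loc[members, mod] > kme_threshold) & (
            pvals.loc[members, mod] < alpha
        )
    return out


def hub_gene(adj: pd.DataFrame, labels: pd.Series) -> dict[int, str]:
    """Per module, the gene with maximal intramodular connectivity.

    Connectivity sums adjacency to same-module partners (self excluded);
    ties break to the lexicographically first gene id.
    """
    hubs: dict[int, str] = {}
    for mod in sorted(set(labels[labels > 0])):
        members = sorted(labels.index[labels == mod])
        sub = adj.loc[members, members].to_numpy(dtype=float)
        conn = sub.sum(axis=1) - np.diag(sub)
        best = np.flatnonzero(conn == conn.max())[0]  # members sorted => lexicographic tie-break
        hubs[int(mod)] = members[best]
    return hubs


def detect_modules(
    expr: pd.DataFrame,
    beta: float | None = None,
    min_module_size: int = MIN_MODULE_SIZE,
    kme_threshold: float = KME_THRESHOLD,
) -> ModuleAssignment:
    """End-to-end module detection on a genes x samples expression matrix.

    ``beta=None`` triggers automatic soft-threshold selection with fallback
    to the configured default (12).
    """
    if beta is None:
        beta, _ = pick_soft_threshold(expr)
    adj = signed_hybrid_adjacency(expr, beta)
    tom = topological_overlap(adj)
    linkage = average_linkage_cluster(1.0 - tom)
    labels = pd.Series(
        cut_tree_dynamic(linkage, n_leaves=len(expr), min_size=min_module_size),
        index=expr.index,
        name="module",
    )
    if (labels > 0).any():
        eigengenes, varex = module_eigengene(expr, labels)
        kme, pvals = module_membership(expr, eigengenes)
        featured = featured_flags(kme, pvals, labels, kme_threshold)
        hubs = hub_gene(adj, labels)
    else:
        eigengenes = pd.DataFrame(columns=expr.columns)
        varex = pd.Series(dtype=float)
        kme = pd.DataFrame(index=expr.index)
        pvals = pd.DataFrame(index=expr.index)
        featured = pd.Series(False, index=expr.index, name="featured")
        hubs = {}
    return ModuleAssignment(
        labels=labels,
        eigengenes=eigengenes,
        variance_explained=varex,
        kme=kme,
        kme_pvalues=pvals,
        featured=featured,
        hubs=hubs,
    )
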