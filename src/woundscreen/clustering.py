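"""Correlation-distance clustering of morphology signatures.

Signatures (rows of 11 z-scored features) are clustered with the distance
d(i, j) = 1 - Pearson(row_i, row_j) under complete-linkage agglomeration,
and the dendrogram is cut at a fixed height (default 1.5), so two genes land
in one cluster only when every pair within it correlates above -0.5.
Quantile binning is provided for heatmap export only; clustering always runs
on the unbinned z-scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

DEFAULT_CUT_HEIGHT = 1.5


class ZeroVarianceRowError(ValueError):
    """A signature row is constant; correlation distance is undefined."""


def correlation_distance_matrix(matrix) -> np.ndarray:
    """Symmetric matrix of 1 - Pearson correlation between rows; diagonal 0,
    values in [0, 2].  Raises :class:`ZeroVarianceRowError` naming any
    constant row."""
    df = pd.DataFrame(matrix)
    X = df.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to compute distances")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = df.index[np.nonzero(sd == 0)[0][0]]
        raise ZeroVarianceRowError(f"row {bad!r} has zero variance")
    D = 1.0 - np.corrcoef(X)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return np.clip(D, 0.0, 2.0)


def complete_linkage_cut(dist: np.ndarray, cut_height: float = DEFAULT_CUT_HEIGHT,
                         ids=None) -> pd.Series:
    """Complete-linkage agglomeration cut at ``cut_height``.

    Clusters are the groups left after removing every merge higher than the
    cut; they are numbered 1..k by dendrogram leaf order (left to right).
    Returns a Series id -> cluster number.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if ids is None:
        ids = np.arange(n)
    if n == 1:
        return pd.Series([1], index=ids)
    Z = hierarchy.linkage(squareform(D, checks=False), method="complete")
    raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    order = hierarchy.leaves_list(Z)
    renumber: dict[int, int] = {}
    for leaf in order:
        renumber.setdefault(raw[leaf], len(renumber) + 1)
    return pd.Series([renumber[c] for c in raw], index=ids, name="cluster_number")


def cluster_signatures(matrix: pd.DataFrame,
                       cut_height: float = DEFAULT_CUT_HEIGHT) -> pd.Series:
    """Convenience: correlation distances + complete-linkage cut on a
    signature frame indexed by gene."""
    D = correlation_distance_matrix(matrix)
    return complete_linkage_cut(D, cut_height, ids=matrix.index)


def dendrogram_newick(matrix: pd.DataFrame) -> str:
    """Newick export of the complete-linkage dendrogram (correlation
    distance), with merge heights as branch lengths."""
    D = correlation_distance_matrix(matrix)
    Z = hierarchy.linkage(squareform(D, checks=False), method="complete")
    tree = hierarchy.to_tree(Z)
    names = [str(i) for i in matrix.index]

    def recurse(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({recurse(tree.left, tree.dist)},{recurse(tree.right, tree.dist)});"


def cross_celltype_correlation(sig_lec: pd.DataFrame,
                               sig_bec: pd.DataFrame) -> tuple[pd.Series, dict]:
    """Per-gene Pearson r between the two cell types' 11-feature signatures.

    Gene sets must match; a join error lists the genes missing from either
    side.  Returns the per-gene r Series and a distribution summary
    (median, mean, quartiles, n).
    """
    missing_in_bec = sorted(set(sig_lec.index) - set(sig_bec.index))
    missing_in_lec = sorted(set(sig_bec.index) - set(sig_lec.index))
    if missing_in_bec or missing_in_lec:
        raise KeyError(f"gene sets differ between cell types: "
                       f"missing in BEC {missing_in_bec}, missing in LEC {missing_in_lec}")
    cols = [c for c in sig_lec.columns if c in sig_bec.columns]
    r = pd.Series({g: pearsonr(sig_lec.loc[g, cols].astype(float),
                               sig_bec.loc[g, cols].astype(float)).statistic
                   for g in sig_lec.index}, name="pearson_r")
    summary = {"median": float(r.median()), "mean": float(r.mean()),
               "q25": float(r.quantile(0.25)), "q75": float(r.quantile(0.75)),
               "n": int(len(r))}
    return r, summary


def quantile_bin(matrix, n_bins: int) -> np.ndarray:
    """Replace each value by its quantile bin index (1..n_bins) computed over
    the whole matrix.  Display-only transform for heatmap export.  A constant
    matrix falls entirely into bin 1."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    X = np.asarray(matrix, dtype=float)
    flat = X.ravel()
    if np.ptp(flat) == 0:
        return np.ones_like(X, dtype=int)
    binned = pd.qcut(flat, q=n_bins, labels=False, duplicates="drop") + 1
    return np.asarray(binned, dtype=int).reshape(X.shape)
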