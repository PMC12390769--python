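"""Proteome-connectome coupling statistics and hierarchical clustering.

The central statistic relates proteomic dissimilarity (DEP count per ROI
pair) to connectivity (FC or SC) by a plain Pearson correlation over all
unordered ROI pairs (325 pairs for 26 ROIs), with pairs annotated by
hemisphere class (left / right / cross).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage, to_tree

from .datatypes import (
    ConnectivityMatrix,
    ProteinMatrix,
    group_labels,
    validate_sample_meta,
)
from .differential_expression import DEPCountMatrix


@dataclass
class CouplingResult:
    n_pairs: int
    r: float
    p: float
    per_pair: pd.DataFrame  # pair, hemisphere_class, dep_count, connectivity

    def per_class(self) -> pd.DataFrame:
        """Supplementary per-hemisphere-class correlations."""
        rows = []
        for cls, sub in self.per_pair.groupby("hemisphere_class"):
            if len(sub) >= 3 and sub["dep_count"].std() > 0 \
                    and sub["connectivity"].std() > 0:
                res = stats.pearsonr(sub["dep_count"], sub["connectivity"])
                rows.append({"hemisphere_class": cls, "n_pairs": len(sub),
                             "r": res.statistic, "p": res.pvalue})
        return pd.DataFrame(rows)


def coupling_correlation(dep: DEPCountMatrix, conn: ConnectivityMatrix
                         ) -> CouplingResult:
    """Pearson correlation between DEP count and connectivity over pairs."""
    labels = list(dep.counts.index)
    if list(conn.labels) != labels:
        conn_df = conn.to_dataframe()
        if not set(labels) <= set(conn_df.index):
            raise ValueError("DEP and connectivity matrices share no ROI order")
        conn_vals = conn_df.loc[labels, labels].to_numpy()
    else:
        conn_vals = conn.values
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    if iu[0].size < 3:
        raise ValueError("need at least 3 ROI pairs")
    dep_vals = dep.counts.to_numpy()[iu].astype(float)
    con_vals = conn_vals[iu]
    classes = dep.pair_class.to_numpy()[iu]
    res = stats.pearsonr(dep_vals, con_vals)
    per_pair = pd.DataFrame({
        "pair": [f"{labels[i]}|{labels[j]}" for i, j in zip(*iu)],
        "hemisphere_class": classes,
        "dep_count": dep_vals,
        "connectivity": con_vals,
    })
    return CouplingResult(n_pairs=iu[0].size, r=float(res.statistic),
                          p=float(res.pvalue), per_pair=per_pair)


def profile_similarity(m: ProteinMatrix, meta: pd.DataFrame,
                       hemisphere: str = "L",
                       min_common: int = 10) -> pd.DataFrame:
    """13x13 Spearman similarity of region-mean protein profiles.

    Mean profiles are taken over detected donors per region within one
    hemisphere; each pairwise correlation uses the proteins co-detected in
    both regions.  Pairs with fewer than ``min_common`` shared proteins are
    flagged missing (NaN).
    """
    if not m.is_log2:
        raise ValueError("profile similarity expects the log2 matrix")
    validate_sample_meta(meta)
    sub = meta[meta["hemisphere"] == hemisphere]
    groups = group_labels(sub)
    regions = sorted(sub["region"].unique(),
                     key=lambda r: _region_rank(r))
    profiles = {}
    for region in regions:
        cols = [sid for sid in groups.index
                if groups[sid] == f"{region}_{hemisphere}"]
        profiles[region] = m.values[cols].mean(axis=1, skipna=True)
    sim = pd.DataFrame(np.eye(len(regions)), index=regions, columns=regions)
    for i, ra in enumerate(regions):
        for rb in regions[i + 1:]:
            a, b = profiles[ra], profiles[rb]
            ok = a.notna() & b.notna()
            if ok.sum() < min_common:
                rho = np.nan
            else:
                rho = stats.spearmanr(a[ok], b[ok]).statistic
            sim.loc[ra, rb] = sim.loc[rb, ra] = rho
    return sim


def _region_rank(region: str) -> int:
    from .datatypes import REGIONS

    return REGIONS.index(region) if region in REGIONS else len(REGIONS)


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: pd.Series  # cluster id per ROI/region at the requested k
    metric: str

    def to_newick(self) -> str:
        """Dendrogram as Newick text with merge-height branch lengths."""
        tree = to_tree(self.linkage)
        names = list(self.labels.index)

        def recurse(node, parent_dist):
            if node.is_leaf():
                return f"{names[node.id]}:{parent_dist - 0.0:.6g}"
            left = recurse(node.left, node.dist)
            right = recurse(node.right, node.dist)
            return f"({left},{right}):{max(parent_dist - node.dist, 0.0):.6g}"

        return f"({recurse(tree.left, tree.dist)},{recurse(tree.right, tree.dist)});"


def hierarchical_clusters(data: pd.DataFrame | np.ndarray, k: int,
                          metric: str = "one-minus-correlation",
                          method: str = "average",
                          labels: list[str] | None = None) -> ClusterResult:
    """Average-linkage clustering of a similarity/connectivity matrix.

    The distance between two rows is 1 - value for correlation-like inputs
    (``one-minus-correlation``), or 1 - value/max for non-negative
    connectivity (``one-minus-normalized``).
    """
    if isinstance(data, pd.DataFrame):
        arr = data.to_numpy(dtype=float)
        if labels is None:
            labels = list(data.index)
    else:
        arr = np.asarray(data, dtype=float)
        if labels is None:
            labels = [f"R{i}" for i in range(arr.shape[0])]
    n = arr.shape[0]
    if arr.shape != (n, n) or not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("input must be square and symmetric")
    if not 1 <= k <= n:
        raise ValueError("k must lie in [1, n]")
    if metric == "one-minus-correlation":
        dist = 1.0 - arr
    elif metric == "one-minus-normalized":
        mx = arr.max()
        dist = 1.0 - arr / (mx if mx > 0 else 1.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    iu = np.triu_indices(n, k=1)
    Z = linkage(dist[iu], method=method)
    assignments = fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(linkage=Z, labels=pd.Series(assignments, index=labels),
                         metric=metric)
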