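"""Ward hierarchical clustering of the quality panel and cluster profiling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = ["ClusterResult", "ward_cluster", "cluster_profile"]


@dataclass
class ClusterResult:
    """A cut Ward tree: linkage matrix, k, and size-ordered labels.

    Clusters are renumbered 1..k by decreasing size, so cluster 1 is always
    the largest.  ``labels`` is aligned on the panel's sample index.
    """

    linkage: np.ndarray
    k: int
    labels: pd.Series
    standardized: bool

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def ward_cluster(panel: pd.DataFrame, k: int = 3, standardize: bool = True) -> ClusterResult:
    """Ward minimum-variance clustering cut at ``k`` clusters.

    Uses the squared-Euclidean Ward update (the ``ward.D2`` convention:
    linkage heights are Euclidean distances between merged centroids scaled
    by the Ward factor).  With ``standardize`` the variables are z-scored
    first, which keeps kPa-scale moduli from dominating ratio-scale
    attributes.
    """
    x = panel.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("panel contains non-finite values")
    if len(panel) <= k:
        raise ValueError("need more samples than clusters")
    if standardize:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            zero = list(panel.columns[sd == 0])
            raise ValueError(f"zero-variance variables cannot be standardized: {zero}")
        x = (x - x.mean(axis=0)) / sd

    z = hierarchy.linkage(x, method="ward")
    raw = hierarchy.fcluster(z, t=k, criterion="maxclust")
    # renumber by decreasing size (ties: lower raw label first)
    counts = pd.Series(raw).value_counts()
    order = sorted(counts.index, key=lambda c: (-counts[c], c))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=panel.index, name="cluster")
    return ClusterResult(linkage=z, k=k, labels=labels, standardized=standardize)


def cluster_profile(panel: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-cluster mean and sample SD (ddof=1) of every panel variable.

    Returns a frame indexed by variable with a two-level column index
    (cluster, {mean, sd}).  For singleton clusters the SD is NaN.
    """
    if not labels.index.equals(panel.index):
        labels = labels.reindex(panel.index)
    if labels.isna().any():
        raise ValueError("labels do not cover all panel samples")
    means = panel.groupby(labels).mean().T
    sds = panel.groupby(labels).std(ddof=1).T
    out = pd.concat({"mean": means, "sd": sds}, axis=1)
    out = out.swaplevel(axis=1).sort_index(axis=1, level=0)
    out.columns.names = ["cluster", "stat"]
    return out.loc[panel.columns]
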