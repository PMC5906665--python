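"""Treated/control fold changes per time point and hierarchical clustering
of metabolite trajectories.

Each feature's response over the irradiation time course is summarized as
log2(mean treated / mean control) per time point, with an optional Welch
t-test per cell when both sides carry replicates; trajectories are then
clustered agglomeratively so that metabolites sharing a modification-driven
response pattern group together.
"""

from __future__ import annotations

from dataclasses import dataclass

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .chemometrics import IntensityMatrix

__all__ = [
    "FoldChangeTable",
    "Dendrogram",
    "fold_changes",
    "hcluster",
    "cut_clusters",
    "to_newick",
]


@dataclass(frozen=True)
class FoldChangeTable:
    """features x time-points table of log2 fold changes (+ optional p-values)."""

    feature_ids: tuple[str, ...]
    time_points: tuple[float, ...]
    log2fc: np.ndarray
    pvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        fc = np.asarray(self.log2fc, dtype=float)
        object.__setattr__(self, "log2fc", fc)
        if fc.shape != (len(self.feature_ids), len(self.time_points)):
            raise ValueError("log2fc shape does not match feature/time ids")
        if not np.all(np.isfinite(fc)):
            raise ValueError("log2fc must be finite (zero controls are pseudo-replaced)")
        if list(self.time_points) != sorted(set(self.time_points)):
            raise ValueError("time points must be strictly increasing")
        if self.pvalues is not None and np.asarray(self.pvalues).shape != fc.shape:
            raise ValueError("pvalues shape does not match log2fc")

    def zscore_rows(self) -> "FoldChangeTable":
        """Optional per-row standardization before clustering."""
        fc = self.log2fc
        sd = fc.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        z = (fc - fc.mean(axis=1, keepdims=True)) / sd[:, None]
        return FoldChangeTable(self.feature_ids, self.time_points, z, self.pvalues)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.log2fc, index=list(self.feature_ids),
                            columns=[f"{t:g}h" for t in self.time_points])


def fold_changes(
    m: IntensityMatrix,
    treated_group: str = "uvb",
    control_group: str = "control",
) -> FoldChangeTable:
    """Per-feature, per-time-point log2(treated mean / control mean).

    When both means are zero the fold change is 0; when only the control mean
    is zero, a pseudocount of half the smallest positive matrix value keeps
    the ratio finite.  Welch two-sample t-test p-values are attached for every
    cell with >= 2 replicates on both sides.
    """
    if m.time_h is None:
        raise ValueError("matrix has no time_h annotation")
    groups = np.asarray(m.group)
    times = np.asarray(m.time_h, dtype=float)
    time_points = tuple(sorted(set(times.tolist())))
    positive = m.values[m.values > 0]
    eps = positive.min() / 2.0 if positive.size else 1.0
    n_feat = m.n_features
    fc = np.zeros((n_feat, len(time_points)))
    pv = np.full((n_feat, len(time_points)), np.nan)
    for j, t in enumerate(time_points):
        tr_rows = (groups == treated_group) & (times == t)
        ct_rows = (groups == control_group) & (times == t)
        if not tr_rows.any() or not ct_rows.any():
            raise ValueError(f"missing treated or control samples at time {t} h")
        tr = m.values[tr_rows]
        ct = m.values[ct_rows]
        mu_tr = tr.mean(axis=0)
        mu_ct = ct.mean(axis=0)
        both_zero = (mu_tr == 0) & (mu_ct == 0)
        zero_ct = (mu_ct == 0) & ~both_zero
        ok = ~both_zero & ~zero_ct
        fc[ok, j] = np.log2(mu_tr[ok] / mu_ct[ok])
        fc[zero_ct, j] = np.log2((mu_tr[zero_ct] + eps) / eps)
        if tr.shape[0] >= 2 and ct.shape[0] >= 2:
            res = stats.ttest_ind(tr, ct, axis=0, equal_var=False)
            pv[:, j] = res.pvalue
    pvalues = pv if np.isfinite(pv).any() else None
    return FoldChangeTable(m.feature_ids, time_points, fc, pvalues)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree over the fold-change rows."""

    merges: np.ndarray  # scipy linkage matrix (n-1 x 4)
    leaf_order: tuple[int, ...]
    feature_ids: tuple[str, ...]
    linkage: str
    metric: str

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def _row_distances(fc: np.ndarray, metric: str, feature_ids: Sequence[str]) -> np.ndarray:
    if metric == "euclidean":
        from scipy.spatial.distance import pdist

        return pdist(fc, metric="euclidean")
    if metric == "correlation":
        sd = fc.std(axis=1)
        bad = np.where(sd == 0)[0]
        if bad.size:
            raise ValueError(
                f"correlation metric undefined on constant row(s): {feature_ids[bad[0]]}"
            )
        from scipy.spatial.distance import pdist

        return pdist(fc, metric="correlation")
    raise ValueError(f"unknown metric {metric!r}")


def hcluster(
    fc: FoldChangeTable, linkage: str = "complete", metric: str = "euclidean"
) -> Dendrogram:
    """Agglomerative clustering of fold-change trajectories.

    Supported linkages: complete, average, single.  Deterministic: equal
    heights merge in scipy's canonical order (lowest original indices first).
    """
    if linkage not in ("complete", "average", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if len(fc.feature_ids) < 2:
        raise ValueError("clustering needs at least 2 features")
    d = _row_distances(fc.log2fc, metric, fc.feature_ids)
    merges = hierarchy.linkage(d, method=linkage)
    order = tuple(int(i) for i in hierarchy.leaves_list(merges))
    return Dendrogram(merges, order, fc.feature_ids, linkage, metric)


def cut_clusters(d: Dendrogram, k: int) -> np.ndarray:
    """Cut the merge tree into *k* clusters; labels 1..k numbered by first
    appearance in left-to-right leaf order."""
    n = len(d.feature_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    raw = hierarchy.fcluster(d.merges, t=k, criterion="maxclust")
    if len(set(raw.tolist())) != k:
        # ties can make maxclust under-shoot; fall back to cutting by height rank
        raw = hierarchy.cut_tree(d.merges, n_clusters=k).ravel() + 1
    relabel: dict[int, int] = {}
    for leaf in d.leaf_order:
        relabel.setdefault(int(raw[leaf]), len(relabel) + 1)
    return np.array([relabel[int(c)] for c in raw])


def to_newick(d: Dendrogram) -> str:
    """Serialize the dendrogram as a Newick string with branch lengths."""
    n = len(d.feature_ids)
    tree = hierarchy.to_tree(d.merges)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            name = str(d.feature_ids[node.id]).replace(" ", "_").replace(",", "_")
            return f"{name}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
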