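"""Replicate-pool consistency checks and advisory outlier flags.

Pools within an experimental group should resemble each other more than
pools across groups. Consistency is assessed from the pairwise Pearson
correlation of RPM profiles, average-linkage (UPGMA) clustering on the
distance 1 - r, and the per-group mean coefficient of variation
(CV = sample SD / mean per element, averaged over elements).

A pool is flagged as an outlier only when both hold: (a) in the dendrogram
it merges outside its own group before its group-mates have merged
together, and (b) dropping it reduces the group's mean CV substantially --
by at least ``cv_ratio_threshold`` (default 1.2) after correcting each CV
for the small-sample bias of the standard deviation (the c4(n) factor;
without it a 2-replicate CV is systematically ~10% below a 3-replicate
one and dropping any pool looks like an improvement) -- and down to at
most the mean CV of the other groups. Flags are advisory; exclusion is an
explicit caller action and amounts to dropping the pool's column, leaving
every other pool untouched.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .design import PoolDesign

DEFAULT_CV_RATIO_THRESHOLD = 1.2


def c4_factor(n: int) -> float:
    """Unbiasing constant for the sample SD of a normal sample of size n."""
    if n < 2:
        raise ValueError("c4 requires n >= 2")
    return math.sqrt(2.0 / (n - 1)) * math.gamma(n / 2) / math.gamma((n - 1) / 2)


def pool_correlations(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation between pool RPM profiles."""
    if matrix.shape[1] < 2 or matrix.shape[0] < 2:
        raise ValueError("need at least 2 pools and 2 elements")
    std = matrix.std(axis=0, ddof=0)
    flat = std[std == 0]
    if len(flat):
        raise ValueError(f"zero-variance profile in pool(s): {', '.join(flat.index)}")
    return matrix.corr(method="pearson")


def average_linkage_cluster(correlations: pd.DataFrame) -> np.ndarray:
    """UPGMA linkage on the distance d = 1 - r.

    Returns a scipy linkage matrix over the pools in column order of
    ``correlations``. Scipy's nearest-neighbor chain is deterministic;
    exact distance ties merge in index order.
    """
    dist = 1.0 - correlations.to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    return linkage(condensed, method="average")


def dendrogram_newick(linkage_matrix: np.ndarray, labels: list[str]) -> str:
    """Serialize a linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(linkage_matrix)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def element_group_cv(
    matrix: pd.DataFrame,
    design: PoolDesign,
) -> pd.DataFrame:
    """Per-element, per-group CV over the replicate pools present."""
    out = {}
    for (line, cond), _ in design.groups.items():
        pools = design.present(matrix.columns, line, cond)
        if len(pools) < 2:
            raise ValueError(f"group {line}_{cond} has fewer than 2 pools")
        sub = matrix[pools]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        cv = sd / mean
        cv[mean == 0] = np.nan  # zero-mean elements carry no CV information
        out[f"{line}_{cond}"] = cv
    return pd.DataFrame(out)


def group_cv(matrix: pd.DataFrame, design: PoolDesign) -> pd.Series:
    """Mean-over-elements CV per experimental group."""
    return element_group_cv(matrix, design).mean(axis=0, skipna=True)


def _min_node_containing(linkage_matrix: np.ndarray, targets: set[int], n: int) -> set[int]:
    """Members of the first merge node whose cluster covers ``targets``."""
    sets: dict[int, set[int]] = {i: {i} for i in range(n)}
    for k in range(linkage_matrix.shape[0]):
        a, b = int(linkage_matrix[k, 0]), int(linkage_matrix[k, 1])
        merged = sets[a] | sets[b]
        sets[n + k] = merged
        if targets <= merged:
            return merged
    return set(range(n))


@dataclass
class ConsistencyReport:
    correlations: pd.DataFrame
    linkage: np.ndarray
    labels: list[str]
    group_cv: pd.Series
    evidence: pd.DataFrame

    @property
    def flagged(self) -> list[str]:
        return list(self.evidence.index[self.evidence["flagged"]])

    def newick(self) -> str:
        return dendrogram_newick(self.linkage, self.labels)


def consistency_report(
    matrix: pd.DataFrame,
    design: PoolDesign,
    cv_ratio_threshold: float = DEFAULT_CV_RATIO_THRESHOLD,
) -> ConsistencyReport:
    """Compute correlations, dendrogram, group CVs and outlier flags."""
    corr = pool_correlations(matrix)
    Z = average_linkage_cluster(corr)
    labels = list(corr.columns)
    cvs = group_cv(matrix, design)
    evidence = flag_outliers(matrix, design, Z, labels, cvs, cv_ratio_threshold)
    return ConsistencyReport(
        correlations=corr, linkage=Z, labels=labels, group_cv=cvs, evidence=evidence
    )


def flag_outliers(
    matrix: pd.DataFrame,
    design: PoolDesign,
    linkage_matrix: np.ndarray | None = None,
    labels: list[str] | None = None,
    group_cvs: pd.Series | None = None,
    cv_ratio_threshold: float = DEFAULT_CV_RATIO_THRESHOLD,
) -> pd.DataFrame:
    """Advisory outlier evidence per pool.

    Columns: ``topology_outside`` (criterion a), ``cv_with`` /
    ``cv_without`` (group mean CV with and without the pool),
    ``cv_ratio`` (c4-debiased cv_with / cv_without), ``others_mean_cv``
    and the conjunctive ``flagged`` verdict: topology AND
    ``cv_ratio >= cv_ratio_threshold`` AND ``cv_without <= others_mean_cv``.
    """
    if linkage_matrix is None or labels is None:
        corr = pool_correlations(matrix)
        linkage_matrix = average_linkage_cluster(corr)
        labels = list(corr.columns)
    if group_cvs is None:
        group_cvs = group_cv(matrix, design)
    pos = {p: i for i, p in enumerate(labels)}
    n = len(labels)

    rows = []
    for pool in labels:
        line, cond = design.group_of(pool)
        group_label = f"{line}_{cond}"
        mates = [p for p in design.present(labels, line, cond) if p != pool]
        if mates:
            node = _min_node_containing(linkage_matrix, {pos[m] for m in mates}, n)
            topology_outside = pos[pool] not in node
        else:
            topology_outside = False
        cv_with = group_cvs[group_label]
        others_mean = group_cvs.drop(group_label).mean()
        if len(mates) >= 2:
            reduced = matrix.drop(columns=[pool])
            cv_without = group_cv(reduced, design)[group_label]
            # debias before comparing CVs computed from different replicate counts
            cv_ratio = (cv_with / c4_factor(len(mates) + 1)) / (
                cv_without / c4_factor(len(mates))
            ) if cv_without > 0 else np.inf
        else:
            cv_without = np.nan
            cv_ratio = np.nan
        cv_ok = (
            not np.isnan(cv_without)
            and cv_ratio >= cv_ratio_threshold
            and cv_without <= others_mean
        )
        rows.append(
            {
                "pool": pool,
                "group": group_label,
                "topology_outside": topology_outside,
                "cv_with": cv_with,
                "cv_without": cv_without,
                "cv_ratio": cv_ratio,
                "others_mean_cv": others_mean,
                "flagged": bool(topology_outside and cv_ok),
            }
        )
    return pd.DataFrame(rows).set_index("pool")


def exclude_pools(matrix: pd.DataFrame, pools: list[str]) -> pd.DataFrame:
    """Drop pool columns; values of the remaining pools are untouched."""
    missing = [p for p in pools if p not in matrix.columns]
    if missing:
        raise KeyError(f"cannot exclude absent pool(s): {missing}")
    return matrix.drop(columns=list(pools))
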