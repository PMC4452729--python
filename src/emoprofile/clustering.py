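"""Hierarchical clustering of individual animals and cluster profiling.

Agglomerative clustering with Ward's criterion on squared Euclidean
distances over the oriented z-scored input measures, run separately per
prenatal group but on the pooled-cohort z-scale so cluster profiles are
comparable across groups. Merge heights are the raw within-cluster
sum-of-squares increase of each merge (no square-root transform), so the
heights sum to the total SS of the clustered points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX")


def roman(i: int) -> str:
    """1-based roman numeral label for cluster ids (I..XX)."""
    return _ROMAN[i - 1] if 1 <= i <= len(_ROMAN) else str(i)


@dataclass(frozen=True)
class Dendrogram:
    """Merge schedule of an agglomerative clustering.

    Leaves are numbered ``0..n-1``; the merge created at step ``i``
    (0-based) is node ``n + i``. ``merges`` rows are ``(node_a, node_b,
    height, new_size)`` with height = the Ward objective (within-SS)
    increase of that merge.
    """

    n_leaves: int
    merges: tuple[tuple[int, int, float, int], ...]
    leaf_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a dendrogram over n leaves must have exactly n-1 merges")

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf order for plotting (iterative traversal)."""
        if self.n_leaves == 1:
            return [0]
        children = {self.n_leaves + i: (a, b) for i, (a, b, _, _) in enumerate(self.merges)}
        order, stack = [], [2 * self.n_leaves - 2]
        while stack:
            node = stack.pop()
            if node < self.n_leaves:
                order.append(node)
            else:
                a, b = children[node]
                stack.extend((b, a))
        return order


def distance_matrix(Z: pd.DataFrame | np.ndarray, items: Sequence[str] | None = None) -> np.ndarray:
    """Symmetric matrix of squared Euclidean distances over selected columns.

    Rows with any missing value among the selected items must be removed
    by the caller (see ``complete_rows``); fewer than 3 rows is an error.
    """
    if isinstance(Z, pd.DataFrame):
        X = Z[list(items)].to_numpy(dtype=float) if items is not None else Z.to_numpy(dtype=float)
    else:
        X = np.asarray(Z, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 animals to cluster")
    if np.isnan(X).any():
        raise ValueError("missing values among clustering inputs; drop incomplete rows first")
    return cdist(X, X, metric="sqeuclidean")


def complete_rows(Z: pd.DataFrame, items: Sequence[str]) -> pd.DataFrame:
    """Subset of rows with no missing value among the clustering items."""
    sub = Z[list(items)]
    ok = sub.notna().all(axis=1)
    if (~ok).any():
        logger.warning(
            "excluding %d animal(s) with missing core measures from clustering", int((~ok).sum())
        )
    return sub[ok]


def ward_linkage(D: np.ndarray, leaf_ids: Sequence[str] = ()) -> Dendrogram:
    """Ward agglomeration by the Lance-Williams recurrence on squared distances.

    At every step the pair of clusters whose merge minimally increases the
    total within-cluster sum of squares is joined; the recorded height is
    that SS increase. For singletons the increase is d^2/2, and the
    inter-cluster cost D(A,B) = 2 * deltaSS(A,B) obeys the Lance-Williams
    update ((n_i+n_k) d_ik + (n_j+n_k) d_jk - n_k d_ij) / (n_i+n_j+n_k)
    when initialized with squared Euclidean distances. Ties are broken
    toward the lowest (i, j) pair index, making the schedule deterministic.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < -1e-12):
        raise ValueError("squared distances must be non-negative")
    if np.any(np.abs(np.diag(D)) > 1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if leaf_ids and len(leaf_ids) != n:
        raise ValueError("leaf_ids length must match matrix size")

    d = D.copy().astype(float)
    np.fill_diagonal(d, np.inf)
    sizes = {i: 1 for i in range(n)}
    node_of = {i: i for i in range(n)}  # active row -> dendrogram node id
    active = sorted(sizes)
    merges = []
    for step in range(n - 1):
        # lowest-index tie-break: scan active pairs in order
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                if best is None or d[i, j] < best[0] - 1e-15:
                    best = (d[i, j], i, j)
        cost, i, j = best
        height = cost / 2.0  # D = 2 * deltaSS
        new_size = sizes[i] + sizes[j]
        merges.append((node_of[i], node_of[j], height, new_size))
        # Lance-Williams update into row i
        for k in active:
            if k in (i, j):
                continue
            d_new = (
                (sizes[i] + sizes[k]) * d[i, k]
                + (sizes[j] + sizes[k]) * d[j, k]
                - sizes[k] * cost
            ) / (new_size + sizes[k])
            d[i, k] = d[k, i] = d_new
        sizes[i] = new_size
        node_of[i] = n + step
        active.remove(j)
        d[j, :] = d[:, j] = np.inf
    dend = Dendrogram(n_leaves=n, merges=tuple(merges), leaf_ids=tuple(leaf_ids))
    h = dend.heights
    if np.any(np.diff(h) < -1e-9 * max(1.0, h.max())):
        raise AssertionError("Ward merge heights must be non-decreasing")
    return dend


@dataclass(frozen=True)
class ClusterSolution:
    """A k-cluster labeling cut from a dendrogram.

    ``labels`` maps animal id -> roman cluster label, with clusters
    ordered I..k by ascending mean composite score (ties broken by larger
    size, then first animal id).
    """

    k: int
    labels: Mapping[str, str]
    within_cluster_ss: Mapping[str, float] = field(default_factory=dict)

    def members(self, cluster: str) -> list[str]:
        return [a for a, c in self.labels.items() if c == cluster]


def cut_assignments(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Raw cluster indices (0..k-1, arbitrary order) after undoing the
    last k-1 merges."""
    n = dendrogram.n_leaves
    if not (1 <= k <= n):
        raise ValueError("k must be between 1 and the number of leaves")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (a, b, _, _) in enumerate(dendrogram.merges[: n - k]):
        node = n + i
        parent[find(a)] = node
        parent[find(b)] = node
    roots: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for leaf in range(n):
        r = find(leaf)
        out[leaf] = roots.setdefault(r, len(roots))
    return out


def cut(
    dendrogram: Dendrogram,
    k: int,
    scores: pd.Series | None = None,
) -> ClusterSolution:
    """Cut the dendrogram into k clusters labeled I..k.

    Clusters are ordered by ascending mean composite score when ``scores``
    (indexed by animal id) is given, else by first appearance. Ties break
    toward the larger cluster, then the smallest member id.
    """
    raw = cut_assignments(dendrogram, k)
    ids = dendrogram.leaf_ids or tuple(str(i) for i in range(dendrogram.n_leaves))
    groups: dict[int, list[str]] = {}
    for leaf, c in enumerate(raw):
        groups.setdefault(int(c), []).append(ids[leaf])

    def sort_key(c: int):
        members = groups[c]
        if scores is not None:
            mean_score = float(np.nanmean([scores.get(a, np.nan) for a in members]))
        else:
            mean_score = 0.0
        return (mean_score, -len(members), min(members))

    order = sorted(groups, key=sort_key)
    relabel = {c: roman(i + 1) for i, c in enumerate(order)}
    labels = {ids[leaf]: relabel[int(c)] for leaf, c in enumerate(raw)}
    return ClusterSolution(k=k, labels=labels)


def within_cluster_ss(X: np.ndarray, assignments: np.ndarray) -> dict[int, float]:
    """Within-cluster sum of squares per cluster, from coordinates."""
    X = np.asarray(X, dtype=float)
    out = {}
    for c in np.unique(assignments):
        pts = X[assignments == c]
        out[int(c)] = float(((pts - pts.mean(axis=0)) ** 2).sum())
    return out


def homogeneity_diagnostics(dendrogram: Dendrogram, max_k: int = 10) -> pd.DataFrame:
    """Merge-height gaps supporting the choice of k.

    For each k, ``gap`` is the height jump closed by moving from k to k-1
    clusters: h_{n-k+1} - h_{n-k} (with h_0 = 0). Because Ward heights
    grow toward the root even for structureless data, dominance is judged
    on the *ratio* of consecutive merge heights: a cut at k is flagged
    when the merge it avoids is more than 3x taller than the last merge
    it keeps (unstructured data stays below ~2.5).
    """
    h = np.concatenate([[0.0], np.sort(dendrogram.heights)])
    n = dendrogram.n_leaves
    ks = [k for k in range(2, min(max_k, n) + 1)]
    gaps = [h[n - k + 1] - h[n - k] for k in ks]
    ratios = [
        h[n - k + 1] / h[n - k] if h[n - k] > 0 else np.inf if h[n - k + 1] > 0 else 1.0
        for k in ks
    ]
    return pd.DataFrame(
        {
            "k": ks,
            "merge_height_closed": [h[n - k + 1] for k in ks],
            "gap": gaps,
            "height_ratio": ratios,
            "dominant": [bool(r > 3.0) for r in ratios],
        }
    )


def percent_of_group(size: int, group_total: int) -> int:
    """Cluster size as nearest-integer percent of its prenatal group."""
    if group_total <= 0:
        raise ValueError("group total must be positive")
    return int(round(100.0 * size / group_total))


def profile(
    solution: ClusterSolution,
    cohort: pd.DataFrame,
    scores: pd.Series,
    core_vars: Sequence[str],
    predicted_vars: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-cluster summaries over core and held-out variables.

    Returns one row per cluster: size, nearest-integer percent of the
    group, mean +/- sem of the composite score and of every core (input)
    measure, mean +/- sem of every predicted (held-out) variable with
    pairwise deletion, and the ST/UE/PE environment composition.
    """
    df = cohort.set_index("animal_id")
    total = len(solution.labels)
    rows = []
    for c in sorted(set(solution.labels.values()), key=_ROMAN.index):
        members = solution.members(c)
        sub = df.loc[members]
        row: dict = {
            "cluster": c,
            "size": len(members),
            "percent_of_group": percent_of_group(len(members), total),
        }
        svals = scores.loc[[m for m in members if m in scores.index]].dropna()
        row["score_mean"] = float(svals.mean())
        row["score_sem"] = float(svals.std(ddof=1) / np.sqrt(len(svals))) if len(svals) > 1 else 0.0
        for kind, names in (("core", core_vars), ("pred", predicted_vars)):
            for name in names:
                vals = pd.to_numeric(sub[name], errors="coerce").dropna()
                row[f"{kind}_{name}_mean"] = float(vals.mean()) if len(vals) else np.nan
                row[f"{kind}_{name}_sem"] = (
                    float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
                )
        env = sub["environment"].value_counts(normalize=True)
        for e in ("ST", "UE", "PE"):
            row[f"env_{e}"] = float(env.get(e, 0.0))
        rows.append(row)
    out = pd.DataFrame(rows)
    # nearest-integer percents can sum to 100 +/- 1; carried as-is
    return out


def to_newick(dendrogram: Dendrogram) -> str:
    """Dendrogram as a Newick string with merge heights as node depths.

    A child's branch length is the height of its parent merge minus the
    height of the merge that created the child (leaves have height 0).
    """
    n = dendrogram.n_leaves
    ids = dendrogram.leaf_ids or tuple(str(i) for i in range(n))
    height = {i: 0.0 for i in range(n)}
    children = {}
    for i, (a, b, h, _) in enumerate(dendrogram.merges):
        node = n + i
        height[node] = h
        children[node] = (a, b)

    def render(node: int, parent_h: float) -> str:
        bl = max(parent_h - height[node], 0.0)
        if node < n:
            return f"{ids[node]}:{bl:.6g}"
        a, b = children[node]
        return f"({render(a, height[node])},{render(b, height[node])}):{bl:.6g}"

    root = 2 * n - 2
    return f"({render(children[root][0], height[root])},{render(children[root][1], height[root])})root;"


class WardClusterer(BaseEstimator, ClusterMixin):
    """Ward hierarchical clustering as a scikit-learn estimator.

    ``fit`` builds the squared-Euclidean Ward dendrogram over the rows of
    X (oriented z-scores of the core measures) and cuts it into
    ``n_clusters`` clusters. ``labels_`` holds integer labels; the
    roman-numeral, score-ordered solution comes from ``solution(scores)``.

    Attributes
    ----------
    dendrogram_ : Dendrogram
    labels_ : ndarray of int
    heights_ : ndarray
        Merge heights (within-SS increases), non-decreasing.
    """

    def __init__(self, n_clusters: int = 4):
        self.n_clusters = n_clusters

    def fit(self, X, y=None) -> "WardClusterer":
        if isinstance(X, pd.DataFrame):
            ids = tuple(str(i) for i in X.index)
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            ids = tuple(str(i) for i in range(arr.shape[0]))
        D = distance_matrix(arr)
        self.dendrogram_ = ward_linkage(D, leaf_ids=ids)
        self.heights_ = self.dendrogram_.heights
        self.labels_ = cut_assignments(self.dendrogram_, self.n_clusters)
        self.n_features_in_ = arr.shape[1]
        return self

    def solution(self, scores: pd.Series | None = None) -> ClusterSolution:
        check_is_fitted(self, "dendrogram_")
        return cut(self.dendrogram_, self.n_clusters, scores=scores)

    def diagnostics(self, max_k: int = 10) -> pd.DataFrame:
        check_is_fitted(self, "dendrogram_")
        return homogeneity_diagnostics(self.dendrogram_, max_k=max_k)
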