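"""Age-structured behavioral clustering.

Fly lifetimes are partitioned into 10-day age groups; each group is
summarized by the 6-behavior frame-share vector averaged across the flies
alive in it.  Groups are compared either by the Euclidean distance between
these averaged behavior levels or by optimal-matching (edit) distance
between representative categorical behavior sequences, then clustered
agglomeratively into a dendrogram (Newick-exportable) with optional
bootstrap support values from resampling flies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .core import ValidationError

__all__ = [
    "AgeGroupProfile",
    "LinkageTree",
    "age_group_matrix",
    "euclidean_dist",
    "om_distance",
    "om_distance_matrix",
    "linkage_tree",
    "cut_tree",
    "auto_k",
    "tree_to_newick",
    "bootstrap_support",
    "modal_hour_sequences",
]


@dataclass
class AgeGroupProfile:
    """Averaged behavior levels for one 10-day (by default) age interval."""

    start_day: float
    end_day: float
    shares: np.ndarray  # 6-vector, sums to 1
    n_flies: int

    @property
    def label(self) -> str:
        return f"{int(self.start_day)}-{int(self.end_day)}"


def age_group_matrix(
    fly_day_counts: list[pd.DataFrame],
    width_days: float = 10.0,
) -> list[AgeGroupProfile]:
    """Build age-group profiles from per-fly daily behavior counts.

    Each element of *fly_day_counts* is one fly's table with a day-of-life
    index and six behavior-count columns (0..5 in canonical label order).
    For every age interval, each fly with frames contributes its own share
    vector; the profile is the mean of those vectors.  Intervals with no
    data are dropped.
    """
    if not fly_day_counts:
        raise ValidationError("age_group_matrix needs at least one fly")
    max_day = max(int(t.index.max()) for t in fly_day_counts if len(t))
    profiles = []
    start = 0.0
    while start < max_day:
        end = start + width_days
        shares = []
        for table in fly_day_counts:
            rows = table[(table.index > start) & (table.index <= end)]
            counts = rows.to_numpy().sum(axis=0)
            total = counts.sum()
            if total > 0:
                shares.append(counts / total)
        if shares:
            profiles.append(
                AgeGroupProfile(start, end, np.mean(shares, axis=0), len(shares))
            )
        start = end
    if not profiles:
        raise ValidationError("no age interval contains any classified frames")
    return profiles


def euclidean_dist(profiles: list[AgeGroupProfile]) -> np.ndarray:
    """Pairwise Euclidean distance matrix of the 6-vector behavior levels."""
    if len(profiles) < 2:
        raise ValidationError("need at least 2 profiles")
    X = np.vstack([p.shares for p in profiles])
    return squareform(pdist(X, metric="euclidean"))


# ---------------------------------------------------------------------------
# Optimal matching (edit distance for categorical state sequences)
# ---------------------------------------------------------------------------

def om_distance(
    seq_a,
    seq_b,
    sub_cost: float = 2.0,
    indel_cost: float = 1.0,
) -> float:
    """Optimal-matching dissimilarity between two label sequences.

    Classical constant-cost scheme: substitutions cost ``sub_cost``,
    insertions/deletions ``indel_cost``; the distance is the minimum total
    cost of an edit script turning one sequence into the other (dynamic
    programming).  With sub_cost >= 2 * indel_cost this reduces to
    indel_cost times the Levenshtein distance restricted to indels.
    """
    if sub_cost <= 0 or indel_cost <= 0:
        raise ValidationError("OM costs must be positive")
    a = np.asarray(seq_a)
    b = np.asarray(seq_b)
    n, m = len(a), len(b)
    prev = indel_cost * np.arange(m + 1, dtype=float)
    for i in range(1, n + 1):
        cur = np.empty(m + 1)
        cur[0] = i * indel_cost
        sub = prev[:-1] + np.where(b == a[i - 1], 0.0, sub_cost)
        for j in range(1, m + 1):
            cur[j] = min(sub[j - 1], prev[j] + indel_cost, cur[j - 1] + indel_cost)
        prev = cur
    return float(prev[m])


def om_distance_matrix(
    sequences: list,
    sub_cost: float = 2.0,
    indel_cost: float = 1.0,
    normalize: bool = False,
) -> np.ndarray:
    """Pairwise OM distances; optionally divided by the longer length."""
    k = len(sequences)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = om_distance(sequences[i], sequences[j], sub_cost, indel_cost)
            if normalize:
                longest = max(len(sequences[i]), len(sequences[j]))
                d = d / longest if longest else 0.0
            D[i, j] = D[j, i] = d
    return D


def modal_hour_sequences(
    count_matrices_per_group: list[np.ndarray],
) -> list[np.ndarray]:
    """Representative label sequence per age group: the modal behavior of
    each clock hour, concatenated hour 0..23.

    Input: per group, a (6, 24) array of behavior counts by hour.
    """
    out = []
    for counts in count_matrices_per_group:
        counts = np.asarray(counts)
        if counts.shape != (6, 24):
            raise ValidationError("expected a (6, 24) count array per group")
        out.append(counts.argmax(axis=0).astype(np.int8))
    return out


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class LinkageTree:
    """Agglomerative merge tree over age-group leaves."""

    Z: np.ndarray  # scipy linkage matrix
    labels: list[str]
    supports: dict[frozenset, float] | None = None  # leaf-set -> bootstrap support

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]

    def clades(self) -> list[frozenset]:
        """Leaf-label set of every internal node."""
        sets: list[frozenset] = []
        members: dict[int, frozenset] = {i: frozenset([self.labels[i]]) for i in range(self.n_leaves)}
        for k, (a, b, _h, _n) in enumerate(self.Z):
            merged = members[int(a)] | members[int(b)]
            members[self.n_leaves + k] = merged
            sets.append(merged)
        return sets


def linkage_tree(
    dist: np.ndarray,
    labels: list[str] | None = None,
    method: str = "average",
) -> LinkageTree:
    """Agglomerative clustering of a symmetric distance matrix.

    Methods: average (default), complete, ward.  Ties are broken
    deterministically (lowest pair index first).
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9) or (D < 0).any():
        raise ValidationError("distance matrix must be symmetric and non-negative")
    if method not in ("average", "complete", "ward"):
        raise ValidationError(f"unsupported linkage method {method!r}")
    n = D.shape[0]
    labels = labels if labels is not None else [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValidationError("label count differs from matrix size")
    Z = hierarchy.linkage(squareform(D, checks=False), method=method)
    return LinkageTree(Z, list(labels))


def cut_tree(tree: LinkageTree, k: int) -> np.ndarray:
    """Cluster assignment (0-based) of each leaf when cutting into k clusters."""
    if not 1 <= k <= tree.n_leaves:
        raise ValidationError(f"k must be in [1, {tree.n_leaves}]")
    flat = hierarchy.fcluster(tree.Z, t=k, criterion="maxclust")
    return flat - 1


def auto_k(tree: LinkageTree, k_max: int | None = None) -> int:
    """Cluster count at the largest relative gap between merge heights.

    For k clusters the cut sits between the (n-k)-th and (n-k+1)-th merge;
    the chosen k (2 <= k <= n-1) maximizes
    (h[n-k+1] - h[n-k]) / max(h[n-k], eps).
    """
    n = tree.n_leaves
    if n < 3:
        return n
    h = np.sort(tree.heights)
    eps = max(1e-12, 1e-9 * h[-1])
    best_k, best_gap = 2, -np.inf
    upper = min(n - 1, k_max) if k_max else n - 1
    for k in range(2, upper + 1):
        low = h[n - k - 1]  # merge that forms k clusters
        high = h[n - k]  # merge that destroys them
        gap = (high - low) / max(low, eps)
        if gap > best_gap:
            best_k, best_gap = k, gap
    return best_k


def tree_to_newick(tree: LinkageTree) -> str:
    """Newick text with branch lengths (parent height - child height), leaf
    names from the tree labels, and bootstrap supports (if present) as
    internal node labels."""
    n = tree.n_leaves
    clades = tree.clades() if tree.supports else None

    def node_text(idx: int, parent_height: float) -> str:
        if idx < n:
            return f"{tree.labels[idx]}:{parent_height:.6g}"
        k = idx - n
        a, b, h, _cnt = tree.Z[k]
        inner = f"({node_text(int(a), h)},{node_text(int(b), h)})"
        support = ""
        if tree.supports is not None and clades is not None:
            val = tree.supports.get(clades[k])
            if val is not None:
                support = f"{val:.2f}"
        return f"{inner}{support}:{parent_height - h:.6g}"

    root = 2 * n - 2
    if n == 1:
        return f"{tree.labels[0]};"
    _a, _b, root_h, _c = tree.Z[-1]
    a, b = int(tree.Z[-1][0]), int(tree.Z[-1][1])
    return f"({node_text(a, root_h)},{node_text(b, root_h)});"


def bootstrap_support(
    fly_day_counts: list[pd.DataFrame],
    width_days: float = 10.0,
    B: int = 100,
    seed: int = 0,
    method: str = "average",
) -> LinkageTree:
    """Bootstrap support for the age-group dendrogram.

    Flies are resampled with replacement B times; each replicate's profiles
    and tree are rebuilt and a node's support is the fraction of replicates
    (with the same leaf set) in which its leaf set reappears as a clade.
    """
    if B < 1:
        raise ValidationError("bootstrap needs B >= 1")
    if len(fly_day_counts) < 2:
        import warnings

        warnings.warn("bootstrap support over a single fly is degenerate")
    profiles = age_group_matrix(fly_day_counts, width_days)
    base = linkage_tree(euclidean_dist(profiles), [p.label for p in profiles], method)
    base_clades = base.clades()
    hits = {c: 0 for c in base_clades}
    valid = 0
    rng = np.random.default_rng(seed)
    n_flies = len(fly_day_counts)
    for _ in range(B):
        idx = rng.integers(0, n_flies, n_flies)
        try:
            prof_b = age_group_matrix([fly_day_counts[i] for i in idx], width_days)
        except ValidationError:
            continue
        labels_b = [p.label for p in prof_b]
        if set(labels_b) != set(base.labels) or len(prof_b) < 2:
            continue  # replicate lost an age group entirely
        tree_b = linkage_tree(euclidean_dist(prof_b), labels_b, method)
        rep_clades = set(tree_b.clades())
        valid += 1
        for c in base_clades:
            if c in rep_clades:
                hits[c] += 1
    supports = {c: (hits[c] / valid if valid else np.nan) for c in base_clades}
    base.supports = supports
    return base
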