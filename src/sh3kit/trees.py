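"""Comparing interaction-profile dendrograms with sequence dendrograms.

An interaction profile is one row per domain variant (bait) of PCA scores
across preys; a sequence dendrogram comes from pairwise identity on an
alignment of the same domains (distance = 1 - identity). Both distance
matrices are clustered hierarchically (complete linkage by default) and the
agreement between trees is the cophenetic correlation: the Pearson
correlation of the two trees' merge-height distances over all leaf pairs.
Significance comes from permuting the assignment of domains to profiles and
recomputing the correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .seqstruct import pairwise_identity


@dataclass
class Dendrogram:
    """Merge tree over labeled leaves (scipy linkage encoding)."""

    labels: list[str]
    linkage_matrix: np.ndarray
    method: str = "complete"

    def cophenetic_vector(self) -> np.ndarray:
        """Condensed pairwise merge-height distances, in `labels` order."""
        return hierarchy.cophenet(self.linkage_matrix)

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def rec(node, parent_dist):
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_dist - node.dist:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{parent_dist - node.dist:.6g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


@dataclass(frozen=True)
class CopheneticResult:
    r: float
    n_pairs: int
    p: float
    n_perm: int
    seed: int


def profile_distance(profiles: pd.DataFrame, fill_value: float = 0.0) -> pd.DataFrame:
    """Euclidean distances between profile rows; missing entries imputed
    with `fill_value` (the post-normalization plate background)."""
    if profiles.shape[0] < 2:
        raise ValueError("need at least two profile rows")
    m = profiles.fillna(fill_value).to_numpy(dtype=float)
    d = squareform(pdist(m, metric="euclidean"))
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def sequence_distance(rows: dict[str, str]) -> pd.DataFrame:
    """Distance = 1 - pairwise identity over an aligned sequence set."""
    ids = list(rows)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - pairwise_identity(rows[ids[i]], rows[ids[j]])
    return pd.DataFrame(d, index=ids, columns=ids)


def cluster(dist: pd.DataFrame, method: str = "complete") -> Dendrogram:
    """Agglomerative clustering of a symmetric zero-diagonal distance matrix."""
    d = dist.to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    Z = hierarchy.linkage(squareform(d, checks=False), method=method)
    return Dendrogram(labels=list(dist.index), linkage_matrix=Z, method=method)


def cophenetic_correlation(d1: Dendrogram, d2: Dendrogram) -> float:
    """Pearson correlation of cophenetic distances over all leaf pairs."""
    if set(d1.labels) != set(d2.labels):
        raise ValueError("dendrograms have different leaf sets")
    if len(d1.labels) < 3:
        raise ValueError("cophenetic correlation needs at least three leaves")
    v1 = d1.cophenetic_vector()
    # reorder d2's condensed vector to d1's label order
    order = [d2.labels.index(lab) for lab in d1.labels]
    m2 = squareform(d2.cophenetic_vector())[np.ix_(order, order)]
    v2 = squareform(m2, checks=False)
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("constant cophenetic distances: correlation undefined")
    r, _ = stats.pearsonr(v1, v2)
    return float(r)


def permutation_test(
    profiles: pd.DataFrame,
    aligned: dict[str, str],
    n_perm: int = 10_000,
    seed: int = 0,
    method: str = "complete",
    fill_value: float = 0.0,
) -> CopheneticResult:
    """Cophenetic correlation with a label-permutation null.

    The null randomizes the assignment of domains to interaction profiles
    (equivalently, relabels the profile tree's leaves) and recomputes the
    correlation. One-tailed p with add-one smoothing:
    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = list(profiles.index)
    if set(labels) != set(aligned):
        raise ValueError("profile rows and aligned sequences have different ids")
    prof_tree = cluster(profile_distance(profiles, fill_value), method=method)
    seq_tree = cluster(sequence_distance(aligned), method=method)
    r_obs = cophenetic_correlation(prof_tree, seq_tree)

    # Relabeling the profile tree permutes rows/cols of its cophenetic
    # matrix; the tree itself is unchanged, so the null is computed by
    # permuting indices of the fixed cophenetic matrices.
    order = [seq_tree.labels.index(lab) for lab in prof_tree.labels]
    c_prof = squareform(prof_tree.cophenetic_vector())
    c_seq = squareform(seq_tree.cophenetic_vector())[np.ix_(order, order)]
    v_seq = squareform(c_seq, checks=False)
    rng = np.random.default_rng(seed)
    n = len(labels)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        v_perm = squareform(c_prof[np.ix_(perm, perm)], checks=False)
        r_perm, _ = stats.pearsonr(v_perm, v_seq)
        if r_perm >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return CopheneticResult(r=r_obs, n_pairs=n * (n - 1) // 2, p=float(p),
                            n_perm=n_perm, seed=seed)
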