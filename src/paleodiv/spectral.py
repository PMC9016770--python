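"""Spectral clade detection from the tree's modified graph Laplacian.

The tree is treated as a weighted graph on all of its vertices (tips and
internal nodes) with edge weight 1 / branch length between adjacent vertices,
so long stems connect weakly. The Laplacian L = D - W is symmetric positive
semidefinite; the number of well-separated clades is read off the eigengap
of the ascending spectrum, and tips are partitioned by k-means on the
leading eigenvectors (standard spectral clustering, deterministic seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.cluster import KMeans

from .phylo import Phylogeny

__all__ = [
    "SpectralProfile", "laplacian_spectrum", "eigengap_cluster_count",
    "cluster_assignment", "cluster_consistency",
]

_MIN_LEN = 1e-9    # floor on branch lengths when inverting


@dataclass
class SpectralProfile:
    eigenvalues: np.ndarray        # descending, >= 0
    density: object                # Gaussian KDE over log eigenvalues
    eigengaps: np.ndarray          # ascending-order successive differences
    suggested_k: int


def _laplacian(tree: Phylogeny) -> tuple[np.ndarray, list]:
    nodes = list(tree.preorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    for node in nodes:
        if node.parent is None:
            continue
        i, j = index[id(node)], index[id(node.parent)]
        w = 1.0 / max(node.length, _MIN_LEN)
        W[i, j] = W[j, i] = w
    L = np.diag(W.sum(axis=1)) - W
    return L, nodes


def laplacian_spectrum(tree: Phylogeny, max_k: int = 10) -> SpectralProfile:
    """Eigendecomposition of the modified graph Laplacian plus the smoothed
    spectral-density profile (kernel density over log eigenvalues)."""
    L, _ = _laplacian(tree)
    vals = np.linalg.eigvalsh(L)
    vals = np.clip(vals, 0.0, None)
    asc = np.sort(vals)
    desc = asc[::-1]
    logvals = np.log(asc[asc > 1e-12])
    density = gaussian_kde(logvals) if logvals.size > 1 else None
    gaps = np.diff(asc)
    k = eigengap_from_values(asc, max_k)
    return SpectralProfile(eigenvalues=desc, density=density,
                           eigengaps=gaps, suggested_k=k)


def eigengap_from_values(ascending: np.ndarray, max_k: int = 10,
                         ratio_floor: float = 2.0) -> int:
    """Cluster count from the ascending Laplacian spectrum.

    The gap statistic is the ratio lambda_{k+1} / lambda_k (scale-free;
    absolute differences are dominated by the upper spectrum on weighted
    tree graphs). k clusters leave lambda_k near zero and lambda_{k+1}
    of order one, so the ratio peaks at the cluster count. k* = 1 when no
    ratio among the leading eigenvalues exceeds ratio_floor (low signal).
    """
    m = min(max_k, ascending.size - 1)
    if m < 2:
        return 1
    lam = np.maximum(ascending[1: m + 1], 1e-300)   # drop the zero mode
    ratios = lam[1:] / lam[:-1]                     # ratio at k = 2..m
    k_best = int(np.argmax(ratios)) + 2
    return k_best if ratios.max() >= ratio_floor else 1


def eigengap_cluster_count(profile: SpectralProfile, max_k: int = 10) -> int:
    """k* = position of the largest gap among the leading eigenvalues."""
    asc = profile.eigenvalues[::-1]
    return eigengap_from_values(asc, max_k)


def cluster_assignment(tree: Phylogeny, k: int, seed: int = 0) -> dict[str, int]:
    """Partition tips into k groups by k-means on the leading eigenvectors."""
    if k < 1:
        raise ValueError("k must be >= 1")
    tips = tree.tip_labels
    if k == 1:
        return {t: 0 for t in tips}
    if k >= len(tips):
        return {t: i for i, t in enumerate(tips)}
    L, nodes = _laplacian(tree)
    vals, vecs = np.linalg.eigh(L)
    emb = vecs[:, :k]
    tip_rows = [i for i, n in enumerate(nodes) if n.is_tip]
    X = emb[tip_rows]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    return {nodes[i].label: int(lab) for i, lab in zip(tip_rows, labels)}


def _canonical(partition: dict[str, int]) -> frozenset:
    groups: dict[int, set] = {}
    for tip, g in partition.items():
        groups.setdefault(g, set()).add(tip)
    return frozenset(frozenset(g) for g in groups.values())


def cluster_consistency(trees, k: int, n_reps: int = 100,
                        seed: int = 0) -> tuple[float, float]:
    """Share of applications returning the modal tip partition.

    Applies cluster_assignment n_reps times (varying the k-means seed) to
    each tree; returns (mean, sd) over trees of the per-tree share of
    applications that produced the overall modal partition.
    """
    trees = list(trees)
    if not trees:
        raise ValueError("empty tree collection")
    per_tree: list[list[frozenset]] = []
    counts: dict[frozenset, int] = {}
    for ti, tree in enumerate(trees):
        parts = []
        for rep in range(n_reps):
            p = _canonical(cluster_assignment(tree, k, seed=seed + 977 * ti + rep))
            parts.append(p)
            counts[p] = counts.get(p, 0) + 1
        per_tree.append(parts)
    modal = max(counts, key=counts.get)
    shares = np.array([
        sum(p == modal for p in parts) / len(parts) for parts in per_tree])
    return float(shares.mean()), float(shares.std())
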