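"""Hierarchical clustering, flat cuts and low-stress MDS maps.

Complete linkage is implemented directly (Lance-Williams max update) so the
merge order is deterministic: among equal-distance candidates the pair whose
combined leaf set has the lexicographically smallest (min leaf index, max
leaf index) wins.  scipy's linkage machinery is still used downstream for
cophenetic distances and flat cuts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import cophenet, fcluster
from scipy.spatial.distance import squareform
from sklearn.manifold import MDS
from sklearn.metrics import adjusted_rand_score

from epr.distance import DistanceMatrix

#: Flat-cut presets: phylum-level, genus-level and the finer within-genus cut.
PRESET_THRESHOLDS: dict[str, float] = {"phylum": 0.7, "genus": 0.3, "inner": 0.15}


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree.

    ``merges[k] = (a, b, height)`` joins clusters ``a`` and ``b`` into
    cluster ``m + k``; ids below ``m`` are leaves (indices into ``leaves``).
    Complete linkage guarantees non-decreasing heights.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise ValueError("a dendrogram over m leaves needs exactly m-1 merges")

    @property
    def linkage_matrix(self) -> np.ndarray:
        """scipy-format (m-1, 4) linkage array."""
        m = len(self.leaves)
        sizes = {i: 1 for i in range(m)}
        z = np.zeros((m - 1, 4))
        for k, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[m + k] = size
            z[k] = [a, b, h, size]
        return z

    def cophenetic(self) -> np.ndarray:
        """Square matrix of leaf-pair merge heights."""
        return squareform(cophenet(self.linkage_matrix))


@dataclass(frozen=True)
class ClusterAssignment:
    labels: dict[str, int]
    threshold: float


@dataclass(frozen=True)
class Embedding:
    coords: np.ndarray
    stress: float
    n_init: int
    seed: int


def complete_linkage(d: DistanceMatrix) -> Dendrogram:
    """Agglomerate by the maximum inter-cluster pairwise distance."""
    dist = np.asarray(d.values, dtype=float)
    if np.isnan(dist).any():
        raise ValueError("distance matrix contains NaN")
    m = len(d.labels)
    if m < 2:
        raise ValueError("need at least 2 leaves")

    # active cluster id -> (min leaf index, max leaf index) for tie-breaking
    span: dict[int, tuple[int, int]] = {i: (i, i) for i in range(m)}
    inter: dict[frozenset[int], float] = {
        frozenset((i, j)): dist[i, j] for i in range(m) for j in range(i + 1, m)
    }
    merges: list[tuple[int, int, float]] = []
    active = set(range(m))
    next_id = m
    while len(active) > 1:
        best: tuple[float, int, int] | None = None
        best_pair: tuple[int, int] | None = None
        for pair, dval in inter.items():
            a, b = sorted(pair)
            mn = min(span[a][0], span[b][0])
            mx = max(span[a][1], span[b][1])
            key = (dval, mn, mx)
            if best is None or key < best:
                best = key
                best_pair = (a, b)
        assert best is not None and best_pair is not None
        a, b = best_pair
        h = best[0]
        merges.append((a, b, h))
        new = next_id
        next_id += 1
        active.discard(a)
        active.discard(b)
        for c in active:
            inter[frozenset((new, c))] = max(
                inter.pop(frozenset((a, c))), inter.pop(frozenset((b, c)))
            )
        inter.pop(frozenset((a, b)))
        span[new] = (min(span[a][0], span[b][0]), max(span[a][1], span[b][1]))
        active.add(new)
    return Dendrogram(leaves=tuple(d.labels), merges=tuple(merges))


def flat_clusters(dendrogram: Dendrogram, threshold: float) -> ClusterAssignment:
    """Cut the tree so every cluster's maximum cophenetic distance <= threshold.

    Cluster indices are assigned in leaf order, starting at 1.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    raw = fcluster(dendrogram.linkage_matrix, t=threshold, criterion="distance")
    relabel: dict[int, int] = {}
    labels: dict[str, int] = {}
    for leaf, cluster in zip(dendrogram.leaves, raw):
        if cluster not in relabel:
            relabel[cluster] = len(relabel) + 1
        labels[leaf] = relabel[cluster]
    return ClusterAssignment(labels=labels, threshold=float(threshold))


def _make_mds(random_state: int) -> MDS:
    try:  # sklearn >= 1.9
        return MDS(
            n_components=2,
            metric="precomputed",
            metric_mds=True,
            init="random",
            n_init=1,
            normalized_stress=False,
            random_state=random_state,
        )
    except TypeError:  # older API
        return MDS(
            n_components=2,
            dissimilarity="precomputed",
            metric=True,
            n_init=1,
            normalized_stress=False,
            random_state=random_state,
        )


def mds_embed(d: DistanceMatrix, n_init: int, seed: int) -> Embedding:
    """Best-of-``n_init`` metric MDS into the plane.

    Restart seeds are drawn from a single seeded stream whose prefixes are
    stable, so the best-of-k stress is non-increasing in k for a fixed seed.
    """
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    if d.m < 3:
        raise ValueError("2-D embedding needs at least 3 points")
    restart_seeds = np.random.SeedSequence(seed).generate_state(n_init)
    best_coords: np.ndarray | None = None
    best_stress = np.inf
    for s in restart_seeds:
        model = _make_mds(random_state=int(s) % (2**32))
        coords = model.fit_transform(d.values)
        if model.stress_ < best_stress:
            best_stress = float(model.stress_)
            best_coords = coords
    assert best_coords is not None
    return Embedding(coords=best_coords, stress=best_stress, n_init=n_init, seed=seed)


def congruence(
    assignment: ClusterAssignment | Mapping[str, int], truth: Mapping[str, object]
) -> float:
    """Adjusted Rand index between a flat clustering and reference labels."""
    labels = assignment.labels if isinstance(assignment, ClusterAssignment) else assignment
    if set(labels) != set(truth):
        raise ValueError("cluster assignment and truth must cover the same genomes")
    keys = sorted(labels)
    return float(adjusted_rand_score([str(truth[k]) for k in keys], [labels[k] for k in keys]))


def plot_dendrogram(dendrogram: Dendrogram, path: str, threshold: float | None = None) -> None:
    """Basic rectangular dendrogram plot."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

    fig, ax = plt.subplots(figsize=(max(6, len(dendrogram.leaves) * 0.25), 6))
    scipy_dendrogram(
        dendrogram.linkage_matrix, labels=list(dendrogram.leaves), ax=ax, leaf_rotation=90
    )
    if threshold is not None:
        ax.axhline(threshold, color="grey", linestyle="--", linewidth=1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
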