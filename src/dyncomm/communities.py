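"""Dynamic communities from a correlation matrix.

A correlation matrix is turned into a dissimilarity matrix (1 - DCC,
range [0, 2]), clustered agglomeratively with WPGMA (weighted pair-group
method with arithmetic mean), and the dendrogram is cut into a requested
number of communities by undoing the last merges.  A community is a
block of residues whose fluctuations are mutually cohesive.

WPGMA is implemented here rather than delegated so that tie-breaking is
deterministic and documented: among candidate pairs at the minimal
distance, the pair whose clusters have the lexicographically smallest
(min leaf index, second min leaf index) is merged.  On matrices with
distinct distances the merge heights coincide with
``scipy.cluster.hierarchy.linkage(method="weighted")``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .enm import CorrelationMatrix
from .errors import InputError

logger = logging.getLogger(__name__)

#: community counts swept by default, following the 2..10 convention
NC_RANGE = tuple(range(2, 11))


@dataclass
class DistanceCorrelationMatrix:
    """1 - DCC dissimilarity matrix: symmetric, zero diagonal, [0, 2]."""

    matrix: np.ndarray
    source: str = "gnm"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InputError("distance matrix must be square")
        if not np.allclose(m, m.T, atol=1e-8):
            raise InputError("distance matrix must be symmetric")
        if m.min() < -1e-8 or m.max() > 2 + 1e-8:
            raise InputError("distance-correlation entries must lie in [0, 2]")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


@dataclass
class Dendrogram:
    """Merge list in scipy linkage convention.

    Row k of ``merges`` is (cluster a, cluster b, height, size): leaves
    are clusters 0..N-1 and the k-th merge creates cluster N+k.
    """

    merges: np.ndarray  # (N-1, 4)
    n_leaves: int

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass
class CommunityPartition:
    """Per-node community labels 1..n_c, canonically numbered.

    Community 1 contains the lowest node index, community 2 the lowest
    index not in community 1, and so on; partitions are therefore
    directly comparable across runs.
    """

    labels: np.ndarray  # (N,) ints in 1..n_c
    n_c: int
    residue_keys: list | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if len(present) != self.n_c or present[0] != 1 or present[-1] != self.n_c:
            raise InputError(
                f"labels must use exactly the values 1..{self.n_c}; "
                f"found {present.tolist()}"
            )

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[0]


def canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Renumber arbitrary labels so communities appear in node-index order."""
    raw = np.asarray(raw)
    mapping: dict = {}
    out = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def distance_transform(c: CorrelationMatrix) -> DistanceCorrelationMatrix:
    """Convert correlations to dissimilarities: entrywise 1 - DCC."""
    d = 1.0 - c.matrix
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return DistanceCorrelationMatrix(matrix=d, source=c.source)


def wpgma_linkage(d: DistanceCorrelationMatrix | np.ndarray) -> Dendrogram:
    """WPGMA agglomerative clustering of a dissimilarity matrix.

    At each step the pair of clusters at minimal distance is merged and
    the merged cluster's distance to any other cluster C is the plain
    average (d(A,C) + d(B,C)) / 2, independent of cluster sizes.
    """
    mat = d.matrix if isinstance(d, DistanceCorrelationMatrix) else np.asarray(d, float)
    n = mat.shape[0]
    if n < 2:
        raise InputError("need at least 2 nodes to cluster")
    dist = mat.astype(float).copy()
    np.fill_diagonal(dist, np.inf)
    active = list(range(n))          # positions into dist rows
    cluster_id = list(range(n))      # scipy-style cluster ids
    min_leaf = list(range(n))        # smallest leaf index per cluster
    sizes = [1] * n
    merges = np.empty((n - 1, 4))
    prev_h = -np.inf
    warned = False
    for step in range(n - 1):
        sub = dist[np.ix_(active, active)]
        h = sub.min()
        # tie rule: among minimal pairs pick lexicographically smallest
        # (min leaf, other min leaf)
        cand = np.argwhere(sub == h)
        cand = cand[cand[:, 0] < cand[:, 1]]
        keys = sorted(
            (tuple(sorted((min_leaf[active[i]], min_leaf[active[j]]))), i, j)
            for i, j in cand
        )
        _, pi, pj = keys[0]
        a, b = active[pi], active[pj]
        if h < prev_h - 1e-12 and not warned:
            logger.warning(
                "non-monotone merge heights (%.6g after %.6g): the input "
                "dissimilarity is not ultrametric; WPGMA proceeds regardless",
                h, prev_h,
            )
            warned = True
        prev_h = max(prev_h, h)
        merges[step] = (cluster_id[a], cluster_id[b], h, sizes[a] + sizes[b])
        # WPGMA update: merged cluster kept in slot a
        new_row = (dist[a] + dist[b]) / 2.0
        dist[a, :] = new_row
        dist[:, a] = new_row
        dist[a, a] = np.inf
        cluster_id[a] = n + step
        min_leaf[a] = min(min_leaf[a], min_leaf[b])
        sizes[a] = sizes[a] + sizes[b]
        active.remove(b)
    return Dendrogram(merges=merges, n_leaves=n)


def cut_to_communities(
    dg: Dendrogram, n_c: int, residue_keys: list | None = None
) -> CommunityPartition:
    """Cut a dendrogram into exactly ``n_c`` communities.

    Undoes the last ``n_c - 1`` merges: nodes connected by the first
    N - n_c merges share a community.
    """
    n = dg.n_leaves
    if not 2 <= n_c <= min(10, n):
        raise InputError(f"n_c must be in [2, {min(10, n)}], got {n_c}")
    comp = np.arange(n)
    roots = {i: i for i in range(n)}  # cluster id -> representative leaf
    for step in range(n - n_c):
        a, b = int(dg.merges[step, 0]), int(dg.merges[step, 1])
        ra, rb = roots.pop(a), roots.pop(b)
        comp[comp == comp[rb]] = comp[ra]
        roots[n + step] = ra
    labels = canonical_labels(comp)
    return CommunityPartition(labels=labels, n_c=n_c, residue_keys=residue_keys)


def detect_communities(
    c: CorrelationMatrix, n_c: int, residue_keys: list | None = None
) -> CommunityPartition:
    """Full pipeline: 1 - DCC transform, WPGMA, cut at ``n_c`` communities."""
    return cut_to_communities(
        wpgma_linkage(distance_transform(c)), n_c, residue_keys=residue_keys
    )
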