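"""Agreement metrics between two correlation analyses of one protein.

Three complementary views are quantified:

* **Cohen's kappa** between community partitions at each community count
  N_c, K = (p_o - p_e) / (1 - p_e), after matching the arbitrary
  community labels of the two partitions by optimal assignment on their
  confusion matrix (community IDs from independent clusterings carry no
  meaning, so kappa without alignment would be arbitrary).
* **Closeness centrality correlation** on the complete weighted residue
  network whose edge weights are the 1 - DCC dissimilarities: centrality
  of a node is the reciprocal of the sum of its shortest-path lengths to
  all other nodes; the two centrality profiles are compared by Pearson
  correlation (Spearman available as an option).
* **RMSIP** between the n leading singular vectors of the two correlation
  matrices: 1 for identical subspaces, 0 for orthogonal ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from scipy.optimize import linear_sum_assignment
from scipy.sparse.csgraph import csgraph_from_dense, dijkstra

from .communities import (
    NC_RANGE,
    CommunityPartition,
    DistanceCorrelationMatrix,
    detect_communities,
    distance_transform,
)
from .enm import CorrelationMatrix
from .errors import InputError


@dataclass
class ComparisonReport:
    """Summary of agreement between two correlation matrices."""

    kappa_by_nc: dict[int, float]
    kappa_max: float
    kappa_max_nc: int
    centrality_correlation: float
    rmsip: float
    n_modes: int | str = "all"
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_modes": self.n_modes,
            "kappa_by_nc": {str(k): v for k, v in self.kappa_by_nc.items()},
            "kappa_max": self.kappa_max,
            "kappa_max_nc": self.kappa_max_nc,
            "centrality_correlation": self.centrality_correlation,
            "rmsip": self.rmsip,
            "notes": self.notes,
        }


def align_labels(
    a: CommunityPartition, b: CommunityPartition
) -> CommunityPartition:
    """Relabel ``b`` to best match ``a``.

    Solves the assignment problem that maximizes the trace of the a-vs-b
    confusion matrix (Hungarian algorithm), i.e. the number of nodes on
    which the two partitions agree.  Among equal-trace optima the
    assignment minimizing the chance-agreement term (the sum of matched
    marginal products) is chosen, so the aligned kappa is invariant to
    any label permutation of either input even when the optimum is
    degenerate.
    """
    if a.n_nodes != b.n_nodes:
        raise InputError(
            f"partitions cover different node sets ({a.n_nodes} vs {b.n_nodes})"
        )
    if a.n_c != b.n_c:
        raise InputError(f"partitions have different sizes ({a.n_c} vs {b.n_c})")
    k = a.n_c
    n = a.n_nodes
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (a.labels - 1, b.labels - 1), 1)
    # secondary objective (strictly subordinate): minimize matched
    # marginal products n_a(i) * n_b(j)
    na = confusion.sum(axis=1)
    nb = confusion.sum(axis=0)
    tie = np.outer(na, nb) / (k * n * n + 1.0)
    rows, cols = linear_sum_assignment(confusion - tie, maximize=True)
    perm = np.empty(k, dtype=int)
    perm[cols] = rows + 1  # b label c -> a label rows[c]+1
    return CommunityPartition(
        labels=perm[b.labels - 1], n_c=k, residue_keys=b.residue_keys
    )


def cohens_kappa(a: CommunityPartition, b: CommunityPartition) -> float:
    """Chance-corrected agreement K = (p_o - p_e) / (1 - p_e).

    p_o is the fraction of nodes with equal labels and p_e the agreement
    expected from the two marginal label distributions.  Assumes labels
    are already aligned (see :func:`align_labels`).  The degenerate
    single-category case (p_e = 1) returns 1.
    """
    if a.n_nodes != b.n_nodes:
        raise InputError("partitions have different lengths")
    n = a.n_nodes
    p_o = float(np.mean(a.labels == b.labels))
    labels = np.union1d(a.labels, b.labels)
    fa = np.array([np.count_nonzero(a.labels == l) for l in labels]) / n
    fb = np.array([np.count_nonzero(b.labels == l) for l in labels]) / n
    p_e = float(fa @ fb)
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def kappa_profile(
    c1: CorrelationMatrix,
    c2: CorrelationMatrix,
    nc_range: tuple[int, ...] = NC_RANGE,
) -> tuple[dict[int, float], float, int]:
    """Kappa between community structures of two matrices over N_c.

    For each community count, both matrices are clustered, labels are
    aligned and Cohen's kappa computed.  Returns the profile, its maximum
    (Kappa_max) and the community count attaining it (smallest on ties).
    """
    if c1.n_nodes != c2.n_nodes:
        raise InputError(
            f"correlation matrices have different sizes "
            f"({c1.n_nodes} vs {c2.n_nodes})"
        )
    n = c1.n_nodes
    profile: dict[int, float] = {}
    for n_c in nc_range:
        if n_c > n:
            continue
        pa = detect_communities(c1, n_c)
        pb = detect_communities(c2, n_c)
        profile[n_c] = cohens_kappa(pa, align_labels(pa, pb))
    if not profile:
        raise InputError("no valid community count in range")
    kappa_max = max(profile.values())
    best_nc = min(nc for nc, v in profile.items() if v == kappa_max)
    return profile, kappa_max, best_nc


def closeness_centrality(d: DistanceCorrelationMatrix) -> np.ndarray:
    """Closeness centrality on the complete 1 - DCC weighted network.

    centrality(i) = 1 / sum_j shortest_path(i, j).  Indirect paths count:
    two strongly correlated neighbours can bring a residue closer to the
    rest of the network than its direct edges suggest.  A node at zero
    distance from every other node gets infinite centrality (flagged).
    """
    w = d.matrix.copy()
    if w.shape[0] < 2:
        raise InputError("need at least 2 nodes for centrality")
    if w.min() < 0:
        warnings.warn("negative edge weights clipped to 0", stacklevel=2)
        w = np.clip(w, 0.0, None)
    # keep zero-weight edges (perfectly correlated pairs) as real edges:
    # a plain dense array would treat 0 as "no edge"
    graph = csgraph_from_dense(w, null_value=np.inf)
    sp = dijkstra(graph, directed=False)
    farness = sp.sum(axis=1)
    with np.errstate(divide="ignore"):
        cent = 1.0 / farness
    if np.any(farness == 0):
        warnings.warn(
            f"node(s) {np.flatnonzero(farness == 0).tolist()} have zero "
            "farness; centrality reported as inf",
            stacklevel=2,
        )
    return cent


def centrality_correlation(
    x: np.ndarray, y: np.ndarray, method: str = "pearson"
) -> float:
    """Correlation between two per-node centrality profiles."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise InputError("centrality vectors must match and have length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("constant centrality vector: correlation undefined")
    if method == "pearson":
        return float(scipy.stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(scipy.stats.spearmanr(x, y).statistic)
    raise InputError(f"unknown correlation method: {method!r}")


def principal_vectors(c: CorrelationMatrix | np.ndarray, n: int) -> np.ndarray:
    """Leading ``n`` singular vectors (largest singular values) of a matrix."""
    mat = c.matrix if isinstance(c, CorrelationMatrix) else np.asarray(c, float)
    if not 1 <= n <= mat.shape[0]:
        raise InputError(f"n must be in [1, {mat.shape[0]}], got {n}")
    u, _, _ = np.linalg.svd(mat)
    return u[:, :n]


def rmsip(
    a: CorrelationMatrix | np.ndarray, b: CorrelationMatrix | np.ndarray, n: int
) -> float:
    """Root-mean-square inner product of two n-dimensional subspaces.

    RMSIP = sqrt( (1/n) sum_ij (V_i . U_j)^2 ) over the n leading
    singular vectors U, V of the two matrices.
    """
    u = principal_vectors(a, n)
    v = principal_vectors(b, n)
    overlap = v.T @ u
    return float(np.sqrt(np.sum(overlap**2) / n))


def compare_correlations(
    c1: CorrelationMatrix,
    c2: CorrelationMatrix,
    n_rmsip: int | None = None,
    nc_range: tuple[int, ...] = NC_RANGE,
    centrality_method: str = "pearson",
) -> ComparisonReport:
    """Full comparison report between two correlation matrices.

    ``n_rmsip`` defaults to the GNM mode count of ``c1`` when it is a
    finite subset, else to min(10, N): matching the number of principal
    vectors to the number of modes keeps the subspace comparison balanced.
    """
    if n_rmsip is None:
        if isinstance(c1.n_modes_used, int):
            n_rmsip = min(c1.n_modes_used, c1.n_nodes)
        else:
            n_rmsip = min(10, c1.n_nodes)
    profile, kmax, best_nc = kappa_profile(c1, c2, nc_range)
    cent1 = closeness_centrality(distance_transform(c1))
    cent2 = closeness_centrality(distance_transform(c2))
    corr = centrality_correlation(cent1, cent2, method=centrality_method)
    return ComparisonReport(
        kappa_by_nc=profile,
        kappa_max=kmax,
        kappa_max_nc=best_nc,
        centrality_correlation=corr,
        rmsip=rmsip(c1, c2, n_rmsip),
        n_modes=c1.n_modes_used,
        notes={
            "label_alignment": "hungarian-confusion-trace",
            "centrality_method": centrality_method,
        },
    )
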