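"""Gaussian network model: Kirchhoff matrix, normal modes, correlations.

The GNM treats a structure as nodes joined by identical Hookean springs
whenever two nodes lie within a cutoff distance r_c.  Equilibrium
fluctuations then follow from the pseudo-inverse of the contact Kirchhoff
matrix (the graph Laplacian of the contact network): the covariance of
isotropic node fluctuations is proportional to Gamma^-1, and the
normalized cross-correlation between nodes i and j is

    DCC(i, j) = Gamma^-1(i, j) / sqrt(Gamma^-1(i, i) * Gamma^-1(j, j))

computed over a chosen subset of the lowest-frequency non-zero modes.

Defaults follow common practice for proteins: r_c = 7.5 A for C-alpha
models and 3.5 A for all-heavy-atom models; mode subsets of 5, 10, 20,
30 and 50 low-frequency modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.linalg
from scipy.spatial.distance import squareform, pdist

from .errors import InputError, NumericalError
from .structure_io import CoarseModel

#: default contact cutoffs (Angstrom) per node selection
RC_CALPHA = 7.5
RC_HEAVY_ATOM = 3.5
#: default low-frequency mode subsets swept in comparisons
MODE_SUBSETS = (5, 10, 20, 30, 50)
#: relative eigenvalue threshold separating the uniform zero mode
ZERO_TOL = 1e-10


@dataclass
class KirchhoffMatrix:
    """Contact Laplacian of an elastic network."""

    matrix: np.ndarray
    r_c: float
    gamma: float = 1.0

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ModeSet:
    """Full eigensystem of a Kirchhoff matrix, eigenvalues ascending."""

    eigenvalues: np.ndarray  # (N,)
    eigenvectors: np.ndarray  # (N, N), columns orthonormal
    n_zero: int

    @property
    def n_nodes(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def n_nonzero(self) -> int:
        return self.n_nodes - self.n_zero


@dataclass
class CorrelationMatrix:
    """Normalized dynamic cross-correlation matrix (symmetric, diag 1)."""

    matrix: np.ndarray
    source: Literal["gnm", "md"]
    n_modes_used: int | str = "all"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InputError("correlation matrix must be square")
        if not np.allclose(m, m.T, atol=1e-8):
            raise InputError("correlation matrix must be symmetric")
        if np.any(np.abs(m) > 1 + 1e-8):
            raise InputError("correlation entries must lie in [-1, 1]")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def build_kirchhoff(
    m: CoarseModel, r_c: float | None = None, gamma: float = 1.0
) -> KirchhoffMatrix:
    """Build the GNM Kirchhoff (contact Laplacian) matrix.

    Off-diagonal (i, j) is -gamma iff the inter-node distance is <= r_c
    (inclusive at the cutoff); diagonals make every row sum exactly zero.
    ``r_c`` defaults to 7.5 A for C-alpha models and 3.5 A for heavy-atom
    models.
    """
    if r_c is None:
        r_c = RC_CALPHA if m.selection_mode == "calpha" else RC_HEAVY_ATOM
    if r_c <= 0:
        raise InputError(f"cutoff r_c must be positive, got {r_c}")
    d = squareform(pdist(m.node_coords))
    contact = (d <= r_c)
    np.fill_diagonal(contact, False)
    k = -gamma * contact.astype(float)
    np.fill_diagonal(k, -k.sum(axis=1))
    return KirchhoffMatrix(matrix=k, r_c=float(r_c), gamma=float(gamma))


def decompose(k: KirchhoffMatrix, zero_tol: float = ZERO_TOL) -> ModeSet:
    """Full eigendecomposition of the Kirchhoff matrix.

    Eigenvalues below ``zero_tol`` times the largest eigenvalue count as
    zero modes.  A connected contact network has exactly one (the uniform
    vector); more than one means the network is disconnected and the GNM
    is ill-defined.
    """
    mat = k.matrix
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise InputError("Kirchhoff matrix must be symmetric")
    vals, vecs = scipy.linalg.eigh(mat)
    lam_max = float(vals[-1])
    n_zero = int(np.count_nonzero(vals < zero_tol * max(lam_max, 1.0)))
    if n_zero > 1:
        raise NumericalError(
            f"contact network is disconnected ({n_zero} zero modes at "
            f"r_c={k.r_c} A); raise r_c or analyse the largest connected "
            "component"
        )
    return ModeSet(eigenvalues=vals, eigenvectors=vecs, n_zero=n_zero)


def mode_pseudo_inverse(ms: ModeSet, n_modes: int | str = "all") -> np.ndarray:
    """Pseudo-inverse of the Kirchhoff matrix over low-frequency modes.

    Sums lambda_i^-1 V_i V_i^T over the ``n_modes`` lowest-frequency
    non-zero modes; with ``"all"`` this equals the Moore-Penrose
    pseudo-inverse.
    """
    avail = ms.n_nonzero
    if n_modes == "all":
        n_modes = avail
    n_modes = int(n_modes)
    if not 1 <= n_modes <= avail:
        raise InputError(
            f"n_modes must be in [1, {avail}] (non-zero modes available), "
            f"got {n_modes}"
        )
    sl = slice(ms.n_zero, ms.n_zero + n_modes)
    v = ms.eigenvectors[:, sl]
    inv_lam = 1.0 / ms.eigenvalues[sl]
    return (v * inv_lam) @ v.T


def clip_mode_subsets(
    subsets: tuple[int, ...] | list[int], n_nonzero: int
) -> list[int]:
    """Clip requested mode subsets to the modes a model actually has."""
    out: list[int] = []
    for n in subsets:
        clipped = min(int(n), n_nonzero)
        if clipped < n:
            warnings.warn(
                f"mode subset {n} clipped to {clipped} (model has only "
                f"{n_nonzero} non-zero modes)",
                stacklevel=2,
            )
        if clipped not in out:
            out.append(clipped)
    return out


def dcc_gnm(ms: ModeSet, n_modes: int | str = "all") -> CorrelationMatrix:
    """Normalized GNM cross-correlation matrix from a mode subset.

    Fails if any node is invisible to the chosen modes (zero diagonal of
    the mode-limited pseudo-inverse); adding modes resolves this.
    """
    g = mode_pseudo_inverse(ms, n_modes)
    diag = np.diag(g).copy()
    dead = np.flatnonzero(diag <= 1e-14 * max(diag.max(), 1.0))
    if dead.size:
        raise NumericalError(
            f"node(s) {dead.tolist()} have zero fluctuation in the chosen "
            f"mode subset; increase n_modes"
        )
    norm = np.sqrt(diag)
    dcc = g / np.outer(norm, norm)
    dcc = np.clip(dcc, -1.0, 1.0)
    dcc = (dcc + dcc.T) / 2.0
    np.fill_diagonal(dcc, 1.0)
    n_used: int | str = "all" if n_modes == "all" else int(n_modes)
    return CorrelationMatrix(matrix=dcc, source="gnm", n_modes_used=n_used)


def gnm_correlations(
    m: CoarseModel,
    n_modes: int | str = "all",
    r_c: float | None = None,
    gamma: float = 1.0,
) -> CorrelationMatrix:
    """Convenience pipeline: coarse model -> Kirchhoff -> modes -> DCC."""
    return dcc_gnm(decompose(build_kirchhoff(m, r_c=r_c, gamma=gamma)), n_modes)
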