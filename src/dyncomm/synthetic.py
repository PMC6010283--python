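"""Synthetic bead proteins, trajectories and correlation matrices.

These generators provide ground-truth test inputs for every pipeline
stage without external data:

* **Bead proteins** — compact lattice clusters of C-alpha beads (one
  bead per pseudo-residue), one cluster per domain, domains joined
  through a short gap so only the facing beads form contacts.  The
  contact graph is connected but the domains are loosely coupled, which
  is exactly the geometry whose low-frequency modes split into
  domain-coherent communities.
* **GNM-sampled trajectories** — frames drawn i.i.d. from the Gaussian
  the network model implies (per-axis covariance amplitude * Gamma^-1),
  so the time-averaged correlation matrix of the trajectory provably
  converges to the GNM correlation matrix as frames accumulate.
* **Block correlation matrices** — exact community structure plus
  symmetric noise, for clustering-recovery tests.

Frames are independent draws, not time-correlated dynamics: the
correlation estimator is a pure time average, insensitive to frame
order, so i.i.d. sampling exercises it fully.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .enm import CorrelationMatrix, ModeSet, mode_pseudo_inverse
from .errors import InputError
from .structure_io import Structure, Trajectory, structure_from_model

#: beads closer than this are considered clashing (Angstrom)
MIN_BEAD_SEPARATION = 1.0


@dataclass
class FixtureSpec:
    """Geometry of a synthetic multi-domain bead protein.

    Defaults give two 10-bead domains with lattice spacing 3.8 A (the
    C-alpha virtual bond length), a 6.5 A inter-domain gap (inside the
    7.5 A contact cutoff, so the chain stays connected through a few
    contacts) and 0.3 A positional jitter to break lattice degeneracies.
    """

    n_domains: int = 2
    beads_per_domain: int = 10
    intra_spacing: float = 3.8
    linker_length: float = 6.5
    jitter: float = 0.3
    seed: int = 0

    @property
    def n_beads(self) -> int:
        return self.n_domains * self.beads_per_domain

    def __post_init__(self) -> None:
        if self.n_beads < 4:
            raise InputError("fixture needs at least 4 beads in total")
        if self.intra_spacing <= MIN_BEAD_SEPARATION:
            raise InputError("intra-domain spacing must exceed 1 A")


def _lattice_cluster(n: int, spacing: float) -> np.ndarray:
    """First ``n`` points of a compact cubic lattice, lexicographic order."""
    side = math.ceil(n ** (1 / 3))
    pts = []
    for ix in range(side):
        for iy in range(side):
            for iz in range(side):
                pts.append((ix * spacing, iy * spacing, iz * spacing))
                if len(pts) == n:
                    return np.array(pts, dtype=float)
    return np.array(pts, dtype=float)


def true_domain_labels(spec: FixtureSpec) -> np.ndarray:
    """Ground-truth domain label (1-based) of each bead, in node order."""
    return np.repeat(np.arange(1, spec.n_domains + 1), spec.beads_per_domain)


def make_bead_protein(spec: FixtureSpec) -> Structure:
    """Deterministically build the bead protein a spec describes.

    Domains are laid out along x with a gap of ``linker_length`` between
    the facing lattice planes of consecutive domains.  Raises if any two
    beads end up closer than 1 A.
    """
    rng = np.random.default_rng(spec.seed)
    base = _lattice_cluster(spec.beads_per_domain, spec.intra_spacing)
    extent_x = base[:, 0].max()
    coords = []
    offset = 0.0
    for _ in range(spec.n_domains):
        cluster = base + rng.uniform(-spec.jitter, spec.jitter, base.shape)
        cluster[:, 0] += offset
        coords.append(cluster)
        offset += extent_x + spec.linker_length
    xyz = np.vstack(coords)
    if pdist(xyz).min() < MIN_BEAD_SEPARATION:
        raise InputError(
            "fixture spec produces clashing beads (< 1 A apart); "
            "increase spacing or reduce jitter"
        )
    return structure_from_model(xyz)


def sample_gnm_trajectory(
    ms: ModeSet,
    mean_coords: np.ndarray,
    n_frames: int,
    amplitude: float = 1.0,
    seed: int = 0,
) -> Trajectory:
    """Draw i.i.d. frames from the GNM fluctuation distribution.

    Each Cartesian axis of the displacement field is an independent
    zero-mean Gaussian with covariance ``amplitude * Gamma^-1`` (full
    non-zero-mode pseudo-inverse).  ``amplitude`` of 1 gives RMS
    fluctuations of order 1 A for typical bead proteins; its value
    cancels from normalized correlations.
    """
    if n_frames < 2:
        raise InputError(f"n_frames must be >= 2, got {n_frames}")
    if amplitude <= 0:
        raise InputError(f"amplitude must be positive, got {amplitude}")
    mean_coords = np.asarray(mean_coords, dtype=float)
    n = ms.n_nodes
    if mean_coords.shape != (n, 3):
        raise InputError("mean_coords must be (N, 3) matching the mode set")
    rng = np.random.default_rng(seed)
    sl = slice(ms.n_zero, None)
    v = ms.eigenvectors[:, sl]  # (N, N - n_zero)
    scale = np.sqrt(amplitude / ms.eigenvalues[sl])  # per-mode std dev
    # z: (modes, frames, 3) -> displacements (frames, N, 3)
    z = rng.standard_normal((v.shape[1], n_frames, 3))
    disp = np.einsum("nm,mfk->fnk", v * scale, z)
    keys = [("A", i + 1, "") for i in range(n)]
    return Trajectory(frames=mean_coords[None, :, :] + disp, node_to_residue=keys)


def perturb_contacts(
    s: Structure, edits: Sequence[tuple[int, Sequence[float]]]
) -> Structure:
    """Apply deterministic bead displacements (synthetic 'mutations').

    ``edits`` is a list of (node index, (dx, dy, dz)) moves.  The edited
    structure must keep all beads at least 1 A apart.
    """
    coords = s.atoms.coord.astype(float).copy()
    n = coords.shape[0]
    for idx, delta in edits:
        if not 0 <= idx < n:
            raise InputError(f"edit refers to node {idx}, model has {n} nodes")
        coords[idx] += np.asarray(delta, dtype=float)
    if n >= 2 and pdist(coords).min() < MIN_BEAD_SEPARATION:
        raise InputError("edit produces clashing beads (< 1 A apart)")
    keys = [
        (str(c), int(r), str(i))
        for c, r, i in zip(s.atoms.chain_id, s.atoms.res_id, s.atoms.ins_code)
    ]
    return structure_from_model(coords, node_to_residue=keys)


def make_block_dcc(
    block_sizes: Sequence[int],
    within: float = 0.9,
    between: float = 0.1,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[CorrelationMatrix, np.ndarray]:
    """Correlation matrix with exact block (community) structure + noise.

    Off-diagonal entries are ``within`` inside a block and ``between``
    across blocks, plus symmetric Gaussian noise of standard deviation
    ``noise_sd``, clipped to [-1, 1]; the diagonal is exactly 1.
    Returns the matrix and the ground-truth block labels (1-based).
    """
    sizes = [int(s) for s in block_sizes]
    if any(s < 1 for s in sizes) or len(sizes) < 2:
        raise InputError("need >= 2 blocks of positive size")
    labels = np.repeat(np.arange(1, len(sizes) + 1), sizes)
    same = labels[:, None] == labels[None, :]
    mat = np.where(same, within, between).astype(float)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, mat.shape)
    noise = (noise + noise.T) / 2.0
    mat = np.clip(mat + noise, -1.0, 1.0)
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 1.0)
    return CorrelationMatrix(matrix=mat, source="gnm", n_modes_used="all"), labels
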