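"""Dynamic cross-correlation matrix of a coordinate trajectory.

For node displacement vectors about their time mean,
Delta r_i(t) = r_i(t) - <r_i>_t, the normalized cross-correlation is

    DCC(i, j) = <Delta r_i . Delta r_j>_t
                / sqrt(<|Delta r_i|^2>_t <|Delta r_j|^2>_t)

with the dot product over the three Cartesian components and the average
over frames.  No mass weighting and no frame superposition are applied;
correlations from unaligned trajectories therefore include any rigid-body
motion present in the input.
"""

from __future__ import annotations

import numpy as np

from .enm import CorrelationMatrix
from .errors import NumericalError
from .structure_io import Trajectory

# frames per accumulation chunk; bounds the temporary (chunk, N, 3) arrays
_CHUNK = 2048


def displacement_covariance(t: Trajectory) -> np.ndarray:
    """Time-averaged displacement covariance C(i,j) = <dr_i . dr_j>_t.

    Two-pass streaming computation (means first, then cross-products in
    chunks) so memory stays bounded for long trajectories; identical to
    the naive formula to machine precision.
    """
    frames = t.frames
    f, n, _ = frames.shape
    mean = frames.mean(axis=0)
    cov = np.zeros((n, n))
    for start in range(0, f, _CHUNK):
        d = frames[start : start + _CHUNK] - mean
        cov += np.einsum("fik,fjk->ij", d, d)
    return cov / f


def dcc_md(t: Trajectory) -> CorrelationMatrix:
    """Normalized cross-correlation matrix of a trajectory.

    Raises :class:`NumericalError` naming any node whose coordinates never
    move (zero variance makes the normalization undefined).
    """
    cov = displacement_covariance(t)
    var = np.diag(cov).copy()
    frozen = np.flatnonzero(var <= 1e-14 * max(var.max(), 1.0))
    if frozen.size:
        raise NumericalError(
            f"node(s) {frozen.tolist()} have zero fluctuation across frames; "
            "cannot normalize their correlations"
        )
    norm = np.sqrt(var)
    dcc = cov / np.outer(norm, norm)
    dcc = np.clip((dcc + dcc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(dcc, 1.0)
    return CorrelationMatrix(matrix=dcc, source="md", n_modes_used="all")
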