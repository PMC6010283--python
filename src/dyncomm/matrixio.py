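"""Plain-text serialization of matrices, partitions and reports.

All artifacts are diff-able text: square numeric matrices with a
``# key: value`` comment header, two-column partition tables, merge-list
dendrogram tables and JSON reports with fixed float formatting.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .communities import CommunityPartition, Dendrogram, DistanceCorrelationMatrix
from .enm import CorrelationMatrix
from .errors import InputError


def save_matrix(
    path: str | Path,
    matrix: CorrelationMatrix | DistanceCorrelationMatrix | np.ndarray,
    **header,
) -> None:
    """Write a square matrix as whitespace-delimited text with a header."""
    if isinstance(matrix, CorrelationMatrix):
        header.setdefault("kind", "correlation")
        header.setdefault("source", matrix.source)
        header.setdefault("n_modes", matrix.n_modes_used)
        data = matrix.matrix
    elif isinstance(matrix, DistanceCorrelationMatrix):
        header.setdefault("kind", "distance_correlation")
        header.setdefault("source", matrix.source)
        data = matrix.matrix
    else:
        data = np.asarray(matrix, dtype=float)
    lines = [f"# {k}: {v}" for k, v in header.items()]
    body = "\n".join(" ".join(f"{x:.10g}" for x in row) for row in data)
    Path(path).write_text("\n".join(lines + [body]) + "\n")


def load_matrix(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a matrix written by :func:`save_matrix`; returns (array, header)."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"matrix file not found: {path}")
    header: dict[str, str] = {}
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" in line:
                k, v = line[1:].split(":", 1)
                header[k.strip()] = v.strip()
            continue
        rows.append([float(x) for x in line.split()])
    if not rows:
        raise InputError(f"no numeric rows in {path}")
    arr = np.array(rows, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise InputError(f"{path} does not contain a square matrix")
    return arr, header


def load_correlation(path: str | Path) -> CorrelationMatrix:
    """Read a correlation matrix, restoring source / mode metadata."""
    arr, header = load_matrix(path)
    n_modes: int | str = header.get("n_modes", "all")
    if isinstance(n_modes, str) and n_modes.isdigit():
        n_modes = int(n_modes)
    source = header.get("source", "gnm")
    if source not in ("gnm", "md"):
        source = "gnm"
    return CorrelationMatrix(matrix=arr, source=source, n_modes_used=n_modes)


def save_partition(path: str | Path, p: CommunityPartition, **header) -> None:
    """Write a partition as two-column text: residue key, community label."""
    keys = p.residue_keys or [("A", i + 1, "") for i in range(p.n_nodes)]
    lines = [f"# {k}: {v}" for k, v in header.items()]
    lines.append("# residue community")
    for key, lab in zip(keys, p.labels):
        c, r, i = key
        lines.append(f"{c}:{r}{i} {lab}")
    Path(path).write_text("\n".join(lines) + "\n")


def save_dendrogram(path: str | Path, dg: Dendrogram, **header) -> None:
    """Write a dendrogram merge list (cluster_a cluster_b height size)."""
    lines = [f"# {k}: {v}" for k, v in header.items()]
    lines.append("# cluster_a cluster_b height size")
    for a, b, h, s in dg.merges:
        lines.append(f"{int(a)} {int(b)} {h:.10g} {int(s)}")
    Path(path).write_text("\n".join(lines) + "\n")


def save_json_report(path: str | Path, payload: dict) -> None:
    """Write a JSON report with sorted keys and stable float formatting."""
    Path(path).write_text(
        json.dumps(_round_floats(payload), indent=2, sort_keys=True) + "\n"
    )


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return round(float(obj), ndigits)
    return obj
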