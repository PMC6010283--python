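"""Structure and trajectory input for elastic-network modelling.

PDB files are parsed with biotite; this module reduces them to the node
sets an isotropic elastic network needs: either one C-alpha per residue
(coarse-grained) or all heavy atoms (used for the all-atom mutant screen).
HETATM records, waters, hydrogens and alternate locations other than
blank/'A' are always excluded so that node sets are reproducible across
PDB entries deposited with or without explicit hydrogens.

Trajectories are C-alpha coordinate series, read either from multi-model
PDB files or from a plain text table with columns ``frame,node,x,y,z``
(1-based frames, 0-based nodes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import InputError

#: residue key = (chain id, residue number, insertion code); survives
#: multi-chain proteins and insertion codes
ResidueKey = tuple[str, int, str]

SelectionMode = Literal["calpha", "heavy_atom"]


@dataclass
class Structure:
    """A single-model set of ATOM records.

    ``atoms`` is a biotite :class:`AtomArray` already filtered to
    heavy protein atoms in a single conformation.
    """

    atoms: struc.AtomArray
    model_index: int = 1

    def __len__(self) -> int:
        return self.atoms.array_length()

    def residue_keys(self) -> list[ResidueKey]:
        """Residue keys in file order (first-appearance order)."""
        keys: list[ResidueKey] = []
        seen: set[ResidueKey] = set()
        for key in _atom_residue_keys(self.atoms):
            if key not in seen:
                seen.add(key)
                keys.append(key)
        return keys


@dataclass
class CoarseModel:
    """Elastic-network node set extracted from a :class:`Structure`."""

    node_coords: np.ndarray  # (N, 3) Angstrom
    node_to_residue: list[ResidueKey]
    selection_mode: SelectionMode
    node_names: list[str] = field(default_factory=list)  # atom name per node

    def __post_init__(self) -> None:
        self.node_coords = np.asarray(self.node_coords, dtype=float)
        if self.node_coords.ndim != 2 or self.node_coords.shape[1] != 3:
            raise InputError("node_coords must be an (N, 3) array")
        if self.node_coords.shape[0] < 2:
            raise InputError("a coarse model needs at least 2 nodes")
        if not np.all(np.isfinite(self.node_coords)):
            raise InputError("node coordinates must be finite")

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]


@dataclass
class Trajectory:
    """C-alpha coordinate series: ``frames`` is (F, N, 3) in Angstrom."""

    frames: np.ndarray
    node_to_residue: list[ResidueKey]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise InputError("frames must be an (F, N, 3) array")
        if self.frames.shape[0] < 2:
            raise InputError(
                f"a trajectory needs at least 2 frames, got {self.frames.shape[0]}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.frames.shape[1]


def _atom_residue_keys(atoms: struc.AtomArray) -> list[ResidueKey]:
    return [
        (str(c), int(r), str(i))
        for c, r, i in zip(atoms.chain_id, atoms.res_id, atoms.ins_code)
    ]


def _filter_model(atoms: struc.AtomArray) -> struc.AtomArray:
    """Keep heavy protein atoms in the blank/'A' alternate location."""
    mask = ~atoms.hetero
    mask &= ~np.isin(atoms.element, ("H", "D"))
    if "altloc_id" in atoms.get_annotation_categories():
        mask &= np.isin(atoms.altloc_id, ("", " ", ".", "A"))
    return atoms[mask]


def read_pdb(path: str | Path, model_index: int = 1) -> Structure:
    """Read one model of a PDB file as a :class:`Structure`.

    Parameters
    ----------
    path
        PDB file path.
    model_index
        1-based model number (MODEL records; a file without MODEL records
        counts as a single model 1).
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"PDB file not found: {path}")
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if not 1 <= model_index <= n_models:
        raise InputError(
            f"model index {model_index} out of range: {path} has {n_models} model(s)"
        )
    atoms = pdb.get_structure(
        model=model_index, altloc="all"
    )
    atoms = _filter_model(atoms)
    if atoms.array_length() == 0:
        raise InputError(f"no ATOM records in model {model_index} of {path}")
    return Structure(atoms=atoms, model_index=model_index)


def select_nodes(s: Structure, mode: SelectionMode = "calpha") -> CoarseModel:
    """Reduce a structure to elastic-network nodes.

    ``calpha`` keeps exactly one C-alpha per residue (an error lists any
    residue without one); ``heavy_atom`` keeps every non-hydrogen atom.
    Node order is PDB file order.
    """
    atoms = s.atoms
    keys = _atom_residue_keys(atoms)
    if mode == "calpha":
        is_ca = (atoms.atom_name == "CA") & (atoms.element == "C")
        residue_order = s.residue_keys()
        ca_for: dict[ResidueKey, int] = {}
        for idx in np.flatnonzero(is_ca):
            ca_for.setdefault(keys[idx], int(idx))
        missing = [k for k in residue_order if k not in ca_for]
        if missing:
            raise InputError(
                "residue(s) missing a CA atom: "
                + ", ".join(f"{c}:{r}{i}".rstrip() for c, r, i in missing)
            )
        order = [ca_for[k] for k in residue_order]
        return CoarseModel(
            node_coords=atoms.coord[order],
            node_to_residue=residue_order,
            selection_mode="calpha",
            node_names=["CA"] * len(order),
        )
    elif mode == "heavy_atom":
        if atoms.array_length() == 0:
            raise InputError("empty atom selection")
        return CoarseModel(
            node_coords=atoms.coord.copy(),
            node_to_residue=keys,
            selection_mode="heavy_atom",
            node_names=[str(n) for n in atoms.atom_name],
        )
    raise InputError(f"unknown selection mode: {mode!r}")


def read_trajectory(
    path: str | Path,
    format: Literal["multi_model_pdb", "frames_table"] = "multi_model_pdb",
    selection: Literal["calpha", "all"] = "calpha",
) -> Trajectory:
    """Read a coordinate trajectory.

    ``multi_model_pdb`` parses every MODEL of a PDB file (selecting
    C-alphas by default); ``frames_table`` parses a plain text table with
    header ``frame,node,x,y,z``. All frames must share node count and
    ordering.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"trajectory file not found: {path}")
    if format == "multi_model_pdb":
        return _read_multi_model_pdb(path, selection)
    elif format == "frames_table":
        return _read_frames_table(path)
    raise InputError(f"unknown trajectory format: {format!r}")


def _model_nodes(s: Structure, selection: str) -> CoarseModel:
    if selection == "calpha":
        return select_nodes(s, "calpha")
    return select_nodes(s, "heavy_atom")


def _read_multi_model_pdb(path: Path, selection: str) -> Trajectory:
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models < 2:
        raise InputError(f"{path} has {n_models} model(s); a trajectory needs >= 2")
    ref: CoarseModel | None = None
    coords = []
    for m in range(1, n_models + 1):
        atoms = _filter_model(
            pdb.get_structure(model=m, altloc="all")
        )
        model = _model_nodes(Structure(atoms=atoms, model_index=m), selection)
        if ref is None:
            ref = model
        elif (
            model.n_nodes != ref.n_nodes
            or model.node_to_residue != ref.node_to_residue
        ):
            raise InputError(
                f"frame {m} of {path} has {model.n_nodes} nodes, "
                f"expected {ref.n_nodes} with identical residue ordering"
            )
        coords.append(model.node_coords)
    assert ref is not None
    return Trajectory(frames=np.stack(coords), node_to_residue=ref.node_to_residue)


def _read_frames_table(path: Path) -> Trajectory:
    try:
        table = pd.read_csv(path, sep=r"[,\s]+", engine="python", comment="#")
    except Exception as exc:  # malformed text
        raise InputError(f"cannot parse frames table {path}: {exc}") from exc
    required = {"frame", "node", "x", "y", "z"}
    if not required.issubset(table.columns):
        raise InputError(
            f"frames table {path} must have columns frame,node,x,y,z; "
            f"got {list(table.columns)}"
        )
    frame_ids = np.sort(table["frame"].unique())
    if len(frame_ids) < 2:
        raise InputError(f"{path}: a trajectory needs >= 2 frames")
    if frame_ids[0] != 1 or not np.array_equal(
        frame_ids, np.arange(1, len(frame_ids) + 1)
    ):
        raise InputError(f"{path}: frame indices must be contiguous starting at 1")
    n_nodes = int(table["node"].max()) + 1
    frames = np.full((len(frame_ids), n_nodes, 3), np.nan)
    fi = table["frame"].to_numpy(int) - 1
    ni = table["node"].to_numpy(int)
    frames[fi, ni, 0] = table["x"].to_numpy(float)
    frames[fi, ni, 1] = table["y"].to_numpy(float)
    frames[fi, ni, 2] = table["z"].to_numpy(float)
    bad = np.flatnonzero(~np.isfinite(frames).all(axis=(1, 2)))
    if bad.size:
        raise InputError(
            f"{path}: frame {bad[0] + 1} is missing nodes or has non-finite values"
        )
    # synthetic tables carry no residue metadata: one pseudo-residue per node
    keys: list[ResidueKey] = [("A", i + 1, "") for i in range(n_nodes)]
    return Trajectory(frames=frames, node_to_residue=keys)


def coarse_to_atom_array(m: CoarseModel) -> struc.AtomArray:
    """Render a coarse model as a biotite AtomArray (CA beads)."""
    n = m.n_nodes
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(m.node_coords, dtype=np.float32)
    chains, res_ids, ins = zip(*m.node_to_residue)
    atoms.chain_id = np.array(chains)
    atoms.res_id = np.array(res_ids, dtype=int)
    atoms.ins_code = np.array(ins)
    atoms.res_name = np.array(["GLY"] * n)
    names = m.node_names if m.node_names else ["CA"] * n
    atoms.atom_name = np.array(names)
    atoms.element = np.array([nm[0] if nm else "C" for nm in names])
    atoms.hetero = np.zeros(n, dtype=bool)
    return atoms


def write_coarse_pdb(m: CoarseModel, path: str | Path) -> None:
    """Write a coarse model as a single-model PDB file."""
    pdb = PDBFile()
    pdb.set_structure(coarse_to_atom_array(m))
    pdb.write(str(path))


def write_trajectory_pdb(t: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file (one MODEL per frame)."""
    n, f = t.n_nodes, t.n_frames
    stack = struc.AtomArrayStack(f, n)
    template = coarse_to_atom_array(
        CoarseModel(t.frames[0], t.node_to_residue, "calpha")
    )
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = np.asarray(t.frames, dtype=np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def write_frames_table(t: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a ``frame,node,x,y,z`` text table."""
    f, n = t.n_frames, t.n_nodes
    frame = np.repeat(np.arange(1, f + 1), n)
    node = np.tile(np.arange(n), f)
    xyz = t.frames.reshape(f * n, 3)
    pd.DataFrame(
        {"frame": frame, "node": node, "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2]}
    ).to_csv(path, index=False, float_format="%.6f")


def structure_from_model(
    coords: np.ndarray | Sequence[Sequence[float]],
    node_to_residue: list[ResidueKey] | None = None,
) -> Structure:
    """Build a bead Structure directly from coordinates (fixtures, tests)."""
    coords = np.asarray(coords, dtype=float)
    if node_to_residue is None:
        node_to_residue = [("A", i + 1, "") for i in range(coords.shape[0])]
    m = CoarseModel(coords, node_to_residue, "calpha")
    return Structure(atoms=coarse_to_atom_array(m), model_index=1)
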