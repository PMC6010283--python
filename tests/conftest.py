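"""Shared fixtures: handcrafted PDB texts and small reference models."""

from __future__ import annotations

import numpy as np
import pytest

from dyncomm.enm import build_kirchhoff, decompose
from dyncomm.structure_io import CoarseModel, select_nodes
from dyncomm.synthetic import FixtureSpec, make_bead_protein


def atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    xyz: tuple[float, float, float],
    element: str,
    altloc: str = " ",
    icode: str = " ",
    record: str = "ATOM",
) -> str:
    """One fixed-column ATOM/HETATM record."""
    pad_name = name if len(name) == 4 else f" {name:<3}"
    x, y, z = xyz
    return (
        f"{record:<6}{serial:>5} {pad_name}{altloc}{resname:>3} {chain}"
        f"{resseq:>4}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2}"
    )


# Gly (4 heavy atoms) + Ala (5) + Ser (6) = 15 heavy atoms, approximate
# backbone geometry along x.  Includes hydrogens and a water that parsing
# must drop.
_THREE_RES_ATOMS = [
    # GLY 1
    ("N", "GLY", 1, (0.0, 0.0, 0.0), "N"),
    ("CA", "GLY", 1, (1.5, 0.0, 0.0), "C"),
    ("C", "GLY", 1, (2.2, 1.3, 0.0), "C"),
    ("O", "GLY", 1, (1.6, 2.4, 0.0), "O"),
    # ALA 2
    ("N", "ALA", 2, (3.5, 1.3, 0.0), "N"),
    ("CA", "ALA", 2, (4.3, 2.5, 0.0), "C"),
    ("C", "ALA", 2, (5.8, 2.2, 0.0), "C"),
    ("O", "ALA", 2, (6.4, 1.1, 0.0), "O"),
    ("CB", "ALA", 2, (4.0, 3.4, 1.2), "C"),
    # SER 3
    ("N", "SER", 3, (6.4, 3.3, 0.5), "N"),
    ("CA", "SER", 3, (7.9, 3.3, 0.6), "C"),
    ("C", "SER", 3, (8.5, 4.7, 0.5), "C"),
    ("O", "SER", 3, (7.8, 5.7, 0.5), "O"),
    ("CB", "SER", 3, (8.5, 2.5, 1.8), "C"),
    ("OG", "SER", 3, (8.2, 1.1, 1.7), "O"),
]


def three_residue_pdb_text() -> str:
    lines = []
    serial = 1
    for name, resname, resseq, xyz, element in _THREE_RES_ATOMS:
        lines.append(atom_line(serial, name, resname, "A", resseq, xyz, element))
        serial += 1
    # hydrogen and water records: must be excluded on read
    lines.append(atom_line(serial, "H", "GLY", "A", 1, (0.5, -0.9, 0.0), "H"))
    serial += 1
    lines.append(
        atom_line(serial, "O", "HOH", "A", 101, (12.0, 12.0, 12.0), "O",
                  record="HETATM")
    )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def three_residue_pdb(tmp_path):
    path = tmp_path / "three_res.pdb"
    path.write_text(three_residue_pdb_text())
    return path


@pytest.fixture
def two_model_pdb(tmp_path):
    """Two MODELs of a 3-CA chain; model 2 is model 1 shifted by +1 A in x."""
    lines = []
    for m, shift in ((1, 0.0), (2, 1.0)):
        lines.append(f"MODEL     {m:>4}")
        for i in range(3):
            lines.append(
                atom_line(i + 1, "CA", "GLY", "A", i + 1,
                          (5.0 * i + shift, 0.0, 0.0), "C")
            )
        lines.append("ENDMDL")
    lines.append("END")
    path = tmp_path / "two_model.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def chain3_model():
    """3 collinear beads 5 A apart: the analytic GNM reference model."""
    return CoarseModel(
        node_coords=np.array([[0.0, 0, 0], [5.0, 0, 0], [10.0, 0, 0]]),
        node_to_residue=[("A", 1, ""), ("A", 2, ""), ("A", 3, "")],
        selection_mode="calpha",
    )


@pytest.fixture(scope="session")
def two_domain_spec():
    return FixtureSpec(n_domains=2, beads_per_domain=10, seed=0)


@pytest.fixture(scope="session")
def two_domain_model(two_domain_spec):
    return select_nodes(make_bead_protein(two_domain_spec), "calpha")


@pytest.fixture(scope="session")
def two_domain_modes(two_domain_model):
    return decompose(build_kirchhoff(two_domain_model, r_c=7.5))
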