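"""All-atom GNM screen of mutant community shifts against a wild-type.

Point mutations that strongly destabilize a protein tend to reorganize
its dynamic communities more than near-neutral ones.  The screen builds
an all-heavy-atom GNM (3.5 A contact cutoff) for the wild-type and each
mutant crystal structure, reduces the all-atom correlation matrix to
residue level, clusters both into 2..10 communities for each
low-frequency mode subset, and scores each mutant by Cohen's kappa
against the wild-type communities.  Medians per stability class
(stable / unstable by a ddG split) summarize whether destabilizing
mutations shift community architecture more.

The packaged manifest ``data/t4_lysozyme_ddg.csv`` carries the classic
Arg96 T4-lysozyme mutant series with ddG measured at pH 5.35; the two
-2.6 kcal/mol mutants fall on opposite sides of the split, so stability
classes are stored explicitly rather than recomputed from ddG.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .communities import detect_communities
from .enm import (
    MODE_SUBSETS,
    RC_HEAVY_ATOM,
    CorrelationMatrix,
    build_kirchhoff,
    clip_mode_subsets,
    dcc_gnm,
    decompose,
)
from .errors import InputError
from .metrics import align_labels, cohens_kappa
from .structure_io import CoarseModel, ResidueKey, Structure, select_nodes

#: ddG (kcal/mol) below which a mutant counts as unstable when no explicit
#: class is given; the boundary value itself is ambiguous (see manifest)
DDG_THRESHOLD = -2.6


@dataclass
class MutantRecord:
    """One mutant structure with its stability annotation."""

    pdb_id: str
    mutations: list[tuple[str, int, str]]  # (wild aa, position, mutant aa)
    ddG: float  # kcal/mol relative to wild-type
    stability_class: Literal["stable", "unstable"]
    path: str | None = None


@dataclass
class MutantReport:
    """Per-mutant kappa curves vs wild-type plus class medians."""

    # (pdb_id, n_modes) -> {n_c: kappa}
    kappa_curves: dict[tuple[str, int], dict[int, float]]
    # (stability_class, n_modes) -> {n_c: median kappa}
    class_medians: dict[tuple[str, int], dict[int, float]]
    mode_subsets: list[int]
    nc_range: tuple[int, ...]
    records: list[MutantRecord] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mode_subsets": self.mode_subsets,
            "nc_range": list(self.nc_range),
            "mutants": [
                {
                    "pdb_id": r.pdb_id,
                    "ddG": r.ddG,
                    "stability_class": r.stability_class,
                    "kappa_by_modes": {
                        str(m): {
                            str(nc): v
                            for nc, v in self.kappa_curves[(r.pdb_id, m)].items()
                        }
                        for m in self.mode_subsets
                    },
                }
                for r in self.records
            ],
            "class_medians": {
                f"{cls}/{m}": {str(nc): v for nc, v in curve.items()}
                for (cls, m), curve in sorted(self.class_medians.items())
            },
        }


def parse_mutation(text: str) -> tuple[str, int, str]:
    """Parse an 'xRy' mutation code, e.g. R96Y -> ('R', 96, 'Y')."""
    text = text.strip()
    if len(text) < 3 or not text[0].isalpha() or not text[-1].isalpha():
        raise InputError(f"cannot parse mutation code {text!r}")
    try:
        pos = int(text[1:-1])
    except ValueError as exc:
        raise InputError(f"cannot parse mutation code {text!r}") from exc
    return text[0].upper(), pos, text[-1].upper()


def load_manifest(path: str | Path | None = None) -> list[MutantRecord]:
    """Load a mutant manifest CSV.

    Columns: ``pdb_id``, ``mutations`` (';'-separated xRy codes),
    ``ddG_pH5.35`` (or ``ddG``), ``stability_class``, optional ``path``.
    With no argument, loads the packaged T4-lysozyme Arg96 series.
    """
    if path is None:
        src = importlib.resources.files("dyncomm.data") / "t4_lysozyme_ddg.csv"
        df = pd.read_csv(str(src))
    else:
        path = Path(path)
        if not path.is_file():
            raise InputError(f"manifest not found: {path}")
        df = pd.read_csv(path)
    ddg_col = "ddG_pH5.35" if "ddG_pH5.35" in df.columns else "ddG"
    records = []
    for _, row in df.iterrows():
        muts = [
            parse_mutation(m)
            for m in str(row["mutations"]).split(";")
            if m and m.lower() not in ("none", "nan")
        ]
        cls = str(row.get("stability_class", "")).strip().lower()
        if cls not in ("stable", "unstable"):
            cls = "unstable" if float(row[ddg_col]) < DDG_THRESHOLD else "stable"
        records.append(
            MutantRecord(
                pdb_id=str(row["pdb_id"]),
                mutations=muts,
                ddG=float(row[ddg_col]),
                stability_class=cls,  # type: ignore[arg-type]
                path=str(row["path"]) if "path" in df.columns else None,
            )
        )
    return records


def residue_level_dcc(
    allatom_dcc: CorrelationMatrix,
    model: CoarseModel,
    method: Literal["calpha", "mean"] = "calpha",
) -> tuple[CorrelationMatrix, list[ResidueKey]]:
    """Reduce an all-atom correlation matrix to one node per residue.

    ``calpha`` extracts the C-alpha rows/columns of the normalized
    all-atom matrix (default: one representative atom per residue, no
    re-normalization needed); ``mean`` averages the correlation over all
    atom pairs of each residue pair and re-normalizes.
    """
    if allatom_dcc.n_nodes != model.n_nodes:
        raise InputError("correlation matrix does not match the atom model")
    residues: list[ResidueKey] = []
    atom_groups: dict[ResidueKey, list[int]] = {}
    for idx, key in enumerate(model.node_to_residue):
        if key not in atom_groups:
            atom_groups[key] = []
            residues.append(key)
        atom_groups[key].append(idx)
    if method == "calpha":
        names = model.node_names
        ca_idx = []
        for key in residues:
            cas = [i for i in atom_groups[key] if names and names[i] == "CA"]
            if not cas:
                raise InputError(
                    f"residue {key} has no CA atom in the heavy-atom model"
                )
            ca_idx.append(cas[0])
        sub = allatom_dcc.matrix[np.ix_(ca_idx, ca_idx)].copy()
        np.fill_diagonal(sub, 1.0)
        return (
            CorrelationMatrix(
                matrix=sub, source=allatom_dcc.source,
                n_modes_used=allatom_dcc.n_modes_used,
            ),
            residues,
        )
    elif method == "mean":
        nr = len(residues)
        red = np.empty((nr, nr))
        groups = [atom_groups[k] for k in residues]
        for i in range(nr):
            for j in range(i, nr):
                red[i, j] = red[j, i] = allatom_dcc.matrix[
                    np.ix_(groups[i], groups[j])
                ].mean()
        norm = np.sqrt(np.abs(np.diag(red)))
        red = red / np.outer(norm, norm)
        red = np.clip((red + red.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(red, 1.0)
        return (
            CorrelationMatrix(
                matrix=red, source=allatom_dcc.source,
                n_modes_used=allatom_dcc.n_modes_used,
            ),
            residues,
        )
    raise InputError(f"unknown reduction method: {method!r}")


def _structure_residue_dccs(
    s: Structure,
    mode_subsets: Sequence[int],
    r_c: float,
    reduction: Literal["calpha", "mean"],
) -> tuple[dict[int, CorrelationMatrix], list[ResidueKey]]:
    """All-atom GNM -> residue-level DCC for each requested mode subset."""
    model = select_nodes(s, "heavy_atom")
    ms = decompose(build_kirchhoff(model, r_c=r_c))
    subsets = clip_mode_subsets(tuple(mode_subsets), ms.n_nonzero)
    out: dict[int, CorrelationMatrix] = {}
    residues: list[ResidueKey] = []
    for n_modes in subsets:
        red, residues = residue_level_dcc(
            dcc_gnm(ms, n_modes), model, method=reduction
        )
        out[n_modes] = red
    return out, residues


def screen_mutants(
    wildtype: Structure,
    mutants: Iterable[tuple[Structure, MutantRecord]],
    mode_subsets: Sequence[int] = MODE_SUBSETS,
    nc_range: tuple[int, ...] = tuple(range(2, 11)),
    r_c: float = RC_HEAVY_ATOM,
    reduction: Literal["calpha", "mean"] = "calpha",
) -> MutantReport:
    """Score community agreement of each mutant with the wild-type.

    For every mutant, mode subset and community count: build all-atom
    GNMs (cutoff ``r_c``), reduce correlations to residue level on the
    residues common to both structures, cluster, align labels and compute
    Cohen's kappa.  Mutants sharing fewer than half of the wild-type
    residues are rejected.
    """
    wt_dccs, wt_res = _structure_residue_dccs(
        wildtype, mode_subsets, r_c, reduction
    )
    subsets = sorted(wt_dccs)
    curves: dict[tuple[str, int], dict[int, float]] = {}
    records: list[MutantRecord] = []
    per_class: dict[tuple[str, int, int], list[float]] = {}
    for s, rec in mutants:
        mu_dccs, mu_res = _structure_residue_dccs(s, mode_subsets, r_c, reduction)
        common = [k for k in wt_res if k in set(mu_res)]
        if len(common) < 0.5 * len(wt_res):
            raise InputError(
                f"mutant {rec.pdb_id} shares only {len(common)}/{len(wt_res)} "
                "residues with the wild-type (< 50%)"
            )
        wt_pos = {k: i for i, k in enumerate(wt_res)}
        mu_pos = {k: i for i, k in enumerate(mu_res)}
        wi = [wt_pos[k] for k in common]
        mi = [mu_pos[k] for k in common]
        records.append(rec)
        for n_modes in subsets:
            if n_modes not in mu_dccs:
                continue
            wt_sub = _submatrix(wt_dccs[n_modes], wi)
            mu_sub = _submatrix(mu_dccs[n_modes], mi)
            curve: dict[int, float] = {}
            for n_c in nc_range:
                if n_c > len(common):
                    continue
                pw = detect_communities(wt_sub, n_c)
                pm = detect_communities(mu_sub, n_c)
                k = cohens_kappa(pw, align_labels(pw, pm))
                curve[n_c] = k
                per_class.setdefault(
                    (rec.stability_class, n_modes, n_c), []
                ).append(k)
            curves[(rec.pdb_id, n_modes)] = curve
    class_medians: dict[tuple[str, int], dict[int, float]] = {}
    for (cls, n_modes, n_c), vals in per_class.items():
        class_medians.setdefault((cls, n_modes), {})[n_c] = median(vals)
    for curve in class_medians.values():
        # deterministic ordering of community counts in reports
        for k in sorted(curve):
            curve[k] = curve.pop(k)
    return MutantReport(
        kappa_curves=curves,
        class_medians=class_medians,
        mode_subsets=subsets,
        nc_range=nc_range,
        records=records,
    )


def _submatrix(c: CorrelationMatrix, idx: list[int]) -> CorrelationMatrix:
    sub = c.matrix[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, 1.0)
    return CorrelationMatrix(matrix=sub, source=c.source, n_modes_used=c.n_modes_used)
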