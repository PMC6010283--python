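#!/usr/bin/env python
"""Optional integration harness: T4 lysozyme Arg96 mutant screen.

Requires locally provided PDB files (this script downloads nothing):
a directory containing ``4s0w.pdb`` (wild-type) and one ``<pdb_id>.pdb``
per entry of the packaged ddG manifest (3c80, 3fi5, 3c7z, 3c82, 3c8q,
3cdt, 3cdv, 3c8r, 3cdq, 3c8s, 3cdo, 3c7y, 3c81, 3c83, 3cdr, 3c7w).

Runs the all-heavy-atom GNM screen (3.5 A cutoff) sweeping mode subsets
{5, 10, 20, 30, 50} and community counts 2-10, writes the full report,
and prints the kappa values for the three stable/unstable showcase pairs
(3c80 vs 3c81 at N_c = 2; 3c82 vs 3c81 and 3c82 vs 3c8s at N_c = 3)
for every mode subset.

Usage:
    python scripts/t4_integration.py --structures DIR --out report.json
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

from dyncomm.matrixio import save_json_report
from dyncomm.mutants import load_manifest, screen_mutants
from dyncomm.structure_io import read_pdb

SHOWCASE = [  # (unstable, stable, community count)
    ("3c80", "3c81", 2),
    ("3c82", "3c81", 3),
    ("3c82", "3c8s", 3),
]


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--structures", required=True,
                        help="directory with 4s0w.pdb and mutant PDB files")
    parser.add_argument("--out", default="t4_mutscan.json")
    args = parser.parse_args()

    base = Path(args.structures)
    records = load_manifest()
    missing = [r.pdb_id for r in records
               if not (base / f"{r.pdb_id}.pdb").is_file()]
    if not (base / "4s0w.pdb").is_file():
        missing.insert(0, "4s0w")
    if missing:
        print("missing structure files:", ", ".join(missing), file=sys.stderr)
        print(f"place <id>.pdb files in {base} and re-run", file=sys.stderr)
        return 2

    wt = read_pdb(base / "4s0w.pdb")
    mutants = [(read_pdb(base / f"{r.pdb_id}.pdb"), r) for r in records]
    report = screen_mutants(wt, mutants)  # 3.5 A heavy-atom defaults
    save_json_report(args.out, report.to_dict())
    print(f"wrote {args.out}\n")
    print("showcase pairs (kappa vs wild-type per mode subset):")
    for unstable, stable, n_c in SHOWCASE:
        for m in report.mode_subsets:
            ku = report.kappa_curves[(unstable, m)].get(n_c)
            ks = report.kappa_curves[(stable, m)].get(n_c)
            print(f"  N_c={n_c} modes={m:>2}: {unstable} (unstable) "
                  f"kappa={ku:.3f}   {stable} (stable) kappa={ks:.3f}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
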