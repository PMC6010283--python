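"""All-atom GNM mutant screen: manifest, residue reduction, kappa curves."""

import numpy as np
import pytest

from dyncomm.enm import CorrelationMatrix, gnm_correlations
from dyncomm.errors import InputError
from dyncomm.mutants import (
    MutantRecord,
    load_manifest,
    parse_mutation,
    residue_level_dcc,
    screen_mutants,
)
from dyncomm.structure_io import CoarseModel, select_nodes
from dyncomm.synthetic import FixtureSpec, make_bead_protein, perturb_contacts


class TestManifest:
    def test_packaged_table_loads(self):
        records = load_manifest()
        assert len(records) == 16
        by_id = {r.pdb_id: r for r in records}
        assert by_id["3c80"].ddG == -4.7
        assert by_id["3c80"].stability_class == "unstable"
        assert by_id["3c7w"].ddG == 0.0
        assert by_id["3c7w"].stability_class == "stable"
        # the two -2.6 kcal/mol mutants sit in different classes
        assert by_id["3c8r"].stability_class == "unstable"
        assert by_id["3cdq"].stability_class == "stable"
        assert by_id["3c7z"].mutations == [("D", 89, "A"), ("R", 96, "H")]

    def test_class_counts(self):
        records = load_manifest()
        unstable = [r for r in records if r.stability_class == "unstable"]
        assert len(unstable) == 8

    def test_parse_mutation(self):
        assert parse_mutation("R96Y") == ("R", 96, "Y")
        with pytest.raises(InputError):
            parse_mutation("96Y")

    def test_missing_manifest(self, tmp_path):
        with pytest.raises(InputError):
            load_manifest(tmp_path / "nope.csv")


class TestResidueLevelDcc:
    def test_identity_when_one_atom_per_residue(self, two_domain_spec):
        s = make_bead_protein(two_domain_spec)
        model = select_nodes(s, "heavy_atom")  # beads are single CA atoms
        dcc = gnm_correlations(model, 5, r_c=7.5)
        red, residues = residue_level_dcc(dcc, model)
        assert np.allclose(red.matrix, dcc.matrix)
        assert len(residues) == model.n_nodes

    def test_block_constant_toy(self):
        """CA extraction of a block-constant all-atom matrix is exact."""
        c = 0.4
        mat = np.full((4, 4), c)
        mat[:2, :2] = 1.0
        mat[2:, 2:] = 1.0
        allatom = CorrelationMatrix(matrix=mat, source="gnm")
        model = CoarseModel(
            node_coords=np.array([[0.0, 0, 0], [1.5, 0, 0],
                                  [10.0, 0, 0], [11.5, 0, 0]]),
            node_to_residue=[("A", 1, ""), ("A", 1, ""),
                             ("A", 2, ""), ("A", 2, "")],
            selection_mode="heavy_atom",
            node_names=["CA", "CB", "CA", "CB"],
        )
        red, residues = residue_level_dcc(allatom, model)
        assert np.allclose(red.matrix, [[1.0, c], [c, 1.0]])
        assert residues == [("A", 1, ""), ("A", 2, "")]

    def test_mean_reduction_of_block_constant_matches_calpha(self):
        mat = np.full((4, 4), 0.4)
        mat[:2, :2] = 1.0
        mat[2:, 2:] = 1.0
        allatom = CorrelationMatrix(matrix=mat, source="gnm")
        model = CoarseModel(
            node_coords=np.arange(12.0).reshape(4, 3),
            node_to_residue=[("A", 1, ""), ("A", 1, ""),
                             ("A", 2, ""), ("A", 2, "")],
            selection_mode="heavy_atom",
            node_names=["CA", "CB", "CA", "CB"],
        )
        red_ca, _ = residue_level_dcc(allatom, model, method="calpha")
        red_mean, _ = residue_level_dcc(allatom, model, method="mean")
        assert np.allclose(red_ca.matrix, red_mean.matrix)

    def test_missing_ca_rejected(self):
        allatom = CorrelationMatrix(matrix=np.eye(2), source="gnm")
        model = CoarseModel(
            node_coords=np.array([[0.0, 0, 0], [3.0, 0, 0]]),
            node_to_residue=[("A", 1, ""), ("A", 1, "")],
            selection_mode="heavy_atom",
            node_names=["N", "CB"],
        )
        with pytest.raises(InputError, match="no CA"):
            residue_level_dcc(allatom, model)


def record(pdb_id, ddg, cls):
    return MutantRecord(pdb_id=pdb_id, mutations=[("R", 96, "A")],
                        ddG=ddg, stability_class=cls)


class TestScreenMutants:
    # bead fixtures have 3.8 A spacing, so the screen runs at the
    # C-alpha-scale cutoff instead of the 3.5 A heavy-atom default
    RC = 7.5

    def test_identical_mutant_scores_one(self, two_domain_spec):
        wt = make_bead_protein(two_domain_spec)
        rep = screen_mutants(
            wt, [(wt, record("copy", 0.0, "stable"))],
            mode_subsets=(5, 10), nc_range=(2, 3, 4), r_c=self.RC,
        )
        for curve in rep.kappa_curves.values():
            assert all(v == 1.0 for v in curve.values())

    def test_interface_edit_hurts_more_than_interior_edit(self,
                                                          two_domain_spec):
        """Rewiring inter-domain contacts shifts the 2-community split
        more than an equal-size edit buried inside one domain."""
        wt = make_bead_protein(two_domain_spec)
        coords = wt.atoms.coord
        # node nearest the other domain = interface; node 0 = far corner
        interface = int(np.argmax(coords[:10, 0]))
        # push the bridging bead into the gap: its correlations flip to
        # the opposite domain
        unstable = perturb_contacts(wt, [(interface, (3.0, 0.0, 0.0))])
        stable = perturb_contacts(wt, [(0, (-1.5, 0.0, 0.0))])
        rep = screen_mutants(
            wt,
            [(unstable, record("inter", -4.0, "unstable")),
             (stable, record("intra", -0.5, "stable"))],
            mode_subsets=(5,), nc_range=(2,), r_c=self.RC,
        )
        k_unstable = rep.kappa_curves[("inter", 5)][2]
        k_stable = rep.kappa_curves[("intra", 5)][2]
        assert k_stable == 1.0
        assert k_unstable < k_stable
        assert rep.class_medians[("stable", 5)][2] >= \
            rep.class_medians[("unstable", 5)][2]

    def test_medians_invariant_to_input_order(self, two_domain_spec):
        wt = make_bead_protein(two_domain_spec)
        m1 = perturb_contacts(wt, [(9, (0.0, 0.0, 6.0))])
        m2 = perturb_contacts(wt, [(0, (-1.5, 0.0, 0.0))])
        pairs = [(m1, record("a", -3.0, "unstable")),
                 (m2, record("b", -0.2, "stable"))]
        rep_fwd = screen_mutants(wt, pairs, mode_subsets=(5,),
                                 nc_range=(2, 3), r_c=self.RC)
        rep_rev = screen_mutants(wt, pairs[::-1], mode_subsets=(5,),
                                 nc_range=(2, 3), r_c=self.RC)
        assert rep_fwd.class_medians == rep_rev.class_medians

    def test_low_residue_overlap_rejected(self, two_domain_spec):
        wt = make_bead_protein(two_domain_spec)
        small_spec = FixtureSpec(n_domains=2, beads_per_domain=3, seed=0)
        small = make_bead_protein(small_spec)
        with pytest.raises(InputError, match="50%"):
            screen_mutants(wt, [(small, record("tiny", -1.0, "stable"))],
                           mode_subsets=(3,), nc_range=(2,), r_c=self.RC)

    def test_report_serializes(self, two_domain_spec):
        wt = make_bead_protein(two_domain_spec)
        rep = screen_mutants(wt, [(wt, record("copy", 0.0, "stable"))],
                             mode_subsets=(5,), nc_range=(2,), r_c=self.RC)
        d = rep.to_dict()
        assert d["mutants"][0]["pdb_id"] == "copy"
        assert "stable/5" in d["class_medians"]
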