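"""H-bond detection, pair geometry, N-class and kink angle."""

import numpy as np
import pytest

from kturn.structure import (
    DONOR_ACCEPTOR_TABLE,
    Atom,
    StructureAnnotation,
    StructureModel,
    assign_n_class,
    classify_pair_geometry,
    detect_hbonds,
    kink_angle,
    load_structure,
)
from kturn.synth import (
    gen_pair_fixture,
    gen_structure_fixture,
    random_rigid_motion,
)
from oracles import oracle_hbonds

ATOM_NAMES = ["O2'", "C2'", "N1", "N3", "N6", "N7", "O2", "O6", "P"]
RESNAMES = ["A", "C", "G", "U"]


def _random_structure(rng, n_atoms=30, box=12.0):
    atoms = []
    used = set()
    while len(atoms) < n_atoms:
        key = (rng.choice(["A", "B"]), int(rng.integers(1, 9)),
               ATOM_NAMES[rng.integers(len(ATOM_NAMES))])
        if key in used:
            continue
        used.add(key)
        atoms.append(Atom(key[0], key[1], RESNAMES[rng.integers(4)], key[2],
                          tuple(rng.uniform(0, box, 3))))
    return StructureModel(atoms)


class TestDetectHBonds:
    def test_constructed_bond_reported(self):
        st = StructureModel([
            Atom("A", 1, "G", "O2'", (0.0, 0.0, 0.0)),
            Atom("A", 1, "G", "C2'", (-1.4, 0.0, 0.0)),
            Atom("B", 2, "A", "N3", (2.9, 0.0, 0.0)),
        ])
        bonds = detect_hbonds(st)
        assert len(bonds) == 1
        assert bonds[0].donor == ("A", 1, "O2'")
        assert bonds[0].acceptor == ("B", 2, "N3")
        assert bonds[0].distance == pytest.approx(2.9)
        assert bonds[0].donor_angle == pytest.approx(180.0)

    def test_long_contact_not_reported(self):
        st = StructureModel([
            Atom("A", 1, "G", "O2'", (0.0, 0.0, 0.0)),
            Atom("B", 2, "A", "N3", (5.0, 0.0, 0.0)),
        ])
        assert detect_hbonds(st) == []

    def test_bad_donor_angle_rejected(self):
        # antecedent on the same side as the acceptor: angle ~0
        st = StructureModel([
            Atom("A", 1, "G", "O2'", (0.0, 0.0, 0.0)),
            Atom("A", 1, "G", "C2'", (1.4, 0.0, 0.0)),
            Atom("B", 2, "A", "N3", (2.9, 0.0, 0.0)),
        ])
        assert detect_hbonds(st) == []

    def test_unknown_residue_warned_not_silent(self):
        st = StructureModel([
            Atom("A", 1, "XYZ", "O2'", (0.0, 0.0, 0.0)),
            Atom("B", 2, "A", "N3", (2.9, 0.0, 0.0)),
        ])
        with pytest.warns(UserWarning, match="unknown residue"):
            assert detect_hbonds(st) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        """Exact set equality with an independent all-pairs enumeration
        on random 30-atom structures."""
        rng = np.random.default_rng(1000 + seed)
        st = _random_structure(rng)
        got = {(h.donor, h.acceptor, round(h.distance, 9))
               for h in detect_hbonds(st)}
        expected = oracle_hbonds(
            [(a.chain, a.resnum, a.resname, a.name, a.xyz) for a in st.atoms],
            DONOR_ACCEPTOR_TABLE)
        assert got == expected


class TestPairGeometry:
    @pytest.mark.parametrize("kind,label,n_bonds", [
        ("trans_sugar_hoogsteen_GA", "trans-sugar-Hoogsteen", 2),
        ("trans_AU", "trans single-H-bond", 1),
        ("cis_CA", "cis single-H-bond", 1),
        ("cis_watson_crick_GC", "cis-Watson-Crick", 3),
    ])
    def test_idealized_fixtures(self, kind, label, n_bonds):
        st, r1, r2 = gen_pair_fixture(kind)
        pc = classify_pair_geometry(st, r1, r2)
        assert pc.label == label
        assert len(pc.hbonds) == n_bonds

    def test_missing_glycosidic_atoms_unclassified(self):
        st, r1, r2 = gen_pair_fixture("cis_CA")
        stripped = StructureModel([a for a in st.atoms if a.name != "C1'"])
        pc = classify_pair_geometry(stripped, r1, r2)
        assert pc.label == "unclassified"
        assert "glycosidic" in pc.reason

    def test_rigid_motion_invariance(self):
        st, r1, r2 = gen_pair_fixture("trans_sugar_hoogsteen_GA")
        R, t = random_rigid_motion(11)
        pc = classify_pair_geometry(st.transformed(R, t), r1, r2)
        assert pc.label == "trans-sugar-Hoogsteen"


class TestNClass:
    @pytest.mark.parametrize("truth,expected", [
        ("N3", "N3"), ("N1", "N1"), ("none", "unclassified"),
    ])
    def test_fixture_classification(self, truth, expected):
        fx = gen_structure_fixture(50.0, truth)
        cls = assign_n_class(fx.structure, fx.annotation)
        assert cls.n_class == expected
        assert cls.l1_o2p_to_a1n_n1
        assert cls.reference_kinked_angle == 50.0

    def test_pure_function_of_hbond_census(self):
        fx = gen_structure_fixture(50.0, "N3")
        c1 = assign_n_class(fx.structure, fx.annotation)
        c2 = assign_n_class(fx.structure, fx.annotation)
        assert c1.n_class == c2.n_class
        assert [(h.donor, h.acceptor) for h in c1.hbonds] == \
               [(h.donor, h.acceptor) for h in c2.hbonds]

    def test_incomplete_mapping_raises(self):
        fx = gen_structure_fixture(50.0, "N3")
        with pytest.raises(KeyError, match="incomplete"):
            assign_n_class(fx.structure,
                           StructureAnnotation(label_map={"L1": ("A", 30)}))


class TestKinkAngle:
    @pytest.mark.parametrize("angle", [0.0, 50.0, 120.0])
    def test_constructed_angle_recovered(self, angle):
        fx = gen_structure_fixture(angle, "N3")
        got = kink_angle(fx.structure, fx.annotation.c_helix_residues,
                         fx.annotation.nc_helix_residues)
        assert got == pytest.approx(angle, abs=0.5)

    def test_rigid_motion_invariance(self):
        fx = gen_structure_fixture(50.0, "N3")
        ref = kink_angle(fx.structure, fx.annotation.c_helix_residues,
                         fx.annotation.nc_helix_residues)
        for seed in range(100):
            R, t = random_rigid_motion(seed)
            got = kink_angle(fx.structure.transformed(R, t),
                             fx.annotation.c_helix_residues,
                             fx.annotation.nc_helix_residues)
            assert got == pytest.approx(ref, abs=1e-6)

    def test_kinked_deviates_more_than_extended(self):
        """The tightly kinked geometry bends the 5'->3' axis far from the
        coaxial (extended) arrangement, which reads 0 by convention."""
        kinked = gen_structure_fixture(50.0, "N3")
        extended = gen_structure_fixture(0.0, "N3")

        def measure(fx):
            return kink_angle(fx.structure, fx.annotation.c_helix_residues,
                              fx.annotation.nc_helix_residues)

        assert measure(kinked) > measure(extended)

    def test_too_few_residues(self):
        fx = gen_structure_fixture(50.0, "N3")
        with pytest.raises(ValueError, match=">= 3 residues"):
            kink_angle(fx.structure, fx.annotation.c_helix_residues[:2],
                       fx.annotation.nc_helix_residues)


class TestIO:
    def test_pdb_round_trip(self, tmp_path):
        from kturn.cli import _write_pdb

        fx = gen_structure_fixture(50.0, "N3")
        path = tmp_path / "fixture.pdb"
        _write_pdb(fx.structure, path)
        st = load_structure(path)
        cls = assign_n_class(st, fx.annotation)
        assert cls.n_class == "N3"
        got = kink_angle(st, fx.annotation.c_helix_residues,
                         fx.annotation.nc_helix_residues)
        assert got == pytest.approx(50.0, abs=0.5)
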