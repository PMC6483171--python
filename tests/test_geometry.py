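"""3D duplex geometry: pair detection, helix fit, superposition."""

import math
import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dimerfold.core import RnaSequence
from dimerfold.geometry import (Atom, Residue, Structure3D, StructureError,
                                detect_pairs, dihedral, fit_helix,
                                glycosidic_conformation, kabsch_rmsd,
                                kabsch_superpose, make_ideal_aform,
                                pair_geometry, pair_geometry_altlocs,
                                read_structure, write_pdb)

SEQ = RnaSequence("fix", "GGACUUCG")


def rigid_copy(st: Structure3D, R: np.ndarray, t: np.ndarray) -> Structure3D:
    chains = {}
    for cid, residues in st.chains.items():
        out = []
        for r in residues:
            atoms = {name: Atom(a.name, a.element,
                                tuple(R @ a.coord + t), a.occupancy,
                                a.altloc)
                     for name, a in r.atoms.items()}
            out.append(Residue(r.chain, r.number, r.base, atoms,
                               {(a.name, a.altloc): a
                                for a in atoms.values()}))
        chains[cid] = out
    return Structure3D(st.name + "_moved", chains)


class TestFixtureGeneration:
    def test_detects_all_and_only_planted_pairs(self):
        st = make_ideal_aform(SEQ)
        pairs = detect_pairs(st)
        assert len(pairs) == len(SEQ)
        assert all(p.label == "WC" for p in pairs)
        opposed = {(p.res1.number, p.res2.number) for p in pairs}
        assert opposed == {(k, len(SEQ) + 1 - k)
                          for k in range(1, len(SEQ) + 1)}

    def test_single_strand_has_no_pairs(self):
        st = make_ideal_aform(SEQ)
        solo = Structure3D("solo", {"A": st.chains["A"]})
        assert detect_pairs(solo) == []

    def test_symmetric_pair_lambdas(self):
        st = make_ideal_aform(SEQ)
        p = detect_pairs(st)[0]
        assert p.lambda1 == pytest.approx(p.lambda2, abs=1e-6)
        assert p.c1_c1 == pytest.approx(10.5, abs=1e-3)

    def test_pairs_per_turn_arithmetic(self):
        st = make_ideal_aform(RnaSequence("x", "GGGGGGGGGGGG"))
        frame = fit_helix(detect_pairs(st))
        assert 360.0 / frame.mean_twist == pytest.approx(360.0 / 32.7,
                                                         rel=1e-3)

    def test_self_partner_reproduces_duplex_mismatches(self, study):
        st = make_ideal_aform(study["RNA_II"], partner="self")
        labels = [p.label for p in detect_pairs(st)]
        assert labels.count("WC") == 14
        assert labels.count("AC") == 4
        assert labels.count("GG") == 1


class TestHelixFit:
    @pytest.mark.parametrize("rise", [2.0, 2.81, 3.5])
    @pytest.mark.parametrize("twist", [20.0, 32.7, 40.0])
    def test_parameter_recovery_grid(self, rise, twist):
        st = make_ideal_aform(SEQ, rise=rise, twist=twist)
        frame = fit_helix(detect_pairs(st))
        assert frame.mean_rise == pytest.approx(rise, rel=0.01)
        assert frame.mean_twist == pytest.approx(twist, rel=0.01)

    def test_pure_translation_two_pairs(self):
        st = make_ideal_aform(RnaSequence("x", "GC"), rise=3.0, twist=0.0)
        frame = fit_helix(detect_pairs(st))
        assert frame.rise_per_step == (pytest.approx(3.0, abs=1e-6),)
        assert frame.twist_per_step[0] == pytest.approx(0.0, abs=1e-6)

    def test_too_few_pairs(self):
        st = make_ideal_aform(RnaSequence("x", "G"))
        with pytest.raises(StructureError):
            fit_helix(detect_pairs(st))

    def test_rigid_motion_invariance(self):
        st = make_ideal_aform(SEQ, rise=2.6, twist=31.0)
        R = Rotation.from_euler("xyz", [11, -37, 101],
                                degrees=True).as_matrix()
        moved = rigid_copy(st, R, np.array([5.0, -3.0, 12.0]))
        p0, p1 = detect_pairs(st), detect_pairs(moved)
        f0, f1 = fit_helix(p0), fit_helix(p1)
        assert np.allclose(f0.rise_per_step, f1.rise_per_step, atol=1e-6)
        assert np.allclose(f0.twist_per_step, f1.twist_per_step, atol=1e-6)
        for a, b in zip(p0, p1):
            assert a.c1_c1 == pytest.approx(b.c1_c1, abs=1e-6)
            assert a.lambda1 == pytest.approx(b.lambda1, abs=1e-6)


class TestKabsch:
    def test_identity_and_rigid_motion_are_zero(self):
        P = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [4, 1, 2]])
        assert kabsch_rmsd(P, P) == pytest.approx(0.0, abs=1e-12)
        R = Rotation.from_euler("zyx", [30, 60, -45], degrees=True)
        assert kabsch_rmsd(P, P @ R.as_matrix().T + 7.5) == \
            pytest.approx(0.0, abs=1e-9)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        P, Q = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        assert kabsch_rmsd(P, Q) == pytest.approx(kabsch_rmsd(Q, P))

    def test_three_point_radial_displacement(self):
        # equilateral triangles of radius 2 and 3 about the origin:
        # optimal rotation is the identity, every atom is off by 1 A
        ang = [0.0, 2 * math.pi / 3, 4 * math.pi / 3]
        P = np.array([[2 * math.cos(a), 2 * math.sin(a), 0] for a in ang])
        Q = np.array([[3 * math.cos(a), 3 * math.sin(a), 0] for a in ang])
        assert kabsch_rmsd(P, Q) == pytest.approx(1.0, abs=1e-9)

    def test_against_scipy_align_vectors(self):
        rng = np.random.default_rng(3)
        P, Q = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        Pc, Qc = P - P.mean(0), Q - Q.mean(0)
        _, rssd = Rotation.align_vectors(Qc, Pc)
        assert kabsch_rmsd(P, Q) == pytest.approx(rssd / math.sqrt(10),
                                                  rel=1e-9)

    def test_proper_rotation_enforced(self):
        P = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        mirrored = P * np.array([-1.0, 1.0, 1.0])
        rmsd, R, _ = kabsch_superpose(P, mirrored)
        assert np.linalg.det(R) == pytest.approx(1.0)
        assert rmsd > 0.1

    def test_size_mismatch(self):
        with pytest.raises(StructureError):
            kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


class TestStructureIO:
    def test_roundtrip_via_pdb(self, tmp_path):
        st = make_ideal_aform(SEQ, rise=2.75, twist=30.0)
        path = tmp_path / "fix.pdb"
        write_pdb(st, path)
        st2 = read_structure(path, fmt="pdb")
        for cid in st.chains:
            for r1, r2 in zip(st.chains[cid], st2.chains[cid]):
                for name, a in r1.atoms.items():
                    assert np.allclose(a.coord, r2.atoms[name].coord,
                                       atol=1e-3)

    def test_empty_file_is_io_error(self, tmp_path):
        f = tmp_path / "empty.pdb"
        f.write_text("")
        with pytest.raises(StructureError):
            read_structure(f)

    def test_altloc_highest_occupancy(self, tmp_path):
        st = make_ideal_aform(RnaSequence("x", "GC"))
        res = st.chains["A"][0]
        base = res.atoms["C1'"]
        res.alt_atoms.clear()
        res.alt_atoms[("C1'", "A")] = Atom("C1'", "C", base.xyz, 0.7, "A")
        shifted = tuple(v + 0.5 for v in base.xyz)
        res.alt_atoms[("C1'", "B")] = Atom("C1'", "C", shifted, 0.3, "B")
        for a in res.atoms.values():
            if a.name != "C1'":
                res.alt_atoms[(a.name, "")] = a
        path = tmp_path / "alt.pdb"
        write_pdb(st, path)
        high = read_structure(path, altloc_policy="highest_occupancy")
        got = high.chains["A"][0].atoms["C1'"]
        assert got.occupancy == pytest.approx(0.7)
        assert np.allclose(got.coord, base.coord, atol=1e-3)
        lab = read_structure(path, altloc_policy="label:B")
        assert np.allclose(lab.chains["A"][0].atoms["C1'"].coord,
                           shifted, atol=1e-3)
        combos = pair_geometry_altlocs(lab.chains["A"][0],
                                       lab.chains["B"][0])
        assert set(combos) == {("A", ""), ("B", "")}
        assert combos[("A", "")].c1_c1 != pytest.approx(
            combos[("B", "")].c1_c1)

    def test_missing_c1_excluded_with_warning(self, tmp_path):
        st = make_ideal_aform(RnaSequence("x", "GCGC"))
        del st.chains["A"][0].atoms["C1'"]
        st.chains["A"][0].alt_atoms.pop(("C1'", ""), None)
        path = tmp_path / "noc1.pdb"
        write_pdb(st, path)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            st2 = read_structure(path)
        assert any("C1'" in str(w.message) for w in caught)
        assert len(st2.chains["A"]) == 3


class TestGlycosidic:
    def _residue(self, c4_y):
        atoms = {
            "O4'": Atom("O4'", "O", (-0.5, 1.0, 0.0)),
            "C1'": Atom("C1'", "C", (0.0, 0.0, 0.0)),
            "N9": Atom("N9", "N", (1.5, 0.0, 0.0)),
            "C4": Atom("C4", "C", (2.0, c4_y, 0.0)),
        }
        return Residue("A", 1, "G", atoms)

    def test_syn_and_anti(self):
        assert glycosidic_conformation(self._residue(1.0)) == "syn"
        assert glycosidic_conformation(self._residue(-1.0)) == "anti"

    def test_dihedral_signs(self):
        p = [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)]
        assert dihedral(*p) == pytest.approx(0.0, abs=1e-9)
        q = [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)]
        assert abs(dihedral(*q)) == pytest.approx(180.0, abs=1e-9)
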