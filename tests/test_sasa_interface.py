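import math

import numpy as np
import pytest

from bclkit import sasa_interface as si
from bclkit import structure_io as sio
from bclkit import synthetic_data as sd
from oracles import sphere_area, two_sphere_accessible_area

CARBON_R = si.DEFAULT_RADII["C_aliphatic"]
PROBE = 1.4


def _atom(serial, x, y, z, name="CA", chain="A", resseq=None, resname="ALA",
          element="C"):
    return sio.AtomRecord(serial, name, "", resname, chain,
                          resseq if resseq is not None else serial, "",
                          x, y, z, 1.0, 20.0, element)


class TestSasaAnalytics:
    def test_single_atom_matches_analytic_sphere(self):
        st = sio.Structure(id="one", atoms=[_atom(1, 0, 0, 0)])
        res = si.sasa(st)
        expect = sphere_area(CARBON_R + PROBE)
        assert res.total == pytest.approx(expect, rel=0.005)

    def test_distant_atoms_are_additive(self):
        st = sio.Structure(id="two", atoms=[_atom(1, 0, 0, 0), _atom(2, 20, 0, 0)])
        res = si.sasa(st)
        assert res.total == pytest.approx(2 * sphere_area(CARBON_R + PROBE), rel=0.005)

    def test_two_overlapping_spheres_match_cap_formula(self):
        d = 3.0
        st = sio.Structure(id="pair", atoms=[_atom(1, 0, 0, 0), _atom(2, d, 0, 0)])
        res = si.sasa(st)
        expect = two_sphere_accessible_area(CARBON_R + PROBE, d)
        for area in res.per_atom.values():
            assert area == pytest.approx(expect, rel=0.005)

    def test_quadrature_converges_on_point_doubling(self, helix20):
        t1 = si.sasa(helix20, si.SASAParams(sphere_points=960)).total
        t2 = si.sasa(helix20, si.SASAParams(sphere_points=1920)).total
        assert abs(t2 - t1) / t1 < 0.003

    def test_totals_equal_sum_of_parts(self, helix20):
        res = si.sasa(helix20)
        assert res.total == pytest.approx(sum(res.per_atom.values()), abs=1e-6)
        assert res.total == pytest.approx(sum(res.per_residue.values()), abs=1e-6)

    def test_rigid_motion_invariance(self, rng):
        helix = sd.make_helix(sd.HelixSpec(n_residues=20, with_sidechains=True))
        base = si.sasa(helix)
        for _ in range(3):
            moved = sd.transform_structure(
                helix, sd.random_rotation(rng), rng.normal(0, 10, 3)
            )
            res = si.sasa(moved)
            assert res.total == pytest.approx(base.total, abs=1e-6)

    def test_unknown_element_without_default_radius_raises(self):
        st = sio.Structure(id="odd", atoms=[_atom(1, 0, 0, 0, element="Xx")])
        params = si.SASAParams(radii_table={"C_aliphatic": 1.87, "C_sp2": 1.76})
        with pytest.raises(ValueError, match="radius"):
            si.sasa(st, params)

    def test_waters_excluded_by_default(self):
        atoms = [_atom(1, 0, 0, 0)]
        atoms.append(sio.AtomRecord(2, "O", "", "HOH", "A", 100, "",
                                    3.0, 0, 0, 1.0, 30.0, "O", het=True))
        st = sio.Structure(id="wet", atoms=atoms)
        res = si.sasa(st)
        assert len(res.per_atom) == 1
        assert res.total == pytest.approx(sphere_area(CARBON_R + PROBE), rel=0.005)


class TestBuriedSurface:
    def test_distant_chains_bury_nothing(self):
        a = sd.make_helix(sd.HelixSpec(n_residues=8), chain="A")
        b = sd.make_helix(sd.HelixSpec(n_residues=8), chain="B")
        far = sd.transform_structure(b, np.eye(3), np.array([50.0, 0, 0]))
        st = sio.Structure(id="apart", atoms=a.atoms + far.atoms)
        rep = si.buried_surface(st, {"A"}, {"B"})
        assert rep.buried_total == pytest.approx(0.0, abs=1e-6)

    def test_definition_identity_and_per_partner_split(self):
        cplx, _ = sd.make_groove_complex(
            plan=sd.ContactPlan(hbonds=[(5, 2.9)], hotspots=[10])
        )
        rep = si.buried_surface(cplx, {"R"}, {"P"})
        assert rep.buried_total > 0
        # definitional oracle: independent recomputation of A + B − AB from
        # three SASA runs under the complex's shared quadrature frame
        params = si.SASAParams()
        union = cplx.subset({"R", "P"})
        frame = si._principal_frame(
            np.array([[a.x, a.y, a.z] for a in union.atoms])
        )
        t_a = si.sasa(cplx.subset({"R"}), params, frame=frame).total
        t_b = si.sasa(cplx.subset({"P"}), params, frame=frame).total
        t_ab = si.sasa(union, params, frame=frame).total
        assert rep.buried_total == pytest.approx(t_a + t_b - t_ab, abs=1e-6)
        assert sum(rep.buried_per_partner) == pytest.approx(rep.buried_total, abs=1e-6)
        assert rep.interface_area_pisa == pytest.approx(rep.buried_total / 2, abs=1e-9)

    def test_symmetric_in_partners(self):
        cplx, _ = sd.make_groove_complex(plan=sd.ContactPlan(hbonds=[(5, 2.9)]))
        r1 = si.buried_surface(cplx, {"R"}, {"P"})
        r2 = si.buried_surface(cplx, {"P"}, {"R"})
        assert r1.buried_total == pytest.approx(r2.buried_total, abs=1e-6)

    def test_overlapping_chain_sets_rejected(self):
        cplx, _ = sd.make_groove_complex(plan=sd.ContactPlan(hbonds=[(5, 2.9)]))
        with pytest.raises(ValueError, match="overlap"):
            si.buried_surface(cplx, {"R", "P"}, {"P"})


class TestHbonds:
    def test_planted_pair_detected_at_29_but_not_50(self):
        for dist, expected in ((2.9, 1), (5.0, 0)):
            cplx, truth = sd.make_groove_complex(
                plan=sd.ContactPlan(hbonds=[(5, dist)])
            )
            hits = si.find_hbonds(cplx, {"R"}, {"P"})
            assert len(hits) == expected
            if expected:
                t = truth["hbonds"][0]
                assert hits[0].donor == tuple(t["donor"])
                assert hits[0].acceptor == tuple(t["acceptor"])
                assert hits[0].distance == pytest.approx(dist, abs=1e-6)

    def test_angle_criterion_rejects_backfolded_geometry(self):
        # donor OG with antecedent CB; acceptor placed on the CB side → angle ≈ 0
        cb = _atom(1, 0, 0, 0, name="CB", resname="SER", resseq=1)
        og = _atom(2, 1.4, 0, 0, name="OG", resname="SER", resseq=1, element="O")
        acc = _atom(3, 0.4, 0.5, 0, name="OE1", resname="GLU", resseq=2,
                    chain="B", element="O")
        st = sio.Structure(id="bent", atoms=[cb, og, acc])
        assert si.find_hbonds(st, {"A"}, {"B"}) == []

    def test_each_pair_reported_once(self):
        cplx, _ = sd.make_groove_complex(
            plan=sd.ContactPlan(hbonds=[(5, 2.9), (9, 3.2)])
        )
        hits = si.find_hbonds(cplx, {"R"}, {"P"})
        keys = {(h.donor, h.acceptor) for h in hits}
        assert len(keys) == len(hits) == 2


class TestSaltBridges:
    def test_planted_bridge_detected(self):
        cplx, truth = sd.make_groove_complex(
            plan=sd.ContactPlan(salt_bridges=[(7, 3.2)])
        )
        hits = si.find_salt_bridges(cplx, {"R"}, {"P"})
        assert len(hits) == 1
        t = truth["salt_bridges"][0]
        assert hits[0].basic_atom == tuple(t["basic"])
        assert hits[0].acidic_atom == tuple(t["acidic"])

    def test_six_angstrom_pair_not_detected(self):
        cplx, _ = sd.make_groove_complex(plan=sd.ContactPlan(salt_bridges=[(7, 6.0)]))
        assert si.find_salt_bridges(cplx, {"R"}, {"P"}) == []


class TestHotspots:
    def test_free_peptide_burial_zero(self):
        peptide = sd.make_helix(
            sd.HelixSpec(n_residues=15, with_sidechains=True), chain="P"
        )
        res = si.hotspot_burial(peptide, set(), "P", [("P", 5, ""), ("P", 8, "")])
        # no receptor chains at all → complexed SASA equals free SASA
        assert all(h.burial_fraction == pytest.approx(0.0, abs=1e-9) for h in res)

    def test_caged_sidechain_fully_buried_others_free(self):
        cplx, _ = sd.make_groove_complex(plan=sd.ContactPlan(hotspots=[12]))
        res = si.hotspot_burial(cplx, {"R"}, "P", [("P", 12, ""), ("P", 3, "")])
        by_res = {h.residue: h for h in res}
        assert by_res[("P", 12, "")].burial_fraction > 0.9
        assert by_res[("P", 12, "")].engaged
        assert by_res[("P", 3, "")].burial_fraction < 0.1
        assert not by_res[("P", 3, "")].engaged

    def test_glycine_hotspot_warns_and_reports_zero(self):
        atoms = [
            _atom(1, 0, 0, 0, name="N", resname="GLY", resseq=1, chain="P",
                  element="N"),
            _atom(2, 1.4, 0, 0, name="CA", resname="GLY", resseq=1, chain="P"),
            _atom(3, 10, 0, 0, name="CA", resname="ALA", resseq=1, chain="R"),
        ]
        st = sio.Structure(id="gly", atoms=atoms)
        with pytest.warns(UserWarning, match="side chain"):
            res = si.hotspot_burial(st, {"R"}, "P", [("P", 1, "")])
        assert res[0].sasa_free == 0.0
        assert res[0].burial_fraction == 0.0

    def test_missing_hotspot_residue_raises(self):
        cplx, _ = sd.make_groove_complex(plan=sd.ContactPlan(hotspots=[12]))
        with pytest.raises(KeyError):
            si.hotspot_burial(cplx, {"R"}, "P", [("P", 99, "")])


def test_atom_radius_classes():
    backbone_c = _atom(1, 0, 0, 0, name="C")
    aromatic = _atom(2, 0, 0, 0, name="CZ", resname="PHE")
    aliphatic = _atom(3, 0, 0, 0, name="CB")
    sulfur = _atom(4, 0, 0, 0, name="SD", resname="MET", element="S")
    r = si.DEFAULT_RADII
    assert si.atom_radius(backbone_c, r) == r["C_sp2"]
    assert si.atom_radius(aromatic, r) == r["C_sp2"]
    assert si.atom_radius(aliphatic, r) == r["C_aliphatic"]
    assert si.atom_radius(sulfur, r) == r["S"]
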