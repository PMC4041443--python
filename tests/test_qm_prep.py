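"""Capped dimer models and the interaction-energy arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pisurvey.geometry import dihedral, place_atom, random_rotation
from pisurvey.qm_prep import (HARTREE_TO_KJ, CappedMonomer, CompositeEnergySpec,
                              EnergyRecord, binding_energy, cap_amino_acid,
                              cap_nucleobase, cap_sugar, cbs_extrapolate,
                              ccsdt_cbs_estimate, expand_variants,
                              overlay_reference, read_xyz, write_dimer_geometry,
                              write_dimer_set)
from pisurvey.structure_io import AtomRecord, extract_moieties
from pisurvey.synth import (_moieties_from_records, _records_from_template,
                            build_pi_dimer)
from pisurvey.templates import deoxyribose_template


def moieties_for(base, aa):
    records, _ = build_pi_dimer(base, aa, omega=5.0, rise=3.5)
    ms, _ = extract_moieties(records)
    return (next(m for m in ms if m.kind == "nucleobase_ring"),
            next(m for m in ms if m.kind == "aromatic_aa_ring"))


class TestCapNucleobase:
    @pytest.mark.parametrize("base,n_atoms,formula", [
        ("A", 15, "C5H5N5"), ("C", 13, "C4H5N3O"),
        ("G", 16, "C5H5N5O"), ("T", 15, "C5H6N2O2"),
    ])
    def test_free_base_formula(self, base, n_atoms, formula):
        mb, _ = moieties_for(base, "PHE")
        capped = cap_nucleobase(mb)
        assert capped.n_atoms == n_atoms
        assert capped.formula() == formula
        assert all(capped.atoms[i][0] == "H" for i in capped.cap_atoms)
        assert capped.charge == 0

    def test_cap_lies_on_glycosidic_vector(self):
        mb, _ = moieties_for("A", "PHE")
        capped = cap_nucleobase(mb)
        n9 = dict((n, p) for _, n, p in capped.atoms)["N9"]
        h9 = capped.atoms[capped.cap_atoms[0]][2]
        c1 = mb.atoms["C1'"]
        u = (h9 - n9) / np.linalg.norm(h9 - n9)
        v = (c1 - n9) / np.linalg.norm(c1 - n9)
        angle = np.degrees(np.arccos(np.clip(np.dot(u, v), -1, 1)))
        assert angle < 1.0
        assert np.linalg.norm(h9 - n9) == pytest.approx(1.01, abs=1e-9)


class TestCapAminoAcid:
    def test_phe_is_benzene(self):
        _, ma = moieties_for("A", "PHE")
        capped = cap_amino_acid(ma)
        assert capped.n_atoms == 12
        assert capped.formula() == "C6H6"

    def test_his_variants(self):
        _, ma = moieties_for("A", "HIS")
        variants = expand_variants(ma)
        tags = [v.variant_tag for v in variants]
        assert tags == ["His_delta", "His_epsilon", "His_plus"]
        assert [v.formula() for v in variants] == ["C3H4N2", "C3H4N2", "C3H5N2"]
        assert [v.charge for v in variants] == [0, 0, 1]

    def test_tyr_hydroxyl_orientations(self):
        _, ma = moieties_for("A", "TYR")
        cw, ccw = expand_variants(ma)
        assert {cw.variant_tag, ccw.variant_tag} == {"Tyr_CW", "Tyr_CCW"}
        for v, expected in ((cw, 0.0), (ccw, 180.0)):
            pos = {n: p for _, n, p in v.atoms}
            tor = dihedral(pos["CE1"], pos["CZ"], pos["OH"], pos["HH"])
            assert abs(abs(tor) - abs(expected)) < 1e-6 or \
                tor == pytest.approx(expected, abs=1e-6)
        assert cw.formula() == ccw.formula() == "C6H6O"

    def test_all_added_atoms_are_hydrogens(self):
        for aa in ("PHE", "TYR", "TRP", "HIS"):
            _, ma = moieties_for("A", aa)
            for v in expand_variants(ma):
                heavy_names = set(ma.atoms)
                for element, name, _ in v.atoms:
                    if name not in heavy_names:
                        assert element == "H"


def sugar_with_phosphorus():
    template = deoxyribose_template("N1")
    # a 5' phosphorus defining the crystal C4'-C5'-O5'-P dihedral
    p5 = place_atom(template["C4'"], template["C5'"], template["O5'"],
                    1.60, 120.0, -73.0)
    records = _records_from_template(template, "DT", "B", 1)
    records.append(AtomRecord("P", "P", "DT", "B", 1, "", p5))
    ms, _ = extract_moieties(records)
    return next(m for m in ms if m.kind == "deoxyribose")


class TestCapSugar:
    def test_model_is_c5h10o3(self):
        capped = cap_sugar(sugar_with_phosphorus())
        assert capped.n_atoms == 18
        assert capped.formula() == "C5H10O3"
        assert all(capped.atoms[i][0] == "H" for i in capped.cap_atoms)

    def test_frozen_dihedral_equals_crystal_op_direction(self):
        sugar = sugar_with_phosphorus()
        capped = cap_sugar(sugar)
        frozen5 = next(f for f in capped.frozen_dihedrals
                       if f["atoms"][2] == "O5'")
        crystal = dihedral(sugar.atoms["C4'"], sugar.atoms["C5'"],
                           sugar.atoms["O5'"], sugar.atoms["P"])
        assert frozen5["degrees"] == pytest.approx(crystal, abs=1e-9)
        assert not frozen5["default_used"]
        # construction self-consistency: the cap realizes the frozen value
        pos = {n: p for _, n, p in capped.atoms}
        assert dihedral(pos["C4'"], pos["C5'"], pos["O5'"], pos["HO5'"]) == \
            pytest.approx(frozen5["degrees"], abs=1e-6)

    def test_terminal_without_phosphorus_uses_default_and_flags(self):
        template = deoxyribose_template("N1")
        records = _records_from_template(template, "DT", "B", 1)
        ms, _ = extract_moieties(records)
        capped = cap_sugar(next(m for m in ms if m.kind == "deoxyribose"),
                           default_dihedral=180.0)
        assert all(f["default_used"] for f in capped.frozen_dihedrals)
        assert all(f["degrees"] == 180.0 for f in capped.frozen_dihedrals)


class TestOverlayReference:
    def test_identity_overlay(self):
        mb, _ = moieties_for("G", "TRP")
        template = cap_nucleobase(mb)
        placed, rmsd = overlay_reference(template, mb)
        assert rmsd < 1e-9

    def test_known_rotation_recovered(self):
        mb, _ = moieties_for("C", "PHE")
        template = cap_nucleobase(mb)
        rng = np.random.default_rng(0)
        rot = random_rotation(rng)
        shift = rng.normal(size=3) * 5
        moved = CappedMonomer(
            kind=template.kind, residue_name=template.residue_name,
            atoms=[(el, n, rot @ p + shift) for el, n, p in template.atoms],
            cap_atoms=template.cap_atoms)
        placed, rmsd = overlay_reference(moved, mb)
        assert rmsd < 1e-6

    def test_internal_geometry_preserved(self):
        mb, _ = moieties_for("T", "TYR")
        template = cap_nucleobase(mb)
        rng = np.random.default_rng(1)
        rot = random_rotation(rng)
        moved = CappedMonomer(
            kind=template.kind, residue_name=template.residue_name,
            atoms=[(el, n, rot @ p + 3.0) for el, n, p in template.atoms],
            cap_atoms=template.cap_atoms)
        placed, _ = overlay_reference(moved, mb)
        p0 = moved.positions()
        p1 = placed.positions()
        d0 = np.linalg.norm(p0[:, None] - p0[None], axis=-1)
        d1 = np.linalg.norm(p1[:, None] - p1[None], axis=-1)
        assert np.allclose(d0, d1, atol=1e-9)


class TestEnergyArithmetic:
    def test_binding_energy_kj(self):
        rec = EnergyRecord(E_dimer=-100.0, E_aa=-40.0, E_nt=-50.0,
                           units="kJ/mol")
        assert binding_energy(rec) == pytest.approx(-10.0)

    def test_noninteracting_limit(self):
        rec = EnergyRecord(E_dimer=-90.0, E_aa=-40.0, E_nt=-50.0,
                           units="kJ/mol")
        assert binding_energy(rec) == 0.0

    def test_hartree_conversion(self):
        rec_h = EnergyRecord(E_dimer=-1.0, E_aa=-0.4, E_nt=-0.5)
        assert binding_energy(rec_h) == pytest.approx(-0.1 * HARTREE_TO_KJ)

    def test_cbs_fixed_point(self):
        spec = CompositeEnergySpec(X=2, Y=3, E_X=-0.7, E_Y=-0.7, E_ref_Y=-10.0)
        assert cbs_extrapolate(spec) == pytest.approx(-10.7, abs=1e-12)

    def test_cbs_inverts_inverse_cube_series(self):
        # E(n) = E_inf + A n^-3 is recovered exactly from two points
        e_inf, a = -1.0, 0.5
        spec = CompositeEnergySpec(X=2, Y=3, E_X=e_inf + a / 8.0,
                                   E_Y=e_inf + a / 27.0)
        assert cbs_extrapolate(spec) == pytest.approx(e_inf, abs=1e-12)

    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5),
           st.floats(-5, 5), st.floats(-3, 3), st.floats(-3, 3))
    @settings(max_examples=50, deadline=None)
    def test_cbs_linearity(self, e1x, e1y, e2x, e2y, a, b):
        def extrap(ex, ey):
            return cbs_extrapolate(CompositeEnergySpec(X=2, Y=3, E_X=ex,
                                                       E_Y=ey))
        combined = extrap(a * e1x + b * e2x, a * e1y + b * e2y)
        assert combined == pytest.approx(a * extrap(e1x, e1y)
                                         + b * extrap(e2x, e2y), abs=1e-9)

    def test_cbs_requires_increasing_cardinals(self):
        with pytest.raises(ValueError):
            cbs_extrapolate(CompositeEnergySpec(X=3, Y=3, E_X=0, E_Y=0))

    def test_ccsdt_composite(self):
        assert ccsdt_cbs_estimate(-20.0, -18.0, -15.0) == pytest.approx(-23.0)
        assert ccsdt_cbs_estimate(-20.0, -5.0, -5.0) == pytest.approx(-20.0)

    def test_ccsdt_additive_over_fragments(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(size=3)
            b = rng.normal(size=3)
            total = ccsdt_cbs_estimate(*(a + b))
            assert total == pytest.approx(ccsdt_cbs_estimate(*a)
                                          + ccsdt_cbs_estimate(*b), abs=1e-9)


class TestDimerOutput:
    def test_adenine_benzene_dimer_has_27_atoms(self, tmp_path):
        mb, ma = moieties_for("A", "PHE")
        sidecar = write_dimer_geometry(cap_amino_acid(ma), cap_nucleobase(mb),
                                       tmp_path / "dimer.xyz", entry_id="X1")
        elements, coords, _ = read_xyz(tmp_path / "dimer.xyz")
        assert len(elements) == 27
        assert sidecar["monomers"][0]["atom_range"] == [0, 12]
        assert sidecar["monomers"][1]["atom_range"] == [12, 27]

    def test_round_trip_coordinates(self, tmp_path):
        mb, ma = moieties_for("G", "TYR")
        capped_aa = cap_amino_acid(ma, "Tyr_CW")
        capped_b = cap_nucleobase(mb)
        write_dimer_geometry(capped_aa, capped_b, tmp_path / "d.xyz")
        _, coords, _ = read_xyz(tmp_path / "d.xyz")
        orig = np.vstack([capped_aa.positions(), capped_b.positions()])
        assert np.allclose(coords, orig, atol=1e-6)

    def test_his_dimer_writes_three_files(self, tmp_path):
        mb, ma = moieties_for("C", "HIS")
        paths = write_dimer_set(cap_nucleobase(mb), ma, tmp_path, "c_his")
        assert len(paths) == 3
        assert sorted(p.name for p in paths) == [
            "c_his_His_delta.xyz", "c_his_His_epsilon.xyz",
            "c_his_His_plus.xyz"]
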