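"""Rolling-probe surface area, rASA normalization and burial rules."""

import numpy as np
import pytest

from tmexpo.fixtures import (
    HelixSpec,
    compute_gxg_reference,
    extended_tripeptide,
    ideal_helix_atoms,
)
from tmexpo.sasa import (
    classify_burial,
    compute_asa,
    interface_exclusion,
    load_reference_table,
    relative_asa,
    unit_sphere_points,
)
from tmexpo.structure_io import Atom, StructureModel


def carbon(x, y, z, key=("A", 1, ""), name="C1"):
    return Atom(name=name, element="C", coord=np.array([x, y, z], dtype=float),
                vdw_radius=1.87, residue_key=key, residue_name="ALA")


class TestComputeAsa:
    def test_isolated_atom_matches_analytic_sphere(self):
        st = StructureModel(atoms=[carbon(0, 0, 0)], chains={"A"})
        area = compute_asa(st, probe_radius=2.0).per_atom[0]
        analytic = 4 * np.pi * 3.87 ** 2
        assert area == pytest.approx(analytic, rel=0.01)

    def test_far_apart_atoms_are_additive(self):
        st = StructureModel(
            atoms=[carbon(0, 0, 0), carbon(100, 0, 0, key=("A", 2, ""))],
            chains={"A"},
        )
        res = compute_asa(st)
        single = compute_asa(StructureModel(atoms=[carbon(0, 0, 0)], chains={"A"}))
        assert sum(res.per_atom.values()) == pytest.approx(
            2 * single.per_atom[0], rel=1e-9
        )

    def test_caged_atom_has_zero_area(self):
        # octahedral cage at distance 3 Å fully encloses the central sphere
        cage = [carbon(*(3.0 * np.eye(3)[i] * s), key=("A", 2 + j, ""))
                for j, (i, s) in enumerate([(0, 1), (0, -1), (1, 1), (1, -1),
                                            (2, 1), (2, -1)])]
        st = StructureModel(atoms=[carbon(0, 0, 0)] + cage, chains={"A"})
        assert compute_asa(st).per_atom[0] == 0.0

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        atoms = ideal_helix_atoms(HelixSpec(n_residues=12))
        st = StructureModel(atoms=list(atoms), chains={"A"})
        base = compute_asa(st)
        rot = Rotation.from_euler("zyx", [31, -47, 112], degrees=True).as_matrix()
        moved = [
            Atom(name=a.name, element=a.element,
                 coord=rot @ a.coord + np.array([3.0, -8.0, 5.0]),
                 vdw_radius=a.vdw_radius, residue_key=a.residue_key,
                 residue_name=a.residue_name)
            for a in atoms
        ]
        st2 = StructureModel(atoms=moved, chains={"A"})
        total1 = sum(base.per_atom.values())
        total2 = sum(compute_asa(st2).per_atom.values())
        assert total2 == pytest.approx(total1, rel=0.01)

    def test_doubling_sampling_converges(self):
        st = StructureModel(atoms=ideal_helix_atoms(HelixSpec(n_residues=12)),
                            chains={"A"})
        lo = compute_asa(st, n_points=960).per_residue
        hi = compute_asa(st, n_points=1920).per_residue
        for key in lo:
            assert hi[key] == pytest.approx(lo[key], rel=0.02, abs=0.5)

    def test_too_few_points_rejected(self):
        st = StructureModel(atoms=[carbon(0, 0, 0)], chains={"A"})
        with pytest.raises(ValueError):
            compute_asa(st, n_points=5)

    def test_point_set_deterministic(self):
        assert np.array_equal(unit_sphere_points(960), unit_sphere_points(960))


class TestRelativeAsa:
    def test_reference_value_maps_to_one(self):
        ref = {"ALA": 140.0}
        assert relative_asa(140.0, "ALA", ref) == 1.0
        assert relative_asa(0.0, "ALA", ref) == 0.0

    def test_unknown_residue_rejected(self):
        with pytest.raises(KeyError):
            relative_asa(10.0, "XYZ", {"ALA": 140.0})

    def test_above_one_preserved_unless_clamped(self):
        ref = {"ALA": 100.0}
        assert relative_asa(120.0, "ALA", ref) == pytest.approx(1.2)
        assert relative_asa(120.0, "ALA", ref, clamp=True) == 1.0

    def test_bundled_reference_self_consistent(self):
        """Recomputing extended Gly-X-Gly areas reproduces the bundled table."""
        table = load_reference_table()
        recomputed = compute_gxg_reference(probe_radius=2.0, n_points=960)
        for res in ("ALA", "LEU", "TRP"):
            assert relative_asa(recomputed[res], res, table) == pytest.approx(
                1.0, abs=0.05
            )

    def test_central_residue_fully_extended(self):
        st = extended_tripeptide("PHE")
        asa = compute_asa(st)
        assert relative_asa(asa.per_residue[("A", 2, "")], "PHE") == pytest.approx(
            1.0, abs=0.05
        )


class TestBurial:
    @pytest.mark.parametrize(
        "rasa,label",
        [(0.0, "B"), (0.0213, "B"), (0.0499, "B"), (0.05, "E"), (0.0903, "E"),
         (1.0, "E")],
    )
    def test_five_percent_rule_is_strict(self, rasa, label):
        assert classify_burial(rasa) == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_burial(-0.1)


class TestInterfaceExclusion:
    def test_equal_profiles_keep_everything(self):
        prof = {("A", 1, ""): 0.3, ("A", 2, ""): 0.6}
        mask = interface_exclusion(prof, dict(prof))
        assert not any(mask.values())

    def test_interface_residue_excluded(self):
        sub = {("A", 60, ""): 0.6077}
        com = {("A", 60, ""): 0.0242}
        assert interface_exclusion(sub, com)[("A", 60, "")] is True

    def test_missing_atoms_excluded_regardless(self):
        prof = {("A", 1, ""): 0.3}
        mask = interface_exclusion(prof, dict(prof), missing_atoms={("A", 1, "")})
        assert mask[("A", 1, "")] is True

    def test_mismatched_residue_sets_rejected(self):
        with pytest.raises(ValueError):
            interface_exclusion({("A", 1, ""): 0.1}, {("A", 2, ""): 0.1})


class TestMultimerMonotonicity:
    def test_subunit_rasa_never_below_complex_rasa(self):
        """Adding a second chain can only occlude: exact with a shared,
        deterministic point set."""
        a_atoms = ideal_helix_atoms(HelixSpec(n_residues=14, position=(0.0, 0.0)),
                                    chain="A")
        b_atoms = ideal_helix_atoms(HelixSpec(n_residues=14, position=(7.0, 0.0)),
                                    chain="B")
        alone = compute_asa(StructureModel(atoms=a_atoms, chains={"A"}))
        both = compute_asa(StructureModel(atoms=a_atoms + b_atoms, chains={"A", "B"}))
        for key, area in alone.per_residue.items():
            assert area >= both.per_residue[key] - 1e-9
        # and the contact does reduce someone's exposure
        assert sum(alone.per_residue.values()) > sum(
            both.per_residue[k] for k in alone.per_residue
        )
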