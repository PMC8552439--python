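import numpy as np
import pandas as pd
import pytest

from msmhdx.annotate import (
    APlane,
    backbone_dihedral,
    classify_elements,
    default_insulin_rules,
    element_percentages,
    evaluate_rule,
    helix_content,
    hbond_present,
    load_rules,
    min_distance,
    plane_side,
)
from msmhdx.peptide import ALPHA_HELIX, EXTENDED, build_chain, place_atom
from msmhdx.trajectory import Atom, Topology, TrajectoryEnsemble


def _chain_ensemble(dihedrals, n_frames=1):
    top, xyz = build_chain(dihedrals)
    frames = np.repeat(xyz[None], n_frames, axis=0)
    return TrajectoryEnsemble(top, [frames])


class TestPeptideBuilder:
    def test_bond_lengths_and_sites(self):
        top, xyz = build_chain([ALPHA_HELIX] * 5)
        # every residue after the first is an amide site
        assert top.amide_sites == [("A", r) for r in range(2, 6)]
        for r in range(1, 6):
            n = xyz[top.atom_index("A", r, "N")]
            ca = xyz[top.atom_index("A", r, "CA")]
            c = xyz[top.atom_index("A", r, "C")]
            assert np.isclose(np.linalg.norm(ca - n), 0.1458, atol=1e-6)
            assert np.isclose(np.linalg.norm(c - ca), 0.1525, atol=1e-6)

    def test_place_atom_roundtrip(self):
        """place_atom realises the requested bond/angle/dihedral exactly."""
        from msmhdx.annotate import _dihedral

        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c = rng.normal(size=(3, 3))
            bond, angle, dih = 0.15, 109.5, float(rng.uniform(-179, 180))
            d = place_atom(a, b, c, bond, angle, dih)
            assert np.isclose(np.linalg.norm(d - c), bond, atol=1e-9)
            got = _dihedral(a[None], b[None], c[None], d[None])[0]
            assert np.isclose(got, dih, atol=1e-6)

    def test_too_short_chain(self):
        with pytest.raises(ValueError, match="at least two"):
            build_chain([ALPHA_HELIX])


class TestBackboneDihedral:
    def test_recovers_construction_dihedrals(self):
        dihedrals = [(-57.0, -47.0), (-120.0, 130.0), (60.0, 40.0), (-75.0, 150.0)]
        ens = _chain_ensemble(dihedrals)
        for r in (2, 3, 4):
            assert np.isclose(
                backbone_dihedral(ens, ("A", r), "phi")[0],
                dihedrals[r - 1][0],
                atol=1e-6,
            )
        for r in (1, 2, 3):
            assert np.isclose(
                backbone_dihedral(ens, ("A", r), "psi")[0],
                dihedrals[r - 1][1],
                atol=1e-6,
            )

    def test_matches_mdtraj(self):
        """Independent oracle: mdtraj's phi/psi on the same coordinates."""
        import mdtraj as md

        from msmhdx.trajectory import _topology_to_mdtraj

        dihedrals = [ALPHA_HELIX, (-130.0, 140.0), (55.0, 45.0), ALPHA_HELIX,
                     (-80.0, 100.0)]
        top, xyz = build_chain(dihedrals)
        ens = TrajectoryEnsemble(top, [xyz[None]])
        traj = md.Trajectory(xyz[None], _topology_to_mdtraj(top))
        _, phi = md.compute_phi(traj)
        _, psi = md.compute_psi(traj)
        ours_phi = [backbone_dihedral(ens, ("A", r), "phi")[0] for r in range(2, 6)]
        ours_psi = [backbone_dihedral(ens, ("A", r), "psi")[0] for r in range(1, 5)]
        np.testing.assert_allclose(ours_phi, np.degrees(phi[0]), atol=1e-3)
        np.testing.assert_allclose(ours_psi, np.degrees(psi[0]), atol=1e-3)

    def test_terminal_residues_raise(self):
        ens = _chain_ensemble([ALPHA_HELIX] * 3)
        with pytest.raises(ValueError, match="cannot compute phi of A1"):
            backbone_dihedral(ens, ("A", 1), "phi")
        with pytest.raises(ValueError, match="cannot compute psi of A3"):
            backbone_dihedral(ens, ("A", 3), "psi")
        with pytest.raises(ValueError, match="phi.*psi"):
            backbone_dihedral(ens, ("A", 2), "omega")


class TestPlaneSide:
    def _flat_topology(self):
        atoms = [Atom("A", r, "GLY", "CA", "C") for r in (1, 2, 3)]
        atoms.append(Atom("A", 4, "GLY", "CA", "C"))
        atoms.append(Atom("A", 5, "GLY", "CB", "C"))
        return Topology(atoms)

    def test_signed_distance_oracle(self):
        top = self._flat_topology()
        xyz = np.zeros((2, 5, 3))
        xyz[:, 0] = (0, 0, 0)
        xyz[:, 1] = (1, 0, 0)
        xyz[:, 2] = (0, 1, 0)  # plane z = 0, normal +z
        xyz[0, 3] = (0.3, 0.3, 0.7)
        xyz[1, 3] = (0.1, 0.1, -0.2)
        ens = TrajectoryEnsemble(top, [xyz])
        plane = APlane(anchors=(("A", 1), ("A", 2), ("A", 3)))
        d = plane_side(ens, plane, ("A", 4, "CA"))
        np.testing.assert_allclose(d, [0.7, -0.2], atol=1e-12)

    def test_reference_atom_fixes_sign(self):
        top = self._flat_topology()
        xyz = np.zeros((1, 5, 3))
        xyz[:, 0] = (0, 0, 0)
        xyz[:, 1] = (1, 0, 0)
        xyz[:, 2] = (0, 1, 0)
        xyz[:, 3] = (0, 0, 0.5)
        xyz[:, 4] = (0, 0, -1.0)  # reference below the plane
        ens = TrajectoryEnsemble(top, [xyz])
        plane = APlane(
            anchors=(("A", 1), ("A", 2), ("A", 3)), reference=("A", 5, "CB")
        )
        # reference must be positive, so the probe atom flips to negative
        np.testing.assert_allclose(plane_side(ens, plane, ("A", 4, "CA")), [-0.5])
        np.testing.assert_allclose(plane_side(ens, plane, ("A", 5, "CB")), [1.0])

    def test_collinear_anchors_rejected(self):
        top = self._flat_topology()
        xyz = np.zeros((1, 5, 3))
        xyz[:, 0] = (0, 0, 0)
        xyz[:, 1] = (1, 0, 0)
        xyz[:, 2] = (2, 0, 0)
        ens = TrajectoryEnsemble(top, [xyz])
        plane = APlane(anchors=(("A", 1), ("A", 2), ("A", 3)))
        with pytest.raises(ValueError, match="collinear"):
            plane_side(ens, plane, ("A", 4, "CA"))

    def test_plane_needs_three_anchors(self):
        with pytest.raises(ValueError, match="3 anchor"):
            APlane(anchors=(("A", 1), ("A", 2)))


class TestHelixContent:
    def test_ideal_helix_is_fully_helical(self):
        ens = _chain_ensemble([ALPHA_HELIX] * 12)
        np.testing.assert_allclose(helix_content(ens, "A", 1, 12), [1.0])

    def test_extended_strand_has_no_helix(self):
        ens = _chain_ensemble([EXTENDED] * 12)
        np.testing.assert_allclose(helix_content(ens, "A", 1, 12), [0.0])

    def test_partial_helix_fraction(self):
        """First half helical, second half extended: the helical i -> i+4
        pairs are exactly those fully inside the helical segment."""
        dihedrals = [ALPHA_HELIX] * 10 + [EXTENDED] * 10
        ens = _chain_ensemble(dihedrals)
        vals = helix_content(ens, "A", 1, 20)
        # evaluable pairs: i = 1..16; helical requires i..i+4 helical geometry
        assert 0.0 < vals[0] < 1.0

    def test_denominator_constant_and_range_checks(self):
        ens = _chain_ensemble([ALPHA_HELIX] * 8)
        # i+4 beyond the chain is excluded, not an error
        vals = helix_content(ens, "A", 2, 8)
        assert len(vals) == 1
        with pytest.raises(ValueError, match="at least 5"):
            helix_content(ens, "A", 1, 4)
        with pytest.raises(ValueError, match="no evaluable"):
            helix_content(ens, "A", 6, 12)


class TestHbondAndMinDistance:
    def test_hbond_present_on_helix(self):
        ens = _chain_ensemble([ALPHA_HELIX] * 10)
        # canonical i -> i+4: donor N-H of residue 6, acceptor O of residue 2
        assert hbond_present(ens, ("A", 6), ("A", 2)).all()
        assert not hbond_present(ens, ("A", 6), ("A", 9)).any()

    def test_min_distance_brute_force(self):
        ens = _chain_ensemble([ALPHA_HELIX, (-130, 140), (60, 50), ALPHA_HELIX,
                               EXTENDED, ALPHA_HELIX])
        top = ens.topology
        sel_a = {"chain": "A", "start": 1, "end": 2, "atoms": "heavy"}
        sel_b = {"chain": "A", "start": 5, "end": 6, "atoms": "heavy"}
        got = min_distance(ens, sel_a, sel_b)
        xyz = ens.concatenated()[0]
        ia = [i for i, a in enumerate(top.atoms)
              if a.resid in (1, 2) and a.element != "H"]
        ib = [i for i, a in enumerate(top.atoms)
              if a.resid in (5, 6) and a.element != "H"]
        expected = min(
            np.linalg.norm(xyz[i] - xyz[j]) for i in ia for j in ib
        )
        np.testing.assert_allclose(got, [expected], atol=1e-12)

    def test_selection_modes_and_errors(self):
        ens = _chain_ensemble([ALPHA_HELIX] * 4)
        ca_only = {"chain": "A", "start": 1, "end": 2, "atoms": "CA"}
        named = {"chain": "A", "start": 3, "end": 4, "atoms": ["O"]}
        d = min_distance(ens, ca_only, named)
        assert d.shape == (1,) and d[0] > 0
        with pytest.raises(ValueError, match="matches no residue"):
            min_distance(ens, {"chain": "B", "start": 1, "end": 2}, named)
        with pytest.raises(ValueError, match="matches no atom"):
            min_distance(ens, {"chain": "A", "start": 1, "end": 1,
                               "atoms": ["CB"]}, named)


class TestRuleEvaluation:
    def test_each_cv_type(self):
        ens = _chain_ensemble([ALPHA_HELIX] * 12)
        helix_rule = {"cv": "helix_fraction", "chain": "A", "start": 1,
                      "end": 12, "op": ">=", "threshold": 0.9}
        assert evaluate_rule(ens, helix_rule).all()
        melted = {"cv": "helix_fraction", "chain": "A", "start": 1, "end": 12,
                  "op": "<", "threshold": 0.5}
        assert not evaluate_rule(ens, melted).any()
        dihedral_rule = {"cv": "dihedral", "residue": ["A", 5], "which": "phi",
                         "lo": -80, "hi": -30}
        assert evaluate_rule(ens, dihedral_rule).all()
        hbond_rule = {"cv": "hbond", "donor": {"chain": "A", "resid": 6},
                      "acceptor": {"chain": "A", "resid": 2}}
        assert evaluate_rule(ens, hbond_rule).all()
        combo = {"cv": "all_of", "rules": [helix_rule, hbond_rule]}
        assert evaluate_rule(ens, combo).all()
        either = {"cv": "any_of", "rules": [melted, hbond_rule]}
        assert evaluate_rule(ens, either).all()
        negated = {"cv": "not", "rule": melted}
        assert evaluate_rule(ens, negated).all()

    def test_between_and_unknown(self):
        ens = _chain_ensemble([ALPHA_HELIX] * 12)
        rule = {"cv": "min_distance",
                "selection_a": {"chain": "A", "start": 1, "end": 2},
                "selection_b": {"chain": "A", "start": 11, "end": 12},
                "op": "between", "lo": 0.0, "hi": 100.0}
        assert evaluate_rule(ens, rule).all()
        with pytest.raises(ValueError, match="unknown collective variable"):
            evaluate_rule(ens, {"cv": "rmsd"})
        with pytest.raises(ValueError, match="unknown comparison op"):
            evaluate_rule(ens, {**rule, "op": "~", "threshold": 1.0})

    def test_classify_elements_frame(self):
        ens = _chain_ensemble([ALPHA_HELIX] * 12, n_frames=3)
        rules = {
            "helical": {"cv": "helix_fraction", "chain": "A", "start": 1,
                        "end": 12, "op": ">=", "threshold": 0.9},
            "melted": {"cv": "helix_fraction", "chain": "A", "start": 1,
                       "end": 12, "op": "<", "threshold": 0.5},
        }
        flags = classify_elements(ens, rules)
        assert list(flags.columns) == ["helical", "melted"]
        assert flags["helical"].all() and not flags["melted"].any()
        assert len(flags) == 3

    def test_default_rules_load(self, tmp_path):
        rules = default_insulin_rules()
        assert "elements" in rules
        names = set(rules["elements"])
        assert {"an_helix_melting", "bc_detachment", "a_plane_crossing"} <= names
        # every rule parses into a known cv type
        known = {"helix_fraction", "min_distance", "plane_side", "dihedral",
                 "hbond", "all_of", "any_of", "not"}
        for rule in rules["elements"].values():
            assert rule["cv"] in known
        # load_rules reads the same structure from an explicit path
        p = tmp_path / "rules.yaml"
        import yaml

        p.write_text(yaml.safe_dump(rules))
        assert load_rules(p) == rules


class TestElementPercentages:
    def test_hand_computed_percentages(self):
        flags = pd.DataFrame(
            {
                "a": [True, True, False, False],
                "b": [True, False, True, False],
            }
        )
        weights = np.array([0.4, 0.3, 0.2, 0.1])
        labels = np.array([0, 0, 1, 1])
        summary = element_percentages(flags, weights, labels,
                                      headline_elements=["a"])
        pct = summary.percentages
        np.testing.assert_allclose(pct.loc["a", 0], 100.0)
        np.testing.assert_allclose(pct.loc["a", 1], 0.0)
        np.testing.assert_allclose(pct.loc["b", 0], 100 * 0.4 / 0.7)
        np.testing.assert_allclose(pct.loc["b", 1], 100 * 0.2 / 0.3)
        np.testing.assert_allclose(pct.loc["a", "ensemble"], 70.0)
        np.testing.assert_allclose(pct.loc["b", "ensemble"], 60.0)
        assert summary.headline_fraction == pytest.approx(0.7)

    def test_bands(self):
        flags = pd.DataFrame({"x": [True, False], "y": [True, True],
                              "z": [False, False]})
        weights = np.array([0.5, 0.5])
        labels = np.zeros(2, dtype=int)
        summary = element_percentages(flags, weights, labels)
        assert summary.bands.loc["x", 0] == "orange"  # 50%
        assert summary.bands.loc["y", 0] == "green"  # 100%
        assert summary.bands.loc["z", 0] == "low"  # 0%

    def test_weight_validation(self):
        flags = pd.DataFrame({"x": [True, False]})
        with pytest.raises(ValueError, match="sum to 1"):
            element_percentages(flags, np.array([0.5, 0.4]), np.zeros(2))
        with pytest.raises(ValueError, match="align"):
            element_percentages(flags, np.array([1.0]), np.zeros(2))
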