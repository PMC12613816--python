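"""Geometric interaction perception: rules, equivariance, oracle parity."""

import numpy as np
import pytest

from oracle_utils import detect_bruteforce
from phoreseek import interactions as ia
from phoreseek import synthetic_data as syn
from phoreseek._geometry import random_rotation
from phoreseek.errors import SelectionError
from phoreseek.structio import AtomRecord, StructureModel


def _atom(serial, name, element, resname, resnum, chain, pos, charge=0):
    return AtomRecord(serial, name, element, resname, resnum, chain,
                      np.asarray(pos, float), charge, het=(resname == "LIG"))


def _hbond_toy(distance, angle_deg):
    """Ligand N-H donating toward a backbone O at given N...O distance and
    D-H...A angle (H placed accordingly)."""
    n = np.zeros(3)
    o = np.array([distance, 0.0, 0.0])
    # place H at 1.0 A from N such that angle(N-H-O) = angle_deg
    theta = np.radians(180.0 - angle_deg)
    h = None
    from scipy.optimize import brentq

    def ang_at(t):
        cand = np.array([np.cos(t), np.sin(t), 0.0])
        v1, v2 = n - cand, o - cand
        c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return np.degrees(np.arccos(np.clip(c, -1, 1))) - angle_deg

    t = brentq(ang_at, 1e-6, np.pi - 1e-6)
    h = np.array([np.cos(t), np.sin(t), 0.0])
    atoms = (
        _atom(1, "N1", "N", "LIG", 1, "L", n),
        _atom(2, "H1", "H", "LIG", 1, "L", h),
        _atom(3, "O", "O", "GLY", 10, "A", o),
        _atom(4, "C", "C", "GLY", 10, "A", o + [0.0, 1.23, 0.0]),
    )
    return StructureModel(atoms=atoms)


class TestHydrogenBond:
    def test_within_cutoffs_detected(self):
        m = _hbond_toy(2.9, 165.0)
        events = ia.detect_interactions(m, ia.ligand_selector("LIG"))
        assert [e.kind for e in events] == ["HBOND_LIG_DONOR"]
        assert events[0].measurements["distance"] == pytest.approx(2.9)
        assert events[0].measurements["angle"] == pytest.approx(165.0, abs=1e-6)

    def test_stretched_beyond_cutoff_rejected(self):
        m = _hbond_toy(4.0, 165.0)
        assert ia.detect_interactions(m, ia.ligand_selector("LIG")) == []

    def test_bent_below_angle_rejected(self):
        m = _hbond_toy(2.9, 110.0)
        assert ia.detect_interactions(m, ia.ligand_selector("LIG")) == []

    def test_empty_selection_is_error(self):
        m = _hbond_toy(2.9, 165.0)
        with pytest.raises(SelectionError):
            ia.detect_interactions(m, ia.ligand_selector("NOPE"))


class TestPlantedComplexOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_detection_equals_bruteforce_scan(self, seed):
        kinds = ["HBOND_LIG_DONOR", "HBOND_LIG_ACCEPTOR", "HYDROPHOBIC",
                 "IONIC", "AROMATIC_PI"]
        cx = syn.gen_complex(seed=seed, planted=kinds)
        events = ia.detect_interactions(cx.structure, cx.selector(), cx.rules)
        got = {(e.kind, e.protein_residue) for e in events}
        oracle = detect_bruteforce(cx.structure, cx.selector(), cx.rules)
        assert got == oracle
        assert sorted(e.kind for e in events) == sorted(kinds)

    def test_k_contacts_of_each_kind(self):
        planted = ["HYDROPHOBIC"] * 3 + ["HBOND_LIG_DONOR"] * 2 + ["IONIC"]
        cx = syn.gen_complex(seed=5, planted=planted)
        events = ia.detect_interactions(cx.structure, cx.selector(), cx.rules)
        counts = {}
        for e in events:
            counts[e.kind] = counts.get(e.kind, 0) + 1
        assert counts == {"HYDROPHOBIC": 3, "HBOND_LIG_DONOR": 2, "IONIC": 1}


class TestInvariants:
    def test_rigid_motion_equivariance(self, rng):
        cx = syn.gen_complex(seed=9, planted=["HBOND_LIG_DONOR", "IONIC",
                                              "HYDROPHOBIC", "AROMATIC_PI"])
        before = ia.detect_interactions(cx.structure, cx.selector(), cx.rules)
        R = random_rotation(rng)
        t = rng.uniform(-10, 10, 3)
        moved = cx.structure.transformed(R, t)
        after = ia.detect_interactions(moved, cx.selector(), cx.rules)
        assert len(before) == len(after)
        for b, a in zip(before, after):
            assert b.identity == a.identity
            for key in b.measurements:
                assert a.measurements[key] == pytest.approx(b.measurements[key], abs=1e-6)
            np.testing.assert_allclose(
                a.ligand_site_position, R @ b.ligand_site_position + t, atol=1e-6
            )

    def test_tightening_thresholds_never_adds_events(self, rng):
        cx = syn.gen_complex(seed=11, planted=["HBOND_LIG_DONOR", "HYDROPHOBIC",
                                               "IONIC"])
        base = ia.GeometricRules()
        n_base = len(ia.detect_interactions(cx.structure, cx.selector(), base))
        for _ in range(10):
            tighter = ia.GeometricRules(
                hbond_heavy_dist_max=base.hbond_heavy_dist_max * rng.uniform(0.5, 1.0),
                hbond_angle_min=base.hbond_angle_min + rng.uniform(0, 30),
                hydrophobic_dist_max=base.hydrophobic_dist_max * rng.uniform(0.5, 1.0),
                ionic_dist_max=base.ionic_dist_max * rng.uniform(0.5, 1.0),
                aromatic_centroid_dist_max=base.aromatic_centroid_dist_max
                * rng.uniform(0.5, 1.0),
            )
            n = len(ia.detect_interactions(cx.structure, cx.selector(), tighter))
            assert n <= n_base

    def test_events_ordered_and_deduplicated(self):
        cx = syn.gen_complex(seed=2, planted=["HYDROPHOBIC", "HBOND_LIG_DONOR",
                                              "HYDROPHOBIC"])
        events = ia.detect_interactions(cx.structure, cx.selector(), cx.rules)
        keys = [(e.kind, e.protein_residue[2], e.protein_residue[0]) for e in events]
        assert keys == sorted(keys)
        assert len({e.identity for e in events}) == len(events)


class TestLigandFeatureClassification:
    def test_charged_amine_is_positive_ionizable(self):
        # protonated cyclic-amine nitrogen: formal charge +1
        atoms = [
            _atom(1, "N1", "N", "LIG", 1, "L", [0, 0, 0], charge=1),
            _atom(2, "C1", "C", "LIG", 1, "L", [1.5, 0, 0]),
            _atom(3, "C2", "C", "LIG", 1, "L", [-1.5, 0, 0]),
        ]
        feats = ia.classify_ligand_features(atoms)
        assert ("PI", (1,)) in [(k, s) for k, _, s in feats]

    def test_azole_ring_nitrogen_is_acceptor(self):
        # planar five-membered O/N/C ring; the ring N (no H) accepts
        ring = []
        elements = ["O", "N", "C", "C", "C"]
        for i, el in enumerate(elements):
            ang = 2 * np.pi * i / 5
            ring.append(
                _atom(i + 1, f"{el}{i+1}", el, "LIG", 1, "L",
                      [1.17 * np.cos(ang), 1.17 * np.sin(ang), 0.0])
            )
        feats = ia.classify_ligand_features(ring)
        kinds = {(k, s) for k, _, s in feats}
        assert ("HBA", (2,)) in kinds
        assert any(k == "AR" for k, _, _ in feats)

    def test_butyl_chain_centroid(self):
        atoms = [
            _atom(i + 1, f"C{i+1}", "C", "LIG", 1, "L", [1.5 * i, 0, 0])
            for i in range(4)
        ]
        feats = ia.classify_ligand_features(atoms)
        hyd = [f for f in feats if f[0] == "HYD"]
        assert len(hyd) == 1
        expected = np.mean([a.position for a in atoms], axis=0)
        np.testing.assert_allclose(hyd[0][1], expected)
        assert hyd[0][2] == (1, 2, 3, 4)

    def test_no_typed_atoms_gives_empty_list(self):
        assert ia.classify_ligand_features([]) == []

    def test_missing_bonds_without_inference_is_capability_error(self):
        from phoreseek.errors import CapabilityError

        atoms = [_atom(1, "C1", "C", "LIG", 1, "L", [0, 0, 0])]
        with pytest.raises(CapabilityError):
            ia.classify_ligand_features(atoms, bonds=None, infer=False)
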