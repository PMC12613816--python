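"""Model derivation, rigid overlay, consensus retention rule."""

import numpy as np
import pytest

from oracle_utils import consensus_count_bruteforce, overlay_rmsd_bruteforce
from phoreseek import pharmacophore as ph
from phoreseek import synthetic_data as syn
from phoreseek._geometry import random_rotation
from phoreseek.errors import AlignmentError
from phoreseek.interactions import InteractionEvent, detect_interactions


def _event(kind, serials, resnum, pos, **meas):
    return InteractionEvent(
        kind=kind,
        ligand_atom_serials=serials,
        protein_residue=("A", "GLY", resnum),
        measurements=meas,
        ligand_site_position=np.asarray(pos, float),
    )


class TestDeriveModel:
    def test_reference_composition(self):
        """1 acceptor + 1 charge + 3 hydrophobics -> HBA, PI, 3x HYD."""
        events = [
            _event("HBOND_LIG_ACCEPTOR", (1,), 301, [0, 0, 0], distance=2.9),
            _event("IONIC", (2,), 302, [8, 0, 0], distance=5.0, ligand_charge=1.0),
            _event("HYDROPHOBIC", (3, 4), 303, [0, 8, 0], distance=4.0),
            _event("HYDROPHOBIC", (5, 6), 304, [0, 0, 8], distance=4.0),
            _event("HYDROPHOBIC", (7, 8), 305, [8, 8, 0], distance=4.0),
        ]
        model = ph.derive_model(events, frame_label="toy")
        assert sorted(model.kinds()) == ["HBA", "HYD", "HYD", "HYD", "PI"]
        assert all(f.tolerance == 1.5 for f in model.features)

    def test_negative_ligand_charge_maps_to_NI(self):
        ev = _event("IONIC", (1,), 301, [0, 0, 0], distance=5.0, ligand_charge=-1.0)
        model = ph.derive_model([ev])
        assert model.kinds() == ("NI",)

    def test_anchor_labels_with_partner_chain_star(self):
        ev = InteractionEvent(
            kind="HYDROPHOBIC",
            ligand_atom_serials=(1,),
            protein_residue=("B", "PHE", 494),
            measurements={"distance": 4.0},
            ligand_site_position=np.zeros(3),
        )
        model = ph.derive_model([ev], reference_chain="A")
        assert model.features[0].anchors == ("F494*",)

    def test_duplicate_events_collapse(self):
        ev = _event("HYDROPHOBIC", (3, 4), 303, [0, 8, 0], distance=4.0)
        model = ph.derive_model([ev, ev])
        assert len(model) == 1

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError):
            ph.derive_model([])


class TestOverlay:
    def test_self_overlay_is_identity(self, reference_model):
        res = ph.overlay(reference_model, reference_model)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(res.translation, 0.0, atol=1e-9)

    def test_recovers_applied_rigid_motion(self, reference_model, rng):
        R = random_rotation(rng)
        t = rng.uniform(-10, 10, 3)
        # move the model away; overlay must bring it back
        moved = reference_model.transformed(R, t)
        res = ph.overlay(moved, reference_model)
        assert res.rmsd <= 1e-6
        np.testing.assert_allclose(res.rotation @ R, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(
            res.transformed.positions(), reference_model.positions(), atol=1e-6
        )

    def test_jittered_sibling_matches_bruteforce_assignment(self, rng):
        for trial in range(10):
            ref_feats = []
            kinds = ["HBA", "PI", "HYD", "HYD", "HYD"]
            pts = rng.uniform(-6, 6, (5, 3))
            for k, p in zip(kinds, pts):
                ref_feats.append(ph.ChemFeature(kind=k, position=p))
            reference = ph.PharmacophoreModel(tuple(ref_feats))
            # 4-feature sibling with jitter
            sel = rng.choice(5, size=4, replace=False)
            sib_feats = [
                ph.ChemFeature(
                    kind=reference.features[i].kind,
                    position=reference.features[i].position + rng.normal(0, 0.5, 3),
                )
                for i in sel
            ]
            model = ph.PharmacophoreModel(tuple(sib_feats))
            res = ph.overlay(model, reference)
            oracle = overlay_rmsd_bruteforce(model, reference)
            assert res.rmsd == pytest.approx(oracle, abs=1e-9)

    def test_too_few_correspondences_is_error(self):
        a = ph.PharmacophoreModel(
            (ph.ChemFeature(kind="HBA", position=[0, 0, 0]),
             ph.ChemFeature(kind="PI", position=[3, 0, 0]))
        )
        with pytest.raises(AlignmentError):
            ph.overlay(a, a)


def _planted_models(k, n_models=8, base_seed=0):
    """n_models single-HBA models; the feature appears in exactly k of them.

    Models that do not carry the planted feature carry a far-away decoy
    feature of a different kind so every model is non-empty.
    """
    site = np.array([1.0, 2.0, 3.0])
    models = []
    for m in range(n_models):
        feats = [ph.ChemFeature(kind="HYD", position=[50.0 + 10 * m, 0, 0])]
        if m < k:
            feats.append(ph.ChemFeature(kind="HBA", position=site + 0.05 * m))
        models.append(ph.PharmacophoreModel(tuple(feats), frame_label=f"m{m}"))
    return models


class TestConsensus:
    def test_identical_models_all_retained(self, reference_model):
        models = [reference_model] * 8
        cons = ph.consensus(models, min_models=4)
        assert len(cons) == len(reference_model)
        np.testing.assert_allclose(cons.positions(), reference_model.positions(),
                                   atol=1e-9)

    def test_single_model_high_threshold_is_empty(self, reference_model):
        cons = ph.consensus([reference_model], min_models=4)
        assert len(cons) == 0

    @pytest.mark.parametrize("k", list(range(1, 9)))
    def test_strictly_more_than_four_rule(self, k):
        """A feature planted in exactly k of 8 models is retained iff k > 4."""
        models = _planted_models(k)
        cons = ph.consensus(models, min_models=4, strict_greater=True)
        hba = [f for f in cons.features if f.kind == "HBA"]
        assert (len(hba) == 1) == (k > 4)
        # brute-force cluster-and-count oracle agrees
        sets = [[(f.kind, f.position) for f in m.features] for m in models]
        oracle = consensus_count_bruteforce(sets, merge_radius=1.5)
        assert [(kk, n) for kk, n in oracle if kk == "HBA"] == [("HBA", k)]

    @pytest.mark.parametrize("k", [4, 5])
    def test_at_least_semantics_flag(self, k):
        models = _planted_models(k)
        cons = ph.consensus(models, min_models=4, strict_greater=False)
        assert any(f.kind == "HBA" for f in cons.features) == (k >= 4)

    def test_count_nonincreasing_in_threshold(self):
        models = _planted_models(6)
        sizes = [
            len(ph.consensus(models, min_models=t)) for t in range(1, 9)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_invariant_to_model_ordering(self, rng):
        models = _planted_models(5)
        cons_a = ph.consensus(models, min_models=4)
        order = rng.permutation(len(models))
        cons_b = ph.consensus([models[i] for i in order], min_models=4)
        assert cons_a.kinds() == cons_b.kinds()
        np.testing.assert_allclose(cons_a.positions(), cons_b.positions(), atol=1e-9)

    def test_retained_feature_merges_position_tolerance_anchors(self):
        f1 = ph.ChemFeature(kind="HBA", position=[0, 0, 0], tolerance=1.0,
                            anchors=("G351",))
        f2 = ph.ChemFeature(kind="HBA", position=[1.0, 0, 0], tolerance=2.0,
                            anchors=("E427",))
        models = [ph.PharmacophoreModel((f,)) for f in (f1, f2)]
        cons = ph.consensus(models, min_models=2, strict_greater=False)
        assert len(cons) == 1
        got = cons.features[0]
        np.testing.assert_allclose(got.position, [0.5, 0, 0])
        assert got.tolerance == 2.0
        assert got.anchors == ("E427", "G351")


class TestJSONRoundTrip:
    def test_roundtrip(self, reference_model):
        text = ph.model_to_json(reference_model)
        back = ph.model_from_json(text)
        assert back.kinds() == reference_model.kinds()
        np.testing.assert_allclose(back.positions(), reference_model.positions())
        assert back.frame_label == reference_model.frame_label

    def test_direction_preserved(self):
        f = ph.ChemFeature(kind="HBA", position=[0, 0, 0],
                           direction=[0.0, 0.0, 1.0])
        m = ph.PharmacophoreModel((f,))
        back = ph.model_from_json(ph.model_to_json(m))
        np.testing.assert_allclose(back.features[0].direction, [0, 0, 1])


class TestEndToEndDerivation:
    def test_pocket_to_model(self):
        cx = syn.gen_reference_complex(seed=3)
        events = detect_interactions(cx.structure, cx.selector(), cx.rules)
        model = ph.derive_model(events, frame_label="pocket")
        assert sorted(model.kinds()) == ["HBA", "HYD", "HYD", "HYD", "PI"]
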