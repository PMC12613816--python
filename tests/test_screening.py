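"""Correspondence search, rigid fitting, hit rules, library screening."""

import warnings

import numpy as np
import pytest

from oracle_utils import best_match_bruteforce, enumerate_mappings_bruteforce
from phoreseek import pharmacophore as ph
from phoreseek import screening as sc
from phoreseek import synthetic_data as syn
from phoreseek._geometry import random_rotation
from phoreseek.errors import DegenerateAlignmentError
from phoreseek.structio import FeaturePoint


def _model(kinds_positions, tolerance=1.5):
    feats = tuple(
        ph.ChemFeature(kind=k, position=p, tolerance=tolerance)
        for k, p in kinds_positions
    )
    return ph.PharmacophoreModel(feats)


def _conf(model, transform=None, jitter=None, rng=None):
    pts = model.positions()
    if jitter is not None:
        pts = pts + rng.normal(0, jitter, pts.shape)
    if transform is not None:
        R, t = transform
        pts = pts @ R.T + t
    return tuple(FeaturePoint(k, p) for k, p in zip(model.kinds(), pts))


@pytest.fixture()
def five_feature_model():
    return _model(
        [
            ("HBA", [0.0, 0.0, 0.0]),
            ("PI", [6.0, 0.0, 0.0]),
            ("HYD", [0.0, 6.0, 0.0]),
            ("HYD", [0.0, 0.0, 6.0]),
            ("HYD", [5.0, 5.0, 0.0]),
        ]
    )


def _random_instance(rng, n_model=5, n_conf=5):
    kinds = ["HBA", "HBD", "HYD", "PI", "AR"]
    mk = [kinds[i] for i in rng.integers(0, len(kinds), n_model)]
    ck = [kinds[i] for i in rng.integers(0, len(kinds), n_conf)]
    model = _model(list(zip(mk, rng.uniform(-5, 5, (n_model, 3)))))
    conf = tuple(FeaturePoint(k, p) for k, p in zip(ck, rng.uniform(-5, 5, (n_conf, 3))))
    return model, conf


class TestEnumerateCorrespondences:
    def test_identity_mapping_is_maximal_for_identical_sets(self, five_feature_model):
        conf = _conf(five_feature_model)
        maps = sc.enumerate_correspondences(five_feature_model, conf)
        assert tuple((i, i) for i in range(5)) in maps
        assert max(len(m) for m in maps) == 5

    def test_no_common_kinds_gives_empty(self, five_feature_model):
        conf = tuple(FeaturePoint("NI", p) for p in np.eye(3) * 3)
        assert sc.enumerate_correspondences(five_feature_model, conf) == []

    def test_equals_bruteforce_on_random_instances(self, rng):
        settings = sc.ScreenSettings(min_required_features=3)
        for _ in range(50):
            model, conf = _random_instance(rng)
            got = sc.enumerate_correspondences(model, conf, settings)
            oracle = enumerate_mappings_bruteforce(model, conf, settings)
            assert sorted(got) == sorted(oracle)


class TestFitMapping:
    def test_exact_copy_scores_n(self, five_feature_model):
        conf = _conf(five_feature_model)
        mapping = tuple((i, i) for i in range(5))
        res = sc.fit_mapping(five_feature_model, conf, mapping)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert res.n_valid == 5
        assert res.score == pytest.approx(5.0, abs=1e-9)

    def test_rotation_translation_invariance(self, five_feature_model, rng):
        mapping = tuple((i, i) for i in range(5))
        base = sc.fit_mapping(five_feature_model, _conf(five_feature_model), mapping)
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        conf = _conf(five_feature_model, transform=(Rz, np.array([3.0, -2.0, 7.0])))
        res = sc.fit_mapping(five_feature_model, conf, mapping)
        assert res.rmsd == pytest.approx(base.rmsd, abs=1e-9)
        assert res.score == pytest.approx(base.score, abs=1e-9)

    def test_one_point_beyond_tolerance_is_invalid(self, five_feature_model):
        """Perturb one feature by 2x tolerance along a fixed axis; the fit must
        flag exactly that pair invalid and rmsd must match direct arithmetic."""
        pts = five_feature_model.positions().copy()
        pts[1] = pts[1] + np.array([0.0, 0.0, 3.2])  # >> 1.5 A tolerance
        conf = tuple(FeaturePoint(k, p) for k, p in zip(five_feature_model.kinds(), pts))
        mapping = tuple((i, i) for i in range(5))
        res = sc.fit_mapping(five_feature_model, conf, mapping)
        # oracle: closed-form Kabsch on the fixture coordinates
        from phoreseek._geometry import kabsch

        R, t, rmsd = kabsch(five_feature_model.positions(), np.array([p.position for p in conf]))
        assert res.rmsd == pytest.approx(rmsd, abs=1e-12)
        assert res.n_valid == 4

    def test_collinear_mapping_is_degenerate(self):
        model = _model([("HYD", [0, 0, 0]), ("HYD", [1, 0, 0]), ("HYD", [2, 0, 0])])
        conf = _conf(model)
        with pytest.raises(DegenerateAlignmentError):
            sc.fit_mapping(model, conf, ((0, 0), (1, 1), (2, 2)))


class TestMatchConformer:
    def test_exact_match_is_hit(self, five_feature_model):
        res = sc.match_conformer(five_feature_model, _conf(five_feature_model))
        assert res.hit and res.n_matched == 5

    def test_omitted_feature_semantics(self, five_feature_model):
        """A 4/5 partial match misses at 0 omitted and hits at 1 omitted."""
        conf = _conf(five_feature_model)[:4]
        strict = sc.match_conformer(five_feature_model, conf, sc.ScreenSettings())
        assert strict is not None and not strict.hit and strict.n_valid == 4
        relaxed = sc.match_conformer(
            five_feature_model, conf, sc.ScreenSettings(max_omitted_features=1)
        )
        assert relaxed.hit

    def test_best_equals_bruteforce_on_random_instances(self, rng):
        settings = sc.ScreenSettings(min_required_features=3)
        n_nontrivial = 0
        for _ in range(100):
            model, conf = _random_instance(rng, n_model=int(rng.integers(3, 7)))
            got = sc.match_conformer(model, conf, settings)
            oracle = best_match_bruteforce(model, conf, settings)
            if oracle is None:
                assert got is None or got.score == float("-inf")
                continue
            n_nontrivial += 1
            (oscore, _), _, onv = oracle
            assert got.score == pytest.approx(oscore, abs=1e-9)
            assert got.n_valid == onv
        assert n_nontrivial >= 10

    def test_hit_invariant_under_rigid_motion(self, five_feature_model, rng):
        base = sc.match_conformer(five_feature_model, _conf(five_feature_model))
        for _ in range(10):
            R = random_rotation(rng)
            t = rng.uniform(-20, 20, 3)
            conf = _conf(five_feature_model, transform=(R, t))
            res = sc.match_conformer(five_feature_model, conf)
            assert res.hit == base.hit
            assert res.score == pytest.approx(base.score, abs=1e-6)

    def test_raising_tolerance_scale_never_unhits(self, five_feature_model, rng):
        conf = _conf(five_feature_model, jitter=0.5, rng=rng)
        for scale in (1.0, 1.2, 1.5, 2.0, 3.0):
            res = sc.match_conformer(
                five_feature_model, conf, sc.ScreenSettings(tolerance_scale=scale)
            )
            if res is not None and res.hit:
                for bigger in (scale * 1.5, scale * 2.0):
                    res2 = sc.match_conformer(
                        five_feature_model,
                        conf,
                        sc.ScreenSettings(tolerance_scale=bigger),
                    )
                    assert res2 is not None and res2.hit


class TestScreenLibrary:
    def test_planted_actives_hit(self, reference_model):
        lib = syn.gen_library(reference_model, n_active=3, n_decoy=7,
                              jitter_sd=0.3, n_conformers=2, seed=21)
        report = sc.screen_library(reference_model, lib.as_screen_input())
        assert report.n_screened == 10
        assert report.n_hits == 3
        hits = report.hits()
        for e in lib.entries:
            assert hits[e.molecule_id] == (e.label == "active")

    def test_single_matching_conformer_of_many(self, reference_model):
        lib = syn.gen_library(reference_model, n_active=1, n_decoy=0,
                              jitter_sd=0.2, n_conformers=25, seed=8)
        report = sc.screen_library(reference_model, lib.as_screen_input())
        assert report.n_hits == 1
        # per-conformer oracle: exactly one conformer matches
        entry = lib.entries[0]
        per_conf = [
            sc.match_conformer(reference_model, conf) for conf in entry.conformers
        ]
        hits = [r is not None and r.hit for r in per_conf]
        assert sum(hits) == 1
        assert report.results[0].best_conformer == hits.index(True)

    def test_zero_conformer_molecule_warns_not_crashes(self, reference_model):
        lib = [("empty-mol", [])]
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            report = sc.screen_library(reference_model, lib)
        assert report.n_hits == 0
        assert any("no conformers" in str(x.message) for x in w)

    def test_default_settings_are_paper_style(self):
        s = sc.ScreenSettings()
        assert s.min_required_features == 3
        assert s.max_omitted_features == 0
        assert s.tolerance_scale == 1.0
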