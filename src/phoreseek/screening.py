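"""Conformer-vs-pharmacophore matching and library screening.

A conformer matches a model through a feature correspondence found with the
classic correspondence-graph formulation: nodes are kind-compatible
(model feature, conformer feature) pairs, edges connect pairs whose
inter-feature distances agree within the summed tolerances, and maximal
cliques are the candidate mappings.  Each candidate is scored after rigid
least-squares superposition; the hit rule mirrors screening-tool settings
(minimum required features, allowed omitted features — with 0 omitted a hit
must validate every model feature).

The score is an artifact-defined quantity, ``n_valid - rmsd_valid / mean
tolerance``: monotone up in satisfied features and down in geometric
deviation.  Rankings, not absolute score values, carry meaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from ._geometry import kabsch
from .errors import DegenerateAlignmentError
from .pharmacophore import PharmacophoreModel
from .structio import FeaturePoint

#: Sentinel score assigned to molecules with no candidate mapping; sorts
#: below every real score.
NO_MATCH_SCORE = float("-inf")


@dataclass(frozen=True)
class ScreenSettings:
    """Matching knobs mirroring virtual-screening tool settings.

    ``min_required_features`` — smallest mapping size considered;
    ``max_omitted_features`` — how many model features a hit may leave
    unsatisfied (0 forces a full match);
    ``tolerance_scale`` — multiplier on per-feature tolerance radii.
    """

    min_required_features: int = 3
    max_omitted_features: int = 0
    tolerance_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.min_required_features < 1:
            raise ValueError("min_required_features must be >= 1")
        if self.max_omitted_features < 0:
            raise ValueError("max_omitted_features must be >= 0")
        if self.tolerance_scale <= 0:
            raise ValueError("tolerance_scale must be positive")


DEFAULT_SETTINGS = ScreenSettings()


@dataclass(frozen=True)
class MatchResult:
    """Best feature correspondence for one conformer."""

    mapping: tuple[tuple[int, int], ...]  # (model idx, conformer idx)
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_matched: int
    n_valid: int
    score: float
    hit: bool = False


def enumerate_correspondences(
    model: PharmacophoreModel,
    conformer: tuple[FeaturePoint, ...],
    settings: ScreenSettings = DEFAULT_SETTINGS,
) -> list[tuple[tuple[int, int], ...]]:
    """All maximal kind- and distance-consistent mappings.

    A mapping is consistent when for every two of its pairs (i,j), (k,l)
    the model distance d(i,k) and conformer distance d(j,l) agree within
    ``(tol_i + tol_k) * tolerance_scale``.  Mappings smaller than
    ``min_required_features`` are pruned.  Returned in lexicographic order.
    """
    if len(model) == 0 or len(conformer) == 0:
        return []
    mpos = model.positions()
    cpos = np.array([f.position for f in conformer])
    tol = np.array([f.tolerance for f in model.features]) * settings.tolerance_scale

    nodes = [
        (i, j)
        for i, mf in enumerate(model.features)
        for j, cf in enumerate(conformer)
        if mf.kind == cf.kind
    ]
    if not nodes:
        return []
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a in range(len(nodes)):
        i, j = nodes[a]
        for b in range(a + 1, len(nodes)):
            k, l = nodes[b]
            if i == k or j == l:
                continue
            dm = np.linalg.norm(mpos[i] - mpos[k])
            dc = np.linalg.norm(cpos[j] - cpos[l])
            if abs(dm - dc) <= tol[i] + tol[k]:
                g.add_edge(nodes[a], nodes[b])
    mappings = [
        tuple(sorted(clique))
        for clique in nx.find_cliques(g)
        if len(clique) >= settings.min_required_features
    ]
    mappings.sort()
    return mappings


def fit_mapping(
    model: PharmacophoreModel,
    conformer: tuple[FeaturePoint, ...],
    mapping: tuple[tuple[int, int], ...],
    settings: ScreenSettings = DEFAULT_SETTINGS,
) -> MatchResult:
    """Rigid least-squares fit of one mapping; scores validity per pair.

    A mapped pair is *valid* when its post-transform distance is within the
    model feature's (scaled) tolerance.  Raises
    :class:`DegenerateAlignmentError` for < 3 pairs or collinear model
    points.
    """
    mapping = tuple(sorted(mapping))
    P = np.array([model.features[i].position for i, _ in mapping])
    Q = np.array([conformer[j].position for _, j in mapping])
    R, t, rmsd = kabsch(P, Q)  # raises DegenerateAlignmentError when under-determined
    moved = Q @ R.T + t
    dists = np.linalg.norm(moved - P, axis=1)
    tols = np.array([model.features[i].tolerance for i, _ in mapping])
    valid = dists <= tols * settings.tolerance_scale
    n_valid = int(valid.sum())
    if n_valid:
        rmsd_valid = float(np.sqrt((dists[valid] ** 2).mean()))
        mean_tol = float(tols[valid].mean())
        score = n_valid - rmsd_valid / mean_tol
    else:
        score = NO_MATCH_SCORE
    return MatchResult(
        mapping=mapping,
        rotation=R,
        translation=t,
        rmsd=rmsd,
        n_matched=len(mapping),
        n_valid=n_valid,
        score=score,
    )


def _is_hit(model: PharmacophoreModel, result: MatchResult, settings: ScreenSettings) -> bool:
    required = len(model) - settings.max_omitted_features
    return result.n_valid >= required and result.n_valid >= settings.min_required_features


def match_conformer(
    model: PharmacophoreModel,
    conformer: tuple[FeaturePoint, ...],
    settings: ScreenSettings = DEFAULT_SETTINGS,
) -> MatchResult | None:
    """Best mapping by score (ties: lower rmsd, then lexicographic mapping).

    Returns ``None`` when no candidate mapping exists or none can be
    rigidly fitted; a returned result carries the hit decision under
    ``settings``.
    """
    best: MatchResult | None = None
    for mapping in enumerate_correspondences(model, conformer, settings):
        try:
            res = fit_mapping(model, conformer, mapping, settings)
        except DegenerateAlignmentError:
            continue
        if best is None or (res.score, -res.rmsd, _neg_lex(res.mapping)) > (
            best.score,
            -best.rmsd,
            _neg_lex(best.mapping),
        ):
            best = res
    if best is None:
        return None
    return replace(best, hit=_is_hit(model, best, settings))


def _neg_lex(mapping: tuple[tuple[int, int], ...]):
    # lexicographically *smaller* mapping wins ties -> negate for max()
    return tuple((-i, -j) for i, j in mapping)


@dataclass(frozen=True)
class MoleculeResult:
    molecule_id: str
    hit: bool
    best_conformer: int | None
    match: MatchResult | None

    @property
    def score(self) -> float:
        return self.match.score if self.match is not None else NO_MATCH_SCORE


@dataclass(frozen=True)
class ScreenReport:
    results: tuple[MoleculeResult, ...]

    @property
    def n_screened(self) -> int:
        return len(self.results)

    @property
    def n_hits(self) -> int:
        return sum(r.hit for r in self.results)

    def scores(self) -> dict[str, float]:
        return {r.molecule_id: r.score for r in self.results}

    def hits(self) -> dict[str, bool]:
        return {r.molecule_id: r.hit for r in self.results}

    def to_rows(self) -> list[dict]:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "molecule_id": r.molecule_id,
                    "hit": r.hit,
                    "best_conformer": r.best_conformer,
                    "n_matched": r.match.n_matched if r.match else 0,
                    "n_valid": r.match.n_valid if r.match else 0,
                    "rmsd": r.match.rmsd if r.match else float("nan"),
                    "score": r.score,
                }
            )
        return rows


def screen_library(
    model: PharmacophoreModel,
    library: list[tuple[str, list[tuple[FeaturePoint, ...]]]],
    settings: ScreenSettings = DEFAULT_SETTINGS,
) -> ScreenReport:
    """Per-molecule best conformer match over a feature library.

    ``library`` is a list of ``(molecule_id, [conformer feature sets])`` as
    produced by :func:`phoreseek.structio.read_feature_library` or the
    synthetic generators.  Molecules with zero conformers are recorded as
    no-match with a warning.
    """
    if not library:
        raise ValueError("library is empty")
    results = []
    for mol_id, conformers in library:
        if not conformers:
            warnings.warn(f"molecule {mol_id!r} has no conformers; recorded as no-match")
            results.append(MoleculeResult(mol_id, False, None, None))
            continue
        best: MatchResult | None = None
        best_idx: int | None = None
        for idx, conf in enumerate(conformers):
            res = match_conformer(model, conf, settings)
            if res is None:
                continue
            if best is None or (res.hit, res.score) > (best.hit, best.score):
                best, best_idx = res, idx
        results.append(
            MoleculeResult(mol_id, best.hit if best else False, best_idx, best)
        )
    return ScreenReport(tuple(results))
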