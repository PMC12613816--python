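"""3D pharmacophore models: derivation, rigid overlay, and consensus.

A pharmacophore abstracts a binding mode into typed feature spheres (HBA,
HBD, HYD, PI, NI, AR) with positions and tolerance radii.  Per-complex
models are derived from detected interaction events; multiple overlaid
models are merged into a consensus by retaining feature clusters shared by
more than a threshold number of source models.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, replace

import numpy as np

from ._geometry import apply_rigid, kabsch
from .errors import AlignmentError, SchemaError
from .interactions import InteractionEvent
from .structio import FEATURE_KINDS

SCHEMA_VERSION = 1

#: Default tolerance sphere radius per feature kind (A) — the customary
#: pharmacophore sphere size.
DEFAULT_TOLERANCES: dict[str, float] = {k: 1.5 for k in FEATURE_KINDS}

#: Interaction kind -> feature kind.  IONIC resolves by the sign of the
#: ligand charge center (positive -> PI, negative -> NI).
_EVENT_TO_FEATURE = {
    "HBOND_LIG_ACCEPTOR": "HBA",
    "HBOND_LIG_DONOR": "HBD",
    "HYDROPHOBIC": "HYD",
    "AROMATIC_PI": "AR",
}


@dataclass(frozen=True)
class ChemFeature:
    """A typed pharmacophore feature sphere."""

    kind: str
    position: np.ndarray
    tolerance: float = 1.5
    direction: np.ndarray | None = None
    anchors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise SchemaError(f"unknown feature kind {self.kind!r}")
        if self.tolerance <= 0:
            raise SchemaError("tolerance must be positive")
        pos = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "position", pos)
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            norm = float(np.linalg.norm(d))
            if abs(norm - 1.0) > 1e-6:
                raise SchemaError("direction must be a unit vector")
            object.__setattr__(self, "direction", d)
        object.__setattr__(self, "anchors", tuple(self.anchors))

    def sort_key(self) -> tuple:
        return (self.kind, tuple(np.round(self.position, 6)))


@dataclass(frozen=True)
class PharmacophoreModel:
    """An ordered set of features plus provenance.

    Feature order is canonical (kind, then position lexicographically), so
    two models with the same features compare equal regardless of build
    order.  A consensus that retains nothing is represented as an explicit
    empty model.
    """

    features: tuple[ChemFeature, ...]
    frame_label: str = ""
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        feats = tuple(sorted(self.features, key=lambda f: f.sort_key()))
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "provenance", tuple(self.provenance))

    def __len__(self) -> int:
        return len(self.features)

    def positions(self) -> np.ndarray:
        return np.array([f.position for f in self.features]).reshape(len(self.features), 3)

    def kinds(self) -> tuple[str, ...]:
        return tuple(f.kind for f in self.features)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "PharmacophoreModel":
        feats = []
        for f in self.features:
            d = None if f.direction is None else np.asarray(R, float) @ f.direction
            feats.append(replace(f, position=apply_rigid(f.position[None], R, t)[0], direction=d))
        return PharmacophoreModel(tuple(feats), self.frame_label, self.provenance)


# ---------------------------------------------------------------------------
# Derivation from interaction events
# ---------------------------------------------------------------------------


def derive_model(
    events: list[InteractionEvent],
    tolerances: dict[str, float] | None = None,
    frame_label: str = "",
    reference_chain: str | None = None,
) -> PharmacophoreModel:
    """One feature per (deduplicated) interaction event.

    The feature sits at the event's ligand-site position; the protein
    residue becomes the feature's anchor label.  Ionic events map to PI or
    NI depending on the sign of the ligand charge recorded with the event.
    """
    if not events:
        raise ValueError("cannot derive a pharmacophore from zero events")
    tol = dict(DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    seen: dict[tuple, ChemFeature] = {}
    for ev in events:
        if ev.identity in seen:
            continue
        if ev.kind == "IONIC":
            kind = "PI" if ev.measurements.get("ligand_charge", 1.0) > 0 else "NI"
        else:
            kind = _EVENT_TO_FEATURE.get(ev.kind)
            if kind is None:
                raise SchemaError(f"unmapped interaction kind {ev.kind!r}")
        seen[ev.identity] = ChemFeature(
            kind=kind,
            position=ev.ligand_site_position,
            tolerance=tol[kind],
            anchors=(ev.residue_label(reference_chain),),
        )
    return PharmacophoreModel(tuple(seen.values()), frame_label=frame_label,
                              provenance=(frame_label,) if frame_label else ())


# ---------------------------------------------------------------------------
# Rigid overlay
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OverlayResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    mapping: tuple[tuple[int, int], ...]  # (model feature idx, reference feature idx)
    transformed: PharmacophoreModel


def _assignments_by_kind(model: PharmacophoreModel, reference: PharmacophoreModel):
    """All maximal same-kind injective assignments (model idx -> ref idx)."""
    kinds = sorted(set(model.kinds()) & set(reference.kinds()))
    per_kind = []
    for k in kinds:
        mi = [i for i, f in enumerate(model.features) if f.kind == k]
        ri = [i for i, f in enumerate(reference.features) if f.kind == k]
        size = min(len(mi), len(ri))
        opts = []
        for msub in itertools.combinations(mi, size):
            for rperm in itertools.permutations(ri, size):
                opts.append(tuple(zip(msub, rperm)))
        per_kind.append(opts)
    for combo in itertools.product(*per_kind):
        yield tuple(sorted(p for group in combo for p in group))


def overlay(model: PharmacophoreModel, reference: PharmacophoreModel) -> OverlayResult:
    """Least-squares rigid superposition of ``model`` onto ``reference``.

    The same-kind correspondence set is chosen exhaustively: over all
    maximal per-kind injective assignments, the one with the smallest
    superposition RMSD wins.  Exhaustive search is exact and cheap at
    pharmacophore sizes (a handful of features per model).
    """
    best: tuple[float, tuple, np.ndarray, np.ndarray] | None = None
    for mapping in _assignments_by_kind(model, reference):
        if len(mapping) < 3:
            continue
        P = np.array([reference.features[j].position for _, j in mapping])
        Q = np.array([model.features[i].position for i, _ in mapping])
        try:
            R, t, rmsd = kabsch(P, Q)
        except Exception:
            continue
        if best is None or rmsd < best[0] - 1e-12:
            best = (rmsd, mapping, R, t)
    if best is None:
        raise AlignmentError(
            "fewer than 3 usable same-kind correspondences (or all collinear); "
            "pass an identity transform explicitly if models share a frame"
        )
    rmsd, mapping, R, t = best
    return OverlayResult(R, t, rmsd, mapping, model.transformed(R, t))


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------


def consensus(
    models: list[PharmacophoreModel],
    min_models: int = 4,
    merge_radius: float = 1.5,
    strict_greater: bool = True,
    frame_label: str = "consensus",
) -> PharmacophoreModel:
    """Merge overlaid models, retaining features shared across models.

    Features are clustered per kind by greedy centroid linkage within
    ``merge_radius`` (clustering order is canonical — kind, then position —
    so the result does not depend on the order models are passed in).  A
    cluster is retained iff it contains features from strictly more than
    ``min_models`` distinct source models (``strict_greater=True``, the
    default reading of a "present in more than N models" rule) or at least
    ``min_models`` of them (``strict_greater=False``).

    Retained feature: position = member centroid, tolerance = max member
    tolerance, anchors = union.  Direction vectors do not participate in
    membership; the consensus direction is the normalized mean when every
    member carries one.
    """
    if not models:
        raise ValueError("need at least one model")
    if min_models < 1:
        raise ValueError("min_models must be >= 1")
    if merge_radius <= 0:
        raise ValueError("merge_radius must be positive")

    # canonical member order: independent of the model list ordering
    members = [
        (feat, src)
        for src, mdl in enumerate(models)
        for feat in mdl.features
    ]
    members.sort(key=lambda m: (m[0].sort_key(), m[1]))

    clusters: list[dict] = []  # {kind, members: [(feat, src)], centroid}
    for feat, src in members:
        placed = None
        best_d = merge_radius
        for cl in clusters:
            if cl["kind"] != feat.kind:
                continue
            d = float(np.linalg.norm(feat.position - cl["centroid"]))
            if d <= best_d:
                placed, best_d = cl, d
        if placed is None:
            clusters.append({"kind": feat.kind, "members": [(feat, src)],
                             "centroid": feat.position.copy()})
        else:
            placed["members"].append((feat, src))
            placed["centroid"] = np.mean([f.position for f, _ in placed["members"]], axis=0)

    kept: list[ChemFeature] = []
    for cl in clusters:
        n_sources = len({src for _, src in cl["members"]})
        ok = n_sources > min_models if strict_greater else n_sources >= min_models
        if not ok:
            continue
        feats = [f for f, _ in cl["members"]]
        direction = None
        if all(f.direction is not None for f in feats):
            d = np.mean([f.direction for f in feats], axis=0)
            n = float(np.linalg.norm(d))
            if n > 1e-9:
                direction = d / n
        kept.append(
            ChemFeature(
                kind=cl["kind"],
                position=cl["centroid"],
                tolerance=max(f.tolerance for f in feats),
                direction=direction,
                anchors=tuple(sorted({a for f in feats for a in f.anchors})),
            )
        )
    provenance = tuple(
        m.frame_label if m.frame_label else f"model-{i}" for i, m in enumerate(models)
    )
    return PharmacophoreModel(tuple(kept), frame_label=frame_label, provenance=provenance)


# ---------------------------------------------------------------------------
# JSON schema
# ---------------------------------------------------------------------------


def model_to_json(model: PharmacophoreModel) -> str:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "frame_label": model.frame_label,
        "features": [
            {
                "kind": f.kind,
                "position": [float(v) for v in f.position],
                "tolerance": f.tolerance,
                "direction": None if f.direction is None else [float(v) for v in f.direction],
                "anchors": list(f.anchors),
            }
            for f in model.features
        ],
        "provenance": list(model.provenance),
    }
    return json.dumps(doc, indent=1)


def model_from_json(json_text: str) -> PharmacophoreModel:
    try:
        doc = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"invalid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "features" not in doc:
        raise SchemaError("pharmacophore document must contain 'features'")
    feats = []
    for f in doc["features"]:
        try:
            feats.append(
                ChemFeature(
                    kind=f["kind"],
                    position=f["position"],
                    tolerance=float(f.get("tolerance", 1.5)),
                    direction=f.get("direction"),
                    anchors=tuple(f.get("anchors", ())),
                )
            )
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"malformed feature entry: {exc}") from exc
    return PharmacophoreModel(
        tuple(feats),
        frame_label=str(doc.get("frame_label", "")),
        provenance=tuple(doc.get("provenance", ())),
    )
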