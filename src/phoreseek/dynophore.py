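"""Dynamic interaction profiling over trajectories ("dynophores").

Every trajectory frame is run through the same geometric interaction
perception used for static complexes; the result is a per-frame presence
matrix over discovered interaction keys, from which occurrence
percentages (per key and aggregated per interaction kind) and 3D feature
point clouds are derived.  Replicas of the same system can be concatenated
before analysis, weighting every frame equally.

An interaction key is ``(kind, sorted ligand atom serials, protein
chain/residue)`` — stable across frames, and the granularity at which
per-residue interaction frequencies are customarily reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import TrajectoryConsistencyError
from .interactions import GeometricRules, detect_interactions
from .structio import Trajectory

InteractionKey = tuple  # (kind, ligand_serials, (chain, resname, resnum))


@dataclass(frozen=True)
class InteractionTimeline:
    """Per-frame presence of interaction keys plus their site positions."""

    keys: tuple[InteractionKey, ...]
    presence: np.ndarray  # (frames, keys) bool
    site_positions: np.ndarray  # (frames, keys, 3), NaN where absent
    atom_signature: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        pres = np.asarray(self.presence, dtype=bool)
        sites = np.asarray(self.site_positions, dtype=float)
        if pres.ndim != 2 or pres.shape[1] != len(self.keys):
            raise ValueError("presence matrix shape inconsistent with keys")
        if sites.shape != (*pres.shape, 3):
            raise ValueError("site_positions shape inconsistent with presence")
        if len(self.keys) and not pres.any(axis=0).all():
            raise ValueError("every key must be present in at least one frame")
        object.__setattr__(self, "presence", pres)
        object.__setattr__(self, "site_positions", sites)
        object.__setattr__(self, "keys", tuple(self.keys))

    @property
    def frame_count(self) -> int:
        return int(self.presence.shape[0])


def _event_key(ev) -> InteractionKey:
    return (ev.kind, ev.ligand_atom_serials, ev.protein_residue)


def profile_trajectory(
    traj: Trajectory,
    selector,
    rules: GeometricRules | None = None,
) -> InteractionTimeline:
    """Detect interactions on every frame and assemble the timeline.

    Keys are discovered as the union over all frames; per-frame results are
    identical to calling :func:`detect_interactions` frame by frame.
    """
    rules = rules or GeometricRules()
    per_frame: list[dict[InteractionKey, np.ndarray]] = []
    for frame in traj.frames:
        events = detect_interactions(frame, selector, rules)
        per_frame.append({_event_key(ev): ev.ligand_site_position for ev in events})
    keys = sorted({k for fr in per_frame for k in fr})
    n_frames, n_keys = len(traj), len(keys)
    presence = np.zeros((n_frames, n_keys), dtype=bool)
    sites = np.full((n_frames, n_keys, 3), np.nan)
    index = {k: i for i, k in enumerate(keys)}
    for f, fr in enumerate(per_frame):
        for k, pos in fr.items():
            presence[f, index[k]] = True
            sites[f, index[k]] = pos
    return InteractionTimeline(
        keys=tuple(keys),
        presence=presence,
        site_positions=sites,
        atom_signature=traj.frames[0].signature(),
    )


def concat_replicas(timelines: list[InteractionTimeline]) -> InteractionTimeline:
    """Concatenate replica timelines of the same system.

    Frames are appended in argument order; keys are unioned, with a key
    absent from a replica back-filled as absent in its frames.  Replicas
    must share atom identities.
    """
    if not timelines:
        raise ValueError("need at least one timeline")
    sig = timelines[0].atom_signature
    for i, tl in enumerate(timelines[1:], start=2):
        if tl.atom_signature != sig:
            raise TrajectoryConsistencyError(f"replica {i} atom identities differ from replica 1")
    keys = sorted({k for tl in timelines for k in tl.keys})
    index = {k: i for i, k in enumerate(keys)}
    total = sum(tl.frame_count for tl in timelines)
    presence = np.zeros((total, len(keys)), dtype=bool)
    sites = np.full((total, len(keys), 3), np.nan)
    row = 0
    for tl in timelines:
        cols = [index[k] for k in tl.keys]
        presence[row : row + tl.frame_count, cols] = tl.presence
        sites[row : row + tl.frame_count, cols] = tl.site_positions
        row += tl.frame_count
    return InteractionTimeline(
        keys=tuple(keys), presence=presence, site_positions=sites, atom_signature=sig
    )


@dataclass(frozen=True)
class FrequencyReport:
    """Occurrence percentages, both per key and aggregated per kind.

    ``per_key_percent`` is exact (float); ``per_key_percent_int`` is the
    integer-percent rendering used in reports.  The per-kind aggregate
    counts a frame when *any* key of that kind is present, so it is always
    >= the largest member-key percentage.
    """

    per_key_percent: dict[InteractionKey, float]
    per_key_percent_int: dict[InteractionKey, int]
    per_kind_percent: dict[str, float]


def frequencies(timeline: InteractionTimeline) -> FrequencyReport:
    """Occurrence percentage of every key and kind over the timeline."""
    if timeline.frame_count < 1:
        raise ValueError("timeline has no frames")
    n = timeline.frame_count
    per_key = {
        k: 100.0 * int(timeline.presence[:, i].sum()) / n
        for i, k in enumerate(timeline.keys)
    }
    per_key_int = {k: int(round(v)) for k, v in per_key.items()}
    kinds = sorted({k[0] for k in timeline.keys})
    per_kind = {}
    for kind in kinds:
        cols = [i for i, k in enumerate(timeline.keys) if k[0] == kind]
        any_present = timeline.presence[:, cols].any(axis=1)
        per_kind[kind] = 100.0 * int(any_present.sum()) / n
    return FrequencyReport(
        per_key_percent=per_key,
        per_key_percent_int=per_key_int,
        per_kind_percent=per_kind,
    )


def clouds(timeline: InteractionTimeline) -> dict[InteractionKey, np.ndarray]:
    """Per-key point cloud: the site positions of every frame where present."""
    out = {}
    for i, k in enumerate(timeline.keys):
        mask = timeline.presence[:, i]
        out[k] = timeline.site_positions[mask, i, :]
    return out
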