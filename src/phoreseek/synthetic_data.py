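"""Seeded synthetic-data generators with known ground truth.

Every pipeline input has a generator here: toy binding pockets with
planted interaction geometries, screening libraries with a known active
fraction plus property-matched decoys, trajectories with planted per-frame
interaction schedules, and 4PL dose-response data under competitive or
non-competitive antagonism.

Generators use NumPy's Philox counter-based generator with explicit
integer seeding, so identical specs reproduce identical outputs.  Each
generator validates its own output against its ground truth before
returning (rejection sampling where needed) and raises
:class:`GenerationError` instead of handing back an input that violates
its contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._geometry import random_rotation
from .errors import GenerationError
from .interactions import (
    GeometricRules,
    InteractionEvent,
    detect_interactions,
    ligand_selector,
)
from .pharmacology import DoseResponse
from .pharmacophore import PharmacophoreModel
from .screening import DEFAULT_SETTINGS, ScreenSettings, match_conformer
from .structio import AtomRecord, FeaturePoint, StructureModel, Trajectory
from .validation import LabeledLibrary, LibraryEntry

LIGAND_RESNAME = "LIG"
LIGAND_CHAIN = "L"

#: Library / assay shapes mirroring published validation designs; contents
#: are synthetic.
SCENARIOS: dict[str, dict] = {
    "setA": {"n_active": 158, "n_inactive": 231, "n_decoy": 8406,
             "jitter_sd": 0.3, "n_conformers": 3},
    "setB": {"n_active": 47, "n_inactive": 231, "n_decoy": 2538,
             "jitter_sd": 0.3, "n_conformers": 3},
    "fig6": {"fourpl": {"bottom": 0.0, "top": 100.0, "hill": 1.0, "half_max": 1e-7},
             "K_B": 1e-7, "antagonist_factors": (1.0, 3.0, 10.0, 30.0),
             "noise_sd": 5.0, "n_replicates": 2},
}


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(int(seed)))


# ---------------------------------------------------------------------------
# Toy complexes with planted interactions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Plant:
    """One planted interaction: its kind, realizing atoms and geometry."""

    kind: str
    ligand_serials: tuple[int, ...]
    protein_residue: tuple[str, str, int]
    axis: np.ndarray  # unit vector, ligand -> protein, final coordinates


@dataclass(frozen=True)
class SyntheticComplex:
    structure: StructureModel
    events: tuple[InteractionEvent, ...]  # ground truth
    plants: tuple[Plant, ...]
    rules: GeometricRules

    def selector(self):
        return ligand_selector(LIGAND_RESNAME, LIGAND_CHAIN)


def _sphere_directions(n: int) -> np.ndarray:
    """n reasonably spread unit vectors (golden-spiral points)."""
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    idx = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * idx
    z = 1.0 - 2.0 * (idx + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _perp(u: np.ndarray) -> np.ndarray:
    v = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(u, v)
    return p / np.linalg.norm(p)


def gen_complex(
    seed: int = 0,
    planted: list[str] | None = None,
    rules: GeometricRules | None = None,
    min_site_distance: float = 12.0,
) -> SyntheticComplex:
    """A toy pocket whose only contacts are the planted interactions.

    ``planted`` lists interaction kinds (HBOND_LIG_DONOR,
    HBOND_LIG_ACCEPTOR, HYDROPHOBIC, IONIC, AROMATIC_PI; repeats allowed).
    Each plant is realized just inside the rule thresholds at a site
    well-separated from every other plant; a seeded rigid motion of the
    whole complex varies coordinates between seeds without touching the
    geometry.  The returned ground-truth events are verified against
    :func:`detect_interactions` before returning.
    """
    rules = rules or GeometricRules()
    planted = list(planted or [])
    rng = _rng(seed)
    n_sites = max(1, len(planted))
    dirs = _sphere_directions(n_sites)
    if n_sites > 1:
        chords = [
            float(np.linalg.norm(dirs[i] - dirs[j]))
            for i in range(n_sites)
            for j in range(i + 1, n_sites)
        ]
        min_chord = min(chords)
        if min_chord <= 1e-6:
            raise GenerationError("cannot place planted sites apart")
        radius = max(12.0, (min_site_distance + 8.0) / min_chord)
    else:
        radius = 12.0

    lig_atoms: list[AtomRecord] = []
    prot_atoms: list[AtomRecord] = []
    plants: list[Plant] = []
    gt: list[InteractionEvent] = []
    serial = 0
    resnum = 300

    def lig_atom(name, element, pos, charge=0):
        nonlocal serial
        serial += 1
        lig_atoms.append(
            AtomRecord(serial, name, element, LIGAND_RESNAME, 1, LIGAND_CHAIN,
                       np.asarray(pos, float), charge, het=True)
        )
        return serial

    def prot_atom(name, element, resname, rnum, pos):
        nonlocal serial
        serial += 1
        prot_atoms.append(
            AtomRecord(serial, name, element, resname, rnum, "A", np.asarray(pos, float))
        )
        return serial

    for i, kind in enumerate(planted):
        u = dirs[i]
        p = _perp(u)
        q = np.cross(u, p)
        site = radius * u
        resnum += 1
        if kind == "HBOND_LIG_DONOR":
            n_pos = site - 1.45 * u
            sn = lig_atom(f"N{i+1}", "N", n_pos)
            lig_atom(f"H{i+1}", "H", n_pos + 1.0 * u)
            prot_atom("O", "O", "GLY", resnum, site + 1.45 * u)
            prot_atom("C", "C", "GLY", resnum, site + 1.45 * u + 1.23 * p)
            reskey = ("A", "GLY", resnum)
            gt.append(InteractionEvent(kind, (sn,), reskey, {"distance": 2.9}, n_pos))
            plants.append(Plant(kind, (sn, sn + 1), reskey, u))
        elif kind == "HBOND_LIG_ACCEPTOR":
            o_pos = site - 1.45 * u
            sn = lig_atom(f"O{i+1}", "O", o_pos)
            prot_atom("N", "N", "GLY", resnum, site + 1.45 * u)
            prot_atom("H", "H", "GLY", resnum, site + 0.45 * u)
            prot_atom("CA", "C", "GLY", resnum, site + 1.45 * u + 1.45 * p)
            reskey = ("A", "GLY", resnum)
            gt.append(InteractionEvent(kind, (sn,), reskey, {"distance": 2.9}, o_pos))
            plants.append(Plant(kind, (sn,), reskey, u))
        elif kind == "HYDROPHOBIC":
            c1 = site - 2.0 * u
            c2 = c1 + 1.5 * p
            s1 = lig_atom(f"C{i+1}A", "C", c1)
            s2 = lig_atom(f"C{i+1}B", "C", c2)
            prot_atom("CB", "C", "ALA", resnum, site + 2.0 * u)
            prot_atom("CA", "C", "ALA", resnum, site + 2.0 * u + 1.52 * q)
            reskey = ("A", "ALA", resnum)
            gt.append(
                InteractionEvent(kind, (s1, s2), reskey, {"distance": 4.0},
                                 0.5 * (c1 + c2))
            )
            plants.append(Plant(kind, (s1, s2), reskey, u))
        elif kind == "IONIC":
            n_pos = site - 2.5 * u
            sn = lig_atom(f"N{i+1}", "N", n_pos, charge=+1)
            prot_atom("OE1", "O", "GLU", resnum, site + 2.5 * u + 1.1 * p)
            prot_atom("OE2", "O", "GLU", resnum, site + 2.5 * u - 1.1 * p)
            prot_atom("CD", "C", "GLU", resnum, site + 3.2 * u)
            reskey = ("A", "GLU", resnum)
            gt.append(
                InteractionEvent(kind, (sn,), reskey,
                                 {"distance": 5.0, "ligand_charge": 1.0}, n_pos)
            )
            plants.append(Plant(kind, (sn,), reskey, u))
        elif kind == "AROMATIC_PI":
            lc = site - 1.9 * u
            pc = site + 1.9 * u
            ring_serials = []
            for k in range(6):
                ang = math.pi * k / 3.0
                pos = lc + 1.39 * (math.cos(ang) * p + math.sin(ang) * q)
                ring_serials.append(lig_atom(f"C{i+1}{k}", "C", pos))
            for name, k in zip(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), range(6)):
                ang = math.pi * k / 3.0
                prot_atom(name, "C", "PHE", resnum,
                          pc + 1.39 * (math.cos(ang) * p + math.sin(ang) * q))
            reskey = ("A", "PHE", resnum)
            gt.append(
                InteractionEvent(kind, tuple(ring_serials), reskey,
                                 {"distance": 3.8, "plane_angle": 0.0}, lc)
            )
            plants.append(Plant(kind, tuple(ring_serials), reskey, u))
        else:
            raise ValueError(f"unknown planted interaction kind {kind!r}")

    if not lig_atoms:
        # a plant-free pocket still needs a ligand to select
        lig_atom("C1", "C", np.zeros(3))

    # inert scaffold far outside every cutoff
    for j, u in enumerate(_sphere_directions(4)):
        resnum += 1
        prot_atom("CA", "C", "GLY", resnum, (radius + 12.0) * -u)

    # seeded rigid motion: coordinates differ between seeds, geometry doesn't
    R = random_rotation(rng)
    t = rng.uniform(-5.0, 5.0, size=3)

    def moved(a: AtomRecord) -> AtomRecord:
        from dataclasses import replace
        return replace(a, position=R @ a.position + t)

    atoms = tuple(moved(a) for a in lig_atoms) + tuple(moved(a) for a in prot_atoms)
    structure = StructureModel(atoms=atoms)
    gt_moved = tuple(
        InteractionEvent(e.kind, e.ligand_atom_serials, e.protein_residue,
                         e.measurements, R @ e.ligand_site_position + t)
        for e in gt
    )
    plants_moved = tuple(
        Plant(pl.kind, pl.ligand_serials, pl.protein_residue, R @ pl.axis) for pl in plants
    )

    result = SyntheticComplex(structure, gt_moved, plants_moved, rules)
    detected = detect_interactions(structure, result.selector(), rules)
    if {e.identity for e in detected} != {e.identity for e in gt_moved}:
        raise GenerationError(
            "planted complex failed its self-check: detected "
            f"{sorted(e.identity for e in detected)} vs planted "
            f"{sorted(e.identity for e in gt_moved)}"
        )
    return result


# ---------------------------------------------------------------------------
# Trajectories with planted presence schedules
# ---------------------------------------------------------------------------


def duty_cycle_schedule(
    n_frames: int, duty: float, seed: int = 0, mode: str = "random"
) -> np.ndarray:
    """Boolean schedule with exactly ``round(duty * n_frames)`` on-frames."""
    if not (0.0 <= duty <= 1.0):
        raise ValueError("duty must be in [0, 1]")
    n_on = int(round(duty * n_frames))
    sched = np.zeros(n_frames, dtype=bool)
    if mode == "block":
        sched[:n_on] = True
    elif mode == "random":
        idx = _rng(seed).choice(n_frames, size=n_on, replace=False)
        sched[idx] = True
    else:
        raise ValueError("mode must be 'random' or 'block'")
    return sched


def gen_trajectory(
    base: SyntheticComplex,
    schedules: list[np.ndarray],
    n_frames: int | None = None,
    positional_noise_sd: float = 0.02,
    seed: int = 0,
    displacement: float = 5.0,
) -> Trajectory:
    """Frames realizing per-plant presence schedules.

    ``schedules`` aligns with ``base.plants``; in frames where a plant is
    scheduled off, its ligand atoms are displaced along the contact axis
    beyond threshold plus margin.  Small Gaussian positional noise is
    applied to every atom.  The result is validated frame by frame against
    the schedules (via full interaction re-detection) before returning.
    """
    if len(schedules) != len(base.plants):
        raise ValueError("one schedule per planted interaction required")
    schedules = [np.asarray(s, dtype=bool) for s in schedules]
    if n_frames is None:
        n_frames = len(schedules[0]) if schedules else 0
    for s in schedules:
        if len(s) != n_frames:
            raise ValueError("schedule length must equal n_frames")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = _rng(seed)
    base_atoms = base.structure.atoms
    serial_index = {a.serial: i for i, a in enumerate(base_atoms)}
    base_pos = base.structure.positions()

    from dataclasses import replace

    frames = []
    for f in range(n_frames):
        pos = base_pos + rng.normal(0.0, positional_noise_sd, size=base_pos.shape)
        for plant, sched in zip(base.plants, schedules):
            if not sched[f]:
                for s in plant.ligand_serials:
                    pos[serial_index[s]] -= displacement * plant.axis
        atoms = tuple(
            replace(a, position=pos[i]) for i, a in enumerate(base_atoms)
        )
        frames.append(StructureModel(atoms=atoms, model_id=f + 1))
    traj = Trajectory(frames=tuple(frames))

    # post-hoc ground-truth validation
    from .dynophore import profile_trajectory

    timeline = profile_trajectory(traj, base.selector(), base.rules)
    expected = {ev.identity: sched for ev, sched in zip(base.events, schedules)}
    index = {k: i for i, k in enumerate(timeline.keys)}
    for ident, sched in expected.items():
        if not sched.any():
            if ident in index:
                raise GenerationError(f"interaction {ident} detected despite all-off schedule")
            continue
        if ident not in index:
            raise GenerationError(f"planted interaction {ident} never detected")
        got = timeline.presence[:, index[ident]]
        if not np.array_equal(got, sched):
            raise GenerationError(
                f"schedule violated for {ident}: noise flipped "
                f"{int((got != sched).sum())} frame(s)"
            )
    extra = set(index) - set(expected)
    if extra:
        raise GenerationError(f"unplanted interactions detected: {sorted(extra)}")
    return traj


# ---------------------------------------------------------------------------
# Screening libraries
# ---------------------------------------------------------------------------


def _scrambled_conformer(
    model: PharmacophoreModel,
    rng: np.random.Generator,
    settings: ScreenSettings,
    max_iter: int = 200,
) -> tuple[FeaturePoint, ...]:
    """Kind-preserving conformer guaranteed not to match the model."""
    kinds = model.kinds()
    pos = model.positions()
    center = pos.mean(axis=0)
    span = max(4.0, float(np.abs(pos - center).max()) * 2.0)
    for _ in range(max_iter):
        pts = center + rng.uniform(-span, span, size=(len(kinds), 3))
        conf = tuple(FeaturePoint(k, p) for k, p in zip(kinds, pts))
        res = match_conformer(model, conf, settings)
        if res is None or not res.hit:
            return conf
    raise GenerationError("could not scramble a non-matching conformer within iteration cap")


def _matching_conformer(
    model: PharmacophoreModel,
    rng: np.random.Generator,
    jitter_sd: float,
    settings: ScreenSettings,
    max_iter: int = 200,
) -> tuple[FeaturePoint, ...]:
    kinds = model.kinds()
    pos = model.positions()
    for _ in range(max_iter):
        pts = pos + rng.normal(0.0, jitter_sd, size=pos.shape)
        conf = tuple(FeaturePoint(k, p) for k, p in zip(kinds, pts))
        res = match_conformer(model, conf, settings)
        if res is not None and res.hit:
            return conf
    raise GenerationError(
        f"could not realize a matching conformer at jitter_sd={jitter_sd} within iteration cap"
    )


def gen_library(
    model: PharmacophoreModel,
    n_active: int,
    n_decoy: int,
    jitter_sd: float = 0.3,
    n_conformers: int = 5,
    seed: int = 0,
    n_inactive: int = 0,
    settings: ScreenSettings = DEFAULT_SETTINGS,
) -> LabeledLibrary:
    """Labeled screening library with known ground truth.

    Actives carry exactly one conformer that matches ``model`` (the model's
    features under Gaussian jitter of ``jitter_sd`` angstrom, rejection-
    sampled to guarantee the match); every other conformer, and every
    conformer of decoys and inactives, is a kind-preserving geometric
    scramble rejection-sampled to *not* match.  Properties (MW, H-bond
    donor/acceptor counts, rotatable bonds, formal charge, apolar-atom
    fraction) are filled from the model's feature counts plus randomized
    strata, with decoy properties drawn within matching tolerance of an
    active's.
    """
    if n_conformers < 1:
        raise ValueError("n_conformers must be >= 1")
    rng = _rng(seed)
    kinds = model.kinds()
    base_props = {
        "hba_count": float(sum(k == "HBA" for k in kinds)),
        "hbd_count": float(sum(k == "HBD" for k in kinds)),
        "formal_charge": float(sum(k == "PI" for k in kinds) - sum(k == "NI" for k in kinds)),
    }
    entries: list[LibraryEntry] = []
    active_props: list[dict[str, float]] = []

    for i in range(n_active):
        match_idx = int(rng.integers(n_conformers))
        conformers = []
        for ci in range(n_conformers):
            if ci == match_idx:
                conformers.append(_matching_conformer(model, rng, jitter_sd, settings))
            else:
                conformers.append(_scrambled_conformer(model, rng, settings))
        props = dict(base_props)
        props["mw"] = float(rng.normal(380.0, 20.0))
        props["apolar_fraction"] = float(rng.uniform(0.30, 0.50))
        props["rotatable_bonds"] = float(rng.integers(3, 9))
        active_props.append(props)
        entries.append(LibraryEntry(f"act-{i:04d}", "active", props, tuple(conformers)))

    def matched_props() -> dict[str, float]:
        ref = active_props[int(rng.integers(len(active_props)))] if active_props else dict(
            base_props, mw=380.0, apolar_fraction=0.4, rotatable_bonds=5.0
        )
        props = dict(base_props)
        props["mw"] = ref["mw"] + float(rng.uniform(-20.0, 20.0))
        props["apolar_fraction"] = ref["apolar_fraction"] + float(rng.uniform(-0.08, 0.08))
        props["rotatable_bonds"] = ref["rotatable_bonds"] + float(rng.integers(-1, 2))
        return props

    for label, count, tag in (("inactive", n_inactive, "inact"), ("decoy", n_decoy, "dec")):
        for i in range(count):
            conformers = tuple(
                _scrambled_conformer(model, rng, settings) for _ in range(n_conformers)
            )
            entries.append(
                LibraryEntry(f"{tag}-{i:05d}", label, matched_props(), conformers)
            )
    return LabeledLibrary(tuple(entries))


# ---------------------------------------------------------------------------
# Dose-response data
# ---------------------------------------------------------------------------


def gen_dose_response(
    fourpl: dict[str, float],
    agonist_concs: np.ndarray,
    antagonist_concs: list[float],
    K_B: float,
    mechanism: str = "competitive",
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> list[DoseResponse]:
    """Agonist curves at several antagonist concentrations.

    Competitive antagonism shifts the half-max rightward,
    ``c50(B) = c50 * (1 + B / K_B)`` with top and bottom unchanged; the
    non-competitive mechanism instead scales the top by ``1 / (1 + B/K_B)``.
    Gaussian noise of ``noise_sd`` (assay units) is added per observation.
    """
    if K_B <= 0:
        raise ValueError("K_B must be positive")
    if mechanism not in ("competitive", "noncompetitive"):
        raise ValueError("mechanism must be 'competitive' or 'noncompetitive'")
    agonist_concs = np.asarray(agonist_concs, dtype=float)
    if (agonist_concs <= 0).any():
        raise ValueError("agonist concentrations must be positive")
    rng = _rng(seed)
    bottom, top = float(fourpl["bottom"]), float(fourpl["top"])
    hill, half = float(fourpl["hill"]), float(fourpl["half_max"])
    out = []
    for B in antagonist_concs:
        if mechanism == "competitive":
            c50, topB = half * (1.0 + B / K_B), top
        else:
            c50, topB = half, top / (1.0 + B / K_B)
        c = np.tile(agonist_concs, n_replicates)
        reps = np.repeat(np.arange(n_replicates), len(agonist_concs))
        y = bottom + (topB - bottom) / (1.0 + (c50 / c) ** hill)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=y.shape)
        out.append(
            DoseResponse(
                concentrations=c,
                responses=y,
                antagonist_concentration=float(B),
                replicate_ids=tuple(int(r) for r in reps),
            )
        )
    return out


def gen_schild_design(
    seed: int = 0,
    K_B: float = 1e-7,
    fourpl: dict[str, float] | None = None,
    antagonist_factors: tuple[float, ...] = (1.0, 3.0, 10.0, 30.0),
    mechanism: str = "competitive",
    noise_sd: float = 0.0,
    n_replicates: int = 1,
) -> list[DoseResponse]:
    """A full Schild design: control plus antagonist at multiples of K_B.

    Agonist concentrations are half-log spaced over a range wide enough to
    cover the largest expected shift.
    """
    fourpl = fourpl or {"bottom": 0.0, "top": 100.0, "hill": 1.0, "half_max": 1e-7}
    half = float(fourpl["half_max"])
    max_shift = 1.0 + max(antagonist_factors)
    agonist = half * np.logspace(-2.5, math.log10(max_shift) + 2.5, 11)
    antagonist = [0.0] + [f * K_B for f in antagonist_factors]
    return gen_dose_response(
        fourpl, agonist, antagonist, K_B, mechanism, noise_sd, n_replicates, seed
    )


# ---------------------------------------------------------------------------
# Reference pharmacophore scenario
# ---------------------------------------------------------------------------

#: The classic antagonist-pocket composition: one H-bond acceptor, one
#: positive ionizable center, three hydrophobic contacts.
REFERENCE_PLANTS = (
    "HBOND_LIG_ACCEPTOR",
    "IONIC",
    "HYDROPHOBIC",
    "HYDROPHOBIC",
    "HYDROPHOBIC",
)


def gen_reference_complex(seed: int = 0) -> SyntheticComplex:
    """A pocket realizing the 5-feature reference composition."""
    return gen_complex(seed=seed, planted=list(REFERENCE_PLANTS))


def gen_reference_model(seed: int = 0) -> PharmacophoreModel:
    """The 5-feature pharmacophore (HBA, PI, 3x HYD) derived from the pocket."""
    from .pharmacophore import derive_model

    cx = gen_reference_complex(seed)
    events = detect_interactions(cx.structure, cx.selector(), cx.rules)
    return derive_model(events, frame_label=f"synthetic-ref-{seed}")
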