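"""Geometric perception of typed protein-ligand interactions.

Given a 3D complex, this module detects the interaction vocabulary used
throughout structure-based pharmacophore work: hydrogen bonds (split by
which side donates), hydrophobic contacts between apolar carbons, ionic
contacts between opposite formal charges, and aromatic ring stacking.

Protein-side donors, acceptors, charged centers, apolar carbons and rings
come from a fixed residue template table (no pKa or protonation-state
prediction).  Ligand-side chemistry is inferred from elements, formal
charges and geometry (covalent-distance bond inference), or taken from an
RDKit molecule when an SDF is available.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import CapabilityError, SelectionError
from .structio import AtomRecord, FeaturePoint, StructureModel

# ---------------------------------------------------------------------------
# Rules and events
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeometricRules:
    """Distance/angle cutoffs for interaction perception.

    Defaults are standard structural-biology criteria: hydrogen bonds at
    heavy-atom distance <= 3.5 A with a D-H...A angle >= 130 deg (distance
    only when no hydrogens are present, as in most raw PDB files),
    hydrophobic C...C <= 4.5 A, ionic charged-center distance <= 5.5 A, and
    aromatic ring centroids <= 5.5 A with an inter-plane angle <= 30 deg
    (parallel stacking) or >= 60 deg (T-shaped).
    """

    hbond_heavy_dist_max: float = 3.5
    hbond_angle_min: float = 130.0
    hydrophobic_dist_max: float = 4.5
    ionic_dist_max: float = 5.5
    aromatic_centroid_dist_max: float = 5.5
    aromatic_plane_angle_max: float = 30.0
    aromatic_tshape_angle_min: float = 60.0

    def __post_init__(self) -> None:
        for name in (
            "hbond_heavy_dist_max",
            "hydrophobic_dist_max",
            "ionic_dist_max",
            "aromatic_centroid_dist_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("hbond_angle_min", "aromatic_plane_angle_max", "aromatic_tshape_angle_min"):
            v = getattr(self, name)
            if not (0 < v <= 180):
                raise ValueError(f"{name} must be in (0, 180]")


INTERACTION_KINDS = (
    "HBOND_LIG_ACCEPTOR",
    "HBOND_LIG_DONOR",
    "HYDROPHOBIC",
    "IONIC",
    "AROMATIC_PI",
)


@dataclass(frozen=True)
class InteractionEvent:
    """A typed geometric contact between the ligand and one protein residue."""

    kind: str
    ligand_atom_serials: tuple[int, ...]
    protein_residue: tuple[str, str, int]  # (chain_id, residue_name, residue_number)
    measurements: dict[str, float]
    ligand_site_position: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ligand_atom_serials", tuple(sorted(self.ligand_atom_serials)))
        object.__setattr__(
            self, "ligand_site_position", np.asarray(self.ligand_site_position, dtype=float)
        )

    @property
    def identity(self) -> tuple:
        return (self.kind, self.ligand_atom_serials, self.protein_residue)

    def residue_label(self, reference_chain: str | None = None) -> str:
        """Residue label in the one-letter convention, e.g. ``G351``.

        Residues on a chain other than ``reference_chain`` are starred
        (``F494*``), the usual rendering for the partner protomer of a
        dimer interface.
        """
        chain, resname, resnum = self.protein_residue
        letter = _THREE_TO_ONE.get(resname, "X")
        star = "*" if reference_chain is not None and chain != reference_chain else ""
        return f"{letter}{resnum}{star}"


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

# ---------------------------------------------------------------------------
# Protein residue templates
# ---------------------------------------------------------------------------

SIDECHAIN_ACCEPTORS: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "ASN": frozenset({"OD1"}),
    "GLN": frozenset({"OE1"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "HIS": frozenset({"ND1", "NE2"}),
}

SIDECHAIN_DONORS: dict[str, frozenset[str]] = {
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "ASN": frozenset({"ND2"}),
    "GLN": frozenset({"NE2"}),
    "LYS": frozenset({"NZ"}),
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "TRP": frozenset({"NE1"}),
    "HIS": frozenset({"ND1", "NE2"}),
}

#: Charged side-chain centers: the centroid of the named atoms carries the
#: sign.  Carboxylates are negative; lysine ammonium and the arginine
#: guanidinium are positive.  No pKa calculation is attempted.
NEGATIVE_CENTERS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
POSITIVE_CENTERS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
}

#: Side-chain carbons treated as apolar (bonded only to C/H in the
#: template); backbone CA/C are excluded.
APOLAR_CARBONS: dict[str, frozenset[str]] = {
    "ALA": frozenset({"CB"}),
    "VAL": frozenset({"CB", "CG1", "CG2"}),
    "LEU": frozenset({"CB", "CG", "CD1", "CD2"}),
    "ILE": frozenset({"CB", "CG1", "CG2", "CD1"}),
    "MET": frozenset({"CB", "CG", "CE"}),
    "PHE": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TYR": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2"}),
    "TRP": frozenset({"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"}),
    "PRO": frozenset({"CB", "CG", "CD"}),
    "LYS": frozenset({"CB", "CG", "CD"}),
    "ARG": frozenset({"CB", "CG"}),
    "GLU": frozenset({"CB", "CG"}),
    "GLN": frozenset({"CB", "CG"}),
    "ASP": frozenset({"CB"}),
    "ASN": frozenset({"CB"}),
    "HIS": frozenset({"CB"}),
    "CYS": frozenset({"CB"}),
    "THR": frozenset({"CG2"}),
}

AROMATIC_RING_ATOMS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}
_BOND_SLACK = 0.45  # A added to the covalent-radii sum for bond inference


# ---------------------------------------------------------------------------
# Selectors
# ---------------------------------------------------------------------------


def ligand_selector(residue_name: str, chain_id: str | None = None):
    """Predicate matching atoms of the named ligand residue (optional chain)."""

    def predicate(atom: AtomRecord) -> bool:
        if atom.residue_name != residue_name:
            return False
        return chain_id is None or atom.chain_id == chain_id

    return predicate


def _split(complex_model: StructureModel, selector) -> tuple[list[AtomRecord], list[AtomRecord]]:
    lig = [a for a in complex_model.atoms if selector(a)]
    prot = [a for a in complex_model.atoms if not selector(a)]
    if not lig:
        raise SelectionError("ligand selector matched no atoms")
    if not prot:
        raise SelectionError("complex has no non-ligand atoms")
    return lig, prot


# ---------------------------------------------------------------------------
# Ligand-side perception helpers
# ---------------------------------------------------------------------------


def infer_bonds(atoms: list[AtomRecord]) -> list[tuple[int, int]]:
    """Geometric covalent-bond inference: pairs within r_i + r_j + slack."""
    bonds = []
    for a, b in itertools.combinations(atoms, 2):
        ra = _COVALENT_RADII.get(a.element, 0.9)
        rb = _COVALENT_RADII.get(b.element, 0.9)
        if np.linalg.norm(a.position - b.position) <= ra + rb + _BOND_SLACK:
            bonds.append((a.serial, b.serial))
    return bonds


def _bond_graph(atoms: list[AtomRecord], bonds) -> nx.Graph:
    g = nx.Graph()
    for a in atoms:
        g.add_node(a.serial, atom=a)
    for i, j in bonds:
        if i in g and j in g:
            g.add_edge(i, j)
    return g


def _ring_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Centroid, unit normal and max out-of-plane deviation of a ring."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, _, Vt = np.linalg.svd(centered)
    normal = Vt[2]
    dev = float(np.abs(centered @ normal).max())
    return centroid, normal, dev


_RING_PLANARITY_TOL = 0.15  # A


def _ligand_rings(graph: nx.Graph) -> list[tuple[int, ...]]:
    """Planar 5/6-membered C/N rings from the ligand bond graph."""
    rings = []
    for cycle in nx.cycle_basis(graph):
        if len(cycle) not in (5, 6):
            continue
        atoms = [graph.nodes[s]["atom"] for s in cycle]
        if any(a.element not in ("C", "N", "O", "S") for a in atoms):
            continue
        pts = np.array([a.position for a in atoms])
        _, _, dev = _ring_plane(pts)
        if dev <= _RING_PLANARITY_TOL:
            rings.append(tuple(sorted(cycle)))
    return rings


@dataclass
class _LigandChemistry:
    atoms: list[AtomRecord]
    graph: nx.Graph
    rings: list[tuple[int, ...]]
    ring_atoms: frozenset[int]
    donors: list[tuple[AtomRecord, list[AtomRecord]]]  # (heavy donor, attached Hs)
    acceptors: list[AtomRecord]
    charged: list[AtomRecord]
    apolar_groups: list[tuple[AtomRecord, ...]]
    has_hydrogens: bool


def _perceive_ligand(lig_atoms: list[AtomRecord], bonds=None) -> _LigandChemistry:
    if bonds is None:
        bonds = infer_bonds(lig_atoms)
    graph = _bond_graph(lig_atoms, bonds)
    by_serial = {a.serial: a for a in lig_atoms}
    heavy = [a for a in lig_atoms if a.element != "H"]
    has_h = any(a.element == "H" for a in lig_atoms)

    rings = _ligand_rings(graph)
    ring_atoms = frozenset(s for ring in rings for s in ring)

    donors, acceptors, charged = [], [], []
    for a in heavy:
        if a.element in ("N", "O"):
            hs = [by_serial[n] for n in graph.neighbors(a.serial) if by_serial[n].element == "H"]
            if hs:
                donors.append((a, hs))
            if a.formal_charge <= 0:
                acceptors.append(a)
        if a.formal_charge != 0:
            charged.append(a)

    # apolar carbons: bonded only to C/H, and not part of an aromatic ring
    # (ring carbons express as AR, following pharmacophore practice)
    apolar = []
    for a in heavy:
        if a.element != "C" or a.serial in ring_atoms:
            continue
        nbr_elems = {by_serial[n].element for n in graph.neighbors(a.serial)}
        if nbr_elems <= {"C", "H"}:
            apolar.append(a)
    apolar_serials = {a.serial for a in apolar}
    sub = graph.subgraph(apolar_serials)
    groups = [
        tuple(sorted((by_serial[s] for s in comp), key=lambda x: x.serial))
        for comp in nx.connected_components(sub)
    ]
    groups.sort(key=lambda grp: grp[0].serial)

    return _LigandChemistry(
        atoms=lig_atoms,
        graph=graph,
        rings=rings,
        ring_atoms=ring_atoms,
        donors=donors,
        acceptors=acceptors,
        charged=charged,
        apolar_groups=groups,
        has_hydrogens=has_h,
    )


# ---------------------------------------------------------------------------
# Feature classification (ligand-only view)
# ---------------------------------------------------------------------------


def classify_ligand_features(
    lig_atoms: list[AtomRecord],
    bonds: list[tuple[int, int]] | None = None,
    infer: bool = True,
) -> list[tuple[str, np.ndarray, tuple[int, ...]]]:
    """Type the ligand's pharmacophoric features.

    Returns ``(kind, position, member_serials)`` triples:

    * HBA — N/O with lone-pair capacity (non-positive formal charge, N not
      tetrasubstituted);
    * HBD — N/O bearing at least one hydrogen;
    * PI — formally positive atom, or a protonatable aliphatic amine
      (heuristic: non-ring N bonded only to C/H with < 4 heavy neighbors);
    * HYD — centroid of each contiguous apolar-carbon group of >= 2 atoms;
    * AR — aromatic (planar 5/6) ring centroid.

    Bonds may be supplied explicitly (e.g. from an SDF); by default they are
    inferred from covalent distances.  Pass ``infer=False`` without bonds to
    get a :class:`CapabilityError` instead of geometric inference.
    """
    if not lig_atoms:
        return []
    if bonds is None and not infer:
        raise CapabilityError(
            "bond information required for ring/feature perception; "
            "supply bonds explicitly or use SDF input"
        )
    chem = _perceive_ligand(lig_atoms, bonds)
    by_serial = {a.serial: a for a in lig_atoms}
    feats: list[tuple[str, np.ndarray, tuple[int, ...]]] = []

    for a in chem.acceptors:
        if a.element == "N":
            degree = chem.graph.degree(a.serial)
            if degree >= 4:
                continue
        feats.append(("HBA", a.position.copy(), (a.serial,)))
    for a, _hs in chem.donors:
        feats.append(("HBD", a.position.copy(), (a.serial,)))
    for a in chem.atoms:
        if a.element != "N":
            continue
        if a.formal_charge > 0:
            feats.append(("PI", a.position.copy(), (a.serial,)))
            continue
        if a.serial in chem.ring_atoms:
            continue
        nbrs = [by_serial[n] for n in chem.graph.neighbors(a.serial)]
        heavy_nbrs = [n for n in nbrs if n.element != "H"]
        if nbrs and all(n.element in ("C", "H") for n in nbrs) and len(heavy_nbrs) < 4:
            # protonatable aliphatic amine (flagged heuristic)
            feats.append(("PI", a.position.copy(), (a.serial,)))
    for a in chem.atoms:
        if a.formal_charge < 0:
            feats.append(("NI", a.position.copy(), (a.serial,)))
    for grp in chem.apolar_groups:
        if len(grp) < 2:
            continue
        pos = np.mean([a.position for a in grp], axis=0)
        feats.append(("HYD", pos, tuple(a.serial for a in grp)))
    for ring in chem.rings:
        pts = np.array([by_serial[s].position for s in ring])
        centroid, _, _ = _ring_plane(pts)
        feats.append(("AR", centroid, ring))

    feats.sort(key=lambda f: (f[0], f[2]))
    return feats


def features_from_rdkit(mol, conf_id: int = -1) -> tuple[FeaturePoint, ...]:
    """Feature set of one RDKit conformer via the default feature factory.

    Family mapping: Donor->HBD, Acceptor->HBA, PosIonizable->PI,
    NegIonizable->NI, Hydrophobe/LumpedHydrophobe->HYD, Aromatic->AR.
    """
    try:
        from rdkit import Chem, RDConfig
        from rdkit.Chem import ChemicalFeatures
        import os
    except ImportError as exc:  # pragma: no cover
        raise CapabilityError(f"RDKit is required: {exc}") from exc
    fdef = os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
    factory = ChemicalFeatures.BuildFeatureFactory(fdef)
    family_map = {
        "Donor": "HBD",
        "Acceptor": "HBA",
        "PosIonizable": "PI",
        "NegIonizable": "NI",
        "Hydrophobe": "HYD",
        "LumpedHydrophobe": "HYD",
        "Aromatic": "AR",
    }
    out = []
    for f in factory.GetFeaturesForMol(mol, confId=conf_id):
        kind = family_map.get(f.GetFamily())
        if kind is None:
            continue
        p = f.GetPos()
        out.append(FeaturePoint(kind=kind, position=np.array([p.x, p.y, p.z])))
    return tuple(out)


# ---------------------------------------------------------------------------
# Interaction detection
# ---------------------------------------------------------------------------


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b (degrees)."""
    v1 = a - b
    v2 = c - b
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _protein_residues(prot_atoms: list[AtomRecord]):
    residues: dict[tuple[str, str, int], list[AtomRecord]] = {}
    for a in prot_atoms:
        residues.setdefault((a.chain_id, a.residue_name, a.residue_number), []).append(a)
    return residues


def _attached_hydrogens(atoms_in_res: list[AtomRecord], heavy: AtomRecord) -> list[AtomRecord]:
    out = []
    for a in atoms_in_res:
        if a.element != "H":
            continue
        rh = _COVALENT_RADII["H"]
        r = _COVALENT_RADII.get(heavy.element, 0.9)
        if np.linalg.norm(a.position - heavy.position) <= rh + r + _BOND_SLACK:
            out.append(a)
    return out


def _hbond_geometry_ok(
    donor: AtomRecord,
    donor_hs: list[AtomRecord],
    acceptor: AtomRecord,
    rules: GeometricRules,
) -> tuple[bool, dict[str, float]]:
    dist = float(np.linalg.norm(donor.position - acceptor.position))
    if dist > rules.hbond_heavy_dist_max:
        return False, {}
    if not donor_hs:
        # heavy-atom fallback (hydrogens absent, as in most raw PDB files)
        return True, {"distance": dist}
    best = max(_angle_deg(donor.position, h.position, acceptor.position) for h in donor_hs)
    if best < rules.hbond_angle_min:
        return False, {}
    return True, {"distance": dist, "angle": best}


def detect_interactions(
    complex_model: StructureModel,
    selector,
    rules: GeometricRules | None = None,
    ligand_bonds: list[tuple[int, int]] | None = None,
) -> list[InteractionEvent]:
    """Detect all typed ligand-protein contacts satisfying ``rules``.

    ``selector`` is a predicate over :class:`AtomRecord` (see
    :func:`ligand_selector`).  Events are deduplicated at
    ``(kind, ligand atom set, protein residue)`` granularity and returned in
    deterministic order (kind, then residue number, then chain, then ligand
    atoms).
    """
    rules = rules or GeometricRules()
    lig_atoms, prot_atoms = _split(complex_model, selector)
    chem = _perceive_ligand(lig_atoms, ligand_bonds)
    residues = _protein_residues(prot_atoms)
    by_serial = {a.serial: a for a in lig_atoms}

    events: dict[tuple, InteractionEvent] = {}

    def emit(kind, lig_serials, reskey, measurements, site):
        ev = InteractionEvent(
            kind=kind,
            ligand_atom_serials=tuple(lig_serials),
            protein_residue=reskey,
            measurements=measurements,
            ligand_site_position=site,
        )
        prev = events.get(ev.identity)
        if prev is None or measurements.get("distance", 0.0) < prev.measurements.get(
            "distance", float("inf")
        ):
            events[ev.identity] = ev

    for reskey, res_atoms in residues.items():
        resname = reskey[1]
        acceptor_names = {"O", "OXT"} | set(SIDECHAIN_ACCEPTORS.get(resname, ()))
        donor_names = {"N"} | set(SIDECHAIN_DONORS.get(resname, ()))

        # --- hydrogen bonds, ligand donating -------------------------------
        for donor, hs in chem.donors:
            for pa in res_atoms:
                if pa.name not in acceptor_names or pa.element not in ("N", "O"):
                    continue
                ok, meas = _hbond_geometry_ok(donor, hs, pa, rules)
                if ok:
                    emit("HBOND_LIG_DONOR", (donor.serial,), reskey, meas, donor.position)
        # ligand N/O without explicit hydrogens can still donate under the
        # heavy-atom fallback when the ligand carries no hydrogens at all
        if not chem.has_hydrogens:
            for a in chem.atoms:
                if a.element not in ("N", "O") or a.formal_charge < 0:
                    continue
                for pa in res_atoms:
                    if pa.name not in acceptor_names or pa.element not in ("N", "O"):
                        continue
                    ok, meas = _hbond_geometry_ok(a, [], pa, rules)
                    if ok:
                        emit("HBOND_LIG_DONOR", (a.serial,), reskey, meas, a.position)

        # --- hydrogen bonds, ligand accepting ------------------------------
        for acc in chem.acceptors:
            for pa in res_atoms:
                if pa.name not in donor_names or pa.element not in ("N", "O"):
                    continue
                p_hs = _attached_hydrogens(res_atoms, pa)
                ok, meas = _hbond_geometry_ok(pa, p_hs, acc, rules)
                if ok:
                    emit("HBOND_LIG_ACCEPTOR", (acc.serial,), reskey, meas, acc.position)

        # --- hydrophobic contacts (per apolar group x residue) -------------
        apolar_names = APOLAR_CARBONS.get(resname, frozenset())
        prot_apolar = [a for a in res_atoms if a.name in apolar_names and a.element == "C"]
        if prot_apolar:
            for grp in chem.apolar_groups:
                in_contact = []
                dmin = float("inf")
                for la in grp:
                    d = min(
                        float(np.linalg.norm(la.position - pa.position)) for pa in prot_apolar
                    )
                    if d <= rules.hydrophobic_dist_max:
                        in_contact.append(la)
                        dmin = min(dmin, d)
                if in_contact:
                    site = np.mean([a.position for a in in_contact], axis=0)
                    emit(
                        "HYDROPHOBIC",
                        tuple(a.serial for a in in_contact),
                        reskey,
                        {"distance": dmin},
                        site,
                    )

        # --- ionic contacts ------------------------------------------------
        for table, prot_sign in ((NEGATIVE_CENTERS, -1), (POSITIVE_CENTERS, +1)):
            names = table.get(resname)
            if not names:
                continue
            pts = [a.position for a in res_atoms if a.name in names]
            if not pts:
                continue
            center = np.mean(pts, axis=0)
            for la in chem.charged:
                if la.formal_charge * prot_sign >= 0:
                    continue  # like charges do not pair
                d = float(np.linalg.norm(la.position - center))
                if d <= rules.ionic_dist_max:
                    emit(
                        "IONIC",
                        (la.serial,),
                        reskey,
                        {"distance": d, "ligand_charge": float(np.sign(la.formal_charge))},
                        la.position,
                    )

        # --- aromatic stacking ---------------------------------------------
        ring_names = AROMATIC_RING_ATOMS.get(resname)
        if ring_names and chem.rings:
            ring_pts = [a.position for name in ring_names for a in res_atoms if a.name == name]
            if len(ring_pts) == len(ring_names):
                p_centroid, p_normal, _ = _ring_plane(np.array(ring_pts))
                for ring in chem.rings:
                    pts = np.array([by_serial[s].position for s in ring])
                    l_centroid, l_normal, _ = _ring_plane(pts)
                    d = float(np.linalg.norm(l_centroid - p_centroid))
                    if d > rules.aromatic_centroid_dist_max:
                        continue
                    cosang = abs(float(np.dot(l_normal, p_normal)))
                    ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                    if ang <= rules.aromatic_plane_angle_max or ang >= rules.aromatic_tshape_angle_min:
                        emit(
                            "AROMATIC_PI",
                            ring,
                            reskey,
                            {"distance": d, "plane_angle": ang},
                            l_centroid,
                        )

    out = sorted(
        events.values(),
        key=lambda e: (e.kind, e.protein_residue[2], e.protein_residue[0], e.ligand_atom_serials),
    )
    return out
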