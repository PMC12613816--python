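"""Structure, formula and table I/O.

This module owns the package's plumbing formats:

* molecular formulas and exact monoisotopic m/z arithmetic (the HRMS
  "calcd" convention: lightest-isotope masses, minus one electron mass per
  positive charge);
* single- and multi-MODEL PDB files mapped onto light-weight
  :class:`AtomRecord` / :class:`StructureModel` / :class:`Trajectory`
  containers (parsing is delegated to :mod:`gemmi`);
* the conformer feature-library JSON schema consumed by the screening
  engine;
* dose-response CSV tables.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace

import gemmi
import numpy as np
import pandas as pd

from .errors import (
    CapabilityError,
    FormulaParseError,
    MassTableError,
    SchemaError,
    StructureParseError,
    TrajectoryConsistencyError,
)

# ---------------------------------------------------------------------------
# Molecular formulas and monoisotopic mass
# ---------------------------------------------------------------------------

#: Monoisotopic (lightest stable isotope) atomic masses in u.  Frozen in-code
#: so that m/z values are bit-stable across environments.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
    "F": 18.99840316,
    "Cl": 34.96885268,
    "Br": 78.91833760,
    "P": 30.97376200,
    "I": 126.90447300,
    "B": 11.00930536,
    "Si": 27.97692653,
    "Na": 22.98976928,
    "K": 38.96370649,
    "Se": 73.92247593,
}

#: Electron rest mass in u; subtracted once per positive charge.
ELECTRON_MASS: float = 0.00054858

SUPPORTED_ELEMENTS = frozenset(MONOISOTOPIC_MASS)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element composition of a (possibly ionic) species.

    ``counts`` maps element symbols to strictly positive integer counts.
    The canonical text rendering follows Hill order: carbon first, hydrogen
    second, then the remaining elements alphabetically (all alphabetical
    when no carbon is present).
    """

    counts: dict[str, int]

    def __post_init__(self) -> None:
        for sym, n in self.counts.items():
            if sym not in SUPPORTED_ELEMENTS:
                raise FormulaParseError(f"unsupported element symbol {sym!r}")
            if not isinstance(n, int) or n < 1:
                raise FormulaParseError(f"count for {sym} must be a positive integer, got {n!r}")
        object.__setattr__(self, "counts", dict(self.counts))

    def __str__(self) -> str:
        symbols = sorted(self.counts)
        if "C" in self.counts:
            ordered = ["C"] + (["H"] if "H" in self.counts else [])
            ordered += [s for s in symbols if s not in ("C", "H")]
        else:
            ordered = symbols
        return "".join(s + (str(self.counts[s]) if self.counts[s] > 1 else "") for s in ordered)


def parse_formula(text: str) -> MolecularFormula:
    """Parse a molecular-formula string such as ``"C24H28N3O3"``.

    An element symbol without a trailing number counts once; a repeated
    symbol accumulates.  Unknown symbols and malformed input raise
    :class:`FormulaParseError` naming the offending token.
    """
    if not text:
        raise FormulaParseError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(0):
            raise FormulaParseError(f"unparseable token at {text[pos:]!r} in formula {text!r}")
        sym, digits = m.group(1), m.group(2)
        if sym not in SUPPORTED_ELEMENTS:
            raise FormulaParseError(f"unknown element {sym!r} in formula {text!r}")
        n = int(digits) if digits else 1
        if n < 1:
            raise FormulaParseError(f"zero count for {sym!r} in formula {text!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return MolecularFormula(counts)


def monoisotopic_mz(formula: MolecularFormula | str, charge: int = 1) -> float:
    """Exact monoisotopic m/z of a positive ion.

    ``formula`` is the full ion composition (adduct hydrogens included, as
    in an [M + H]+ annotation).  The value is
    ``(sum_e count_e * mass_e - charge * m_electron) / charge`` and is
    returned unrounded; HRMS-style reporting rounds to 5 decimals on output
    (see :func:`format_mz`).
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    total = 0.0
    for sym, n in formula.counts.items():
        try:
            total += n * MONOISOTOPIC_MASS[sym]
        except KeyError:  # pragma: no cover - counts are pre-validated
            raise MassTableError(f"no monoisotopic mass for element {sym!r}") from None
    return (total - charge * ELECTRON_MASS) / charge


def format_mz(formula: MolecularFormula | str, charge: int = 1) -> str:
    """m/z rendered to the 5 decimals customary for HRMS calcd values."""
    return f"{monoisotopic_mz(formula, charge):.5f}"


# ---------------------------------------------------------------------------
# Structures and trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structural model (PDB ATOM/HETATM content)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray  # (3,) in A
    formal_charge: int = 0
    het: bool = False
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureParseError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class StructureModel:
    """An ordered set of atoms forming one structural model."""

    atoms: tuple[AtomRecord, ...]
    model_id: int = 1

    def __post_init__(self) -> None:
        atoms = tuple(self.atoms)
        if not atoms:
            raise StructureParseError("structure has no atoms")
        serials = [a.serial for a in atoms]
        if len(set(serials)) != len(serials):
            raise StructureParseError("duplicate atom serials within model")
        object.__setattr__(self, "atoms", atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def signature(self) -> tuple[tuple[int, str], ...]:
        return tuple((a.serial, a.element) for a in self.atoms)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "StructureModel":
        atoms = tuple(
            replace(a, position=np.asarray(R, float) @ a.position + np.asarray(t, float))
            for a in self.atoms
        )
        return StructureModel(atoms=atoms, model_id=self.model_id)


@dataclass(frozen=True)
class Trajectory:
    """An ordered list of frames with identical atom identities."""

    frames: tuple[StructureModel, ...]
    frame_times_ns: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if not frames:
            raise TrajectoryConsistencyError("trajectory has no frames")
        sig0 = frames[0].signature()
        for i, f in enumerate(frames[1:], start=2):
            if f.signature() != sig0:
                raise TrajectoryConsistencyError(
                    f"frame {i} atom identities differ from frame 1 "
                    f"({len(f)} vs {len(frames[0])} atoms)"
                )
        if self.frame_times_ns is not None and len(self.frame_times_ns) != len(frames):
            raise TrajectoryConsistencyError("frame_times_ns length mismatch")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)


def _atoms_from_gemmi_model(model: gemmi.Model, model_id: int) -> StructureModel:
    atoms: list[AtomRecord] = []
    # altloc policy: keep the highest-occupancy alternative; ties keep the
    # first encountered in file order.
    best: dict[tuple, int] = {}
    for chain in model:
        for res in chain:
            for atom in res:
                rec = AtomRecord(
                    serial=atom.serial,
                    name=atom.name,
                    element=atom.element.name,
                    residue_name=res.name,
                    residue_number=res.seqid.num,
                    chain_id=chain.name or " ",
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    formal_charge=int(atom.charge),
                    het=res.het_flag == "H",
                    occupancy=float(atom.occ),
                )
                if atom.altloc not in ("", " ", "\x00"):
                    key = (chain.name, res.seqid.num, res.name, atom.name)
                    if key in best:
                        if rec.occupancy > atoms[best[key]].occupancy:
                            atoms[best[key]] = rec
                        continue
                    best[key] = len(atoms)
                atoms.append(rec)
    if not atoms:
        raise StructureParseError("model contains no atoms")
    return StructureModel(atoms=tuple(atoms), model_id=model_id)


def _read_gemmi(pdb_text: str) -> gemmi.Structure:
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"PDB parse failure: {exc}") from exc
    st.setup_entities()
    return st


def read_structure(pdb_text: str) -> StructureModel:
    """Read the first MODEL of a PDB document into a :class:`StructureModel`."""
    st = _read_gemmi(pdb_text)
    if len(st) == 0:
        raise StructureParseError("no MODEL/atoms in PDB input")
    return _atoms_from_gemmi_model(st[0], model_id=1)


def read_trajectory(pdb_text: str) -> Trajectory:
    """Read every MODEL block of a multi-model PDB as trajectory frames."""
    st = _read_gemmi(pdb_text)
    if len(st) == 0:
        raise StructureParseError("no MODEL/atoms in PDB input")
    frames = [_atoms_from_gemmi_model(m, model_id=i + 1) for i, m in enumerate(st)]
    return Trajectory(frames=tuple(frames))


def _format_atom_line(a: AtomRecord) -> str:
    record = "HETATM" if a.het else "ATOM  "
    name = a.name
    if len(name) < 4 and len(a.element) == 1:
        name = " " + name
    charge = ""
    if a.formal_charge:
        charge = f"{abs(a.formal_charge)}{'+' if a.formal_charge > 0 else '-'}"
    x, y, z = a.position
    return (
        f"{record}{a.serial:>5d} {name:<4s} {a.residue_name:>3s} {a.chain_id:1s}"
        f"{a.residue_number:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
        f"          {a.element:>2s}{charge:<2s}"
    )


def write_structure(model: StructureModel) -> str:
    """Render a model as PDB text (coordinates to the format's 3 decimals)."""
    lines = [_format_atom_line(a) for a in model.atoms]
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_trajectory(traj: Trajectory) -> str:
    """Render a trajectory as a multi-MODEL PDB document."""
    lines: list[str] = []
    for i, frame in enumerate(traj.frames, start=1):
        lines.append(f"MODEL {i:>8d}")
        lines.extend(_format_atom_line(a) for a in frame.atoms)
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Feature libraries (screening input)
# ---------------------------------------------------------------------------

#: The pharmacophore feature vocabulary: hydrogen-bond acceptor/donor,
#: hydrophobic, positive/negative ionizable, aromatic ring.
FEATURE_KINDS = ("HBA", "HBD", "HYD", "PI", "NI", "AR")


@dataclass(frozen=True)
class FeaturePoint:
    """A typed feature position — the unit the matching engine consumes."""

    kind: str
    position: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise SchemaError(f"unknown feature kind {self.kind!r}")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise SchemaError("feature position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


ConformerFeatureSet = tuple  # tuple[FeaturePoint, ...]


def read_feature_library(json_text: str) -> list[tuple[str, list[tuple[FeaturePoint, ...]]]]:
    """Parse the conformer feature-library JSON schema.

    Schema::

        {"schema_version": 1,
         "molecules": [{"id": str,
                        "conformers": [[{"kind": str, "position": [x,y,z]}, ...], ...]}]}

    Ordering of molecules, conformers and features is preserved.
    """
    try:
        doc = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"invalid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "molecules" not in doc:
        raise SchemaError("feature library document must contain a 'molecules' list")
    out: list[tuple[str, list[tuple[FeaturePoint, ...]]]] = []
    for mol in doc["molecules"]:
        try:
            mol_id = str(mol["id"])
            conformers = [
                tuple(FeaturePoint(kind=f["kind"], position=f["position"]) for f in conf)
                for conf in mol["conformers"]
            ]
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"malformed molecule entry: {exc}") from exc
        out.append((mol_id, conformers))
    return out


def write_feature_library(library: list[tuple[str, list[tuple[FeaturePoint, ...]]]]) -> str:
    doc = {
        "schema_version": 1,
        "molecules": [
            {
                "id": mol_id,
                "conformers": [
                    [{"kind": f.kind, "position": [float(v) for v in f.position]} for f in conf]
                    for conf in conformers
                ],
            }
            for mol_id, conformers in library
        ],
    }
    return json.dumps(doc, indent=1)


# ---------------------------------------------------------------------------
# Dose-response tables
# ---------------------------------------------------------------------------

DOSE_RESPONSE_COLUMNS = ("molecule", "antagonist_conc", "agonist_conc", "response", "replicate")


def read_dose_response_csv(csv_source) -> pd.DataFrame:
    """Read a dose-response CSV with the canonical column set.

    Columns: ``molecule`` (str), ``antagonist_conc`` (molar, 0 for control),
    ``agonist_conc`` (molar), ``response`` (assay units), ``replicate`` (id).
    """
    df = pd.read_csv(csv_source)
    missing = [c for c in DOSE_RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"dose-response table missing columns: {missing}")
    if (df["agonist_conc"] <= 0).any():
        raise SchemaError("agonist concentrations must be positive")
    if (df["antagonist_conc"] < 0).any():
        raise SchemaError("antagonist concentrations must be non-negative")
    return df


def read_sdf_molecules(path: str):
    """Yield RDKit molecules from an SDF file (requires the ``chem`` extra)."""
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover
        raise CapabilityError(f"RDKit is required for SDF input: {exc}") from exc
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for mol in supplier:
        if mol is not None:
            yield mol
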