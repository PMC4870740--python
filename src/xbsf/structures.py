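"""Reading and writing protein/ligand structures for halogen-bond scoring.

Handles two fixed-column dialects: standard PDB, and the PDBQT files written
by AutoDock receptor preparation and by Vina as multi-MODEL pose output.
PDBQT shares the PDB coordinate columns; the trailing partial-charge and
AutoDock-type columns are used only to resolve elements. One reader covers
both so element resolution is identical on every code path.

Scoring is heavy-atom only: hydrogens are parsed and retained but every
geometric operation in this package ignores them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

WATER_RESIDUES = frozenset({"HOH", "WAT", "H2O", "DOD"})

HALOGENS = ("Cl", "Br", "I")

#: maximum C-X bond length accepted when inferring covalent halogen sites
#: (typical C-Cl/C-Br/C-I bonds are 1.79/1.94/2.13 A; cutoffs add slack).
CX_COVALENT_CUTOFF = {"Cl": 2.1, "Br": 2.2, "I": 2.4}

# AutoDock atom types -> element (Vina's standard type set).
_AUTODOCK_ELEMENTS = {
    "C": "C", "A": "C", "N": "N", "NA": "N", "NS": "N",
    "O": "O", "OA": "O", "OS": "O", "S": "S", "SA": "S",
    "H": "H", "HD": "H", "HS": "H",
    "F": "F", "CL": "Cl", "BR": "Br", "I": "I", "P": "P",
    "MG": "Mg", "MN": "Mn", "ZN": "Zn", "CA": "Ca", "FE": "Fe",
}

# element -> AutoDock type used when writing PDBQT fixtures
_ELEMENT_AUTODOCK = {
    "C": "C", "N": "NA", "O": "OA", "S": "SA", "H": "HD",
    "F": "F", "Cl": "Cl", "Br": "Br", "I": "I", "P": "P",
}

_TWO_LETTER = {"CL": "Cl", "BR": "Br", "FE": "Fe", "ZN": "Zn", "MG": "Mg",
               "MN": "Mn", "NA": "Na", "CA": "Ca", "SE": "Se"}


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


@dataclass
class Atom:
    """One heavy (or hydrogen) atom with its structural context."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    source_record: str = "ATOM"
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial}: element could not be resolved")

    @property
    def is_water(self) -> bool:
        return self.residue_name.upper() in WATER_RESIDUES

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    def distance_to(self, other: "Atom") -> float:
        return float(np.linalg.norm(self.position - other.position))


@dataclass
class Structure:
    """An ordered collection of atoms from one MODEL of a coordinate file."""

    atoms: list[Atom] = field(default_factory=list)
    model_id: int = 1
    resolution: float | None = None
    source: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def coordinates(self, heavy_only: bool = False) -> np.ndarray:
        atoms = self.heavy_atoms if heavy_only else self.atoms
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in atoms])

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Structure":
        """Return a rigidly transformed copy (x' = R x + t)."""
        rot = np.eye(3) if rotation is None else np.asarray(rotation, float)
        tra = np.zeros(3) if translation is None else np.asarray(translation, float)
        atoms = [replace(a, position=rot @ a.position + tra) for a in self.atoms]
        return Structure(atoms=atoms, model_id=self.model_id,
                         resolution=self.resolution, source=self.source)


@dataclass(frozen=True)
class HalogenSite:
    """A carbon-bonded halogen (the C-X donor of a C-X...A halogen bond)."""

    halogen: Atom
    bonded_carbon: Atom
    cx_bond_length: float


def element_from_name(name: str) -> str:
    """Infer an element symbol from a PDB atom name.

    Digits and primes are stripped; a leading two-letter symbol such as CL
    or BR wins over the one-letter reading, which is how prepared docking
    files usually spell halogens (CL1, BR2, ...).
    """
    letters = "".join(c for c in name if c.isalpha()).upper()
    if not letters:
        return ""
    if letters[:2] in _TWO_LETTER:
        return _TWO_LETTER[letters[:2]]
    return letters[0]


def _resolve_element(name: str, element_col: str, ad_type: str, dialect: str) -> str:
    if dialect == "pdb" and element_col:
        sym = element_col.capitalize()
        return sym
    if dialect == "pdbqt" and ad_type:
        sym = _AUTODOCK_ELEMENTS.get(ad_type.upper())
        if sym:
            return sym
    return element_from_name(name)


def _parse_atom_line(line: str, lineno: int, dialect: str) -> Atom | None:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        residue_name = line[17:21].strip()
        chain_id = line[21].strip()
        residue_number = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        bfac = float(line[60:66]) if line[60:66].strip() else 0.0
    except (ValueError, IndexError) as exc:
        raise StructureParseError(f"line {lineno}: malformed coordinate record: {exc}") from exc

    # deterministic geometry: keep only blank or primary alternate locations
    if altloc not in ("", "A"):
        return None

    if dialect == "pdbqt":
        ad_type = line[77:79].strip() if len(line) > 77 else ""
        element = _resolve_element(name, "", ad_type, dialect)
    else:
        element_col = line[76:78].strip() if len(line) > 76 else ""
        element = _resolve_element(name, element_col, "", dialect)
    if not element:
        raise StructureParseError(f"line {lineno}: cannot resolve element for atom name {name!r}")

    return Atom(serial=serial, name=name, element=element,
                residue_name=residue_name, chain_id=chain_id,
                residue_number=residue_number, position=np.array([x, y, z]),
                occupancy=occ, b_factor=bfac,
                source_record=line[:6].strip(), altloc=altloc)


def parse_structure(path: str | Path, dialect: str | None = None) -> list[Structure]:
    """Parse a PDB or PDBQT file into one :class:`Structure` per MODEL.

    Parameters
    ----------
    path
        Coordinate file. A file without MODEL records yields one structure.
    dialect
        ``"pdb"`` or ``"pdbqt"``; inferred from the file suffix when omitted.

    Returns
    -------
    list of Structure
        Atom order is preserved; waters are retained (flagged via
        ``Atom.is_water``). REMARK 2 resolution, when present, is attached
        to every model.
    """
    path = Path(path)
    if dialect is None:
        dialect = "pdbqt" if path.suffix.lower() == ".pdbqt" else "pdb"
    if dialect not in ("pdb", "pdbqt"):
        raise ValueError(f"unknown dialect {dialect!r}")

    text = path.read_text()
    models: list[Structure] = []
    current: list[Atom] = []
    model_id = 1
    in_model = False
    saw_model = False
    resolution: float | None = None

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            saw_model = True
            in_model = True
            current = []
            try:
                model_id = int(line.split()[1])
            except (IndexError, ValueError):
                model_id = len(models) + 1
        elif rec.startswith("ENDMDL"):
            models.append(Structure(atoms=current, model_id=model_id, source=str(path)))
            in_model = False
            current = []
        elif rec in ("ATOM  ", "HETATM"):
            atom = _parse_atom_line(line, lineno, dialect)
            if atom is not None:
                current.append(atom)
        elif rec.startswith("REMARK") and "RESOLUTION." in line:
            tail = line.split("RESOLUTION.", 1)[1]
            for tok in tail.split():
                try:
                    resolution = float(tok)
                    break
                except ValueError:
                    continue

    if current and (not saw_model or in_model):
        models.append(Structure(atoms=current, model_id=model_id, source=str(path)))

    if not models or all(len(m) == 0 for m in models):
        raise StructureParseError(f"{path}: no atoms found")

    for m in models:
        m.resolution = resolution
        serials = [a.serial for a in m.atoms]
        if len(set(serials)) != len(serials):
            raise StructureParseError(f"{path}: duplicate atom serials in model {m.model_id}")
    return models


def find_halogen_sites(ligand: Structure) -> list[HalogenSite]:
    """Locate carbon-bonded Cl/Br/I atoms (halogen-bond donors).

    Every halogen with a carbon inside its covalent cutoff appears exactly
    once, paired with the nearest such carbon (ties broken by lowest carbon
    serial). Fluorine and free halide ions are excluded.
    """
    carbons = [a for a in ligand.atoms if a.element == "C"]
    sites: list[HalogenSite] = []
    for atom in ligand.atoms:
        if atom.element not in CX_COVALENT_CUTOFF:
            continue
        cutoff = CX_COVALENT_CUTOFF[atom.element]
        best: tuple[float, int, Atom] | None = None
        for carbon in carbons:
            d = atom.distance_to(carbon)
            if d <= cutoff:
                key = (round(d, 6), carbon.serial)
                if best is None or key < (best[0], best[1]):
                    best = (key[0], key[1], carbon)
        if best is not None:
            sites.append(HalogenSite(halogen=atom, bonded_carbon=best[2],
                                     cx_bond_length=atom.distance_to(best[2])))
    return sites


def find_acceptors(protein: Structure, include_waters: bool = False,
                   include_hetero: bool = True) -> list[Atom]:
    """Return the halogen-bond acceptor atoms (O, N, S) of a receptor.

    Water oxygens are excluded by default, mirroring standard receptor
    preparation; ``include_hetero=False`` additionally drops HETATM
    cofactor atoms.
    """
    out = []
    for atom in protein.atoms:
        if atom.element not in ("O", "N", "S"):
            continue
        if atom.is_water and not include_waters:
            continue
        if atom.source_record == "HETATM" and not include_hetero and not atom.is_water:
            continue
        out.append(atom)
    return out


def _format_atom_line(atom: Atom, dialect: str) -> str:
    record = atom.source_record if atom.source_record in ("ATOM", "HETATM") else "ATOM"
    name = atom.name
    # PDB alignment rule: 1/2-char names start in column 14 unless 4 chars
    if len(name) < 4 and len(atom.element) == 1:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    line = (f"{record:<6s}{atom.serial:>5d} {name_field}{atom.altloc or ' '}"
            f"{atom.residue_name:<4s}{atom.chain_id or 'A'}{atom.residue_number:>4d}    "
            f"{atom.position[0]:8.3f}{atom.position[1]:8.3f}{atom.position[2]:8.3f}"
            f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}")
    if dialect == "pdbqt":
        ad_type = _ELEMENT_AUTODOCK.get(atom.element, atom.element.upper())
        line += f"    {0.0:6.3f} {ad_type:<2s}"
    else:
        line += f"          {atom.element:>2s}"
    return line


def write_structure(structures: Structure | Sequence[Structure], path: str | Path,
                    dialect: str = "pdb") -> Path:
    """Write one or more models as PDB or (minimal, zero-charge) PDBQT."""
    if isinstance(structures, Structure):
        structures = [structures]
    if dialect not in ("pdb", "pdbqt"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    lines: list[str] = []
    multi = len(structures) > 1
    for model in structures:
        if multi:
            lines.append(f"MODEL {model.model_id:>8d}")
        for atom in model.atoms:
            lines.append(_format_atom_line(atom, dialect))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def measure_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, in degrees."""
    v1 = np.asarray(a, float) - np.asarray(b, float)
    v2 = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
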