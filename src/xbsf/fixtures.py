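"""Synthetic protein-ligand complexes with exactly specified C-X...A geometry.

These are geometric probes, not chemically realistic molecules: the ligand
is a carbon-halogen fragment (plus optional decoy carbons), the "protein"
is a single acceptor atom in a glycine-like residue plus decoy alpha
carbons. Decoys sit at least 6 A from the contact triple so they cannot
perturb any score. Every scoring and mining operation in the package is
testable against these without downloading a single deposited structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .structures import Atom, Structure, write_structure

#: typical C-X covalent bond lengths, Angstrom
DEFAULT_CX_BOND = {"Cl": 1.79, "Br": 1.94, "I": 2.13}

_ACCEPTOR_NAME = {"O": "O", "N": "N", "S": "SG"}
_ACCEPTOR_RESIDUE = {"O": "GLY", "N": "GLY", "S": "CYS"}


@dataclass(frozen=True)
class GeometrySpec:
    """Requested C-X...A geometry for one synthetic complex."""

    halogen: str = "I"
    acceptor: str = "O"
    distance_XA: float = 3.354
    theta: float = 177.8
    cx_bond_length: float | None = None  # default per halogen
    decoy_atoms: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.halogen not in DEFAULT_CX_BOND:
            raise ValueError(f"halogen must be one of {sorted(DEFAULT_CX_BOND)}")
        if self.acceptor not in _ACCEPTOR_NAME:
            raise ValueError(f"acceptor must be one of {sorted(_ACCEPTOR_NAME)}")
        if self.distance_XA <= 0:
            raise ValueError("distance_XA must be positive")
        if not 0.0 <= self.theta <= 180.0:
            raise ValueError("theta must lie in [0, 180] degrees")

    @property
    def bond_length(self) -> float:
        return self.cx_bond_length if self.cx_bond_length is not None \
            else DEFAULT_CX_BOND[self.halogen]


def _decoy_positions(rng: np.random.Generator, n: int,
                     contact: np.ndarray) -> list[np.ndarray]:
    """Random points 8-12 A from the origin, >= 6 A from every contact atom."""
    out: list[np.ndarray] = []
    while len(out) < n:
        v = rng.normal(size=3)
        v *= rng.uniform(8.0, 12.0) / np.linalg.norm(v)
        if np.min(np.linalg.norm(contact - v, axis=1)) >= 6.0:
            out.append(v)
    return out


def make_complex(spec: GeometrySpec) -> tuple[Structure, Structure]:
    """Build a (protein, ligand) pair realising ``spec`` exactly.

    The halogen X sits at the origin with its bonded carbon along -x; the
    acceptor is placed so that |X...A| = ``distance_XA`` and the C-X...A
    angle equals ``theta`` to machine precision (1e-3 after PDB coordinate
    rounding). ``decoy_atoms`` extra carbons are split between ligand and
    protein.
    """
    x_pos = np.zeros(3)
    c_pos = np.array([-spec.bond_length, 0.0, 0.0])
    th = np.radians(spec.theta)
    # unit vector from X making angle theta with the X->C direction (-x)
    a_pos = spec.distance_XA * np.array([-np.cos(th), np.sin(th), 0.0])

    rng = np.random.default_rng(spec.seed)
    contact = np.stack([c_pos, x_pos, a_pos])
    n_lig_decoys = spec.decoy_atoms // 2
    n_prot_decoys = spec.decoy_atoms - n_lig_decoys
    decoys = _decoy_positions(rng, spec.decoy_atoms, contact)

    lig_atoms = [
        Atom(serial=1, name="C1", element="C", residue_name="LIG", chain_id="L",
             residue_number=1, position=c_pos, source_record="HETATM"),
        Atom(serial=2, name=spec.halogen.upper() + "1", element=spec.halogen,
             residue_name="LIG", chain_id="L", residue_number=1,
             position=x_pos, source_record="HETATM"),
    ]
    for i, pos in enumerate(decoys[:n_lig_decoys]):
        lig_atoms.append(Atom(serial=3 + i, name=f"C{2 + i}", element="C",
                              residue_name="LIG", chain_id="L",
                              residue_number=1, position=pos,
                              source_record="HETATM"))

    resname = _ACCEPTOR_RESIDUE[spec.acceptor]
    prot_atoms = [
        Atom(serial=1, name=_ACCEPTOR_NAME[spec.acceptor], element=spec.acceptor,
             residue_name=resname, chain_id="A", residue_number=1,
             position=a_pos, source_record="ATOM"),
    ]
    for i, pos in enumerate(decoys[n_lig_decoys:]):
        prot_atoms.append(Atom(serial=2 + i, name="CA", element="C",
                               residue_name="GLY", chain_id="A",
                               residue_number=2 + i, position=pos,
                               source_record="ATOM"))

    return (Structure(atoms=prot_atoms, source="fixture-protein"),
            Structure(atoms=lig_atoms, source="fixture-ligand"))


def _random_rotation(rng: np.random.Generator, max_angle: float) -> np.ndarray:
    """Rotation matrix about a random axis by an angle in [0, max_angle] rad."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = rng.uniform(0.0, max_angle)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(ang) * k + (1 - np.cos(ang)) * (k @ k)


def make_pose_set(spec: GeometrySpec, n_poses: int, perturbation: float,
                  seed: int = 0) -> list[Structure]:
    """A multi-MODEL pose set: pose 0 exact, the rest rigidly perturbed.

    Each perturbed pose is translated by a random direction with magnitude
    drawn uniformly from [0.75, 1.25] x ``perturbation`` and rotated about
    its centroid by up to 0.1 rad, so the mean heavy-atom RMSD to pose 0
    tracks ``perturbation``. Deterministic under ``seed``.
    """
    if n_poses < 1:
        raise ValueError("n_poses must be >= 1")
    _, ligand = make_complex(spec)
    rng = np.random.default_rng(seed)
    poses = [Structure(atoms=list(ligand.atoms), model_id=1,
                       source=ligand.source)]
    coords = ligand.coordinates()
    centroid = coords.mean(axis=0)
    for i in range(1, n_poses):
        if perturbation == 0.0:
            pose = ligand.transformed()
        else:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            shift = direction * perturbation * rng.uniform(0.75, 1.25)
            rot = _random_rotation(rng, 0.1)
            # rotate about the centroid, then translate
            pose = ligand.transformed(rotation=rot,
                                      translation=centroid - rot @ centroid + shift)
        pose.model_id = i + 1
        poses.append(pose)
    return poses


def write_fixture(spec: GeometrySpec, out_dir: str | Path,
                  n_poses: int = 0, perturbation: float = 1.0) -> dict[str, Path]:
    """Write protein.pdb, ligand.pdb, ligand.pdbqt (and optional poses.pdbqt)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    protein, ligand = make_complex(spec)
    offset = max(a.serial for a in protein.atoms)
    merged = Structure(atoms=(list(protein.atoms)
                              + [replace(a, serial=a.serial + offset)
                                 for a in ligand.atoms]),
                       source="fixture-complex")
    paths = {
        "protein": write_structure(protein, out_dir / "protein.pdb"),
        "ligand": write_structure(ligand, out_dir / "ligand.pdb"),
        "ligand_pdbqt": write_structure(ligand, out_dir / "ligand.pdbqt",
                                        dialect="pdbqt"),
        "complex": write_structure(merged, out_dir / "complex.pdb"),
    }
    if n_poses:
        poses = make_pose_set(spec, n_poses, perturbation, seed=spec.seed)
        paths["poses"] = write_structure(poses, out_dir / "poses.pdbqt",
                                         dialect="pdbqt")
    return paths
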