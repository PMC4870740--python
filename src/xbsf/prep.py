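"""Docking-protocol utilities: grid boxes, pose RMSD, pose-set rescoring.

The grid box follows the benchmark recipe used with Vina-style engines:
per axis, size = (coordinate extent) + 15 A total padding, centered on the
extent midpoint, with an optional randomized shift of each center component
by -2.5, 0 or +2.5 A (drawn independently per axis) so results do not hinge
on perfect box centering.

Pose RMSD is the docking convention: heavy atoms, in place (no
superposition), atoms matched by name order. An optional Hungarian mode
matches atoms within each element instead, for poses whose atom order was
scrambled by a preparation tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from .params import ParameterSet
from .scoring import score_complex
from .structures import Structure


@dataclass(frozen=True)
class GridBox:
    """A Vina-style search box (center and size per axis, Angstrom)."""

    center: tuple[float, float, float]
    size: tuple[float, float, float]
    seed: int | None = None
    shift_applied: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.size):
            raise ValueError("grid-box size components must be positive")


@dataclass(frozen=True)
class PoseComparison:
    """Per-pose rescoring summary."""

    pose_index: int
    rmsd_to_reference: float | None
    xb_energy: float
    n_xb_contacts: int


def compute_grid_box(ligand: Structure, padding_total: float = 15.0,
                     shift_magnitude: float = 2.5,
                     seed: int | None = None) -> GridBox:
    """Grid box around a ligand: extent + total padding, optional seeded shift.

    With a seed, each center component is independently shifted by a value
    drawn from {-shift_magnitude, 0, +shift_magnitude} with equal
    probability; ``seed=None`` applies no shift. Same seed, same box.
    """
    if len(ligand) == 0:
        raise ValueError("cannot compute a grid box for an empty structure")
    coords = ligand.coordinates()
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    size = (hi - lo) + padding_total
    center = 0.5 * (hi + lo)
    shift = np.zeros(3)
    if seed is not None:
        rng = np.random.default_rng(seed)
        shift = rng.choice([-shift_magnitude, 0.0, shift_magnitude], size=3)
        center = center + shift
    return GridBox(center=tuple(float(c) for c in center),
                   size=tuple(float(s) for s in size),
                   seed=seed, shift_applied=tuple(float(s) for s in shift))


def write_vina_config(box: GridBox, path: str | Path, receptor: str = "",
                      ligand: str = "") -> Path:
    """Write the Vina config.txt keys (receptor, ligand, seed, center, size)."""
    lines = []
    if receptor:
        lines.append(f"receptor = {receptor}")
    if ligand:
        lines.append(f"ligand = {ligand}")
    if box.seed is not None:
        lines.append(f"seed = {box.seed}")
    for axis, c in zip("xyz", box.center):
        lines.append(f"center_{axis} = {c:.3f}")
    for axis, s in zip("xyz", box.size):
        lines.append(f"size_{axis} = {s:.3f}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def _check_template(ref_atoms, pose_atoms) -> None:
    if len(ref_atoms) != len(pose_atoms):
        raise ValueError(f"heavy-atom count mismatch: reference has "
                         f"{len(ref_atoms)}, pose has {len(pose_atoms)}")
    for i, (a, b) in enumerate(zip(ref_atoms, pose_atoms)):
        if a.name != b.name:
            raise ValueError(f"atom name mismatch at heavy-atom index {i}: "
                             f"{a.name!r} (reference) vs {b.name!r} (pose)")


def pose_rmsd(reference: Structure, pose: Structure,
              match: str = "name") -> float:
    """In-place heavy-atom RMSD between a pose and the reference conformation.

    No superposition and no symmetry correction. ``match="name"`` (default)
    pairs atoms by name order and errors on any mismatch; ``match="element"``
    solves a minimum-cost assignment within each element for renumbered
    poses.
    """
    ref_atoms = reference.heavy_atoms
    pose_atoms = pose.heavy_atoms
    if match == "name":
        _check_template(ref_atoms, pose_atoms)
        ref = np.array([a.position for a in ref_atoms])
        pos = np.array([a.position for a in pose_atoms])
        return float(np.sqrt(np.mean(np.sum((ref - pos) ** 2, axis=1))))
    if match != "element":
        raise ValueError(f"unknown match mode {match!r}")

    if len(ref_atoms) != len(pose_atoms):
        raise ValueError("heavy-atom count mismatch between reference and pose")
    total = 0.0
    n = 0
    elements = sorted({a.element for a in ref_atoms})
    for el in elements:
        r = np.array([a.position for a in ref_atoms if a.element == el])
        p = np.array([a.position for a in pose_atoms if a.element == el])
        if len(r) != len(p):
            raise ValueError(f"element count mismatch for {el}")
        cost = np.sum((r[:, None, :] - p[None, :, :]) ** 2, axis=2)
        ri, ci = linear_sum_assignment(cost)
        total += float(cost[ri, ci].sum())
        n += len(r)
    return float(np.sqrt(total / n))


def rescore_poses(protein: Structure, poses: list[Structure],
                  reference: Structure | None = None,
                  include_waters: bool = False,
                  params: ParameterSet | None = None,
                  match: str = "name") -> list[PoseComparison]:
    """Halogen-bond energy (and optional RMSD) for each pose of a set."""
    rows: list[PoseComparison] = []
    for index, pose in enumerate(poses):
        result = score_complex(protein, pose, include_waters=include_waters,
                               params=params)
        rmsd = pose_rmsd(reference, pose, match=match) \
            if reference is not None else None
        rows.append(PoseComparison(pose_index=index, rmsd_to_reference=rmsd,
                                   xb_energy=result.total_energy,
                                   n_xb_contacts=len(result)))
    return rows
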