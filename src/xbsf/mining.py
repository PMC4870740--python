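"""Mining C-X...A contact geometries and binning them by angle and distance.

This reproduces the survey methodology behind the polar-flattening delta
table: enumerate every carbon-bonded halogen against every acceptor within
a distance/angle window, then histogram the contacts in three 15-degree
angle bins (135-150, 150-165, 165-180) against fine distance bins. Peaks
that shift to shorter distances as the angle approaches 180 degrees are the
crystallographic signature of sigma-hole flattening.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scoring import geometry_from_pair
from .structures import Structure, find_acceptors, find_halogen_sites

ANGLE_BINS: tuple[tuple[float, float], ...] = ((135.0, 150.0), (150.0, 165.0),
                                               (165.0, 180.0))


@dataclass(frozen=True)
class ContactRecord:
    """One mined C-X...A contact."""

    source_id: str
    halogen_element: str
    acceptor_element: str
    distance_XA: float
    theta: float
    acceptor_context: str  # e.g. "GLY O" for a backbone carbonyl oxygen


@dataclass(frozen=True)
class GeometryHistogram:
    """Contact counts over 15-degree angle bins x distance bins."""

    angle_bins: tuple[tuple[float, float], ...]
    distance_bin_edges: np.ndarray
    counts: np.ndarray  # shape (n_angle_bins, n_distance_bins)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (alo, ahi) in enumerate(self.angle_bins):
            for j in range(len(self.distance_bin_edges) - 1):
                rows.append({
                    "angle_low": alo, "angle_high": ahi,
                    "distance_low": float(self.distance_bin_edges[j]),
                    "distance_high": float(self.distance_bin_edges[j + 1]),
                    "count": int(self.counts[i, j]),
                })
        return pd.DataFrame(rows)


def _split_mixed(structure: Structure) -> tuple[Structure, Structure]:
    """Partition one structure into (ATOM protein, HETATM non-water ligand)."""
    prot = [a for a in structure.atoms if a.source_record == "ATOM" or a.is_water]
    lig = [a for a in structure.atoms
           if a.source_record == "HETATM" and not a.is_water]
    return (Structure(atoms=prot, resolution=structure.resolution,
                      source=structure.source),
            Structure(atoms=lig, resolution=structure.resolution,
                      source=structure.source))


def mine_contacts(
    structures: Iterable[tuple[Structure, Structure] | Structure],
    max_distance: float = 4.5,
    min_theta: float = 120.0,
    resolution_cutoff: float | None = None,
    include_waters: bool = False,
) -> list[ContactRecord]:
    """Enumerate C-X...A contacts within a distance/angle window.

    ``structures`` is an iterable of (protein, ligand) pairs, or of single
    mixed structures which are partitioned into ATOM receptor atoms and
    HETATM ligand atoms. Entries whose known resolution exceeds
    ``resolution_cutoff`` contribute nothing.
    """
    if max_distance <= 0 or min_theta < 0:
        raise ValueError("cutoffs must be positive")
    records: list[ContactRecord] = []
    for entry in structures:
        if isinstance(entry, Structure):
            protein, ligand = _split_mixed(entry)
        else:
            protein, ligand = entry
        if resolution_cutoff is not None:
            res = protein.resolution or ligand.resolution
            if res is not None and res > resolution_cutoff:
                continue
        source_id = protein.source or ligand.source
        acceptors = find_acceptors(protein, include_waters=include_waters)
        for site in find_halogen_sites(ligand):
            for acceptor in acceptors:
                geom = geometry_from_pair(site, acceptor)
                if geom.distance_XA <= max_distance and geom.theta >= min_theta:
                    records.append(ContactRecord(
                        source_id=source_id,
                        halogen_element=site.halogen.element,
                        acceptor_element=acceptor.element,
                        distance_XA=geom.distance_XA,
                        theta=geom.theta,
                        acceptor_context=f"{acceptor.residue_name} {acceptor.name}",
                    ))
    return records


def bin_contacts(records: Sequence[ContactRecord], halogen: str, acceptor: str,
                 distance_bin_width: float = 0.1) -> GeometryHistogram:
    """Histogram matching contacts over angle bins x distance bins.

    Only records of the requested element pair with theta in [135, 180]
    degrees are counted. Distance bins are half-open multiples of
    ``distance_bin_width``; angle bins are half-open with the top bin
    closed at 180 degrees.
    """
    if distance_bin_width <= 0:
        raise ValueError("distance_bin_width must be positive")
    selected = [r for r in records
                if r.halogen_element == halogen and r.acceptor_element == acceptor
                and 135.0 <= r.theta <= 180.0]
    if selected:
        dmin = min(r.distance_XA for r in selected)
        dmax = max(r.distance_XA for r in selected)
        lo = np.floor(dmin / distance_bin_width) * distance_bin_width
        n_bins = max(1, int(np.ceil((dmax - lo) / distance_bin_width + 1e-9)))
        if lo + n_bins * distance_bin_width <= dmax:  # boundary value
            n_bins += 1
    else:
        lo, n_bins = 0.0, 1
    edges = lo + distance_bin_width * np.arange(n_bins + 1)

    counts = np.zeros((len(ANGLE_BINS), n_bins), dtype=int)
    for r in selected:
        for i, (alo, ahi) in enumerate(ANGLE_BINS):
            if alo <= r.theta < ahi or (ahi == 180.0 and r.theta == 180.0):
                j = min(int((r.distance_XA - lo) / distance_bin_width), n_bins - 1)
                counts[i, j] += 1
                break
    return GeometryHistogram(angle_bins=ANGLE_BINS, distance_bin_edges=edges,
                             counts=counts)


_CONTACT_COLUMNS = ["source_id", "halogen", "acceptor", "distance_XA",
                    "theta", "acceptor_context"]


def records_to_frame(records: Sequence[ContactRecord]) -> pd.DataFrame:
    """Tidy DataFrame, one contact per row (headers kept even when empty)."""
    if not records:
        return pd.DataFrame(columns=_CONTACT_COLUMNS)
    return pd.DataFrame([{
        "source_id": r.source_id,
        "halogen": r.halogen_element,
        "acceptor": r.acceptor_element,
        "distance_XA": r.distance_XA,
        "theta": r.theta,
        "acceptor_context": r.acceptor_context,
    } for r in records])


def write_contacts_csv(records: Sequence[ContactRecord], path: str | Path) -> Path:
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False)
    return path


def write_histogram_csv(hist: GeometryHistogram, path: str | Path) -> Path:
    path = Path(path)
    hist.to_frame().to_csv(path, index=False)
    return path


def plot_histogram(hist: GeometryHistogram, path: str | Path) -> Path:
    """Render per-angle-bin distance histograms (one panel per angle range)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(hist.angle_bins), figsize=(12, 3.2),
                             sharey=True)
    centers = 0.5 * (hist.distance_bin_edges[:-1] + hist.distance_bin_edges[1:])
    width = float(np.diff(hist.distance_bin_edges).mean())
    for ax, (alo, ahi), row in zip(np.atleast_1d(axes), hist.angle_bins,
                                   hist.counts):
        ax.bar(centers, row, width=width * 0.9)
        ax.set_title(f"{alo:.0f}\N{DEGREE SIGN}-{ahi:.0f}\N{DEGREE SIGN}")
        ax.set_xlabel("X···A distance (Å)")
    np.atleast_1d(axes)[0].set_ylabel("contacts")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
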