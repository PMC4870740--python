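"""The XBSF scoring core: E = W * Phi * D per C-X...A interaction.

Each candidate interaction pairs a carbon-bonded halogen X (Cl, Br, I) with
an acceptor A (O, N, S). Its energy is the product of

* ``W`` -- the per-halogen energy-well weight (negative, so E <= 0),
* ``Phi`` -- the angle factor: the halogen's effective sigma-hole charge at
  the C-X...A angle Theta, normalized by its value at the ideal linear
  geometry (Theta = 180 deg), and clamped to zero below the electroneutral
  angle Theta_0 where the surface charge turns negative,
* ``D`` -- the distance factor: a linear ramp in the signed van der Waals
  overlap ``d = |X...A| - (r_X + r_A)``, reaching 1 once the overlap exceeds
  the polar-flattening depth delta for the current angle bin and 0 when the
  radii no longer interpenetrate.

Both factors lie in [0, 1], so each interaction contributes between W and 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet, default_parameters
from .structures import (Atom, HalogenSite, Structure, find_acceptors,
                         find_halogen_sites, measure_angle)

__all__ = [
    "XBGeometry", "XBScore", "ComplexScore",
    "angle_factor", "distance_factor", "halogen_weight",
    "geometry_from_pair", "score_interaction", "score_complex",
]


@dataclass(frozen=True)
class XBGeometry:
    """One candidate C-X...A triple."""

    site: HalogenSite
    acceptor: Atom
    distance_XA: float  # X...A internuclear distance, Angstrom
    theta: float        # C-X...A angle, degrees

    def __post_init__(self) -> None:
        if self.distance_XA <= 0:
            raise ValueError("distance_XA must be positive")
        if not 0.0 <= self.theta <= 180.0:
            raise ValueError("theta must lie in [0, 180] degrees")


@dataclass(frozen=True)
class XBScore:
    """Evaluated scoring terms for one interaction."""

    geometry: XBGeometry
    phi: float
    dfac: float
    weight: float

    @property
    def pre_weight(self) -> float:
        """Phi * D, the score before the halogen weight is applied."""
        return self.phi * self.dfac

    @property
    def energy(self) -> float:
        return self.weight * self.phi * self.dfac


@dataclass(frozen=True)
class ComplexScore:
    """All nonzero interactions of one protein-ligand pair, plus the total."""

    interactions: tuple[XBScore, ...]
    total_energy: float

    def __len__(self) -> int:
        return len(self.interactions)


def angle_factor(theta: float, halogen: str,
                 params: ParameterSet | None = None) -> float:
    """Angle factor Phi(Theta) in [0, 1].

    Phi is the effective halogen charge Z at Theta normalized by Z at
    180 deg, for Theta_0 <= Theta <= 180 deg, and exactly zero below the
    electroneutral angle Theta_0. Phi(180 deg) = 1 and Phi(Theta_0) = 0.
    """
    if not 0.0 <= theta <= 180.0:
        raise ValueError(f"theta must lie in [0, 180] degrees, got {theta}")
    params = params or default_parameters()
    h = params.halogen(halogen)
    if theta < h.theta0:
        return 0.0
    z = h.charge_model.z(theta, h.theta0)
    z180 = h.charge_model.z(180.0, h.theta0)
    phi = z / z180
    return float(min(1.0, max(0.0, phi)))


def distance_factor(distance_XA: float, theta: float, halogen: str,
                    acceptor_element: str,
                    params: ParameterSet | None = None) -> float:
    """Distance factor D in [0, 1] with polar-flattening correction.

    The signed overlap is ``d = distance_XA - (r_X + r_A)``. D ramps
    linearly from 0 at d = 0 to 1 at d = -delta, where delta is read from
    the per-halogen table at the 15-deg bin containing ``theta`` (the
    sigma-hole end of the halogen is flattened, so delta shrinks as Theta
    moves away from 180 deg).
    """
    if distance_XA <= 0:
        raise ValueError("distance_XA must be positive")
    if not 0.0 <= theta <= 180.0:
        raise ValueError(f"theta must lie in [0, 180] degrees, got {theta}")
    params = params or default_parameters()
    h = params.halogen(halogen)
    a = params.acceptor(acceptor_element)
    d = distance_XA - (h.vdw_radius + a.vdw_radius)
    delta = h.delta(theta, params.below_table)
    # overlaps below float noise (1e-9 A) count as the d = 0 boundary
    if d >= -1e-9:
        return 0.0
    if delta <= 0.0 or d <= -delta:
        return 1.0 if delta > 0.0 else 0.0
    return float(-d / delta)


def halogen_weight(halogen: str, params: ParameterSet | None = None) -> float:
    """The tabled energy-well weight W for Cl, Br or I (always negative)."""
    params = params or default_parameters()
    return params.halogen(halogen).weight


def geometry_from_pair(site: HalogenSite, acceptor: Atom) -> XBGeometry:
    """Measure the X...A distance and C-X...A angle for one candidate pair."""
    distance = site.halogen.distance_to(acceptor)
    theta = measure_angle(site.bonded_carbon.position, site.halogen.position,
                          acceptor.position)
    return XBGeometry(site=site, acceptor=acceptor,
                      distance_XA=distance, theta=theta)


def score_interaction(geometry: XBGeometry,
                      params: ParameterSet | None = None) -> XBScore:
    """Evaluate Phi, D, W and E = W*Phi*D for one C-X...A geometry."""
    params = params or default_parameters()
    halogen = geometry.site.halogen.element
    phi = angle_factor(geometry.theta, halogen, params)
    dfac = distance_factor(geometry.distance_XA, geometry.theta, halogen,
                           geometry.acceptor.element, params)
    return XBScore(geometry=geometry, phi=phi, dfac=dfac,
                   weight=halogen_weight(halogen, params))


def score_complex(protein: Structure, ligand: Structure,
                  include_waters: bool = False,
                  params: ParameterSet | None = None) -> ComplexScore:
    """Score every (halogen site, acceptor) pair of a protein-ligand complex.

    Returns the interactions with nonzero energy, ordered by halogen serial
    then acceptor serial, and their sum. A non-halogenated ligand yields an
    empty interaction list and a total of exactly zero.
    """
    params = params or default_parameters()
    sites = find_halogen_sites(ligand)
    acceptors = find_acceptors(protein, include_waters=include_waters)

    scores: list[XBScore] = []
    for site in sorted(sites, key=lambda s: s.halogen.serial):
        for acceptor in sorted(acceptors, key=lambda a: a.serial):
            score = score_interaction(geometry_from_pair(site, acceptor), params)
            if score.energy != 0.0:
                scores.append(score)
    total = float(sum(s.energy for s in scores))
    return ComplexScore(interactions=tuple(scores), total_energy=total)
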