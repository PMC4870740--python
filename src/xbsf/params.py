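"""Empirical parameters of the halogen-bond scoring function.

The shipped defaults encode the published XBSF parameterisation: per-halogen
energy-well weights W, electroneutral angles Theta_0 at which the sigma-hole
surface charge crosses zero, van der Waals radii, and the angle-binned
polar-flattening overlap depths delta. Acceptors (O, N, S) carry only a
radius and are equally weighted.

The effective surface charge on the halogen follows
``Z(Theta) = A*cos(nu*alpha) + B`` with ``alpha = 180 - Theta``. The default
charge model uses ``nu = 1``, ``A = 1`` and fixes ``B`` so that
``Z(Theta_0) = 0``, which makes the normalized angle factor a closed-form
cosine ramp; per-halogen (A, B, nu) overrides may be supplied via config for
users holding the originally cited coefficients.

All parameters are serialisable to a human-editable YAML config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass(frozen=True)
class ChargeModel:
    """Coefficients of the effective-charge law Z = A*cos(nu*alpha) + B."""

    A: float = 1.0
    B: float | None = None  # None -> derived so Z(theta0) = 0
    nu: float = 1.0

    def resolved_B(self, theta0: float) -> float:
        if self.B is not None:
            return self.B
        alpha0 = math.radians(180.0 - theta0)
        return -self.A * math.cos(self.nu * alpha0)

    def z(self, theta: float, theta0: float) -> float:
        alpha = math.radians(180.0 - theta)
        return self.A * math.cos(self.nu * alpha) + self.resolved_B(theta0)


@dataclass(frozen=True)
class HalogenParams:
    """Per-halogen constants: weight, electroneutral angle, radius, delta table."""

    element: str
    weight: float               # dimensionless energy weight, negative
    theta0: float               # electroneutral angle, degrees
    vdw_radius: float           # Angstrom
    #: (angle_low, angle_high, delta) rows; the top bin is closed at 180 deg,
    #: lower bins are half-open [low, high).
    delta_table: tuple[tuple[float, float, float], ...]
    charge_model: ChargeModel = field(default_factory=ChargeModel)

    def __post_init__(self) -> None:
        if self.weight >= 0:
            raise ValueError(f"{self.element}: weight must be negative")
        if not 90.0 < self.theta0 < 180.0:
            raise ValueError(f"{self.element}: theta0 must lie in (90, 180) degrees")
        # rows ordered from the 180-deg bin downward; deltas strictly decrease
        deltas = [row[2] for row in self.delta_table]
        if any(later >= earlier for earlier, later in zip(deltas, deltas[1:])):
            raise ValueError(f"{self.element}: delta must decrease away from 180 deg")

    def delta(self, theta: float, below_table: str = "extend") -> float:
        """Polar-flattening overlap depth for the bin containing ``theta``.

        Below the lowest tabulated range the table is either extended with
        its last delta down to 0 deg (default; the angle factor is already
        ~0 there) or zeroed, per ``below_table``.
        """
        for low, high, delta in self.delta_table:
            if (low <= theta < high) or (high == 180.0 and theta == 180.0):
                return delta
        if below_table == "extend":
            return self.delta_table[-1][2]
        if below_table == "zero":
            return 0.0
        raise ValueError(f"unknown below_table mode {below_table!r}")


@dataclass(frozen=True)
class AcceptorParams:
    element: str
    vdw_radius: float


@dataclass(frozen=True)
class ParameterSet:
    """The complete, config-serialisable XBSF parameter set."""

    halogens: dict[str, HalogenParams]
    acceptors: dict[str, AcceptorParams]
    below_table: str = "extend"  # delta lookup below the tabulated ranges

    def halogen(self, element: str) -> HalogenParams:
        try:
            return self.halogens[element]
        except KeyError:
            raise KeyError(f"{element!r} is not an XBSF halogen donor "
                           f"(expected one of {sorted(self.halogens)})") from None

    def acceptor(self, element: str) -> AcceptorParams:
        try:
            return self.acceptors[element]
        except KeyError:
            raise KeyError(f"{element!r} is not an XBSF acceptor "
                           f"(expected one of {sorted(self.acceptors)})") from None

    def to_dict(self) -> dict:
        return {
            "below_table": self.below_table,
            "halogens": {
                el: {
                    "weight": p.weight,
                    "theta0": p.theta0,
                    "vdw_radius": p.vdw_radius,
                    "delta_table": [list(row) for row in p.delta_table],
                    "charge_model": {"A": p.charge_model.A,
                                     "B": p.charge_model.B,
                                     "nu": p.charge_model.nu},
                }
                for el, p in self.halogens.items()
            },
            "acceptors": {el: {"vdw_radius": p.vdw_radius}
                          for el, p in self.acceptors.items()},
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        halogens = {}
        for el, h in data["halogens"].items():
            cm = h.get("charge_model", {})
            halogens[el] = HalogenParams(
                element=el, weight=h["weight"], theta0=h["theta0"],
                vdw_radius=h["vdw_radius"],
                delta_table=tuple(tuple(row) for row in h["delta_table"]),
                charge_model=ChargeModel(A=cm.get("A", 1.0), B=cm.get("B"),
                                         nu=cm.get("nu", 1.0)),
            )
        acceptors = {el: AcceptorParams(element=el, vdw_radius=a["vdw_radius"])
                     for el, a in data["acceptors"].items()}
        return cls(halogens=halogens, acceptors=acceptors,
                   below_table=data.get("below_table", "extend"))

    @classmethod
    def load(cls, path: str | Path) -> "ParameterSet":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_parameters() -> ParameterSet:
    """The published XBSF parameterisation.

    Weights are the halogen energy-well depths (Cl -0.265, Br -0.32, I -0.4);
    electroneutral angles are 146/126/122 deg for Cl/Br/I; radii match the
    Vina atom radii (Cl 1.8, Br 2.02, I 2.2, O 1.7, N 1.8 A). The sulfur
    acceptor radius, not tabulated in the original set, defaults to the
    conventional 2.0 A. Delta rows run from the 165-180 deg bin downward in
    15 deg steps.
    """
    return ParameterSet(
        halogens={
            "Cl": HalogenParams(
                element="Cl", weight=-0.265, theta0=146.0, vdw_radius=1.8,
                delta_table=((165.0, 180.0, 0.25), (150.0, 165.0, 0.15))),
            "Br": HalogenParams(
                element="Br", weight=-0.32, theta0=126.0, vdw_radius=2.02,
                delta_table=((165.0, 180.0, 0.45), (150.0, 165.0, 0.35),
                             (135.0, 150.0, 0.25))),
            "I": HalogenParams(
                element="I", weight=-0.4, theta0=122.0, vdw_radius=2.2,
                delta_table=((165.0, 180.0, 0.55), (150.0, 165.0, 0.45),
                             (135.0, 150.0, 0.35))),
        },
        acceptors={
            "O": AcceptorParams(element="O", vdw_radius=1.7),
            "N": AcceptorParams(element="N", vdw_radius=1.8),
            "S": AcceptorParams(element="S", vdw_radius=2.0),
        },
    )
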