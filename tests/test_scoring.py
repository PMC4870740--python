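"""The scoring core: angle factor, distance factor, weights, E = W*Phi*D."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xbsf import (GeometrySpec, ParameterSet, angle_factor, default_parameters,
                  distance_factor, halogen_weight, make_complex, score_complex,
                  score_interaction)
from xbsf.scoring import XBGeometry, geometry_from_pair
from xbsf.structures import find_acceptors, find_halogen_sites

HALOGENS = ["Cl", "Br", "I"]
THETA0 = {"Cl": 146.0, "Br": 126.0, "I": 122.0}


def closed_form_phi(theta, theta0):
    """Independent closed form: normalized cosine ramp between theta0 and 180."""
    if theta < theta0:
        return 0.0
    a, a0 = math.radians(180 - theta), math.radians(180 - theta0)
    return (math.cos(a) - math.cos(a0)) / (1 - math.cos(a0))


class TestAngleFactor:
    def test_iodine_worked_example(self):
        assert angle_factor(177.8, "I") == pytest.approx(0.998, abs=1e-3)

    @pytest.mark.parametrize("halogen", HALOGENS)
    def test_linear_geometry_is_unity(self, halogen):
        assert angle_factor(180.0, halogen) == 1.0

    @pytest.mark.parametrize("halogen,theta", [("Cl", 146.0), ("I", 120.0),
                                               ("Br", 126.0), ("I", 122.0)])
    def test_electroneutral_and_below(self, halogen, theta):
        assert angle_factor(theta, halogen) == 0.0

    @pytest.mark.parametrize("halogen", HALOGENS)
    def test_matches_independent_closed_form(self, halogen):
        for theta in np.linspace(0, 180, 181):
            assert angle_factor(float(theta), halogen) == pytest.approx(
                closed_form_phi(theta, THETA0[halogen]), abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            angle_factor(190.0, "I")
        with pytest.raises(ValueError):
            angle_factor(-1.0, "Cl")

    def test_unknown_halogen(self):
        with pytest.raises(KeyError):
            angle_factor(170.0, "F")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(theta=st.floats(0.0, 180.0),
           halogen=st.sampled_from(HALOGENS))
    def test_bounded_and_zero_below_theta0(self, theta, halogen):
        phi = angle_factor(theta, halogen)
        assert 0.0 <= phi <= 1.0
        if theta < THETA0[halogen]:
            assert phi == 0.0

    @pytest.mark.parametrize("halogen", HALOGENS)
    def test_monotone_on_scoring_window(self, halogen):
        grid = np.linspace(THETA0[halogen], 180.0, 500)
        vals = [angle_factor(float(t), halogen) for t in grid]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_continuous_at_theta0(self):
        for halogen in HALOGENS:
            just_above = angle_factor(THETA0[halogen] + 1e-7, halogen)
            assert just_above < 1e-6


class TestDistanceFactor:
    def test_iodine_worked_example(self):
        assert distance_factor(3.354, 177.8, "I", "O") == pytest.approx(
            0.992, abs=2e-3)

    def test_zero_overlap_boundary(self):
        # r_I + r_O = 3.9 A exactly
        assert distance_factor(3.90, 175.0, "I", "O") == 0.0

    def test_saturated_overlap(self):
        # d = -0.60 < -delta = -0.55
        assert distance_factor(3.30, 170.0, "I", "O") == 1.0

    @pytest.mark.parametrize("halogen,theta,delta", [
        ("Cl", 170.0, 0.25), ("Cl", 155.0, 0.15),
        ("Br", 170.0, 0.45), ("Br", 155.0, 0.35), ("Br", 140.0, 0.25),
        ("I", 170.0, 0.55), ("I", 155.0, 0.45), ("I", 140.0, 0.35),
    ])
    def test_linear_ramp_slope_encodes_delta(self, halogen, theta, delta):
        p = default_parameters()
        r_sum = p.halogen(halogen).vdw_radius + 1.7
        mid = distance_factor(r_sum - delta / 2, theta, halogen, "O")
        assert mid == pytest.approx(0.5, abs=1e-9)

    def test_bin_boundary_is_half_open(self):
        p = default_parameters()
        # 165 deg belongs to the upper bin for iodine (delta 0.55 not 0.45)
        assert p.halogen("I").delta(165.0) == 0.55
        assert p.halogen("I").delta(164.999) == 0.45
        assert p.halogen("I").delta(180.0) == 0.55

    def test_below_table_extension_modes(self):
        p = default_parameters()
        assert p.halogen("I").delta(125.0) == 0.35  # extend default
        assert p.halogen("I").delta(125.0, below_table="zero") == 0.0
        zero_mode = ParameterSet(halogens=p.halogens, acceptors=p.acceptors,
                                 below_table="zero")
        assert distance_factor(3.5, 125.0, "I", "O", zero_mode) == 0.0

    @pytest.mark.parametrize("halogen", HALOGENS)
    @pytest.mark.parametrize("theta", [140.0, 155.0, 172.0])
    def test_monotone_in_distance_within_bin(self, halogen, theta):
        grid = np.linspace(2.5, 4.5, 400)
        vals = [distance_factor(float(d), theta, halogen, "O") for d in grid]
        assert all(b <= a for a, b in zip(vals, vals[1:]))

    def test_unknown_elements(self):
        with pytest.raises(KeyError):
            distance_factor(3.0, 170.0, "F", "O")
        with pytest.raises(KeyError):
            distance_factor(3.0, 170.0, "Cl", "C")


class TestWeights:
    @pytest.mark.parametrize("halogen,expected", [
        ("Cl", -0.265), ("Br", -0.32), ("I", -0.4)])
    def test_tabled_constants(self, halogen, expected):
        assert halogen_weight(halogen) == expected

    def test_fluorine_is_not_a_donor(self):
        with pytest.raises(KeyError):
            halogen_weight("F")


class TestScoreInteraction:
    def test_worked_example_pre_weight_and_energy(self, worked_example):
        _, protein, ligand = worked_example
        (site,) = find_halogen_sites(ligand)
        acceptor = find_acceptors(protein)[0]
        score = score_interaction(geometry_from_pair(site, acceptor))
        assert score.pre_weight == pytest.approx(0.99014, abs=2e-3)
        assert score.energy == pytest.approx(-0.4 * 0.99014, abs=1e-3)

    def test_below_electroneutral_scores_zero(self):
        _, ligand = make_complex(GeometrySpec(halogen="Cl", theta=140.0,
                                              distance_XA=3.2))
        protein, _ = make_complex(GeometrySpec(halogen="Cl", theta=140.0,
                                               distance_XA=3.2))
        (site,) = find_halogen_sites(ligand)
        acceptor = find_acceptors(protein)[0]
        score = score_interaction(geometry_from_pair(site, acceptor))
        assert score.phi == 0.0
        assert score.energy == 0.0

    def test_invalid_geometry_rejected(self):
        _, ligand = make_complex(GeometrySpec())
        (site,) = find_halogen_sites(ligand)
        protein, _ = make_complex(GeometrySpec())
        acceptor = find_acceptors(protein)[0]
        with pytest.raises(ValueError):
            XBGeometry(site=site, acceptor=acceptor, distance_XA=-1.0,
                       theta=170.0)
        with pytest.raises(ValueError):
            XBGeometry(site=site, acceptor=acceptor, distance_XA=3.0,
                       theta=185.0)


class TestScoreComplex:
    def test_worked_example_single_contact(self, worked_example):
        _, protein, ligand = worked_example
        result = score_complex(protein, ligand)
        assert len(result) == 1
        assert result.total_energy == pytest.approx(result.interactions[0].energy)
        assert result.total_energy == pytest.approx(-0.396, abs=1e-3)

    def test_non_halogenated_ligand_scores_exactly_zero(self, worked_example):
        _, protein, ligand = worked_example
        carbon_only = type(ligand)(atoms=[a for a in ligand.atoms
                                          if a.element == "C"])
        result = score_complex(protein, carbon_only)
        assert result.interactions == ()
        assert result.total_energy == 0.0

    def test_total_equals_exhaustive_pair_sum(self):
        """Brute-force double loop over all (site, acceptor) pairs."""
        from xbsf.structures import Atom, Structure

        rng = np.random.default_rng(42)
        p = default_parameters()
        lig_atoms, prot_atoms = [], []
        serial = 1
        for el in ["Cl", "Br", "I"]:
            c = rng.uniform(-4, 4, 3)
            x = c + np.array([DEFAULTS[el], 0, 0])
            lig_atoms.append(Atom(serial=serial, name="C", element="C",
                                  residue_name="LIG", chain_id="L",
                                  residue_number=1, position=c,
                                  source_record="HETATM"))
            lig_atoms.append(Atom(serial=serial + 1, name=el.upper(),
                                  element=el, residue_name="LIG", chain_id="L",
                                  residue_number=1, position=x,
                                  source_record="HETATM"))
            serial += 2
        for i, el in enumerate(["O", "N", "S", "O"]):
            prot_atoms.append(Atom(serial=i + 1, name=el, element=el,
                                   residue_name="GLY", chain_id="A",
                                   residue_number=i + 1,
                                   position=rng.uniform(-6, 6, 3),
                                   source_record="ATOM"))
        protein = Structure(atoms=prot_atoms)
        ligand = Structure(atoms=lig_atoms)

        result = score_complex(protein, ligand)

        expected = 0.0
        for site in find_halogen_sites(ligand):
            for acc in prot_atoms:
                d = site.halogen.distance_to(acc)
                v1 = site.bonded_carbon.position - site.halogen.position
                v2 = acc.position - site.halogen.position
                theta = math.degrees(math.acos(np.clip(
                    v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2), -1, 1)))
                phi = closed_form_phi(theta, THETA0[site.halogen.element])
                h = p.halogen(site.halogen.element)
                ov = d - (h.vdw_radius + p.acceptor(acc.element).vdw_radius)
                delta = h.delta(theta)
                dfac = 1.0 if ov <= -delta else (0.0 if ov >= 0 else -ov / delta)
                expected += h.weight * phi * dfac
        assert result.total_energy == pytest.approx(expected, abs=1e-12)

    def test_rigid_motion_invariance(self, worked_example):
        from scipy.spatial.transform import Rotation

        _, protein, ligand = worked_example
        before = score_complex(protein, ligand)
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        tra = np.array([12.0, -5.0, 3.0])
        after = score_complex(protein.transformed(rot, tra),
                              ligand.transformed(rot, tra))
        assert len(after) == len(before)
        for a, b in zip(after.interactions, before.interactions):
            assert a.energy == pytest.approx(b.energy, abs=1e-6)
            assert a.phi == pytest.approx(b.phi, abs=1e-6)
            assert a.dfac == pytest.approx(b.dfac, abs=1e-6)

    def test_angle_monotonicity_of_energy(self):
        """At fixed distance, |E| never grows as theta leaves 180 deg
        (within one delta bin; crossing bins steps by the table only)."""
        energies = []
        for theta in np.linspace(180.0, 165.0, 40):
            protein, ligand = make_complex(GeometrySpec(
                halogen="I", distance_XA=3.4, theta=float(theta)))
            energies.append(abs(score_complex(protein, ligand).total_energy))
        assert all(b <= a + 1e-12 for a, b in zip(energies, energies[1:]))


class TestParameterConfig:
    def test_yaml_round_trip_is_identical(self, tmp_path, params):
        path = params.save(tmp_path / "params.yaml")
        reloaded = ParameterSet.load(path)
        assert reloaded == params
        # byte-identical re-serialisation
        assert reloaded.save(tmp_path / "again.yaml").read_bytes() \
            == path.read_bytes()

    def test_custom_charge_model_override(self, params):
        from xbsf.params import ChargeModel, HalogenParams

        iodine = params.halogen("I")
        custom = HalogenParams(
            element="I", weight=iodine.weight, theta0=iodine.theta0,
            vdw_radius=iodine.vdw_radius, delta_table=iodine.delta_table,
            charge_model=ChargeModel(A=2.0, B=None, nu=1.0))
        override = ParameterSet(halogens={**params.halogens, "I": custom},
                                acceptors=params.acceptors)
        # A rescales Z but not the normalized ratio when B tracks theta0
        assert angle_factor(177.8, "I", override) == pytest.approx(
            angle_factor(177.8, "I", params), abs=1e-12)


DEFAULTS = {"Cl": 1.79, "Br": 1.94, "I": 2.13}
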