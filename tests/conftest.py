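import numpy as np
import pytest

from xbsf import GeometrySpec, default_parameters, make_complex


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture()
def worked_example():
    """The iodine backbone-carbonyl contact: I...O 3.354 A, theta 177.8 deg."""
    spec = GeometrySpec(halogen="I", acceptor="O", distance_XA=3.354,
                        theta=177.8, decoy_atoms=4, seed=7)
    protein, ligand = make_complex(spec)
    return spec, protein, ligand


def brute_force_angle(a, b, c):
    """Angle a-b-c at vertex b, degrees, by direct dot product."""
    v1 = np.asarray(a) - np.asarray(b)
    v2 = np.asarray(c) - np.asarray(b)
    cos = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cos, -1, 1))))
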