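import math

import numpy as np
import pytest
from hypothesis import settings

from nanocorona import Nanoparticle, OrientationGrid
from nanocorona import fixtures as fx

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def np80():
    """The benchmark nanoparticle: 80 nm aluminium sphere, -5 mV, 150 mM salt."""
    return Nanoparticle(radius=80.0, surface_label="S", zeta_potential=-5.0,
                        debye_length=0.78, temperature=300.0)


@pytest.fixture(scope="session")
def deep_pmf():
    return fx.synthetic_pmf(-6.0, 0.23, 0.06, "S", "A")


@pytest.fixture(scope="session")
def flat_pmf():
    return fx.synthetic_pmf(0.0, 0.23, 0.06, "S", "B")


@pytest.fixture(scope="session")
def dumbbell():
    """Strong bead A + neutral bead B, 0.6 nm apart."""
    return fx.toy_molecule("dumbbell", bead_types=("A", "B"), separation=0.6,
                           masses=(100.0, 100.0), charges=(0.0, 0.0))


def make_helix_pdb(path, n_res=10, resname="ALA"):
    """Ideal alpha-helix backbone (N, CA, C, O + CB) as a PDB text file.

    Rise 1.5 A per residue, 100 deg twist, CA radius 2.3 A.
    """
    lines = []
    serial = 1
    # backbone atom offsets relative to the CA helix position (A), crude but
    # geometrically sane for an Rg comparison
    offsets = {
        "N": np.array([-1.2, -0.5, -0.9]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([1.2, 0.3, 0.6]),
        "O": np.array([1.4, 1.5, 0.8]),
        "CB": np.array([-0.4, 1.4, 0.3]),
    }
    for i in range(n_res):
        ang = math.radians(100.0 * i)
        ca = np.array([2.3 * math.cos(ang), 2.3 * math.sin(ang), 1.5 * i])
        names = ["N", "CA", "C", "O"] + (["CB"] if resname != "GLY" else [])
        for name in names:
            x, y, z = ca + offsets[name]
            elem = name[0]
            lines.append(
                f"ATOM  {serial:5d} {name:^4s} {resname:>3s} A{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f"{elem:>2s}"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def helix_pdb(tmp_path):
    return make_helix_pdb(tmp_path / "helix.pdb")
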