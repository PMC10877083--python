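"""Energy model: PMF tables, orientations, interaction profiles, averaging."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

import nanocorona as nc
from nanocorona import fixtures as fx
from nanocorona.cg_model import (
    PMFFormatError,
    MissingPMFError,
    default_ssd_grid,
    electrostatic_energy,
)


# ---------------------------------------------------------------------------
# PMF tables


class TestPMFTable:
    def test_csv_read_back(self, tmp_path):
        p = tmp_path / "pmf.csv"
        p.write_text("0.2,-5.0\n0.5,-1.0\n1.5,0.0\n")
        t = nc.load_pmf(p, "S", "ARG")
        assert t.ssd_min == 0.2 and t.ssd_max == 1.5
        assert t.bead_type == "ARG" and t.surface_label == "S"

    def test_header_row_tolerated(self, tmp_path):
        p = tmp_path / "pmf.csv"
        p.write_text("ssd_nm,energy_kBT\n0.2,-5.0\n0.5,-1.0\n1.5,0.0\n")
        t = nc.load_pmf(p, "S", "ARG")
        assert t.ssd_min == 0.2

    def test_linear_interpolation(self, tmp_path):
        p = tmp_path / "pmf.csv"
        p.write_text("0.2,-5.0\n0.5,-1.0\n1.5,0.0\n")
        t = nc.load_pmf(p, "S", "ARG")
        # midpoint of the first segment: half way between -5 and -1
        assert t(0.35) == pytest.approx(-3.0)

    def test_exact_at_nodes(self, deep_pmf):
        assert np.array_equal(deep_pmf(deep_pmf.ssd), deep_pmf.energy)

    def test_extrapolation_contract(self, tmp_path):
        p = tmp_path / "pmf.csv"
        # repulsive wall in the first segment, as in any physical profile
        p.write_text("0.2,10.0\n0.3,-5.0\n0.5,-1.0\n1.5,0.0\n")
        t = nc.load_pmf(p, "S", "X")
        assert t(2.0) == 0.0  # zero tail beyond ssd_max
        # wall below ssd_min: first-segment slope continued, capped at +50
        slope = (-5.0 - 10.0) / 0.1
        assert t(0.15) == pytest.approx(10.0 + slope * (0.15 - 0.2))
        assert t(-1.0) == 50.0

    @pytest.mark.parametrize(
        "content",
        ["0.5,-1.0\n0.2,-5.0\n1.5,0.0\n",  # out of order
         "",  # empty
         "0.2,-5.0\n0.5,-1.0\n1.5,3.0\n"],  # tail not anchored
    )
    def test_bad_tables_rejected(self, tmp_path, content):
        p = tmp_path / "pmf.csv"
        p.write_text(content)
        with pytest.raises(PMFFormatError):
            nc.load_pmf(p, "S", "X")


# ---------------------------------------------------------------------------
# Orientation


def _pairwise(pos):
    return np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)


class TestCanonicalize:
    def test_single_bead_identity(self):
        m = fx.toy_molecule("single-bead")
        with pytest.warns(UserWarning):
            out = nc.canonicalize_orientation(m)
        assert np.allclose(out.positions, 0.0)

    def test_dipole_disambiguation(self):
        # equal masses on the x axis, charges (+1, -1): ends up on z with the
        # positive bead at positive z
        m = nc.CGMolecule(
            name="pair", bead_types=("P", "M"),
            positions=[[0.5, 0.0, 0.0], [-0.5, 0.0, 0.0]],
            masses=[1.0, 1.0], charges=[1.0, -1.0], molecular_weight=2.0,
        )
        out = nc.canonicalize_orientation(m)
        pos = out.positions
        assert np.allclose(np.abs(pos[:, 2]), 0.5, atol=1e-12)
        assert np.allclose(pos[:, :2], 0.0, atol=1e-9)
        assert pos[0, 2] > 0  # the +1 bead

    def test_rigidity(self, dumbbell):
        out = nc.canonicalize_orientation(dumbbell)
        assert np.allclose(_pairwise(out.positions), _pairwise(dumbbell.positions),
                           atol=1e-9)

    @given(st.integers(0, 2**31 - 1))
    def test_rigidity_random_molecules(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        m = nc.CGMolecule(
            name="rand", bead_types=tuple("X" * n),
            positions=rng.normal(size=(n, 3)),
            masses=rng.uniform(50, 200, n), charges=rng.integers(-2, 3, n).astype(float),
            molecular_weight=1000.0,
        )
        out = nc.canonicalize_orientation(m)
        assert np.allclose(_pairwise(out.positions), _pairwise(m.positions), atol=1e-9)


class TestRotate:
    def test_identity_orientation(self, dumbbell):
        pos = nc.rotate_molecule(dumbbell, 0.0, 180.0)
        assert np.allclose(pos, dumbbell.positions, atol=1e-12)

    def test_quarter_turn(self):
        m = nc.CGMolecule(name="x", bead_types=("X",), positions=[[1.0, 0.0, 0.0]],
                          masses=[1.0], charges=[0.0], molecular_weight=1.0)
        pos = nc.rotate_molecule(m, 90.0, 180.0)
        assert np.allclose(pos, [[0.0, -1.0, 0.0]], atol=1e-12)

    @given(st.floats(0, 360, allow_nan=False), st.floats(0, 180, allow_nan=False))
    def test_isometry(self, phi, theta):
        m = fx.toy_molecule("tetrahedron")
        pos = nc.rotate_molecule(m, phi, theta)
        assert np.allclose(_pairwise(pos), _pairwise(m.positions), atol=1e-9)


# ---------------------------------------------------------------------------
# Interaction profile


class TestInteractionProfile:
    def test_single_neutral_bead_equals_pmf(self, np80, deep_pmf):
        m = fx.toy_molecule("single-bead", bead_type="A")
        d = default_ssd_grid([deep_pmf], "S")
        u = nc.interaction_profile(m, np80, 0.0, 180.0, d, [deep_pmf])
        assert np.allclose(u, deep_pmf(d), atol=1e-12)

    def test_additivity_two_coincident_beads(self, deep_pmf):
        # planar limit (huge NP) so the lateral offset adds no curvature term
        np_flat = nc.Nanoparticle(radius=1e6, surface_label="S")
        m2 = nc.CGMolecule(name="two", bead_types=("A", "A"),
                           positions=[[0.2, 0.0, 0.0], [-0.2, 0.0, 0.0]],
                           masses=[1.0, 1.0], charges=[0.0, 0.0],
                           molecular_weight=2.0)
        d = default_ssd_grid([deep_pmf], "S")
        # theta=180 is the identity: the dumbbell lies parallel to the surface
        u = nc.interaction_profile(m2, np_flat, 0.0, 180.0, d, [deep_pmf])
        single = fx.toy_molecule("single-bead", bead_type="A")
        u1 = nc.interaction_profile(single, np_flat, 0.0, 180.0, d, [deep_pmf])
        # the 2e-8 nm residual curvature on the ~2500 kBT/nm wall slope
        # bounds the deviation at ~1e-4 kBT
        assert np.allclose(u, 2 * u1, atol=1e-3)

    def test_additivity_of_bead_subsets(self, np80, deep_pmf, flat_pmf, dumbbell):
        d = default_ssd_grid([deep_pmf, flat_pmf], "S")
        beadA = nc.CGMolecule(name="a", bead_types=("A",),
                              positions=[dumbbell.positions[0]], masses=[100.0],
                              charges=[0.0], molecular_weight=100.0)
        beadB = nc.CGMolecule(name="b", bead_types=("B",),
                              positions=[dumbbell.positions[1]], masses=[100.0],
                              charges=[0.0], molecular_weight=100.0)
        u_ab = nc.interaction_profile(dumbbell, np80, 0.0, 180.0, d,
                                      [deep_pmf, flat_pmf])
        # evaluate each sub-molecule at the height it occupies within the
        # dumbbell: A is the lowest bead (offset 0), B rides 0.6 nm higher
        u_a = nc.interaction_profile(beadA, np80, 0.0, 180.0, d, [deep_pmf])
        u_b = nc.interaction_profile(beadB, np80, 0.0, 180.0, d + 0.6,
                                     [flat_pmf])
        assert np.allclose(u_ab, u_a + u_b, atol=1e-9)

    def test_charged_bead_attracted_to_opposite_zeta(self, np80, deep_pmf):
        d = default_ssd_grid([deep_pmf], "S")
        # +1 charge against a -5 mV surface: electrostatic term negative
        u_el = electrostatic_energy(1.0, d, np80)
        assert np.all(u_el < 0)
        # closed-form screened Coulomb at contact: q e zeta / kBT
        kbt_contact = (1.602176634e-19 * -5e-3) / (1.380649e-23 * 300.0)
        assert u_el[0] == pytest.approx(kbt_contact * math.exp(-d[0] / 0.78)
                                        * 80.0 / (80.0 + d[0]), rel=1e-9)

    def test_missing_pmf_names_bead(self, np80, deep_pmf):
        m = fx.toy_molecule("single-bead", bead_type="ZZZ")
        with pytest.raises(MissingPMFError, match="ZZZ"):
            nc.interaction_profile(m, np80, 0.0, 180.0, np.linspace(0.1, 1.5, 20),
                                   [deep_pmf])


# ---------------------------------------------------------------------------
# Boltzmann averaging over distance


class TestBoltzmannAverage:
    def test_constant_curve(self):
        d = np.linspace(0.2, 1.5, 50)
        e, _ = nc.boltzmann_average_distance(d, np.full_like(d, -2.0))
        assert e == pytest.approx(-2.0)

    def test_square_well_closed_form(self):
        # U = -5 on [0.2, 0.3], 0 on (0.3, 1.5]: the average is
        # -5 w e^5 / (w e^5 + z) with w = 0.1, z = 1.2
        eps = 1e-6
        d = np.concatenate([
            np.linspace(0.2, 0.3, 201),
            np.linspace(0.3 + eps, 1.5, 1201),
        ])
        u = np.where(d <= 0.3, -5.0, 0.0)
        e, r_min = nc.boltzmann_average_distance(d, u)
        w, z = 0.1 * math.exp(5.0), 1.2
        expected = -5.0 * w / (w + z)
        assert expected == pytest.approx(-4.6259, abs=1e-3)
        assert e == pytest.approx(expected, abs=1e-3)
        assert 0.2 <= r_min <= 0.3

    def test_deep_well_limit(self):
        d = np.linspace(0.2, 1.5, 500)
        u = np.where(d < 0.3, -60.0, 0.0)
        e, _ = nc.boltzmann_average_distance(d, u)
        assert e == pytest.approx(-60.0, abs=1e-6)

    def test_matches_quadrature_on_smooth_curve(self, deep_pmf):
        d = np.linspace(deep_pmf.ssd_min, deep_pmf.ssd_max, 4000)
        e, _ = nc.boltzmann_average_distance(d, deep_pmf(d))
        f = lambda x: float(deep_pmf(x))
        num = quad(lambda x: f(x) * math.exp(-f(x)), deep_pmf.ssd_min,
                   deep_pmf.ssd_max, limit=400)[0]
        den = quad(lambda x: math.exp(-f(x)), deep_pmf.ssd_min,
                   deep_pmf.ssd_max, limit=400)[0]
        assert e == pytest.approx(num / den, abs=1e-3)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            nc.boltzmann_average_distance(np.array([0.1, 0.2]), np.array([0.0, 0.0]))


# ---------------------------------------------------------------------------
# Heatmaps


class TestHeatmap:
    def test_single_bead_isotropy(self, np80, deep_pmf):
        m = fx.toy_molecule("single-bead", bead_type="A")
        grid = nc.OrientationGrid.from_spacing(30.0)
        hm = nc.build_heatmap(m, np80, grid, pmfs=[deep_pmf])
        assert np.ptp(hm.e_ads) < 1e-6

    def test_strong_bead_faces_surface(self, np80, deep_pmf, flat_pmf, dumbbell):
        grid = nc.OrientationGrid.from_spacing(15.0)
        hm = nc.build_heatmap(dumbbell, np80, grid, pmfs=[deep_pmf, flat_pmf])
        best = hm.minimum()
        pos = nc.rotate_molecule(dumbbell, best["phi_deg"], best["theta_deg"])
        # bead A (index 0, strongly attractive) is at least as close to the
        # surface as the neutral bead B
        assert pos[0, 2] <= pos[1, 2] + 1e-9

    def test_matches_brute_force(self, np80, deep_pmf, flat_pmf, dumbbell):
        grid = nc.OrientationGrid.from_spacing(45.0)
        d = default_ssd_grid([deep_pmf, flat_pmf], "S")
        hm = nc.build_heatmap(dumbbell, np80, grid, pmfs=[deep_pmf, flat_pmf],
                              ssd_grid=d)
        for i, phi in enumerate(grid.phi):
            for j, theta in enumerate(grid.theta):
                u = nc.interaction_profile(dumbbell, np80, phi, theta, d,
                                           [deep_pmf, flat_pmf])
                e, r = nc.boltzmann_average_distance(d, u)
                assert hm.e_ads[i, j] == e and hm.r_min[i, j] == r

    def test_csv_round_trip(self, np80, deep_pmf, tmp_path):
        m = fx.toy_molecule("single-bead", bead_type="A")
        grid = nc.OrientationGrid.from_spacing(45.0)
        hm = nc.build_heatmap(m, np80, grid, pmfs=[deep_pmf])
        p1, p2 = tmp_path / "h1.csv", tmp_path / "h2.csv"
        hm.to_csv(p1)
        nc.EnergyHeatmap.from_csv(p1).to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestGlobalEnergy:
    def _map(self, thetas, energies):
        grid = nc.OrientationGrid(phi=np.array([0.0]), theta=np.asarray(thetas),
                                  spacing=float(thetas[1] - thetas[0]) if len(thetas) > 1 else 5.0)
        return nc.EnergyHeatmap(grid=grid,
                                e_ads=np.asarray(energies, float).reshape(1, -1),
                                r_min=np.zeros((1, len(thetas))))

    def test_constant_map(self):
        hm = self._map([30.0, 90.0, 150.0], [-10.0, -10.0, -10.0])
        assert nc.global_boltzmann_energy(hm) == pytest.approx(-10.0)

    def test_two_orientation_hand_computation(self):
        hm = self._map([60.0, 120.0], [-1.0, -3.0])
        w = math.sin(math.radians(60.0))  # same weight for both rows
        num = w * (-1.0) * math.exp(1.0) + w * (-3.0) * math.exp(3.0)
        den = w * math.exp(1.0) + w * math.exp(3.0)
        assert nc.global_boltzmann_energy(hm) == pytest.approx(num / den)

    def test_bounded_by_extremes(self, np80, deep_pmf, flat_pmf, dumbbell):
        grid = nc.OrientationGrid.from_spacing(30.0)
        hm = nc.build_heatmap(dumbbell, np80, grid, pmfs=[deep_pmf, flat_pmf])
        g = nc.global_boltzmann_energy(hm)
        assert hm.e_ads.min() <= g <= hm.e_ads.max()
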