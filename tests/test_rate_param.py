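"""Footprints, effective radii, kinetic-theory rates, detailed balance."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import nanocorona as nc
from nanocorona import fixtures as fx
from nanocorona.corona_kmc import acceptance_probability
from nanocorona.rate_param import (
    AVOGADRO,
    WATER_VISCOSITY,
    AdsorbateSpecies,
    parameterize_heatmap,
)


class TestFootprint:
    def test_single_bead_disc_area(self, np80):
        m = fx.toy_molecule("single-bead", bead_type="A")
        beads = [nc.BeadSpec(bead_type="A", radius=0.5)]
        a = nc.footprint_area(m, np80, 0.0, 180.0, beads=beads)
        assert a == pytest.approx(math.pi * 0.5**2, rel=0.05)

    def test_coincident_beads_idempotent(self, np80):
        beads = [nc.BeadSpec(bead_type="A", radius=0.4)]
        m1 = fx.toy_molecule("single-bead", bead_type="A")
        m2 = nc.CGMolecule(name="two", bead_types=("A", "A"),
                           positions=[[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]],
                           masses=[1.0, 1.0], charges=[0.0, 0.0],
                           molecular_weight=2.0)
        a1 = nc.footprint_area(m1, np80, 0.0, 180.0, beads=beads)
        a2 = nc.footprint_area(m2, np80, 0.0, 180.0, beads=beads)
        assert a2 == pytest.approx(a1, rel=1e-9)

    def test_area_grows_with_spread(self, np80):
        beads = [nc.BeadSpec(bead_type="A", radius=0.4)]
        areas = []
        for sep in (0.0, 0.3, 0.6, 1.2, 2.4):
            m = nc.CGMolecule(name="d", bead_types=("A", "A"),
                              positions=[[-sep / 2, 0.0, 0.0], [sep / 2, 0.0, 0.0]],
                              masses=[1.0, 1.0], charges=[0.0, 0.0],
                              molecular_weight=2.0)
            areas.append(nc.footprint_area(m, np80, 0.0, 180.0, beads=beads))
        # hull area is monotone non-decreasing as the beads spread
        assert all(b >= a - 1e-9 for a, b in zip(areas, areas[1:]))

    def test_two_disc_analytic_hull(self, np80):
        # two discs of radius r with centres D apart: hull area
        # pi r^2 + 2 r D (two half-discs + rectangle)
        r, D = 0.37, 0.52
        beads = [nc.BeadSpec(bead_type="A", radius=r)]
        m = nc.CGMolecule(name="d", bead_types=("A", "A"),
                          positions=[[-D / 2, 0.0, 0.0], [D / 2, 0.0, 0.0]],
                          masses=[1.0, 1.0], charges=[0.0, 0.0],
                          molecular_weight=2.0)
        a = nc.footprint_area(m, np80, 0.0, 180.0, beads=beads)
        assert a == pytest.approx(math.pi * r**2 + 2 * r * D, rel=0.02)


class TestEffectiveRadius:
    def test_planar_limit(self):
        assert nc.effective_radius(math.pi * 1.0**2, 1000.0) == pytest.approx(1.0, rel=5e-3)

    def test_sqrt_scaling_in_planar_limit(self):
        r1 = nc.effective_radius(2.0, 5000.0)
        r2 = nc.effective_radius(4.0, 5000.0)
        assert r2 / r1 == pytest.approx(math.sqrt(2.0), rel=1e-3)

    @pytest.mark.parametrize("r_np", [40.0, 80.0, 500.0])
    def test_round_trip_single_bead(self, r_np):
        m = fx.toy_molecule("single-bead", bead_type="A")
        beads = [nc.BeadSpec(bead_type="A", radius=0.6)]
        np_ = nc.Nanoparticle(radius=r_np, surface_label="S")
        a = nc.footprint_area(m, np_, 0.0, 180.0, beads=beads)
        assert nc.effective_radius(a, r_np) == pytest.approx(0.6, rel=0.05)

    def test_oversized_area_rejected(self):
        with pytest.raises(ValueError):
            nc.effective_radius(5 * math.pi * 10.0**2, 1.0)


class TestPairDiffusion:
    def test_worked_value(self):
        d = nc.pair_diffusion(80.0, 2.0, 300.0, 8.9e-4)
        assert d == pytest.approx(1.27e-10, rel=0.01)

    def test_stokes_einstein_limit(self):
        d_inf = nc.pair_diffusion(1e12, 2.0, 300.0)
        se = 1.380649e-23 * 300.0 / (6 * math.pi * WATER_VISCOSITY * 2e-9)
        assert d_inf == pytest.approx(se, rel=1e-6)

    def test_equal_radii_doubles(self):
        d = nc.pair_diffusion(5.0, 5.0, 300.0)
        se = 1.380649e-23 * 300.0 / (6 * math.pi * WATER_VISCOSITY * 5e-9)
        assert d == pytest.approx(2 * se, rel=1e-9)


class TestAdsorptionRate:
    def test_full_coverage_is_smoluchowski(self):
        r_np, r_i = 80.0, 2.0
        d = nc.pair_diffusion(r_np, r_i)
        area = 4 * math.pi * r_np**2
        ka = nc.adsorption_rate_constant(area, r_np, r_i, d)
        smol = 4 * math.pi * d * AVOGADRO * (r_np + r_i) * 1e-9 * 1000.0
        assert ka == pytest.approx(smol, rel=1e-12)

    def test_linear_in_area(self):
        d = nc.pair_diffusion(80.0, 2.0)
        ka1 = nc.adsorption_rate_constant(10.0, 80.0, 2.0, d)
        ka2 = nc.adsorption_rate_constant(5.0, 80.0, 2.0, d)
        assert ka1 == pytest.approx(2 * ka2, rel=1e-12)

    def test_si_recomputation(self):
        # independent dimensional check in pure SI
        r_np, r_i = 80e-9, 2e-9
        area = math.pi * (2e-9) ** 2
        d = nc.pair_diffusion(80.0, 2.0)
        expected_m3 = area / (4 * math.pi * r_np**2) * 4 * math.pi * d * AVOGADRO * (r_np + r_i)
        ka = nc.adsorption_rate_constant(math.pi * 2.0**2, 80.0, 2.0, d)
        assert ka == pytest.approx(expected_m3 * 1000.0, rel=1e-9)


class TestDesorptionRate:
    def test_neutral_affinity(self):
        assert nc.desorption_rate_constant(123.0, 0.0) == pytest.approx(123.0)

    def test_log_ten(self):
        ka = 50.0
        assert nc.desorption_rate_constant(ka, -math.log(10.0)) == pytest.approx(ka / 10.0)

    def test_monotone_in_energy(self):
        kds = [nc.desorption_rate_constant(1.0, e) for e in np.linspace(-20, 5, 30)]
        assert all(a < b for a, b in zip(kds, kds[1:]))

    def test_detailed_balance_ratio(self):
        ka, e = 7.5e5, -12.3
        kd = nc.desorption_rate_constant(ka, e)
        assert ka / kd == pytest.approx(math.exp(-e), rel=1e-12)

    def test_overflow_capped(self):
        with pytest.warns(UserWarning):
            kd = nc.desorption_rate_constant(1.0, 1000.0)
        assert math.isfinite(kd)


class TestOrientationConcentrations:
    def test_single_orientation(self):
        c = nc.orientation_concentrations(5e-4, [90.0])
        assert c[0] == pytest.approx(5e-4)

    def test_symmetric_split(self):
        c = nc.orientation_concentrations(4e-4, [45.0, 135.0])
        assert np.allclose(c, 2e-4)

    def test_half_weight(self):
        c = nc.orientation_concentrations(3e-4, [30.0, 90.0])
        assert c[0] == pytest.approx(1e-4) and c[1] == pytest.approx(2e-4)

    @given(st.lists(st.floats(1.0, 179.0), min_size=1, max_size=40),
           st.floats(0.0, 1.0))
    def test_conservation(self, thetas, c_total):
        c = nc.orientation_concentrations(c_total, thetas)
        assert c.sum() == pytest.approx(c_total, rel=1e-12, abs=1e-300)

    def test_polar_endpoints_not_dropped(self):
        c = nc.orientation_concentrations(1.0, [0.0, 90.0, 180.0], spacing=90.0)
        assert c[0] > 0 and c[2] > 0

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            nc.orientation_concentrations(1.0, [0.0, 180.0])


class TestDisplacementCorrection:
    def test_neutral_halves(self):
        assert nc.displacement_desorption_correction(10.0, 0.0) == pytest.approx(5.0)

    def test_strong_binder_negligible(self):
        ratio = nc.displacement_desorption_correction(1.0, -10.0)
        assert ratio == pytest.approx(0.99995, abs=1e-5)

    @given(st.floats(-50.0, 50.0))
    def test_never_exceeds_uncorrected(self, e):
        assert nc.displacement_desorption_correction(1.0, e) <= 1.0

    @given(st.floats(-50.0, 50.0))
    def test_equilibrium_constant_invariant(self, e):
        # applying p(E) to both ka and kd leaves ka/kd unchanged
        ka, kd = 100.0, 3.0
        p = acceptance_probability(e)
        kd_corr = nc.displacement_desorption_correction(kd, e)
        assert (ka * p) / kd_corr == pytest.approx(ka / kd, rel=1e-12)


class TestSpeciesTable:
    def test_round_trip_bit_exact(self, tmp_path, np80, deep_pmf, flat_pmf, dumbbell):
        grid = nc.OrientationGrid.from_spacing(45.0)
        hm = nc.build_heatmap(dumbbell, np80, grid, pmfs=[deep_pmf, flat_pmf])
        mol = dumbbell.__class__(**{**dumbbell.__dict__})
        species = parameterize_heatmap(hm, dumbbell, np80)
        p1, p2 = tmp_path / "s1.csv", tmp_path / "s2.csv"
        nc.species_to_csv(species, p1)
        nc.species_to_csv(nc.species_from_csv(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_parameterized_rates_finite_positive(self, np80, deep_pmf, flat_pmf, dumbbell):
        grid = nc.OrientationGrid.from_spacing(30.0)
        mol = nc.CGMolecule(**{**dumbbell.__dict__, "bulk_concentration": 1e-4})
        hm = nc.build_heatmap(mol, np80, grid, pmfs=[deep_pmf, flat_pmf])
        species = parameterize_heatmap(hm, mol, np80)
        assert len(species) == grid.theta.size
        for s in species:
            assert 0 < s.ka < math.inf and 0 <= s.kd < math.inf
        # total concentration over orientations conserved exactly
        assert sum(s.concentration for s in species) == pytest.approx(1e-4, rel=1e-12)

    def test_invalid_species_rejected(self):
        with pytest.raises(ValueError):
            AdsorbateSpecies(species_id="x", parent_molecule="x",
                             footprint_area=-1.0, effective_radius=1.0,
                             e_ads=0.0, ka=1.0, kd=1.0, concentration=0.0,
                             molecular_weight=1.0)
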