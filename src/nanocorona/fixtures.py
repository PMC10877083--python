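"""Self-contained inputs for the whole pipeline: synthetic PMFs, toy
molecules, analytic-limit scenarios, and the published milk/aluminium system.

The milk bundle carries the printed characteristics of the six most abundant
cow-milk proteins and lactose (molecular weight, net charge at pH 7, bulk
concentration, radius of gyration), the per-surface minimum-energy
orientations of each protein on the three fcc aluminium facets, and the
reference corona compositions (number densities and mass abundances) for the
worked examples.  Real orientation heatmaps are not publicly tabulated, so
the protein entries are carried as single-orientation species built from the
printed minima — sufficient for ranking and bookkeeping tests, and tagged as
such in the provenance.  All PMFs here are synthetic (softplus-style wall +
Gaussian well) and labelled accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cg_model import (
    BeadSpec,
    CGMolecule,
    Nanoparticle,
    OrientationGrid,
    PMFTable,
    build_heatmap,
    canonicalize_orientation,
    global_boltzmann_energy,
)
from .rate_param import (
    AdsorbateSpecies,
    adsorption_rate_constant,
    desorption_rate_constant,
    effective_radius,
    footprint_area,
    pair_diffusion,
    species_to_csv,
)

__all__ = [
    "FixtureBundle",
    "synthetic_pmf",
    "milk_fixture",
    "single_site_scenario",
    "two_species_scenario",
    "vroman_scenario",
    "acceleration_benchmark",
    "lactose_molecule",
    "toy_molecule",
    "MILK_TABLE",
    "BINDING_TABLE",
    "CORONA_REFERENCE",
    "GLUCOSE_BEAD",
    "LACTOSE_BEAD_SEPARATION_NM",
]

LACTOSE_BEAD_SEPARATION_NM = 0.52  # equilibrium glucose-glucose distance
GLUCOSE_BEAD = BeadSpec(bead_type="GLC", charge=0.0, radius=0.37, mass=171.15,
                        small=True)

# Published characteristics of the milk system (MW Da, net charge e at pH 7,
# residue count, bulk concentration mol/L, radius of gyration nm).
MILK_TABLE = {
    "AS1C": {"mw": 24528.00, "charge": -8.5, "residues": 214, "conc": 4e-4, "rg": 2.005},
    "AS2C": {"mw": 26018.69, "charge": 4.5, "residues": 222, "conc": 1e-4, "rg": 4.081},
    "BC":   {"mw": 25107.33, "charge": -4.5, "residues": 224, "conc": 4e-4, "rg": 2.253},
    "ALAC": {"mw": 16246.61, "charge": -5.0, "residues": 142, "conc": 0.9e-4, "rg": 1.501},
    "BLAC": {"mw": 19883.25, "charge": -6.0, "residues": 178, "conc": 2e-4, "rg": 1.550},
    "BSA":  {"mw": 69293.41, "charge": -4.5, "residues": 607, "conc": 0.1e-4, "rg": 2.769},
    "LAC":  {"mw": 342.3, "charge": 0.0, "residues": None, "conc": 1300e-4, "rg": 0.428},
}

# Minimum-energy orientation per protein and surface:
# (e_ads kBT, phi deg, theta deg, r_min nm), ordered by binding strength.
BINDING_TABLE = {
    "Al100": {
        "AS1C": (-145.65, 175.0, 100.0, 0.19),
        "BC":   (-108.13, 305.0, 40.0, 0.13),
        "AS2C": (-96.12, 315.0, 95.0, 0.05),
        "BSA":  (-91.11, 45.0, 60.0, 0.11),
        "BLAC": (-67.35, 65.0, 90.0, 0.19),
        "ALAC": (-49.12, 125.0, 35.0, 0.20),
    },
    "Al110": {
        "AS1C": (-278.37, 175.0, 100.0, 0.32),
        "AS2C": (-224.01, 345.0, 90.0, 0.10),
        "BSA":  (-173.77, 40.0, 60.0, 0.23),
        "BLAC": (-157.70, 50.0, 95.0, 0.28),
        "ALAC": (-155.17, 70.0, 90.0, 0.29),
        "BC":   (-132.52, 0.0, 70.0, 0.20),
    },
    "Al111": {
        "AS1C": (-242.93, 175.0, 100.0, 0.15),
        "AS2C": (-181.65, 330.0, 90.0, 0.11),
        "BSA":  (-137.46, 45.0, 60.0, 0.13),
        "BC":   (-131.93, 140.0, 110.0, 0.15),
        "ALAC": (-125.76, 75.0, 90.0, 0.17),
        "BLAC": (-113.39, 45.0, 75.0, 0.20),
    },
}

# Reference corona composition on 80 nm NPs (displacement-mode KMC):
# per molecule (number density nm^-2, mass abundance %).
CORONA_REFERENCE = {
    "Al100": {
        "AS1C": (12.26e-3, 57.16), "BC": (4.45e-3, 21.24),
        "BLAC": (2.91e-3, 10.99), "LAC": (96.59e-3, 6.28),
        "ALAC": (1.14e-3, 3.51), "AS2C": (0.11e-3, 0.55),
        "BSA": (0.02e-3, 0.25),
    },
    "Al110": {
        "AS1C": (16.70e-3, 67.82), "BC": (3.38e-3, 14.07),
        "BLAC": (2.97e-3, 9.79), "LAC": (89.13e-3, 5.05),
        "ALAC": (1.13e-3, 3.05), "AS2C": (0.04e-3, 0.16),
        "BSA": (0.00e-3, 0.05),
    },
    "Al111": {
        "AS1C": (27.21e-3, 83.19), "BC": (1.91e-3, 5.84),
        "BLAC": (1.00e-3, 2.43), "LAC": (84.50e-3, 3.62),
        "ALAC": (1.84e-3, 3.60), "AS2C": (3.00e-3, 1.09),
        "BSA": (0.02e-3, 0.21),
    },
}


@dataclass
class FixtureBundle:
    """Everything a pipeline stage needs, generated in memory."""

    pmfs: dict  # (surface, bead_type) -> PMFTable
    molecules: list  # CGMolecule
    np_: Nanoparticle
    species: list = field(default_factory=list)  # AdsorbateSpecies
    provenance: dict = field(default_factory=dict)
    reference: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        surf = self.np_.surface_label
        for mol in self.molecules:
            for bt in set(mol.bead_types):
                if (surf, bt) not in self.pmfs:
                    raise ValueError(
                        f"bundle inconsistent: molecule {mol.name} bead {bt} has "
                        f"no PMF on {surf}"
                    )

    def to_dir(self, path) -> None:
        """Serialise to a directory of standard CSVs plus a YAML manifest."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for (surf, bt), pmf in self.pmfs.items():
            out = path / f"{surf}_{bt}.csv"
            np.savetxt(out, np.column_stack([pmf.ssd, pmf.energy]),
                       delimiter=",", header="ssd_nm,energy_kBT", comments="")
        if self.species:
            species_to_csv(self.species, path / "species.csv")
        manifest = {
            "nanoparticle": {
                "radius_nm": self.np_.radius,
                "surface_label": self.np_.surface_label,
                "zeta_potential_mV": self.np_.zeta_potential,
                "debye_length_nm": self.np_.debye_length,
                "temperature_K": self.np_.temperature,
            },
            "molecules": [m.name for m in self.molecules],
            "provenance": self.provenance,
        }
        (path / "manifest.yaml").write_text(yaml.safe_dump(manifest))


def synthetic_pmf(
    depth: float,
    well_position: float = 0.23,
    width: float = 0.06,
    surface_label: str = "synthetic",
    bead_type: str = "X",
    wall_start: float = 0.05,
    ssd_max: float = 1.5,
    step: float = 0.005,
) -> PMFTable:
    """Smooth wall + Gaussian well + zero tail, mimicking the shape of
    adsorption free-energy profiles on metal slabs (a repulsive wall at small
    separations, a significant minimum near 0.21-0.25 nm, decay by ~1.5 nm).

    The global minimum is exactly ``depth`` (kBT, <= 0) at ``well_position``
    (nm), which is inserted as a sample node.  ``width`` is the Gaussian
    standard deviation (nm).
    """
    if depth > 0:
        raise ValueError("well depth must be <= 0 kBT")
    if width <= 0:
        raise ValueError("well width must be > 0")
    n = int(round((ssd_max - wall_start) / step)) + 1
    ssd = np.linspace(wall_start, ssd_max, n)
    # make sure the well minimum is an exact sample node: snap the nearest
    # grid point onto it (inserting would create a near-duplicate node)
    idx = int(np.argmin(np.abs(ssd - well_position)))
    if abs(ssd[idx] - well_position) <= step / 2:
        ssd[idx] = well_position
    else:
        ssd = np.sort(np.append(ssd, well_position))

    wall = 50.0 * np.exp(-(ssd - wall_start) / 0.02)
    wall_at_pos = 50.0 * math.exp(-(well_position - wall_start) / 0.02)
    gauss = np.exp(-((ssd - well_position) ** 2) / (2.0 * width**2))
    # taper so the tail is exactly 0 at and beyond ssd_max - 0.05
    taper = np.clip((ssd_max - 0.05 - ssd) / 0.05, 0.0, 1.0)
    taper = np.where(ssd <= ssd_max - 0.1, 1.0, taper)
    energy = wall + (depth - wall_at_pos) * gauss * taper
    energy[ssd >= ssd_max - 0.05] = 0.0
    return PMFTable(surface_label=surface_label, bead_type=bead_type,
                    ssd=ssd, energy=energy)


def toy_molecule(spec: str, **kw) -> CGMolecule:
    """Deterministic toy geometries: ``single-bead``, ``dumbbell``, ``rod``,
    ``tetrahedron``.

    Common keywords: ``bead_type(s)``, ``masses``, ``charges``, ``name``,
    ``molecular_weight``, ``bulk_concentration``.  ``dumbbell`` takes
    ``separation`` (nm; glucose beads at 0.52 nm model lactose), ``rod`` takes
    ``n`` and ``spacing``, ``tetrahedron`` takes ``edge``.
    """
    name = kw.pop("name", spec)
    conc = kw.pop("bulk_concentration", 0.0)

    if spec == "single-bead":
        bt = kw.pop("bead_type", "ALA")
        mass = kw.pop("mass", 110.0)
        charge = kw.pop("charge", 0.0)
        return CGMolecule(name=name, bead_types=(bt,), positions=[[0.0, 0.0, 0.0]],
                          masses=[mass], charges=[charge],
                          molecular_weight=kw.pop("molecular_weight", mass),
                          bulk_concentration=conc)
    if spec == "dumbbell":
        sep = kw.pop("separation", LACTOSE_BEAD_SEPARATION_NM)
        bts = tuple(kw.pop("bead_types", ("GLC", "GLC")))
        masses = list(kw.pop("masses", (171.15, 171.15)))
        charges = list(kw.pop("charges", (0.0, 0.0)))
        pos = [[0.0, 0.0, -sep / 2.0], [0.0, 0.0, sep / 2.0]]
        return CGMolecule(name=name, bead_types=bts, positions=pos, masses=masses,
                          charges=charges,
                          molecular_weight=kw.pop("molecular_weight", sum(masses)),
                          bulk_concentration=conc)
    if spec == "rod":
        n = int(kw.pop("n", 5))
        spacing = kw.pop("spacing", 0.4)
        bt = kw.pop("bead_type", "ALA")
        pos = [[0.0, 0.0, k * spacing] for k in range(n)]
        masses = list(kw.pop("masses", [110.0] * n))
        charges = list(kw.pop("charges", [0.0] * n))
        return CGMolecule(name=name, bead_types=(bt,) * n, positions=pos,
                          masses=masses, charges=charges,
                          molecular_weight=kw.pop("molecular_weight", sum(masses)),
                          bulk_concentration=conc)
    if spec == "tetrahedron":
        edge = kw.pop("edge", 0.5)
        bt = kw.pop("bead_type", "ALA")
        v = edge / math.sqrt(2.0)
        pos = np.array(
            [[v, v, v], [v, -v, -v], [-v, v, -v], [-v, -v, v]]
        ) / 2.0
        masses = list(kw.pop("masses", [110.0] * 4))
        charges = list(kw.pop("charges", [0.0] * 4))
        return CGMolecule(name=name, bead_types=(bt,) * 4, positions=pos,
                          masses=masses, charges=charges,
                          molecular_weight=kw.pop("molecular_weight", sum(masses)),
                          bulk_concentration=conc)
    raise ValueError(f"unknown toy molecule spec {spec!r}")


def lactose_molecule(separation: float = LACTOSE_BEAD_SEPARATION_NM,
                     bulk_concentration: float = 1300e-4) -> CGMolecule:
    """Lactose as a pair of neutral glucose beads at the equilibrium
    glucose-glucose distance."""
    return toy_molecule(
        "dumbbell", separation=separation, bead_types=("GLC", "GLC"),
        masses=(171.15, 171.15), charges=(0.0, 0.0), name="LAC",
        molecular_weight=MILK_TABLE["LAC"]["mw"],
        bulk_concentration=bulk_concentration,
    )


def _protein_species(surface: str, np_: Nanoparticle, temperature: float) -> list:
    """Single-orientation species per protein from the printed minimum-energy
    orientations; footprint from the printed radius of gyration (disc of
    radius Rg)."""
    out = []
    for prot, (e_ads, phi, theta, _r_min) in BINDING_TABLE[surface].items():
        row = MILK_TABLE[prot]
        area = math.pi * row["rg"] ** 2
        r_i = effective_radius(area, np_.radius)
        d = pair_diffusion(np_.radius, r_i, temperature)
        ka = adsorption_rate_constant(area, np_.radius, r_i, d)
        kd = desorption_rate_constant(ka, e_ads)
        out.append(
            AdsorbateSpecies(
                species_id=f"{prot}_min",
                parent_molecule=prot,
                footprint_area=area,
                effective_radius=r_i,
                e_ads=e_ads,
                ka=ka,
                kd=kd,
                concentration=row["conc"],
                molecular_weight=row["mw"],
                phi_deg=phi,
                theta_deg=theta,
            )
        )
    return out


def milk_fixture(
    surface: str = "Al100",
    radius_nm: float = 80.0,
    glucose_well_depth: float = -2.0,
    grid_spacing: float = 30.0,
    include_lactose_species: bool = True,
) -> FixtureBundle:
    """The milk/aluminium benchmark system.

    Seven bulk species (six proteins + lactose) with their published
    molecular weights, charges and milk concentrations; an 80 nm aluminium
    NP at zeta potential -5 mV in 150 mM NaCl; the published per-surface
    minimum-energy orientations as single-orientation protein species; and
    the published corona compositions bundled as reference vectors for the
    mass-abundance worked examples.

    The lactose species is parameterised through the full pipeline (synthetic
    glucose PMF -> dumbbell heatmap -> kinetic rates); ``glucose_well_depth``
    sets the synthetic PMF minimum.
    """
    if surface not in BINDING_TABLE:
        raise ValueError(f"unknown surface {surface!r}")
    np_ = Nanoparticle(radius=radius_nm, surface_label=surface,
                       zeta_potential=-5.0, debye_length=0.78, temperature=300.0)
    glc_pmf = synthetic_pmf(glucose_well_depth, well_position=0.23, width=0.06,
                            surface_label=surface, bead_type="GLC")
    lactose = lactose_molecule()
    pmfs = {(surface, "GLC"): glc_pmf}
    species = _protein_species(surface, np_, np_.temperature)

    if include_lactose_species:
        grid = OrientationGrid.from_spacing(grid_spacing)
        heatmap = build_heatmap(lactose, np_, grid, pmfs=[glc_pmf],
                                beads=[GLUCOSE_BEAD])
        e_lac = global_boltzmann_energy(heatmap)
        area = footprint_area(lactose, np_, 0.0, 90.0, beads=[GLUCOSE_BEAD])
        r_i = effective_radius(area, np_.radius)
        d = pair_diffusion(np_.radius, r_i, np_.temperature)
        ka = adsorption_rate_constant(area, np_.radius, r_i, d)
        kd = desorption_rate_constant(ka, e_lac)
        species.append(
            AdsorbateSpecies(
                species_id="LAC_avg",
                parent_molecule="LAC",
                footprint_area=area,
                effective_radius=r_i,
                e_ads=e_lac,
                ka=ka,
                kd=kd,
                concentration=lactose.bulk_concentration,
                molecular_weight=lactose.molecular_weight,
                phi_deg=0.0,
                theta_deg=90.0,
            )
        )

    return FixtureBundle(
        pmfs=pmfs,
        molecules=[lactose],
        np_=np_,
        species=species,
        reference={
            "corona": CORONA_REFERENCE,
            "milk_table": MILK_TABLE,
            "binding_table": BINDING_TABLE,
        },
        provenance={
            "milk_table": "published characteristics (printed table)",
            "binding_table": "published minimum-energy orientations (printed table)",
            "corona_reference": "published corona composition (printed table)",
            "protein_species": "single-orientation species from printed minima; "
                               "footprint = pi*Rg^2 (qualitative ranking only)",
            "glucose_pmf": f"synthetic softplus-wall + Gaussian well, depth "
                           f"{glucose_well_depth} kBT at 0.23 nm",
        },
    )


def _kinetic_species(np_: Nanoparticle, species_id: str, area: float,
                     e_ads: float, ka: float, concentration: float,
                     molecular_weight: float) -> AdsorbateSpecies:
    """Species with detailed-balance desorption from explicit (area, E, ka)."""
    r_i = effective_radius(area, np_.radius)
    return AdsorbateSpecies(
        species_id=species_id, parent_molecule=species_id,
        footprint_area=area, effective_radius=r_i, e_ads=e_ads, ka=ka,
        kd=desorption_rate_constant(ka, e_ads), concentration=concentration,
        molecular_weight=molecular_weight,
    )


def two_species_scenario(radius_nm: float = 20.0) -> FixtureBundle:
    """Dilute competitive pair with unequal affinities and concentrations:
    the equilibrium occupancy ratio is (ka1 C1/kd1)/(ka2 C2/kd2)."""
    np_ = Nanoparticle(radius=radius_nm, surface_label="synthetic")
    a = _kinetic_species(np_, "A", 5.0, -4.0, 1e6, 1e-6, 1000.0)
    b = _kinetic_species(np_, "B", 5.0, -2.0, 1e6, 2e-6, 1000.0)
    return FixtureBundle(pmfs={}, molecules=[], np_=np_, species=[a, b],
                         provenance={"scenario": "synthetic dilute two-species pair"})


def vroman_scenario(radius_nm: float = 20.0) -> FixtureBundle:
    """Weak fast-arriving binder vs strong binder arriving 100x more slowly:
    the displacement channel lets the strong species take over the surface
    faster than waiting for gaps in hard-sphere mode (Vroman-type exchange)."""
    np_ = Nanoparticle(radius=radius_nm, surface_label="synthetic")
    weak = _kinetic_species(np_, "weak", 6.0, -10.0, 1e7, 1e-4, 500.0)
    strong = _kinetic_species(np_, "strong", 6.0, -25.0, 1e7, 1e-6, 5000.0)
    return FixtureBundle(pmfs={}, molecules=[], np_=np_, species=[weak, strong],
                         provenance={"scenario": "synthetic Vroman exchange pair"})


def acceleration_benchmark(radius_nm: float = 20.0) -> FixtureBundle:
    """Lactose-like quasi-equilibrium benchmark: a high-concentration, small,
    weakly binding species whose adsorption/desorption dominates the event
    stream, plus a slower protein-like competitor.  Used to check that
    quasi-equilibrium rate scaling does not shift the steady state."""
    np_ = Nanoparticle(radius=radius_nm, surface_label="synthetic")
    # rates chosen so the slow species still relaxes many times within a
    # ~1e5-event run while the fast species dominates the event stream ~100:1
    lac = _kinetic_species(np_, "lac", 0.8, -1.0, 1e6, 0.13, 342.3)
    prot = _kinetic_species(np_, "prot", 6.0, -4.0, 1e7, 4e-4, 24528.0)
    return FixtureBundle(pmfs={}, molecules=[], np_=np_, species=[lac, prot],
                         provenance={"scenario": "synthetic quasi-equilibrium benchmark"})


def single_site_scenario(ka: float, kd: float, concentration: float,
                         radius_nm: float = 20.0) -> FixtureBundle:
    """One species whose footprint covers the entire NP (one binding site):
    occupancy is a two-state Markov chain with mean ka*C/(ka*C + kd)."""
    if ka <= 0 or kd < 0 or concentration < 0:
        raise ValueError("rates must be positive (kd may be 0)")
    np_ = Nanoparticle(radius=radius_nm, surface_label="synthetic")
    area = np_.surface_area  # N_sites = 1
    e_ads = math.log(kd / ka) if kd > 0 else -745.0
    sp = AdsorbateSpecies(
        species_id="probe",
        parent_molecule="probe",
        footprint_area=area,
        effective_radius=radius_nm,
        e_ads=e_ads,
        ka=ka,
        kd=kd,
        concentration=concentration,
        molecular_weight=1000.0,
    )
    return FixtureBundle(
        pmfs={},
        molecules=[],
        np_=np_,
        species=[sp],
        provenance={"scenario": "synthetic single-site analytic harness"},
    )
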