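"""Kinetic-theory rate parameterization of adsorbate species.

Each (molecule, orientation) pair becomes one adsorbate species with a
footprint area A_i on the nanoparticle, an effective radius R_i, a per-site
adsorption rate constant from the collision rate of two diffusing spheres,
and a desorption rate constant fixed by detailed balance against the
orientation's adsorption energy.  Orientation-resolved bulk concentrations
are sin(theta)-weighted so the total concentration is exactly conserved.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .cg_model import (
    KB,
    T_DEFAULT,
    CGMolecule,
    EnergyHeatmap,
    Nanoparticle,
    rotate_molecule,
    _resolve_beads,
)

__all__ = [
    "AdsorbateSpecies",
    "footprint_area",
    "effective_radius",
    "pair_diffusion",
    "adsorption_rate_constant",
    "desorption_rate_constant",
    "orientation_concentrations",
    "displacement_desorption_correction",
    "parameterize_heatmap",
    "species_to_csv",
    "species_from_csv",
    "WATER_VISCOSITY",
    "AVOGADRO",
    "C_REF",
]

AVOGADRO = 6.02214076e23  # 1/mol
WATER_VISCOSITY = 8.9e-4  # Pa*s
C_REF = 1.0  # mol/L reference concentration for detailed balance
_DISC_N = 64  # polygon points per projected bead disc


@dataclass(frozen=True)
class AdsorbateSpecies:
    """One (molecule, orientation) adsorbate with its kinetic parameters.

    Units: A_i nm^2, R_i nm, e_ads kBT, ka L mol^-1 s^-1, kd s^-1,
    concentration mol/L, molecular weight Da.
    """

    species_id: str
    parent_molecule: str
    footprint_area: float  # nm^2
    effective_radius: float  # nm
    e_ads: float  # kBT
    ka: float  # L/mol/s
    kd: float  # 1/s
    concentration: float  # mol/L
    molecular_weight: float  # Da
    phi_deg: float = 0.0
    theta_deg: float = 90.0

    def __post_init__(self) -> None:
        if self.footprint_area <= 0:
            raise ValueError(f"{self.species_id}: footprint_area must be > 0")
        if self.effective_radius <= 0:
            raise ValueError(f"{self.species_id}: effective_radius must be > 0")
        if self.ka <= 0:
            raise ValueError(f"{self.species_id}: ka must be > 0")
        if self.kd < 0:
            raise ValueError(f"{self.species_id}: kd must be >= 0")
        if self.concentration < 0:
            raise ValueError(f"{self.species_id}: concentration must be >= 0")

    def n_sites(self, np_: Nanoparticle) -> float:
        """Number of binding sites 4 pi R_NP^2 / A_i (kept as a real number)."""
        return np_.surface_area / self.footprint_area


# ---------------------------------------------------------------------------
# Geometry


def footprint_area(
    molecule: CGMolecule,
    np_: Nanoparticle,
    phi: float,
    theta: float,
    beads=None,
    standoff: float = 0.2,
) -> float:
    """Footprint area (nm^2) of the NP surface occluded by the molecule.

    The molecule is rotated to (phi, theta) and placed above the NP north pole
    with its lowest bead ``standoff`` nm from the surface.  Each bead disc (of
    its bead radius) is projected radially onto the sphere, the projections are
    mapped gnomonically to the tangent plane at the north pole — where great
    circles become straight lines, so the planar convex hull is the spherical
    hull — and the hull area is returned: the exact spherical-polygon area if
    the footprint subtends more than 10 degrees of arc, the planar hull area
    otherwise (they agree in that regime).
    """
    pos = rotate_molecule(molecule, phi, theta)
    specs = _resolve_beads(molecule, beads)
    z = pos[:, 2]
    offset = np_.radius + standoff - z.min()
    centers = pos + np.array([0.0, 0.0, offset])

    ang = np.linspace(0.0, 2.0 * math.pi, _DISC_N, endpoint=False)
    circle = np.column_stack([np.cos(ang), np.sin(ang)])

    pts = []
    for k, spec in enumerate(specs):
        c = centers[k]
        # local orthonormal frame perpendicular to the radial direction
        u = c / np.linalg.norm(c)
        a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(u, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        disc = c[None, :] + spec.radius * (
            circle[:, :1] * e1[None, :] + circle[:, 1:] * e2[None, :]
        )
        pts.append(disc)
    pts = np.vstack(pts)

    # gnomonic projection onto the tangent plane at the north pole
    zp = pts[:, 2]
    if np.any(zp <= 0):
        raise ValueError("footprint subtends a hemisphere or more; not supported")
    gx = np_.radius * pts[:, 0] / zp
    gy = np_.radius * pts[:, 1] / zp
    plane = np.column_stack([gx, gy])

    if np.allclose(plane, plane[0], atol=1e-12):
        # all projected points coincide: zero-extent footprint
        return 0.0
    try:
        hull = ConvexHull(plane)
    except Exception:
        # collinear degenerate hull: treat as a thin sliver of zero area
        return 0.0
    verts = plane[hull.vertices]

    # maximum angular radius of the footprint about the pole
    max_arc = math.degrees(
        float(np.max(np.arctan2(np.hypot(plane[:, 0], plane[:, 1]), np_.radius)))
    )
    if max_arc <= 10.0:
        return float(hull.volume)  # 2-D hull "volume" is the polygon area
    return _spherical_polygon_area(verts, np_.radius)


def _spherical_polygon_area(plane_verts: np.ndarray, radius: float) -> float:
    """Area (nm^2) of the spherical polygon whose gnomonic image is the given
    convex planar polygon (vertices in hull order), via the spherical excess."""
    v = np.column_stack([plane_verts[:, 0], plane_verts[:, 1],
                         np.full(len(plane_verts), radius)])
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    n = len(v)
    total = 0.0
    for i in range(n):
        a, b, c = v[(i - 1) % n], v[i], v[(i + 1) % n]
        # interior angle at b between great-circle arcs b->a and b->c
        t1 = a - b * (a @ b)
        t2 = c - b * (c @ b)
        t1 /= np.linalg.norm(t1)
        t2 /= np.linalg.norm(t2)
        total += math.acos(float(np.clip(t1 @ t2, -1.0, 1.0)))
    excess = total - (n - 2) * math.pi
    return excess * radius**2


def effective_radius(area: float, r_np: float) -> float:
    """Radius R_i (nm) of the sphere whose radial projection onto the NP
    produces a cap of the given area (nm^2).

    A sphere of radius R_i resting on the NP subtends the tangent-cone
    half-angle alpha with sin(alpha) = R_i/(R_NP + R_i); the shadow cap has
    area 2 pi R_NP^2 (1 - cos alpha).  Inverting gives R_i.  Reduces to
    sqrt(A/pi) in the planar limit A << R_NP^2.  Caps of a hemisphere or more
    cannot be produced by this construction and raise ``ValueError`` (as does
    an area exceeding the NP surface).
    """
    if area <= 0:
        raise ValueError("area must be > 0")
    sphere = 4.0 * math.pi * r_np**2
    if area > sphere:
        raise ValueError(f"footprint area {area} nm^2 exceeds NP surface {sphere} nm^2")
    cos_a = 1.0 - area / (2.0 * math.pi * r_np**2)
    if cos_a <= 0.0:
        raise ValueError("footprint cap of a hemisphere or more has no finite "
                         "projecting sphere")
    sin_a = math.sqrt(1.0 - cos_a**2)
    return r_np * sin_a / (1.0 - sin_a)


# ---------------------------------------------------------------------------
# Rates


def pair_diffusion(r_np_nm: float, r_a_nm: float, temperature: float = T_DEFAULT,
                   viscosity: float = WATER_VISCOSITY) -> float:
    """Pair diffusion coefficient (m^2/s) of the NP and the adsorbate,
    D = kBT/(6 pi eta) (1/R_NP + 1/R_A), radii in nm."""
    if r_np_nm <= 0 or r_a_nm <= 0:
        raise ValueError("radii must be > 0")
    return (KB * temperature / (6.0 * math.pi * viscosity)) * (
        1.0 / (r_np_nm * 1e-9) + 1.0 / (r_a_nm * 1e-9)
    )


def adsorption_rate_constant(area_nm2: float, r_np_nm: float, r_i_nm: float,
                             diffusion: float) -> float:
    """Per-site adsorption rate constant (L mol^-1 s^-1) from the kinetic
    theory of collisions between two diffusing spheres, normalised by the
    number of binding sites:

        ka = [A_i / (4 pi R_NP^2)] * 4 pi D N_A (R_NP + R_i),

    evaluated in SI and multiplied by 1000 to convert m^3/mol/s to L/mol/s.
    """
    site_fraction = area_nm2 / (4.0 * math.pi * r_np_nm**2)
    smoluchowski = 4.0 * math.pi * diffusion * AVOGADRO * (r_np_nm + r_i_nm) * 1e-9
    return site_fraction * smoluchowski * 1000.0


def desorption_rate_constant(ka: float, e_ads: float) -> float:
    """Desorption rate constant (s^-1) from detailed balance,
    kd = ka * c0 * exp(E_ads) with c0 = 1 mol/L and E_ads in kBT, so
    ka/kd = exp(-E_ads) L/mol.  Exponents above 700 are capped with a warning
    to avoid overflow."""
    if ka <= 0:
        raise ValueError("ka must be > 0")
    e = e_ads
    if e > 700.0:
        warnings.warn(f"e_ads={e_ads} capped at 700 kBT in desorption rate",
                      stacklevel=2)
        e = 700.0
    return ka * C_REF * math.exp(e)


def orientation_concentrations(c_total: float, thetas_deg, spacing: float | None = None):
    """Split a bulk concentration over orientations with sin(theta) weights,
    C_ij = C sin(theta_j) / sum_k sin(theta_k); the sum over orientations
    reproduces C exactly.  Polar endpoints (0, 180 deg) get their half-cell
    midpoint weight when a grid ``spacing`` is supplied."""
    if c_total < 0:
        raise ValueError("C_total must be >= 0")
    t = np.asarray(thetas_deg, dtype=float)
    if t.size == 0:
        raise ValueError("thetas must be non-empty")
    if spacing is not None:
        t = np.clip(t, 0.5 * spacing, 180.0 - 0.5 * spacing)
    w = np.sin(np.radians(t))
    w[w < 1e-12] = 0.0  # sin(0)/sin(180) round to exactly zero weight
    total = w.sum()
    if total <= 0:
        raise ValueError("all orientation weights are zero")
    return c_total * w / total


def displacement_desorption_correction(kd: float, e_ads: float) -> float:
    """Desorption rate corrected for the displacement-mode acceptance factor.

    In displacement mode an incoming adsorbate landing on bare surface is
    accepted with the logistic probability p(E_ads), which multiplies the
    effective adsorption rate; the desorption rate is multiplied by the same
    factor so the equilibrium constant is unchanged.  Only significant for
    weak binders (E_ads >~ -3 kBT).
    """
    from .corona_kmc import acceptance_probability

    return kd * acceptance_probability(e_ads)


# ---------------------------------------------------------------------------
# Heatmap -> species table


def parameterize_heatmap(
    heatmap: EnergyHeatmap,
    molecule: CGMolecule,
    np_: Nanoparticle,
    beads=None,
    temperature: float | None = None,
    viscosity: float = WATER_VISCOSITY,
    theta_only: bool = True,
) -> list:
    """Convert an orientation heatmap into a list of adsorbate species.

    With ``theta_only`` (the default), orientations are grouped by theta: for
    each theta row the phi-Boltzmann-averaged energy is used and the molecule's
    bulk concentration is split over theta with sin weights.  With
    ``theta_only=False`` every (phi, theta) cell becomes its own species and
    the sin(theta) split is further divided evenly over phi.
    """
    if temperature is None:
        temperature = np_.temperature
    grid = heatmap.grid
    species: list[AdsorbateSpecies] = []
    if theta_only:
        c_by_theta = orientation_concentrations(
            molecule.bulk_concentration, grid.theta, spacing=grid.spacing
        )
        for j, theta in enumerate(grid.theta):
            col = heatmap.e_ads[:, j]
            shift = col.min()
            w = np.exp(-(col - shift))
            e_eff = float((col * w).sum() / w.sum())
            phi_star = float(grid.phi[int(np.argmin(col))])
            area = footprint_area(molecule, np_, phi_star, theta, beads)
            area = max(area, 1e-6)
            r_i = effective_radius(area, np_.radius)
            d = pair_diffusion(np_.radius, r_i, temperature, viscosity)
            ka = adsorption_rate_constant(area, np_.radius, r_i, d)
            kd = desorption_rate_constant(ka, e_eff)
            species.append(
                AdsorbateSpecies(
                    species_id=f"{molecule.name}_t{theta:g}",
                    parent_molecule=molecule.name,
                    footprint_area=area,
                    effective_radius=r_i,
                    e_ads=e_eff,
                    ka=ka,
                    kd=kd,
                    concentration=float(c_by_theta[j]),
                    molecular_weight=molecule.molecular_weight,
                    phi_deg=phi_star,
                    theta_deg=float(theta),
                )
            )
    else:
        c_by_theta = orientation_concentrations(
            molecule.bulk_concentration, grid.theta, spacing=grid.spacing
        )
        n_phi = grid.phi.size
        for i, phi in enumerate(grid.phi):
            for j, theta in enumerate(grid.theta):
                e = float(heatmap.e_ads[i, j])
                area = max(footprint_area(molecule, np_, phi, theta, beads), 1e-6)
                r_i = effective_radius(area, np_.radius)
                d = pair_diffusion(np_.radius, r_i, temperature, viscosity)
                ka = adsorption_rate_constant(area, np_.radius, r_i, d)
                kd = desorption_rate_constant(ka, e)
                species.append(
                    AdsorbateSpecies(
                        species_id=f"{molecule.name}_p{phi:g}_t{theta:g}",
                        parent_molecule=molecule.name,
                        footprint_area=area,
                        effective_radius=r_i,
                        e_ads=e,
                        ka=ka,
                        kd=kd,
                        concentration=float(c_by_theta[j]) / n_phi,
                        molecular_weight=molecule.molecular_weight,
                        phi_deg=float(phi),
                        theta_deg=float(theta),
                    )
                )
    return species


# ---------------------------------------------------------------------------
# Species-table CSV interface

_CSV_COLUMNS = [
    "species_id", "parent", "phi_deg", "theta_deg", "e_ads_kBT", "area_nm2",
    "radius_nm", "ka_Lmols", "kd_s", "conc_molL", "mw_Da",
]


def species_to_csv(species, path) -> None:
    """Write the species hand-off table; floats at full precision so a
    write -> read -> write round trip is bit-exact."""
    rows = [
        {
            "species_id": s.species_id,
            "parent": s.parent_molecule,
            "phi_deg": s.phi_deg,
            "theta_deg": s.theta_deg,
            "e_ads_kBT": s.e_ads,
            "area_nm2": s.footprint_area,
            "radius_nm": s.effective_radius,
            "ka_Lmols": s.ka,
            "kd_s": s.kd,
            "conc_molL": s.concentration,
            "mw_Da": s.molecular_weight,
        }
        for s in species
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False,
                                                    float_format="%.17g")


def species_from_csv(path) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"species CSV missing columns: {missing}")
    return [
        AdsorbateSpecies(
            species_id=str(r.species_id),
            parent_molecule=str(r.parent),
            footprint_area=float(r.area_nm2),
            effective_radius=float(r.radius_nm),
            e_ads=float(r.e_ads_kBT),
            ka=float(r.ka_Lmols),
            kd=float(r.kd_s),
            concentration=float(r.conc_molL),
            molecular_weight=float(r.mw_Da),
            phi_deg=float(r.phi_deg),
            theta_deg=float(r.theta_deg),
        )
        for r in df.itertuples()
    ]
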