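"""Rigid-body coarse-grained energy model for biomolecule–nanoparticle adsorption.

A biomolecule is a rigid set of typed, charged beads (one bead per residue for
proteins; explicit bead lists for small molecules).  Its interaction with a
spherical nanoparticle is pairwise additive over beads: a tabulated short-range
potential of mean force (PMF) per bead type and surface, a screened-Coulomb
electrostatic term between the bead charge and the NP at its zeta potential,
and an optional long-range Hamaker core term.  Orientations are parameterised
by two angles (phi, theta) relative to a canonical principal-axis frame, and
the orientation-resolved adsorption energy is obtained by Boltzmann averaging
the total potential over the approach distance.

Units: lengths nm, energies kBT (T = 300 K unless stated), charges e,
zeta potential mV, Hamaker constant J.  Conversions happen only here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "PMFTable",
    "BeadSpec",
    "CGMolecule",
    "Nanoparticle",
    "OrientationGrid",
    "EnergyHeatmap",
    "load_pmf",
    "canonicalize_orientation",
    "rotate_molecule",
    "interaction_profile",
    "boltzmann_average_distance",
    "build_heatmap",
    "global_boltzmann_energy",
    "electrostatic_energy",
    "hamaker_energy",
]

KB = 1.380649e-23  # J/K
E_CHARGE = 1.602176634e-19  # C
T_DEFAULT = 300.0  # K
WALL_CAP_KBT = 50.0  # hard-wall cap for PMF extrapolation below ssd_min


class PMFFormatError(ValueError):
    """Raised when a PMF table violates its format contract."""


class MissingPMFError(KeyError):
    """Raised when a bead type has no PMF for the requested surface."""


@dataclass(frozen=True)
class PMFTable:
    """Tabulated short-range free energy vs surface separation for one bead type.

    ``ssd`` is the surface separation distance in nm between the bead and the
    material surface; ``energy`` is the free energy of adsorption in kBT.
    Below ``ssd_min`` the first segment's slope is continued linearly and
    capped at +50 kBT (hard wall); above ``ssd_max`` the energy is exactly 0.
    """

    surface_label: str
    bead_type: str
    ssd: np.ndarray  # nm, strictly increasing
    energy: np.ndarray  # kBT

    def __post_init__(self) -> None:
        ssd = np.asarray(self.ssd, dtype=float)
        energy = np.asarray(self.energy, dtype=float)
        object.__setattr__(self, "ssd", ssd)
        object.__setattr__(self, "energy", energy)
        if ssd.ndim != 1 or ssd.size < 3:
            raise PMFFormatError(
                f"PMF {self.surface_label}/{self.bead_type}: need >=3 samples, "
                f"got {ssd.size}"
            )
        if energy.shape != ssd.shape:
            raise PMFFormatError("ssd and energy lengths differ")
        if not np.all(np.isfinite(ssd)) or not np.all(np.isfinite(energy)):
            raise PMFFormatError("non-finite values in PMF table")
        if not np.all(np.diff(ssd) > 0):
            raise PMFFormatError(
                f"PMF {self.surface_label}/{self.bead_type}: ssd not strictly increasing"
            )
        if abs(energy[-1]) > 0.5:
            raise PMFFormatError(
                f"PMF {self.surface_label}/{self.bead_type}: tail energy "
                f"{energy[-1]:.3f} kBT not anchored near 0 at ssd_max"
            )

    @property
    def ssd_min(self) -> float:
        return float(self.ssd[0])

    @property
    def ssd_max(self) -> float:
        return float(self.ssd[-1])

    def __call__(self, d) -> np.ndarray:
        """Evaluate the PMF at separation(s) ``d`` (nm), with the documented
        extrapolation: linear wall (capped at +50 kBT) below ``ssd_min``,
        exactly 0 above ``ssd_max``.  Exact at the tabulated nodes."""
        d = np.asarray(d, dtype=float)
        out = np.interp(d, self.ssd, self.energy)
        below = d < self.ssd[0]
        if np.any(below):
            slope = (self.energy[1] - self.energy[0]) / (self.ssd[1] - self.ssd[0])
            wall = self.energy[0] + slope * (d - self.ssd[0])
            out = np.where(below, np.minimum(wall, WALL_CAP_KBT), out)
        out = np.where(d > self.ssd[-1], 0.0, out)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class BeadSpec:
    """Physical parameters of one bead type."""

    bead_type: str
    charge: float = 0.0  # e
    radius: float = 0.3  # nm
    mass: float = 110.0  # Da
    small: bool = False  # small beads skip the Hamaker core term

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"bead {self.bead_type}: radius must be > 0")
        if self.mass < 0:
            raise ValueError(f"bead {self.bead_type}: mass must be >= 0")


@dataclass(frozen=True)
class CGMolecule:
    """Rigid coarse-grained molecule: typed beads at fixed relative positions.

    ``positions`` are nm; per-bead masses and charges default to the values in
    the bead table used downstream but may be carried explicitly (``masses``,
    ``charges``) so canonicalisation does not need a bead table.
    """

    name: str
    bead_types: tuple
    positions: np.ndarray  # (n, 3) nm
    masses: np.ndarray  # Da, per bead
    charges: np.ndarray  # e, per bead
    molecular_weight: float  # Da
    bulk_concentration: float = 0.0  # mol/L

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "bead_types", tuple(self.bead_types))
        object.__setattr__(self, "masses", np.asarray(self.masses, dtype=float))
        object.__setattr__(self, "charges", np.asarray(self.charges, dtype=float))
        n = pos.shape[0]
        if n < 1 or pos.shape[1] != 3:
            raise ValueError("positions must be (n, 3) with n >= 1")
        if len(self.bead_types) != n or self.masses.size != n or self.charges.size != n:
            raise ValueError("bead_types/masses/charges must match positions")
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be > 0")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    @property
    def radius_of_gyration(self) -> float:
        """Mass-weighted radius of gyration (nm) about the centre of mass."""
        m = self.masses
        if m.sum() <= 0:
            m = np.ones_like(m)
        com = np.average(self.positions, axis=0, weights=m)
        r2 = ((self.positions - com) ** 2).sum(axis=1)
        return float(np.sqrt(np.average(r2, weights=m)))

    def with_positions(self, positions: np.ndarray) -> "CGMolecule":
        return replace(self, positions=np.asarray(positions, dtype=float))


@dataclass(frozen=True)
class Nanoparticle:
    """Spherical nanoparticle with a uniformly charged surface.

    ``zeta_potential`` (mV) sets the surface potential for the screened-Coulomb
    term; ``debye_length`` (nm) encodes the medium ionic strength (0.78 nm for
    150 mM NaCl near room temperature).  ``hamaker_constant`` (J) of 0 disables
    the long-range core van der Waals term.
    """

    radius: float  # nm
    surface_label: str = "Al100"
    zeta_potential: float = -5.0  # mV
    debye_length: float = 0.78  # nm
    temperature: float = T_DEFAULT  # K
    hamaker_constant: float = 0.0  # J

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("NP radius must be > 0")
        if self.debye_length <= 0:
            raise ValueError("debye_length must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def surface_area(self) -> float:
        """nm^2"""
        return 4.0 * math.pi * self.radius**2


@dataclass(frozen=True)
class OrientationGrid:
    """Uniform grid over the two rigid-body orientation angles.

    phi in [0, 360) deg (azimuthal rotation about the canonical z axis),
    theta in [0, 180] deg (tilt of the canonical z axis from the outward
    surface normal).
    """

    phi: np.ndarray  # degrees
    theta: np.ndarray  # degrees
    spacing: float  # degrees

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        theta = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "theta", theta)
        if np.any(phi < 0) or np.any(phi >= 360):
            raise ValueError("phi values must lie in [0, 360)")
        if np.any(theta < 0) or np.any(theta > 180):
            raise ValueError("theta values must lie in [0, 180]")
        for v in (phi, theta):
            if v.size > 1 and not np.allclose(np.diff(v), self.spacing):
                raise ValueError("grid spacing must be uniform")

    @classmethod
    def from_spacing(cls, spacing: float = 5.0, include_poles: bool = True) -> "OrientationGrid":
        phi = np.arange(0.0, 360.0, spacing)
        if include_poles:
            theta = np.arange(0.0, 180.0 + 0.5 * spacing, spacing)
        else:
            theta = np.arange(0.5 * spacing, 180.0, spacing)
        return cls(phi=phi, theta=theta, spacing=spacing)

    @property
    def shape(self) -> tuple:
        return (self.phi.size, self.theta.size)

    def theta_weights(self) -> np.ndarray:
        """sin(theta) orientation weights; polar endpoints get their half-cell
        midpoint weight sin(spacing/2) instead of 0 so coarse grids do not
        silently drop polar orientations."""
        t = np.clip(self.theta, 0.5 * self.spacing, 180.0 - 0.5 * self.spacing)
        return np.sin(np.radians(t))


@dataclass
class EnergyHeatmap:
    """Orientation-resolved adsorption energies on one surface.

    ``e_ads[i, j]`` is the distance-Boltzmann-averaged adsorption energy (kBT)
    at ``(phi[i], theta[j])``; ``r_min[i, j]`` is the separation (nm) of the
    global minimum of the interaction profile at that orientation.
    """

    grid: OrientationGrid
    e_ads: np.ndarray  # kBT, shape grid.shape
    r_min: np.ndarray  # nm, shape grid.shape
    molecule: str = ""
    surface_label: str = ""

    def __post_init__(self) -> None:
        self.e_ads = np.asarray(self.e_ads, dtype=float)
        self.r_min = np.asarray(self.r_min, dtype=float)
        if self.e_ads.shape != self.grid.shape or self.r_min.shape != self.grid.shape:
            raise ValueError("heatmap arrays must match grid shape")
        if not np.all(np.isfinite(self.e_ads)):
            raise ValueError("non-finite adsorption energies")
        if np.any(self.r_min < 0):
            raise ValueError("r_min must be >= 0")

    def minimum(self) -> dict:
        """The most favourable orientation, reported like a binding-table row."""
        i, j = np.unravel_index(np.argmin(self.e_ads), self.e_ads.shape)
        return {
            "e_ads_kBT": float(self.e_ads[i, j]),
            "phi_deg": float(self.grid.phi[i]),
            "theta_deg": float(self.grid.theta[j]),
            "r_min_nm": float(self.r_min[i, j]),
        }

    def to_frame(self) -> pd.DataFrame:
        """Row-major (phi outer, theta inner) long-format table."""
        pp, tt = np.meshgrid(self.grid.phi, self.grid.theta, indexing="ij")
        return pd.DataFrame(
            {
                "phi_deg": pp.ravel(),
                "theta_deg": tt.ravel(),
                "e_ads_kBT": self.e_ads.ravel(),
                "r_min_nm": self.r_min.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, molecule: str = "", surface_label: str = "") -> "EnergyHeatmap":
        df = pd.read_csv(path, float_precision="round_trip")
        phi = np.unique(df["phi_deg"].to_numpy())
        theta = np.unique(df["theta_deg"].to_numpy())
        spacing = float(phi[1] - phi[0]) if phi.size > 1 else (
            float(theta[1] - theta[0]) if theta.size > 1 else 5.0
        )
        grid = OrientationGrid(phi=phi, theta=theta, spacing=spacing)
        shape = grid.shape
        e = df["e_ads_kBT"].to_numpy().reshape(shape)
        r = df["r_min_nm"].to_numpy().reshape(shape)
        return cls(grid=grid, e_ads=e, r_min=r, molecule=molecule,
                   surface_label=surface_label)


# ---------------------------------------------------------------------------
# PMF loading


def load_pmf(path, surface_label: str, bead_type: str) -> PMFTable:
    """Read a two-column CSV ``ssd_nm,energy_kBT`` (header optional) into a
    validated :class:`PMFTable`."""
    try:
        df = pd.read_csv(path, header=None, comment="#",
                         float_precision="round_trip")
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise PMFFormatError(f"cannot read PMF file {path}: {exc}") from exc
    # Tolerate an optional header row of column names.
    first = df.iloc[0]
    try:
        float(first[0]), float(first[1])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    if df.shape[1] < 2 or len(df) == 0:
        raise PMFFormatError(f"PMF file {path} is not two-column CSV")
    ssd = df.iloc[:, 0].astype(float).to_numpy()
    energy = df.iloc[:, 1].astype(float).to_numpy()
    return PMFTable(surface_label=surface_label, bead_type=bead_type,
                    ssd=ssd, energy=energy)


# ---------------------------------------------------------------------------
# Orientation handling


def _principal_axes(molecule: CGMolecule):
    """Inertia tensor eigenvectors sorted by ascending moment, about the COM."""
    m = molecule.masses
    if m.sum() <= 0:
        m = np.ones_like(m)
    com = np.average(molecule.positions, axis=0, weights=m)
    r = molecule.positions - com
    x, y, z = r[:, 0], r[:, 1], r[:, 2]
    ixx = np.sum(m * (y**2 + z**2))
    iyy = np.sum(m * (x**2 + z**2))
    izz = np.sum(m * (x**2 + y**2))
    ixy = -np.sum(m * x * y)
    ixz = -np.sum(m * x * z)
    iyz = -np.sum(m * y * z)
    inertia = np.array([[ixx, ixy, ixz], [ixy, iyy, iyz], [ixz, iyz, izz]])
    evals, evecs = np.linalg.eigh(inertia)  # ascending
    return com, r, evals, evecs


def canonicalize_orientation(molecule: CGMolecule) -> CGMolecule:
    """Rotate a molecule into its canonical principal-axis frame.

    The inertia axis with the smallest moment goes to z (typically the axis of
    greatest spatial extent), the second smallest to y; the remaining sign
    freedom is fixed by flipping 180 deg about x and/or z so the electric
    dipole components along z and y are non-negative.  The centre of mass is
    moved to the origin.  Degenerate inertia tensors (single bead, perfectly
    collinear molecules with no unique transverse frame, net-zero dipole) fall
    back to whatever eigenbasis the solver returns — a warning is emitted for
    truly degenerate (single-bead) input and the identity is used.
    """
    if molecule.n_beads == 1:
        warnings.warn(
            f"molecule {molecule.name}: single bead has no principal frame; "
            "using identity orientation",
            stacklevel=2,
        )
        return molecule.with_positions(np.zeros_like(molecule.positions))

    com, r, evals, evecs = _principal_axes(molecule)
    # eigh returns ascending moments: smallest -> z, second -> y, largest -> x.
    axes = np.column_stack([evecs[:, 2], evecs[:, 1], evecs[:, 0]])  # x, y, z
    if np.linalg.det(axes) < 0:
        axes[:, 0] = -axes[:, 0]
    new_r = r @ axes  # coordinates in the principal frame

    q = molecule.charges
    dipole = q @ new_r  # e*nm
    # Flip about x (negates y and z) and/or about z (negates x and y) until
    # the dipole is non-negative along z and y.
    if dipole[2] < 0:
        new_r[:, 1] *= -1
        new_r[:, 2] *= -1
        dipole = q @ new_r
    if dipole[1] < 0:
        new_r[:, 0] *= -1
        new_r[:, 1] *= -1
    return molecule.with_positions(new_r)


def _rotation_matrix(phi_deg: float, theta_deg: float) -> np.ndarray:
    """Orientation (phi, theta): rotation of -phi about z, then 180-theta about y."""
    a = math.radians(-phi_deg)
    b = math.radians(180.0 - theta_deg)
    ca, sa, cb, sb = math.cos(a), math.sin(a), math.cos(b), math.sin(b)
    rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    ry = np.array([[cb, 0.0, sb], [0.0, 1.0, 0.0], [-sb, 0.0, cb]])
    return ry @ rz


def rotate_molecule(molecule: CGMolecule, phi: float, theta: float) -> np.ndarray:
    """Bead positions (nm) after the (phi, theta) orientation rotation.

    The molecule must already be in the canonical frame; (phi=0, theta=180)
    is the identity.
    """
    rot = _rotation_matrix(phi, theta)
    return molecule.positions @ rot.T


# ---------------------------------------------------------------------------
# Energy terms


def _mv_to_kbt(zeta_mv: float, temperature: float) -> float:
    """Energy (kBT) of one elementary charge at a potential of zeta_mv mV."""
    return E_CHARGE * zeta_mv * 1e-3 / (KB * temperature)


def electrostatic_energy(charge_e, ssd_nm, np_: Nanoparticle) -> np.ndarray:
    """Screened-Coulomb (linearised Poisson–Boltzmann) energy in kBT of a point
    charge at surface separation ``ssd_nm`` from a sphere held at the zeta
    potential: U = q e zeta (R/(R+h)) exp(-h/lambda_D)."""
    ssd = np.asarray(ssd_nm, dtype=float)
    r = np_.radius + np.maximum(ssd, 0.0)
    psi = _mv_to_kbt(np_.zeta_potential, np_.temperature)
    return charge_e * psi * (np_.radius / r) * np.exp(-np.maximum(ssd, 0.0) / np_.debye_length)


def hamaker_energy(bead_radius_nm: float, ssd_nm, np_: Nanoparticle) -> np.ndarray:
    """Hamaker core van der Waals energy (kBT) between the NP sphere and a
    bead sphere whose surface sits ``ssd_nm`` from the NP surface.

    Classical two-sphere Hamaker form; returns 0 when the NP's Hamaker
    constant is 0.  The surface-to-surface gap is floored at 0.01 nm to avoid
    the contact singularity (the short-range PMF owns that region).
    """
    if np_.hamaker_constant == 0.0:
        return np.zeros_like(np.asarray(ssd_nm, dtype=float))
    ssd = np.maximum(np.asarray(ssd_nm, dtype=float), 0.01)
    r1, r2 = np_.radius, bead_radius_nm
    d = r1 + r2 + ssd  # centre-centre distance, nm
    s_plus = d**2 - (r1 + r2) ** 2
    s_minus = d**2 - (r1 - r2) ** 2
    a_kbt = np_.hamaker_constant / (KB * np_.temperature)
    return -(a_kbt / 6.0) * (
        2 * r1 * r2 / s_plus + 2 * r1 * r2 / s_minus + np.log(s_plus / s_minus)
    )


def _resolve_beads(molecule: CGMolecule, beads) -> list:
    table = {b.bead_type: b for b in beads} if beads is not None else {}
    out = []
    for k, bt in enumerate(molecule.bead_types):
        if bt in table:
            out.append(table[bt])
        else:
            out.append(BeadSpec(bead_type=bt, charge=float(molecule.charges[k]),
                                mass=float(molecule.masses[k])))
    return out


def interaction_profile(
    molecule: CGMolecule,
    np_: Nanoparticle,
    phi: float,
    theta: float,
    ssd_grid: np.ndarray,
    pmfs,
    beads=None,
) -> np.ndarray:
    """Total molecule–NP interaction energy U(d) in kBT over a distance sweep.

    ``ssd_grid`` is the nominal separation d (nm) between the NP surface and
    the lowest bead, measured along the polar axis: the molecule is rotated to
    (phi, theta), placed above the NP north pole with its lowest bead at height
    R_NP + d, and each bead's surface separation is then the exact sphere
    convention ``|bead - centre| - R_NP``.  Per bead the energy is the sum of
    its tabulated PMF, the screened-Coulomb term for its charge and, unless
    the bead is flagged small, the Hamaker core term.

    ``pmfs`` maps (or lists) :class:`PMFTable` objects; every bead type of the
    molecule must have a table for ``np_.surface_label``.
    """
    pmf_map = _pmf_map(pmfs, np_.surface_label)
    bead_specs = _resolve_beads(molecule, beads)
    for bt in set(molecule.bead_types):
        if bt not in pmf_map:
            raise MissingPMFError(
                f"no PMF for bead type {bt!r} on surface {np_.surface_label!r}"
            )

    pos = rotate_molecule(molecule, phi, theta)
    z = pos[:, 2]
    rho2 = pos[:, 0] ** 2 + pos[:, 1] ** 2
    z_min = z.min()

    d = np.asarray(ssd_grid, dtype=float)
    # height of each bead centre above the NP centre for every d in the sweep
    h = np_.radius + d[:, None] + (z[None, :] - z_min)
    bead_ssd = np.sqrt(h**2 + rho2[None, :]) - np_.radius  # (n_d, n_beads)

    total = np.zeros(d.shape, dtype=float)
    for k, spec in enumerate(bead_specs):
        s = bead_ssd[:, k]
        total += pmf_map[molecule.bead_types[k]](s)
        if spec.charge != 0.0:
            total += electrostatic_energy(spec.charge, s, np_)
        if not spec.small:
            total += hamaker_energy(spec.radius, s, np_)
    return total


def _pmf_map(pmfs, surface_label: str) -> dict:
    if isinstance(pmfs, dict):
        items = pmfs.values()
    else:
        items = pmfs
    return {p.bead_type: p for p in items if p.surface_label == surface_label}


# ---------------------------------------------------------------------------
# Boltzmann averaging


def default_ssd_grid(pmfs=None, surface_label: str = "", start: float | None = None,
                     stop: float = 1.5, step: float = 0.005) -> np.ndarray:
    """Distance sweep for the averaging window: from the PMF wall (smallest
    tabulated ssd of the relevant tables) out to 1.5 nm in 0.005 nm steps."""
    if start is None:
        if pmfs:
            m = _pmf_map(pmfs, surface_label) if surface_label else _pmf_map(pmfs, next(iter(
                {p.surface_label for p in (pmfs.values() if isinstance(pmfs, dict) else pmfs)})))
            start = min(p.ssd_min for p in m.values()) if m else 0.05
        else:
            start = 0.05
    n = int(round((stop - start) / step)) + 1
    return np.linspace(start, stop, n)


def boltzmann_average_distance(ssd_grid: np.ndarray, energy: np.ndarray,
                               temperature: float = T_DEFAULT):
    """Boltzmann-weighted mean energy over the approach distance.

        e_ads = ∫ U(d) e^{-U(d)} dd / ∫ e^{-U(d)} dd        (U in kBT)

    evaluated by trapezoidal quadrature on the supplied window, with the
    weights shifted by min(U) for overflow safety.  Also returns ``r_min``,
    the separation of the global minimum of U.  ``temperature`` is accepted
    for interface symmetry; energies are already in kBT so it does not enter.

    Returns ``(e_ads_kBT, r_min_nm)``.
    """
    d = np.asarray(ssd_grid, dtype=float)
    u = np.asarray(energy, dtype=float)
    if d.size < 3:
        raise ValueError("averaging window must contain at least 3 samples")
    if d.shape != u.shape:
        raise ValueError("ssd_grid and energy must have the same shape")
    u_min = u.min()
    w = np.exp(-(u - u_min))  # shifted Boltzmann weights
    z = np.trapezoid(w, d)
    num = np.trapezoid(u * w, d)
    e_ads = num / z
    r_min = float(d[int(np.argmin(u))])
    return float(e_ads), r_min


def build_heatmap(
    molecule: CGMolecule,
    np_: Nanoparticle,
    grid: OrientationGrid | None = None,
    pmfs=None,
    beads=None,
    ssd_grid: np.ndarray | None = None,
) -> EnergyHeatmap:
    """Orientation-resolved adsorption-energy heatmap.

    For every (phi, theta) grid point: rotate the (already canonicalised)
    molecule, sweep the approach distance, Boltzmann-average the interaction
    profile.  The per-orientation distance of closest approach ``r_min`` is
    recorded alongside the energy.
    """
    if grid is None:
        grid = OrientationGrid.from_spacing(5.0)
    if ssd_grid is None:
        ssd_grid = default_ssd_grid(pmfs, np_.surface_label)
    e = np.empty(grid.shape)
    r = np.empty(grid.shape)
    for i, phi in enumerate(grid.phi):
        for j, theta in enumerate(grid.theta):
            u = interaction_profile(molecule, np_, phi, theta, ssd_grid, pmfs, beads)
            e[i, j], r[i, j] = boltzmann_average_distance(ssd_grid, u, np_.temperature)
    return EnergyHeatmap(grid=grid, e_ads=e, r_min=r, molecule=molecule.name,
                         surface_label=np_.surface_label)


def global_boltzmann_energy(heatmap: EnergyHeatmap) -> float:
    """Single adsorption energy for the whole molecule: the sin(theta)-weighted
    Boltzmann average of the per-orientation energies,

        E = Σ sinθ E e^{-E} / Σ sinθ e^{-E}   (E in kBT),

    overflow-safe via a min-energy shift.  Always lies between min and max of
    the heatmap.
    """
    e = heatmap.e_ads
    w_theta = heatmap.grid.theta_weights()[None, :]
    shift = e.min()
    w = w_theta * np.exp(-(e - shift))
    return float((e * w).sum() / w.sum())
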