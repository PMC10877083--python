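"""Event-driven competitive-adsorption simulator (kinetic Monte Carlo).

Adsorbates are hard spherical caps on the surface of a spherical nanoparticle.
A Gillespie direct-method loop advances the system from one event to the next:
arrival of an incoming adsorbate (placed uniformly at random on the sphere) or
desorption of an adsorbed one, with waiting times exponential in the total
rate.  Two acceptance modes are supported:

* ``hard_sphere`` — an arrival is accepted with unit probability iff it
  overlaps no adsorbed particle;
* ``displacement`` — an arrival overlapping the set J of adsorbed particles is
  accepted with the logistic probability p(dE) = e^{-dE}/(1+e^{-dE}) where
  dE = E_in - sum_{j in J} E_j (dE = E_in when J is empty), and on acceptance
  every particle in J is evicted.  Desorption rates carry the matching
  p(E_ads) factor so equilibrium constants are unchanged.  The asymmetry
  (one incoming molecule may evict many, never the converse) is deliberate:
  the reverse event would require simultaneous multi-molecule collisions that
  are never sampled on simulation timescales.

Bare surface is implicit water with adsorption affinity 0 kBT; all binding
energies are relative to it.  An optional quasi-equilibrium acceleration
uniformly downscales the forward and reverse rates of fast, equilibrated
species (equilibrium constants preserved) so computational effort goes to the
slow events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cg_model import Nanoparticle
from .rate_param import AdsorbateSpecies

__all__ = [
    "CoronaState",
    "EventRecord",
    "CoronaSummary",
    "AccelerationConfig",
    "acceptance_probability",
    "displacement_delta",
    "kmc_step",
    "run_corona",
    "mass_abundance",
    "cap_half_angle",
]


def acceptance_probability(delta_e: float) -> float:
    """Logistic displacement-acceptance probability
    p(dE) = exp(-dE) / (1 + exp(-dE)), overflow-safe; dE in kBT."""
    if not math.isfinite(delta_e):
        raise ValueError("delta_e must be finite")
    if delta_e >= 0:
        x = math.exp(-delta_e)
        return x / (1.0 + x)
    return 1.0 / (1.0 + math.exp(delta_e))


def displacement_delta(incoming_e_ads: float, overlapped_e_ads) -> float:
    """Energy difference dE = E_in - sum_j E_j over the overlapped adsorbates;
    equals E_in when there are no overlaps."""
    return float(incoming_e_ads) - float(sum(overlapped_e_ads))


def cap_half_angle(area_nm2: float, r_np_nm: float) -> float:
    """Half-angle (radians) of the spherical cap of the given area: the
    angular exclusion radius of an adsorbate whose footprint is that cap."""
    cos_a = 1.0 - area_nm2 / (2.0 * math.pi * r_np_nm**2)
    return math.acos(max(-1.0, min(1.0, cos_a)))


@dataclass
class EventRecord:
    """One simulation event for the audit trail."""

    time: float  # s
    kind: str  # adsorb | desorb | displace-accept | reject
    species_id: str
    displaced_ids: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in ("adsorb", "desorb", "displace-accept", "reject"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.displaced_ids and self.kind != "displace-accept":
            raise ValueError("displaced_ids only valid for displace-accept")


@dataclass
class CoronaSummary:
    """Time-averaged corona composition per parent molecule."""

    molecules: list  # parent molecule names
    number_density: np.ndarray  # nm^-2, time-averaged N/(4 pi R^2)
    mass_abundance_pct: np.ndarray  # percent of adsorbed mass
    stderr_density: np.ndarray  # nm^-2, block-averaged standard error
    time_window: tuple  # (t_start, t_end) seconds used for averaging
    event_counts: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "molecule": self.molecules,
                "N_ads_per_nm2": self.number_density,
                "mass_abundance_pct": self.mass_abundance_pct,
                "stderr": self.stderr_density,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def mass_abundance(densities, molecular_weights) -> dict:
    """Mass abundance (percent) per molecule from number densities (nm^-2)
    and molecular weights (Da): M_i = 100 N_i MW_i / sum_j N_j MW_j.

    ``densities`` and ``molecular_weights`` are mappings keyed by molecule.
    """
    keys = list(densities)
    mass = np.array([densities[k] * molecular_weights[k] for k in keys], dtype=float)
    if np.any(mass < 0):
        raise ValueError("densities and molecular weights must be non-negative")
    total = mass.sum()
    if total <= 0:
        raise ValueError("at least one density must be nonzero")
    return {k: 100.0 * m / total for k, m in zip(keys, mass)}


@dataclass
class AccelerationConfig:
    """Quasi-equilibrium rate-scaling parameters.

    Species whose adsorb and desorb counts both exceed ``n_eq`` within an
    assessment window of ``window`` events, with net flux below ``flux_tol``
    (relative to the mean one-way count), have ka and kd multiplied by a
    common factor alpha < 1 chosen so the scaled species' total event rate is
    at most ``rate_cap`` times the fastest non-equilibrated rate.  Scaling
    reverts (and the window restarts) whenever a non-equilibrated species
    fires.
    """

    window: int = 10_000
    n_eq: int = 100
    flux_tol: float = 0.2
    rate_cap: float = 10.0


class CoronaState:
    """Mutable simulator state: adsorbed hard caps on the NP sphere.

    ``anchors`` are unit vectors; per-adsorbate arrays are kept in parallel
    lists for O(1) removal by swap-with-last.  The RNG is owned by the state
    so a fixed seed yields a bit-identical event stream.
    """

    def __init__(self, np_: Nanoparticle, species, mode: str = "hard_sphere",
                 seed: int = 0, acceleration: AccelerationConfig | None = None):
        if not species:
            raise ValueError("species table is empty")
        if mode not in ("hard_sphere", "displacement"):
            raise ValueError(f"unknown mode {mode!r}")
        self.np_ = np_
        self.species = list(species)
        self.mode = mode
        self.rng = np.random.Generator(np.random.PCG64(seed))
        self.accel = acceleration
        self.sim_time = 0.0
        self.events: list[EventRecord] = []
        self.log_events = True

        ns = len(self.species)
        self.s_id = [s.species_id for s in self.species]
        self.s_parent = [s.parent_molecule for s in self.species]
        self.s_e = np.array([s.e_ads for s in self.species])
        self.s_alpha = np.array(
            [cap_half_angle(s.footprint_area, np_.radius) for s in self.species]
        )
        self.s_cos_a = np.cos(self.s_alpha)
        self.s_sin_a = np.sin(self.s_alpha)
        # total arrival rate per species: per-site ka * C * N_sites  (1/s)
        self.s_arrival = np.array(
            [s.ka * s.concentration * s.n_sites(np_) for s in self.species]
        )
        kd = np.array([s.kd for s in self.species])
        if mode == "displacement":
            # matching p(E_ads) factor keeps ka/kd fixed (arrivals already
            # carry p via the acceptance test)
            kd = kd * np.array([acceptance_probability(e) for e in self.s_e])
        self.s_kd = kd
        self.scale = np.ones(ns)  # quasi-equilibrium scale factors

        self.parents = sorted(set(self.s_parent))
        self._parent_idx = {p: i for i, p in enumerate(self.parents)}
        self.s_parent_i = np.array([self._parent_idx[p] for p in self.s_parent])

        cap = 256
        self.n_ads = 0
        self.a_anchor = np.zeros((cap, 3))
        self.a_spec = np.zeros(cap, dtype=np.int64)
        self.a_kd = np.zeros(cap)
        self.parent_counts = np.zeros(len(self.parents), dtype=np.int64)
        # event counters: per species [adsorb, desorb, displace-accept, reject]
        self.counters = np.zeros((ns, 4), dtype=np.int64)
        self.window_counters = np.zeros((ns, 2), dtype=np.int64)
        self._window_events = 0

    # -- bookkeeping ------------------------------------------------------

    def _grow(self) -> None:
        cap = self.a_anchor.shape[0] * 2
        self.a_anchor = np.vstack([self.a_anchor, np.zeros_like(self.a_anchor)])
        self.a_spec = np.concatenate([self.a_spec, np.zeros_like(self.a_spec)])
        self.a_kd = np.concatenate([self.a_kd, np.zeros_like(self.a_kd)])
        del cap

    def _add(self, spec_i: int, anchor: np.ndarray) -> None:
        n = self.n_ads
        if n == self.a_anchor.shape[0]:
            self._grow()
        self.a_anchor[n] = anchor
        self.a_spec[n] = spec_i
        self.a_kd[n] = self.s_kd[spec_i] * self.scale[spec_i]
        self.parent_counts[self.s_parent_i[spec_i]] += 1
        self.n_ads = n + 1

    def _remove(self, idx: int) -> None:
        n = self.n_ads - 1
        self.parent_counts[self.s_parent_i[self.a_spec[idx]]] -= 1
        if idx != n:
            self.a_anchor[idx] = self.a_anchor[n]
            self.a_spec[idx] = self.a_spec[n]
            self.a_kd[idx] = self.a_kd[n]
        self.n_ads = n

    def _overlaps(self, anchor: np.ndarray, alpha_in: float) -> np.ndarray:
        """Indices of adsorbed particles whose caps overlap an incoming cap."""
        n = self.n_ads
        if n == 0:
            return np.empty(0, dtype=np.int64)
        dots = self.a_anchor[:n] @ anchor
        si = self.a_spec[:n]
        # separation < alpha_in + alpha_j; via cos(sep) > cos(alpha_in+alpha_j)
        # when the sum is below pi, and always when it reaches pi (cos is not
        # monotone past pi, so that case must short-circuit)
        alpha_sum = alpha_in + self.s_alpha[si]
        cos_sum = math.cos(alpha_in) * self.s_cos_a[si] - math.sin(alpha_in) * self.s_sin_a[si]
        return np.nonzero((alpha_sum >= math.pi) | (dots > cos_sum))[0]

    def check_integrity(self) -> bool:
        """True iff no two adsorbed caps overlap (exact spherical geometry)."""
        n = self.n_ads
        if n < 2:
            return True
        a = self.a_anchor[:n]
        al = self.s_alpha[self.a_spec[:n]]
        dots = np.clip(a @ a.T, -1.0, 1.0)
        sep = np.arccos(dots)
        lim = al[:, None] + al[None, :]
        bad = sep < lim
        np.fill_diagonal(bad, False)
        return not bad.any()

    # -- quasi-equilibrium scaling ---------------------------------------

    def _total_desorb_by_species(self) -> np.ndarray:
        out = np.zeros(len(self.species))
        n = self.n_ads
        if n:
            np.add.at(out, self.a_spec[:n], self.a_kd[:n])
        return out

    def _apply_scaling(self) -> None:
        cfg = self.accel
        ads = self.window_counters[:, 0]
        des = self.window_counters[:, 1]
        mean_oneway = 0.5 * (ads + des)
        eq = (
            (ads >= cfg.n_eq)
            & (des >= cfg.n_eq)
            & (np.abs(ads - des) <= cfg.flux_tol * np.maximum(mean_oneway, 1))
        )
        if not eq.any() or eq.all():
            return
        desorb = self._total_desorb_by_species()
        base_total = self.s_arrival + desorb / np.maximum(self.scale, 1e-300)
        r_fast = float((base_total[~eq]).max())
        if r_fast <= 0:
            return
        new_scale = np.ones_like(self.scale)
        for i in np.nonzero(eq)[0]:
            if base_total[i] > 0:
                new_scale[i] = min(1.0, cfg.rate_cap * r_fast / base_total[i])
        if np.allclose(new_scale, self.scale):
            return
        self._set_scale(new_scale)

    def _revert_scaling(self) -> None:
        if np.any(self.scale < 1.0):
            self._set_scale(np.ones_like(self.scale))
        self.window_counters[:] = 0
        self._window_events = 0

    def _set_scale(self, new_scale: np.ndarray) -> None:
        self.scale = new_scale
        n = self.n_ads
        if n:
            self.a_kd[:n] = self.s_kd[self.a_spec[:n]] * new_scale[self.a_spec[:n]]

    # -- the Gillespie step ----------------------------------------------

    def step(self, collect=None) -> str:
        """Advance by exactly one event; returns the event kind.

        ``collect(dt, parent_counts)`` — if given — receives the waiting time
        and the pre-event composition, for time averaging.
        """
        rng = self.rng
        n = self.n_ads
        arrival = self.s_arrival * self.scale
        total_arrival = float(arrival.sum())
        total_desorb = float(self.a_kd[:n].sum()) if n else 0.0
        total = total_arrival + total_desorb
        if total <= 0:
            raise RuntimeError("total event rate is zero; nothing can happen")

        dt = -math.log(rng.random()) / total
        if collect is not None:
            collect(dt, self.parent_counts)
        self.sim_time += dt

        u = rng.random() * total
        if u < total_arrival:
            # arrival: choose species by cumulative rate
            cum = np.cumsum(arrival)
            spec_i = int(np.searchsorted(cum, u, side="right"))
            spec_i = min(spec_i, len(self.species) - 1)
            kind = self._attempt_adsorption(spec_i)
        else:
            # desorption: choose adsorbed particle by cumulative kd
            v = u - total_arrival
            cum = np.cumsum(self.a_kd[:n])
            idx = int(np.searchsorted(cum, v, side="right"))
            idx = min(idx, n - 1)
            spec_i = int(self.a_spec[idx])
            self._remove(idx)
            self.counters[spec_i, 1] += 1
            self.window_counters[spec_i, 1] += 1
            if self.log_events:
                self.events.append(
                    EventRecord(self.sim_time, "desorb", self.s_id[spec_i])
                )
            kind = "desorb"

        self._after_event(spec_i)
        return kind

    def _attempt_adsorption(self, spec_i: int) -> str:
        rng = self.rng
        # uniform point on the sphere (area-preserving)
        z = 1.0 - 2.0 * rng.random()
        phi = 2.0 * math.pi * rng.random()
        s = math.sqrt(max(0.0, 1.0 - z * z))
        anchor = np.array([s * math.cos(phi), s * math.sin(phi), z])

        over = self._overlaps(anchor, self.s_alpha[spec_i])
        sid = self.s_id[spec_i]
        if self.mode == "hard_sphere":
            if over.size:
                self.counters[spec_i, 3] += 1
                if self.log_events:
                    self.events.append(EventRecord(self.sim_time, "reject", sid))
                return "reject"
            self._add(spec_i, anchor)
            self.counters[spec_i, 0] += 1
            self.window_counters[spec_i, 0] += 1
            if self.log_events:
                self.events.append(EventRecord(self.sim_time, "adsorb", sid))
            return "adsorb"

        # displacement mode: logistic acceptance on the energy difference,
        # dE = E_in when no overlaps are found
        delta = displacement_delta(
            self.s_e[spec_i], self.s_e[self.a_spec[over]] if over.size else ()
        )
        accept = rng.random() < acceptance_probability(delta)
        if not accept:
            self.counters[spec_i, 3] += 1
            if self.log_events:
                self.events.append(EventRecord(self.sim_time, "reject", sid))
            return "reject"
        if over.size:
            si_over = [int(self.a_spec[i]) for i in over]
            displaced = tuple(self.s_id[i] for i in si_over)
            # displaced removals count as departures in the equilibration
            # window so the net-flux test sees the true population balance
            for i in si_over:
                self.window_counters[i, 1] += 1
            # remove from highest index down so swap-with-last stays valid
            for i in sorted((int(i) for i in over), reverse=True):
                self._remove(i)
            self._add(spec_i, anchor)
            self.counters[spec_i, 2] += 1
            self.window_counters[spec_i, 0] += 1
            if self.log_events:
                self.events.append(
                    EventRecord(self.sim_time, "displace-accept", sid, displaced)
                )
            return "displace-accept"
        self._add(spec_i, anchor)
        self.counters[spec_i, 0] += 1
        self.window_counters[spec_i, 0] += 1
        if self.log_events:
            self.events.append(EventRecord(self.sim_time, "adsorb", sid))
        return "adsorb"

    def _after_event(self, spec_i: int) -> None:
        if self.accel is None:
            return
        if self.scale[spec_i] == 1.0 and np.any(self.scale < 1.0):
            # a non-equilibrated class fired: leave the superbasin
            self._revert_scaling()
            return
        self._window_events += 1
        if self._window_events >= self.accel.window:
            self._apply_scaling()
            self.window_counters[:] = 0
            self._window_events = 0


def kmc_step(state: CoronaState, species=None, mode: str | None = None) -> CoronaState:
    """Advance the corona state by exactly one Gillespie event (in place).

    ``species``/``mode`` are accepted for interface completeness and must
    match the state's configuration if given.
    """
    if species is not None and len(species) != len(state.species):
        raise ValueError("species table does not match the state")
    if mode is not None and mode != state.mode:
        raise ValueError(f"state was built in mode {state.mode!r}")
    state.step()
    return state


def run_corona(
    np_: Nanoparticle,
    species,
    sim_time: float | None = None,
    mode: str = "hard_sphere",
    seed: int = 0,
    burn_in_fraction: float = 0.5,
    max_events: int | None = None,
    acceleration: AccelerationConfig | None = None,
    log_events: bool = False,
    integrity_check: bool = False,
    n_blocks: int = 10,
):
    """Run a corona simulation and summarise the steady-state composition.

    The run length is set by ``sim_time`` (seconds of simulated time) or
    ``max_events`` (number of Gillespie events); at least one must be given
    and ``sim_time`` must be positive when supplied.  The first
    ``burn_in_fraction`` of the run is discarded; the remainder is
    time-averaged in ``n_blocks`` blocks to give per-parent number densities
    (nm^-2), mass abundances (percent) and block standard errors.  A fixed
    seed yields an identical event stream.

    Returns ``(CoronaSummary, list[EventRecord])`` (the list is empty unless
    ``log_events`` is set).
    """
    if sim_time is None and max_events is None:
        raise ValueError("give sim_time or max_events")
    if sim_time is not None and sim_time <= 0:
        raise ValueError("sim_time must be > 0")

    state = CoronaState(np_, species, mode=mode, seed=seed,
                        acceleration=acceleration)
    state.log_events = log_events
    n_parents = len(state.parents)
    blocks = np.zeros((n_blocks, n_parents))
    block_time = np.zeros(n_blocks)

    if sim_time is not None:
        t_burn = burn_in_fraction * sim_time
        span = sim_time - t_burn

        def collect(dt, counts):
            t0 = state.sim_time
            t1 = t0 + dt
            if t1 <= t_burn:
                return
            lo = max(t0, t_burn)
            bi = min(int((lo - t_burn) / span * n_blocks), n_blocks - 1)
            w = min(t1, sim_time) - lo
            if w > 0:
                blocks[bi] += counts * w
                block_time[bi] += w

        ev = 0
        while state.sim_time < sim_time:
            state.step(collect)
            ev += 1
            if integrity_check and mode == "hard_sphere" and not state.check_integrity():
                raise RuntimeError("hard-sphere overlap violation")
            if max_events is not None and ev >= max_events:
                break
    else:
        n_burn = int(burn_in_fraction * max_events)
        per_block = max(1, (max_events - n_burn) // n_blocks)

        for ev in range(max_events):
            if ev >= n_burn:
                bi = min((ev - n_burn) // per_block, n_blocks - 1)

                def collect(dt, counts, bi=bi):
                    blocks[bi] += counts * dt
                    block_time[bi] += dt

                state.step(collect)
            else:
                state.step()
            if integrity_check and mode == "hard_sphere" and not state.check_integrity():
                raise RuntimeError("hard-sphere overlap violation")

    area = np_.surface_area
    used = block_time > 0
    if not used.any():
        mean_counts = state.parent_counts.astype(float)
        stderr = np.zeros(n_parents)
    else:
        block_means = blocks[used] / block_time[used, None]
        mean_counts = np.average(block_means, axis=0, weights=block_time[used])
        nb = used.sum()
        stderr = (
            block_means.std(axis=0, ddof=1) / math.sqrt(nb) if nb > 1
            else np.zeros(n_parents)
        )

    density = mean_counts / area
    mw = {}
    for s in species:
        mw[s.parent_molecule] = s.molecular_weight
    if density.sum() > 0:
        ab = mass_abundance(
            {p: density[i] for i, p in enumerate(state.parents)}, mw
        )
        abundance = np.array([ab[p] for p in state.parents])
    else:
        abundance = np.zeros(n_parents)

    counts_by_kind = {
        "adsorb": int(state.counters[:, 0].sum()),
        "desorb": int(state.counters[:, 1].sum()),
        "displace-accept": int(state.counters[:, 2].sum()),
        "reject": int(state.counters[:, 3].sum()),
    }
    t_start = burn_in_fraction * sim_time if sim_time is not None else 0.0
    summary = CoronaSummary(
        molecules=state.parents,
        number_density=density,
        mass_abundance_pct=abundance,
        stderr_density=stderr / area,
        time_window=(t_start, state.sim_time),
        event_counts=counts_by_kind,
    )
    return summary, state.events
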