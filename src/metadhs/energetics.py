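"""Potential-energy model and stochastic dynamics for the toy complex.

Force field terms: harmonic bonds on the ligand chain, Lennard-Jones 12-6
with Lorentz–Berthelot combination, Debye-screened Coulomb (screening
length 8 Å, relative dielectric 20) standing in for solvent, harmonic
positional restraints holding the pocket scaffold near its native
geometry, repulsive Gaussian ridges on the ligand COM defining the two
exit channels (A: 6.0 kJ/mol, B: 8.1 kJ/mol), and confinement (a 30 Å
reflective sphere plus a soft tunnel wall that keeps exits axial).

Nonbonded interactions couple the ligand to everything else (pocket,
scaffold and non-neighbour ligand beads); the restrained scaffold beads
are mutually non-interacting by construction — their geometry is held by
the restraints, which keeps the model cheap and its fluctuations
analytically predictable (RMSF = sqrt(3 kB T / k)).

Dynamics is BAOAB-splitting Langevin at dt = 10 fs with friction 1/ps.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .system import ToySystem
from .units import COULOMB_K, KB


class SingularityError(ValueError):
    """Coincident beads in a nonbonded pair."""


class IntegrationError(RuntimeError):
    """Non-finite force or coordinate during integration."""


def lj_energy(r: float, epsilon: float, sigma: float) -> float:
    """Lennard-Jones 12-6 pair energy (minimum -epsilon at r = 2^(1/6) sigma)."""
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6)


def screened_coulomb(r: float, q1: float, q2: float,
                     dielectric: float = 20.0, debye_length: float = 8.0) -> float:
    """Debye-screened Coulomb pair energy, kJ/mol."""
    return COULOMB_K * q1 * q2 / (dielectric * r) * math.exp(-r / debye_length)


@dataclass
class SimState:
    """Positions/velocities plus a (seed, counter) RNG stream descriptor."""

    positions: np.ndarray
    velocities: np.ndarray
    time: float = 0.0
    step: int = 0
    seed: int = 0
    counter: int = 0

    def copy(self) -> "SimState":
        return SimState(self.positions.copy(), self.velocities.copy(),
                        self.time, self.step, self.seed, self.counter)

    def next_stream(self) -> int:
        """Derive the integer seed for the next kernel invocation."""
        mix = np.random.SeedSequence([self.seed, self.counter])
        return int(mix.generate_state(1)[0] % (2 ** 31 - 1))


@dataclass
class EnergyModel:
    """Flat parameter arrays driving the numba kernels."""

    n: int
    masses: np.ndarray
    nb_i: np.ndarray
    nb_j: np.ndarray
    nb_eps: np.ndarray
    nb_sig: np.ndarray
    nb_qq: np.ndarray
    debye: float
    b_i: np.ndarray
    b_j: np.ndarray
    b_k: np.ndarray
    b_r0: np.ndarray
    restraint_k: np.ndarray
    native_pos: np.ndarray
    lig_ids: np.ndarray
    lig_mfrac: np.ndarray
    ridge_z: np.ndarray
    ridge_h: np.ndarray
    ridge_w: float
    sphere_r: float
    sphere_k: float
    cyl_r: float
    cyl_k: float
    cyl_z: float
    cyl_s: float
    extra_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.extra_mask is None:
            self.extra_mask = np.zeros(self.n, dtype=np.bool_)

    def kernel_args(self, extra_k: float = 0.0):
        return (self.nb_i, self.nb_j, self.nb_eps, self.nb_sig, self.nb_qq,
                self.debye, self.b_i, self.b_j, self.b_k, self.b_r0,
                self.restraint_k, self.native_pos, extra_k, self.extra_mask,
                self.lig_ids, self.lig_mfrac, self.ridge_z, self.ridge_h,
                self.ridge_w, self.sphere_r, self.sphere_k,
                self.cyl_r, self.cyl_k, self.cyl_z, self.cyl_s)


def build_model(system: ToySystem) -> EnergyModel:
    """Assemble kernel parameter arrays from a built complex."""
    cfg = system.config
    ff = cfg.forcefield
    g = cfg.geometry
    n = system.n_beads
    charges = system.charges()
    eps = np.array([b.lj_epsilon for b in system.beads])
    sig = np.array([b.lj_radius for b in system.beads])
    masses = system.masses()

    lig = set(int(i) for i in system.ligand_bead_ids)
    bonded = {(min(i, j), max(i, j)) for i, j, _, _ in system.bonds}
    pairs_i, pairs_j = [], []
    lig_sorted = sorted(lig)
    for i in lig_sorted:
        for j in range(n):
            if j in lig:
                if j <= i or (i, j) in bonded:
                    continue
            pairs_i.append(i)
            pairs_j.append(j)
    pairs_i = np.array(pairs_i, dtype=np.int64)
    pairs_j = np.array(pairs_j, dtype=np.int64)
    nb_eps = np.sqrt(eps[pairs_i] * eps[pairs_j])
    nb_sig = 0.5 * (sig[pairs_i] + sig[pairs_j])
    nb_qq = COULOMB_K * charges[pairs_i] * charges[pairs_j] / ff.dielectric

    if system.bonds:
        b_i = np.array([b[0] for b in system.bonds], dtype=np.int64)
        b_j = np.array([b[1] for b in system.bonds], dtype=np.int64)
        b_k = np.array([b[2] for b in system.bonds], dtype=float)
        b_r0 = np.array([b[3] for b in system.bonds], dtype=float)
    else:
        b_i = np.empty(0, dtype=np.int64)
        b_j = np.empty(0, dtype=np.int64)
        b_k = np.empty(0, dtype=float)
        b_r0 = np.empty(0, dtype=float)

    lig_ids = system.ligand_bead_ids.astype(np.int64)
    lig_m = masses[lig_ids]
    return EnergyModel(
        n=n, masses=masses,
        nb_i=pairs_i, nb_j=pairs_j, nb_eps=nb_eps, nb_sig=nb_sig, nb_qq=nb_qq,
        debye=ff.debye_length,
        b_i=b_i, b_j=b_j, b_k=b_k, b_r0=b_r0,
        restraint_k=np.array([b.restraint_k for b in system.beads]),
        native_pos=system.native_positions.copy(),
        lig_ids=lig_ids, lig_mfrac=lig_m / lig_m.sum(),
        ridge_z=np.array([g.ridge_z, -g.ridge_z]),
        ridge_h=np.array([g.gateA_barrier, g.gateB_barrier]),
        ridge_w=g.ridge_width,
        sphere_r=ff.sphere_radius, sphere_k=ff.sphere_k,
        cyl_r=ff.cylinder_radius, cyl_k=ff.cylinder_k,
        cyl_z=ff.cylinder_z, cyl_s=ff.cylinder_smooth)


TERM_NAMES = ("bond", "lj", "coulomb", "restraint", "gate", "confinement")


def potential_energy(model: EnergyModel, positions: np.ndarray,
                     extra_k: float = 0.0) -> tuple[float, dict]:
    """Total potential energy and per-term breakdown, kJ/mol."""
    pos = np.ascontiguousarray(positions, dtype=float)
    if pos.shape != (model.n, 3):
        raise ValueError(f"positions must have shape ({model.n}, 3)")
    f = np.zeros_like(pos)
    terms, ok = _kernels._forces(pos, f, *model.kernel_args(extra_k))
    if not ok:
        raise SingularityError("coincident beads in a nonbonded or bonded pair")
    breakdown = dict(zip(TERM_NAMES, terms))
    return float(terms.sum()), breakdown


def forces(model: EnergyModel, positions: np.ndarray,
           extra_k: float = 0.0) -> np.ndarray:
    """Forces, kJ/mol/Å (exact negative gradient of the potential)."""
    pos = np.ascontiguousarray(positions, dtype=float)
    f = np.zeros_like(pos)
    terms, ok = _kernels._forces(pos, f, *model.kernel_args(extra_k))
    if not ok:
        raise SingularityError("coincident beads in a nonbonded or bonded pair")
    return f


def langevin_steps(model: EnergyModel, state: SimState, n_steps: int,
                   dt: float, friction: float, temperature: float,
                   extra_k: float = 0.0, record_stride: int = 0) -> np.ndarray:
    """Advance a state by ``n_steps`` of BAOAB; returns thinned frames.

    The state is advanced in place (positions, velocities, time, step,
    RNG counter).  With ``record_stride`` 0 no frames are stored.
    """
    if dt <= 0 or friction < 0:
        raise ValueError("require dt > 0 and friction >= 0")
    n_frames = (n_steps // record_stride + 1) if record_stride > 0 else 0
    frames = np.zeros((n_frames, model.n, 3))
    kT = KB * temperature
    seed = state.next_stream()
    state.counter += 1
    status = _kernels.run_langevin(
        state.positions, state.velocities, model.masses, dt, friction, kT,
        n_steps, seed, record_stride, frames, *model.kernel_args(extra_k))
    if status == 2:
        raise IntegrationError("non-finite coordinate during Langevin run")
    state.step += n_steps
    state.time += n_steps * dt
    return frames


def langevin_step(model: EnergyModel, state: SimState, dt: float,
                  friction: float, temperature: float) -> SimState:
    """Single BAOAB update (thin wrapper over :func:`langevin_steps`)."""
    if friction <= 0:
        raise ValueError("friction must be positive")
    langevin_steps(model, state, 1, dt, friction, temperature)
    return state


def thermal_velocities(model: EnergyModel, temperature: float,
                       rng: np.random.Generator) -> np.ndarray:
    sd = np.sqrt(KB * temperature / model.masses)[:, None]
    return rng.normal(size=(model.n, 3)) * sd


@dataclass
class EquilibrationReport:
    stages: list          # (extra_k, duration ps, mean restraint energy)
    minimized_energy: float
    state: SimState


def equilibrate(system: ToySystem, model: EnergyModel | None = None,
                ladder: list[tuple[float, float]] | None = None,
                seed: int = 0) -> EquilibrationReport:
    """Minimise, then run the restraint ladder on the ligand.

    The default ladder mirrors a multistage restraint-release protocol:
    extra ligand restraints of 20, 5, 2, 1, 0.5 kJ/mol/Å² (the classic
    2000→500→200→100→50 kJ/mol/nm² series, unit-converted), each held for
    a short toy stage.  Raises ValueError for a non-monotone ladder.
    """
    cfg = system.config.dynamics
    if model is None:
        model = build_model(system)
    if ladder is None:
        ladder = [(k, cfg.equil_stage_ps) for k in cfg.ladder]
    ks = [k for k, _ in ladder]
    if any(b > a for a, b in zip(ks, ks[1:])):
        raise ValueError("restraint ladder must be non-increasing")
    mask = np.zeros(model.n, dtype=np.bool_)
    mask[model.lig_ids] = True
    model.extra_mask = mask

    pos = system.native_positions.copy()
    e_min = _kernels.minimize(pos, cfg.minimize_steps, 1e-3,
                              *model.kernel_args(ladder[0][0]))
    rng = np.random.default_rng([seed, 17])
    state = SimState(pos, thermal_velocities(model, system.simulation_temperature, rng),
                     seed=seed)
    stages = []
    for extra_k, duration in ladder:
        n_steps = max(1, int(round(duration / cfg.dt)))
        langevin_steps(model, state, n_steps, cfg.dt, cfg.friction,
                       system.simulation_temperature, extra_k=extra_k)
        dx = state.positions[model.lig_ids] - model.native_pos[model.lig_ids]
        ladder_energy = 0.5 * extra_k * float((dx ** 2).sum())
        stages.append((extra_k, duration, ladder_energy))
    model.extra_mask = np.zeros(model.n, dtype=np.bool_)
    return EquilibrationReport(stages, e_min, state)


@dataclass
class Trajectory:
    """Thinned frames of a production run."""

    frames: np.ndarray     # (n_frames, n_beads, 3)
    times: np.ndarray      # ps
    temperature: float

    def __len__(self):
        return self.frames.shape[0]


def run_unbiased(system: ToySystem, state: SimState,
                 duration: float | None = None,
                 thinning: int | None = None,
                 model: EnergyModel | None = None) -> Trajectory:
    """Unbiased Langevin production at the variant's own temperature."""
    cfg = system.config.dynamics
    if duration is None:
        duration = cfg.production_ps
    if thinning is None:
        thinning = cfg.thinning
    if model is None:
        model = build_model(system)
    n_steps = int(round(duration / cfg.dt))
    if n_steps == 0:
        return Trajectory(state.positions[None].copy(), np.array([state.time]),
                          system.simulation_temperature)
    t0 = state.time
    frames = langevin_steps(model, state, n_steps, cfg.dt, cfg.friction,
                            system.simulation_temperature,
                            record_stride=thinning)
    times = t0 + np.arange(frames.shape[0]) * thinning * cfg.dt
    return Trajectory(frames, times, system.simulation_temperature)
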