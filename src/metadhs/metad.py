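"""Metadynamics on the contacts collective variable.

Standard (non-well-tempered) metadynamics: Gaussian hills of height
0.2 kJ/mol and width 2.0 contacts deposited every 2 ps at 300 K for both
variants.  A replica's residence time is the biased simulation time until
the CV first drops below 200 contacts; replicas integrate on until the
CV reaches an analysis floor (150 by default) so residence times can be
re-evaluated at nearby thresholds without re-simulation.  Campaigns run
30 independently seeded replicas per variant.

A 1D tilted double-well stub (exposing the CV directly) validates the
bias machinery: filled wells should recover the analytic free-energy
difference between the basins.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernels
from .colvars import coordination
from .energetics import EnergyModel, SimState, build_model, equilibrate
from .system import SwitchingParams, ToySystem, calibrate
from .units import KB


@dataclass(frozen=True)
class Hill:
    center: float        # CV units (contacts)
    sigma: float         # CV units
    height: float        # kJ/mol
    deposit_time: float  # ps

    def __post_init__(self):
        if self.sigma <= 0 or self.height <= 0:
            raise ValueError("hill sigma and height must be positive")


@dataclass
class MetadParams:
    hill_height: float = 0.2
    hill_sigma: float = 2.0
    pace: float = 2.0
    bias_temperature: float = 300.0
    unbind_threshold: float = 200.0
    trace_floor: float = 150.0
    max_time: float = 2000.0
    site_cutoff: float = 4.0

    def validate(self, dt: float, native_cv: float | None = None) -> None:
        steps = self.pace / dt
        if self.pace <= 0 or abs(steps - round(steps)) > 1e-9:
            raise ValueError("pace must be a positive multiple of dt")
        if native_cv is not None and self.unbind_threshold >= native_cv:
            raise ValueError("unbind threshold must lie below the native CV")


def bias_energy(cv_value: float, hills: list[Hill]) -> float:
    """History-dependent bias V(s) = sum_hills h * exp(-(s-c)^2 / 2 sigma^2)."""
    total = 0.0
    for h in hills:
        d = cv_value - h.center
        total += h.height * math.exp(-d * d / (2.0 * h.sigma ** 2))
    return total


def bias_derivative(cv_value: float, hills: list[Hill]) -> float:
    total = 0.0
    for h in hills:
        d = cv_value - h.center
        total += -h.height * math.exp(-d * d / (2.0 * h.sigma ** 2)) * d / h.sigma ** 2
    return total


def bias_force(positions: np.ndarray, hills: list[Hill],
               params: SwitchingParams,
               pair_list: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Per-bead bias force -(dV/dcv) * grad(cv) (chain rule through the CV)."""
    cv, grad = coordination(positions, pair_list, params, return_grad=True)
    return -bias_derivative(cv, hills) * grad


@dataclass
class ReplicaTrace:
    """Per-pace record of one metadynamics replica."""

    times: np.ndarray           # ps
    cv: np.ndarray              # contacts
    bias: np.ndarray            # kJ/mol, bias at the instantaneous CV
    ligand_com: np.ndarray      # (n_frames, 3) Å
    min_dist_gateA: np.ndarray  # Å, ligand to any gate-A bead
    min_dist_gateB: np.ndarray
    amine_gateA_dist: np.ndarray  # Å, amine bead to gate-A anion beads


@dataclass
class ReplicaOutcome:
    replica_id: int
    seed: int
    residence_time: float       # ps (== max_time when censored)
    censored: bool
    path_label: str             # A / B / undetermined
    com_at_unbind: float        # Å
    n_hills: int
    hills: list[Hill]
    trace: ReplicaTrace
    accel_factor: float = math.nan  # logged for information only
    intermediate_state: bool = False


def residence_from_trace(times: np.ndarray, cv: np.ndarray,
                         threshold: float) -> tuple[float, int] | None:
    """First time (and frame index) at which the CV drops below threshold."""
    below = np.nonzero(np.asarray(cv) < threshold)[0]
    if len(below) == 0:
        return None
    k = int(below[0])
    return float(times[k]), k


def run_metad_replica(system: ToySystem, params: MetadParams, seed: int,
                      state: SimState | None = None,
                      model: EnergyModel | None = None,
                      replica_id: int = 0) -> ReplicaOutcome:
    """One biased unbinding run; deterministic for a given seed."""
    if system.switching is None or system.native_cv is None:
        calibrate(system)
    dt = system.config.dynamics.dt
    friction = system.config.dynamics.friction
    params.validate(dt, system.native_cv)
    if model is None:
        model = build_model(system)
    if state is None:
        state = equilibrate(system, model=model, seed=seed).state
    else:
        state = state.copy()
        state.seed = seed
        state.counter = 1000

    sw = system.switching
    n_steps = int(round(params.max_time / dt))
    pace_steps = int(round(params.pace / dt))
    max_hills = n_steps // pace_steps + 1
    max_frames = max_hills + 1
    hill_c = np.zeros(max_hills)
    hill_h = np.zeros(max_hills)
    hill_t = np.zeros(max_hills)
    tr_t = np.zeros(max_frames)
    tr_cv = np.zeros(max_frames)
    tr_bias = np.zeros(max_frames)
    tr_com = np.zeros((max_frames, 3))
    tr_dga = np.zeros(max_frames)
    tr_dgb = np.zeros(max_frames)
    tr_salt = np.zeros(max_frames)

    charges = system.charges()
    gate_a = system.gateA_bead_ids.astype(np.int64)
    gate_b = system.gateB_bead_ids.astype(np.int64)
    gate_a_anions = gate_a[charges[gate_a] < 0]
    if len(gate_a_anions) == 0:
        gate_a_anions = gate_a  # fully neutralised gate: geometric evidence only
    amine = np.array([system.amine_bead_id], dtype=np.int64)
    li, sj = system.cv_pairs()

    kernel_seed = int(np.random.SeedSequence([seed, 7]).generate_state(1)[0]
                      % (2 ** 31 - 1))
    status, n_frames, n_hills_raw = _kernels.run_metad(
        state.positions, state.velocities, model.masses, dt, friction,
        KB * params.bias_temperature, n_steps, kernel_seed,
        pace_steps, params.hill_height, params.hill_sigma, params.trace_floor,
        li, sj, sw.r0, sw.d0, sw.n_exp, sw.m_exp,
        hill_c, hill_h, hill_t,
        tr_t, tr_cv, tr_bias, tr_com, tr_dga, tr_dgb, tr_salt,
        gate_a, gate_b, gate_a_anions, amine,
        *model.kernel_args())
    if status == 2:
        raise RuntimeError(f"metadynamics replica {replica_id} diverged")

    trace = ReplicaTrace(tr_t[:n_frames], tr_cv[:n_frames], tr_bias[:n_frames],
                         tr_com[:n_frames], tr_dga[:n_frames], tr_dgb[:n_frames],
                         tr_salt[:n_frames])
    hills = [Hill(hill_c[k], params.hill_sigma, hill_h[k], hill_t[k])
             for k in range(n_hills_raw)]

    crossing = residence_from_trace(trace.times, trace.cv, params.unbind_threshold)
    if crossing is None:
        residence, censored, k = params.max_time, True, n_frames - 1
    else:
        (residence, k), censored = crossing, False
    native_com = system.ligand_com(system.native_positions)
    com_at_unbind = float(np.linalg.norm(trace.ligand_com[k] - native_com))
    n_hills = sum(1 for h in hills if h.deposit_time <= residence)
    kT = KB * params.bias_temperature
    accel = float(np.mean(np.exp(np.clip(trace.bias[:k + 1] / kT, 0, 500))))

    from .analysis import classify_path  # stats layer owns the path rule
    if censored:
        label, intermediate = "undetermined", False
    else:
        record = classify_path(trace, system, params)
        label, intermediate = record.label, record.intermediate_state

    return ReplicaOutcome(
        replica_id=replica_id, seed=seed, residence_time=residence,
        censored=censored, path_label=label, com_at_unbind=com_at_unbind,
        n_hills=n_hills, hills=hills, trace=trace, accel_factor=accel,
        intermediate_state=intermediate)


@dataclass
class CampaignResult:
    variant: str
    master_seed: int
    outcomes: list[ReplicaOutcome]
    failures: list[tuple[int, str]] = field(default_factory=list)
    out_dir: Path | None = None

    def residence_times(self, include_censored: bool = True) -> np.ndarray:
        return np.array([o.residence_time for o in self.outcomes
                         if include_censored or not o.censored])


def replica_seeds(master_seed: int, n_replicas: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2 ** 31 - 1))
            for child in ss.spawn(n_replicas)]


def run_campaign(system: ToySystem, params: MetadParams, n_replicas: int,
                 master_seed: int, out_dir: str | Path | None = None,
                 state: SimState | None = None,
                 model: EnergyModel | None = None) -> CampaignResult:
    """Run ``n_replicas`` independent metadynamics replicas.

    Per-replica seeds derive from the master seed, so outcomes are
    reproducible and independent of execution order.  When ``out_dir`` is
    given, one HILLS and one COLVAR file per replica plus a campaign
    manifest are written.
    """
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    if system.switching is None:
        calibrate(system)
    if model is None:
        model = build_model(system)
    if state is None:
        state = equilibrate(system, model=model, seed=master_seed).state
    seeds = replica_seeds(master_seed, n_replicas)
    outcomes, failures = [], []
    for rid, seed in enumerate(seeds):
        try:
            outcomes.append(run_metad_replica(system, params, seed,
                                              state=state, model=model,
                                              replica_id=rid))
        except Exception as exc:  # failures recorded, campaign continues
            failures.append((rid, str(exc)))
    result = CampaignResult(system.variant, master_seed, outcomes, failures)
    if out_dir is not None:
        from .fileio import write_campaign
        result.out_dir = Path(out_dir)
        write_campaign(result, system, params, result.out_dir)
    return result


# --------------------------------------------------------------------------
# 1D double-well validation stub

@dataclass
class DoubleWell1D:
    """Tilted quartic double well U(x) = barrier (x²-1)² + tilt·x/2."""

    barrier: float = 6.0      # kJ/mol
    tilt: float = 2.2613      # kJ/mol; chosen so the exact dF is 2.0 at 300 K
    mass: float = 14.0

    def potential(self, x):
        x = np.asarray(x, dtype=float)
        return self.barrier * (x ** 2 - 1.0) ** 2 + 0.5 * self.tilt * x

    def free_energy_difference(self, temperature: float = 300.0) -> float:
        """Exact ΔF = F(right well) - F(left well) by quadrature."""
        kT = KB * temperature
        x = np.linspace(-2.5, 2.5, 20001)
        w = np.exp(-self.potential(x) / kT)
        left = np.trapezoid(np.where(x < 0, w, 0.0), x)
        right = np.trapezoid(np.where(x >= 0, w, 0.0), x)
        return float(-kT * (np.log(right) - np.log(left)))


def run_metad_1d(well: DoubleWell1D, seed: int, duration: float = 5000.0,
                 dt: float = 0.01, friction: float = 1.0,
                 temperature: float = 300.0, hill_height: float = 0.1,
                 hill_sigma: float = 0.3, pace: float = 1.0,
                 x0: float = -1.0):
    """Metadynamics on the 1D stub; returns bias records at the two minima."""
    n_steps = int(round(duration / dt))
    pace_steps = int(round(pace / dt))
    max_hills = n_steps // pace_steps + 1
    hill_c = np.zeros(max_hills)
    hill_hh = np.zeros(max_hills)
    rec_va = np.zeros(max_hills)
    rec_vb = np.zeros(max_hills)
    from scipy.optimize import minimize_scalar
    xa = minimize_scalar(well.potential, bounds=(-1.5, -0.5), method="bounded").x
    xb = minimize_scalar(well.potential, bounds=(0.5, 1.5), method="bounded").x
    status, n_hills, n_rec, _ = _kernels.dw_run(
        x0, dt, friction, KB * temperature, well.mass, n_steps, seed % (2**31 - 1),
        well.barrier, well.tilt, pace_steps, hill_height, hill_sigma,
        hill_c, hill_hh, rec_va, rec_vb, float(xa), float(xb), 0.0, False)
    return {"va": rec_va[:n_rec], "vb": rec_vb[:n_rec], "xa": float(xa),
            "xb": float(xb), "n_hills": n_hills}


def estimate_delta_f_1d(records: dict) -> float:
    """ΔF estimate: time-average of V(x_a) - V(x_b) over the final third."""
    va, vb = records["va"], records["vb"]
    k = 2 * len(va) // 3
    return float(np.mean(va[k:] - vb[k:]))


def first_passage_1d(well: DoubleWell1D, seed: int, x_stop: float = 0.9,
                     biased: bool = False, duration: float = 50000.0,
                     dt: float = 0.01, friction: float = 1.0,
                     temperature: float = 300.0, hill_height: float = 0.12,
                     hill_sigma: float = 0.25, pace: float = 0.5,
                     x0: float = -1.0) -> float | None:
    """First passage time from the left well past ``x_stop`` (ps)."""
    n_steps = int(round(duration / dt))
    pace_steps = int(round(pace / dt)) if biased else n_steps + 1
    max_hills = n_steps // max(pace_steps, 1) + 2
    hill_c = np.zeros(max_hills)
    hill_hh = np.zeros(max_hills)
    rec = np.zeros(1)
    status, _, _, fpt = _kernels.dw_run(
        x0, dt, friction, KB * temperature, well.mass, n_steps, seed % (2**31 - 1),
        well.barrier, well.tilt, pace_steps,
        hill_height if biased else 0.0, hill_sigma,
        hill_c, hill_hh, rec, rec.copy(), -1.0, 1.0, x_stop, True)
    return fpt if status == 0 else None
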