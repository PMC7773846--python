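"""Collective variables and geometric observables.

The central object is the contacts collective variable: a smooth
coordination number summing a rational switching function over all
ligand-bead × site-bead pairs,

    CV = sum_pairs s(r),   s(r) = (1 - x^n) / (1 - x^m),   x = (r - d0)/r0,

with n=6, m=12, d0=0 by default, calibrated so the native bound pose
scores ~650 contacts.  Also provided: mass-weighted centre-of-mass
displacement, per-residue minimum-distance maps, per-bead/per-residue
RMSF and a charge/distance salt-bridge indicator.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .system import SwitchingParams, ToySystem


def switch_value(r, params: SwitchingParams):
    """Rational switching function, elementwise over distances."""
    x = np.maximum((np.asarray(r, dtype=float) - params.d0) / params.r0, 0.0)
    n, m = params.n_exp, params.m_exp
    s = np.where(np.abs(x - 1.0) < 1e-9, n / m,
                 _safe_ratio(x, n, m))
    return s if s.shape else float(s)


def _safe_ratio(x, n, m):
    xn, xm = x ** n, x ** m
    denom = 1.0 - xm
    denom = np.where(np.abs(denom) < 1e-300, 1.0, denom)
    return (1.0 - xn) / denom


def switch_deriv(r, params: SwitchingParams):
    """d s / d r, elementwise; removable singularity at r = r0 handled."""
    r = np.asarray(r, dtype=float)
    x = np.maximum((r - params.d0) / params.r0, 0.0)
    n, m = params.n_exp, params.m_exp
    near = np.abs(x - 1.0) < 1e-6
    xn, xm = x ** n, x ** m
    denom = (1.0 - xm) ** 2
    denom = np.where(near, 1.0, denom)
    ds = (-n * x ** (n - 1) * (1.0 - xm) + m * x ** (m - 1) * (1.0 - xn)) / denom
    ds = np.where(near, n * (n - m) / (2.0 * m), ds)
    ds = np.where(x <= 0.0, 0.0, ds)
    out = ds / params.r0
    return out if out.shape else float(out)


def coordination(positions: np.ndarray,
                 pair_list: tuple[np.ndarray, np.ndarray],
                 params: SwitchingParams,
                 return_grad: bool = False):
    """Smooth contact count over a pair list; optional exact gradient.

    ``pair_list`` is a pair of index arrays (ligand beads, site beads).
    """
    li, sj = pair_list
    li = np.asarray(li, dtype=np.int64)
    sj = np.asarray(sj, dtype=np.int64)
    if len(li) == 0:
        warnings.warn("empty pair list; coordination = 0", stacklevel=2)
        value = 0.0
        return (value, np.zeros_like(positions)) if return_grad else value
    dvec = positions[li] - positions[sj]
    r = np.linalg.norm(dvec, axis=1)
    value = float(np.sum(switch_value(r, params)))
    if not return_grad:
        return value
    ds = switch_deriv(r, params)
    unit = dvec / np.maximum(r, 1e-12)[:, None]
    grad = np.zeros_like(positions)
    np.add.at(grad, li, ds[:, None] * unit)
    np.add.at(grad, sj, -ds[:, None] * unit)
    return value, grad


def com_displacement(positions: np.ndarray,
                     ligand_bead_ids: np.ndarray,
                     reference_positions: np.ndarray,
                     masses: np.ndarray) -> float:
    """Mass-weighted COM distance between current and reference positions."""
    ids = np.asarray(ligand_bead_ids)
    if len(ids) == 0:
        raise ValueError("empty ligand bead set")
    m = np.asarray(masses)[ids]
    com = (positions[ids] * m[:, None]).sum(0) / m.sum()
    ref = (reference_positions[ids] * m[:, None]).sum(0) / m.sum()
    return float(np.linalg.norm(com - ref))


@dataclass
class ContactSeries:
    """Per-residue minimum ligand distances over a trajectory."""

    residues: list[str]
    times: np.ndarray                   # ps, (n_frames,)
    distances: np.ndarray               # Å, (n_residues, n_frames)
    native_contact: np.ndarray          # bool, (n_residues, n_frames)
    threshold: float

    def __post_init__(self):
        if self.distances.shape != (len(self.residues), len(self.times)):
            raise ValueError("distance matrix shape mismatch")
        if (self.distances < 0).any():
            raise ValueError("negative distances")

    def to_frame(self):
        """Long-format DataFrame (residue, time, distance, native_flag)."""
        import pandas as pd
        rows = []
        for i, res in enumerate(self.residues):
            for j, t in enumerate(self.times):
                rows.append((res, t, self.distances[i, j],
                             bool(self.native_contact[i, j])))
        return pd.DataFrame(rows, columns=["residue", "time", "distance",
                                           "native_flag"])


def min_distance_map(trajectory: np.ndarray,
                     system: ToySystem,
                     site_residues: list[str] | None = None,
                     times: np.ndarray | None = None,
                     threshold: float = 4.5) -> ContactSeries:
    """Minimum ligand–residue distance per residue per frame.

    ``trajectory`` has shape (n_frames, n_beads, 3).
    """
    traj = np.asarray(trajectory)
    if traj.ndim == 2:
        traj = traj[None]
    residues = list(system.pocket_map) if site_residues is None else list(site_residues)
    for res in residues:
        if res not in system.pocket_map:
            raise KeyError(f"residue {res!r} not in pocket map")
    lig = system.ligand_bead_ids
    n_frames = traj.shape[0]
    if times is None:
        times = np.arange(n_frames, dtype=float)
    dist = np.empty((len(residues), n_frames))
    for i, res in enumerate(residues):
        ids = system.pocket_map[res]
        d = traj[:, ids, None, :] - traj[:, None, lig, :]
        dist[i] = np.sqrt((d ** 2).sum(-1)).reshape(n_frames, -1).min(1)
    return ContactSeries(residues, np.asarray(times, float), dist,
                         dist < threshold, threshold)


def rmsf(trajectory: np.ndarray, bead_ids: np.ndarray | None = None) -> np.ndarray:
    """Per-bead RMSF about the time-mean position (no superposition fit)."""
    traj = np.asarray(trajectory)
    if traj.ndim != 3 or traj.shape[0] < 2:
        raise ValueError("RMSF needs a trajectory with at least 2 frames")
    if bead_ids is not None:
        traj = traj[:, np.asarray(bead_ids), :]
    mean = traj.mean(0)
    return np.sqrt(((traj - mean) ** 2).sum(-1).mean(0))


def residue_rmsf(trajectory: np.ndarray, system: ToySystem) -> dict[str, float]:
    """Mean RMSF over each pocket residue's beads."""
    per_bead = rmsf(trajectory)
    return {res: float(per_bead[ids].mean())
            for res, ids in system.pocket_map.items()}


def salt_bridge_present(positions: np.ndarray,
                        cation_bead_ids: np.ndarray,
                        anion_bead_ids: np.ndarray,
                        charges: np.ndarray,
                        cutoff: float = 4.0) -> bool:
    """True iff oppositely charged groups approach within ``cutoff``.

    Raises if either group does not carry net charge of the expected sign —
    a neutral position (e.g. the T200 substitution) cannot salt-bridge.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    cat = np.asarray(cation_bead_ids)
    ani = np.asarray(anion_bead_ids)
    q = np.asarray(charges)
    if q[cat].sum() <= 0:
        raise ValueError("cation group carries no positive charge")
    if q[ani].sum() >= 0:
        raise ValueError("anion group carries no negative charge")
    d = np.linalg.norm(positions[cat][:, None, :] - positions[ani][None, :, :],
                       axis=-1)
    return bool(d.min() < cutoff)
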