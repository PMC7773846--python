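"""Run configuration: every tunable constant of the pipeline in one place.

All defaults correspond to the study conditions of the comparative
human-like vs archaeal-like unbinding campaign (hill height 0.2 kJ/mol,
sigma 2.0 contacts, pace 2 ps, unbinding threshold 200 contacts, gate
barriers 6.0/8.1 kJ/mol, restraint ladder 20/5/2/1/0.5 kJ/mol/Å²).
Configs round-trip through YAML and are content-hashed for manifests.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class GeometryConfig:
    """Geometry of the toy tunnel, ligand and pocket perturbations (Å)."""

    tunnel_length: float = 14.0
    tunnel_radius: float = 4.5
    wall_radius: float = 4.0       # ring radius of bulk residue cluster centres
    axial_spread: float = 1.0      # axial jitter of site beads within a residue
    cluster_spread: float = 1.0    # isotropic jitter of beads within a residue
    anchor_radius: float = 3.85    # radial reach of the amine-side anchor (D243)
    anchor_radius_d316: float = 4.4
    anchor_radius_e323: float = 5.0
    steric_radius: float = 4.6     # radial position of the N292/W248 position
    gate_z: float = 7.6            # axial position of gate residue clusters
    gate_charge_radius_a: float = 4.0
    gate_charge_radius_a2: float = 9.0  # E137/H96: second-shell position
    gate_charge_radius_b: float = 3.0
    d95_radial_shift: float = 1.5  # shorter sidechain reach of the D95 analog
    w248_radius_scale: float = 1.5
    n292_epsilon: float = 1.0      # h-bond-like LJ well of N292, kJ/mol
    bead_epsilon: float = 0.05     # base LJ well depth of pocket/ligand beads
    cation_radius: float = 5.5     # radial position of basic lining charges
    ligand_bond_length: float = 1.3
    charge_scale: float = 1.0      # global scale on pocket charges (tests)
    anchor_charge_scale: float = 1.0
    pocket_restraint_k: float = 20.0
    scaffold_restraint_k: float = 50.0
    gateA_barrier: float = 6.0     # kJ/mol, channel A ridge height
    gateB_barrier: float = 8.1     # kJ/mol, channel B ridge height
    ridge_z: float = 5.5
    ridge_width: float = 1.5


@dataclass
class ForceFieldConfig:
    """Nonbonded and confinement parameters."""

    dielectric: float = 20.0
    debye_length: float = 8.0      # Å, implicit-solvent screening length
    sphere_radius: float = 30.0    # reflective sphere about the pocket centre
    sphere_k: float = 100.0
    cylinder_radius: float = 4.0   # soft tunnel wall keeping exits axial
    cylinder_k: float = 10.0
    cylinder_z: float = 7.5
    cylinder_smooth: float = 0.5


@dataclass
class DynamicsConfig:
    """Langevin integrator and equilibration protocol."""

    dt: float = 0.01               # ps
    friction: float = 0.25         # 1/ps
    minimize_steps: int = 2000
    equil_stage_ps: float = 20.0
    ladder: tuple = (20.0, 5.0, 2.0, 1.0, 0.5)  # kJ/mol/Å² ligand restraints
    production_ps: float = 2000.0
    thinning: int = 100            # record one frame per `thinning` steps


@dataclass
class MetadConfig:
    hill_height: float = 0.2       # kJ/mol
    hill_sigma: float = 2.0        # contacts
    pace: float = 2.0              # ps
    bias_temperature: float = 300.0
    unbind_threshold: float = 200.0
    trace_floor: float = 150.0     # integrate until CV drops below this
    max_time: float = 2000.0       # ps, censoring horizon
    site_cutoff: float = 4.0       # Å, binding-site selection cutoff


@dataclass
class CalibrationConfig:
    target_native_cv: float = 650.0
    tolerance: float = 50.0
    r0_min: float = 3.0
    r0_max: float = 7.0
    n_exp: int = 6
    m_exp: int = 12


@dataclass
class AnalysisConfig:
    native_contact_threshold: float = 4.5
    salt_bridge_cutoff: float = 4.0
    dwell_ratio: float = 2.0       # gate A vs gate B contact-time factor
    dwell_min_ps: float = 5.0      # salt-bridge persistence for intermediate
    exit_window_frac: float = 0.9  # exit window starts at this * native CV
    thresholds: tuple = (150.0, 200.0, 250.0)
    bootstrap_samples: int = 10000


@dataclass
class ToyConfig:
    """Top-level configuration; schema_version guards file compatibility."""

    schema_version: int = 1
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    forcefield: ForceFieldConfig = field(default_factory=ForceFieldConfig)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    metad: MetadConfig = field(default_factory=MetadConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_config() -> ToyConfig:
    return ToyConfig()


def _coerce(cls, data: dict):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise KeyError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        if isinstance(value, dict):
            sub = known[name].default_factory  # type: ignore[union-attr]
            kwargs[name] = _coerce(sub, value)
        elif isinstance(value, list) and "tuple" in str(ftype):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def config_from_dict(data: dict) -> ToyConfig:
    return _coerce(ToyConfig, data)


def load_config(path: str | Path) -> ToyConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(cfg: ToyConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_listify(cfg.to_dict()), fh, sort_keys=False)


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def config_hash(cfg: ToyConfig) -> str:
    """Stable content hash of a configuration (for run manifests)."""
    payload = json.dumps(_listify(cfg.to_dict()), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
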