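"""Coarse-grained ligand–pocket complexes for the DHS/GC7 unbinding study.

The binding site of deoxyhypusine synthase (DHS) is a narrow tunnel at a
dimer interface; its inhibitor GC7 (N1-guanyl-1,7-diaminoheptane) is a
doubly charged linear molecule pinned by acidic anchor residues at both
termini.  This module builds a bead model of one such site in two
variants:

* ``human-like`` — three acidic anchors (D243 at the amine end, D316 and
  E323 at the guanidino end), an N292 position with an h-bond-like well,
  and two charged gate clusters (E136/E137 at the channel-A mouth, E180
  at the channel-B mouth).
* ``archaeal-like`` — the enumerated substitutions of the thermophilic
  enzyme: D243→T200 and D316→L272 lose their charge, E136→D95 keeps its
  charge but with a shorter radial reach, E137→H96 loses its charge,
  N292→W248 trades the h-bond well for steric bulk, while E180→E141 and
  the E323 analog are conserved.  10 of the 25 pocket positions differ.

Each residue is a cluster of heavy beads (counts from amino-acid
heavy-atom numbers, mean ≈ 8 beads/residue); the ligand is 9 beads with
+1 charges on the terminal guanidinium and amine beads; a restrained
6-bead scaffold stands in for the adjacent NAD cofactor.
"""
from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .config import ToyConfig, default_config

VARIANTS = ("human-like", "archaeal-like")

#: heavy-atom counts per amino-acid one-letter code (bead count per residue)
HEAVY_ATOMS = {
    "G": 4, "A": 5, "S": 6, "C": 6, "T": 7, "V": 7, "P": 7, "L": 8,
    "I": 8, "N": 8, "D": 8, "M": 8, "Q": 9, "E": 9, "K": 9, "H": 10,
    "R": 11, "F": 11, "Y": 12, "W": 14,
}

ROLES = ("anchor_amine", "anchor_guanidino", "gateA", "gateB", "bulk", "steric")


class CalibrationError(RuntimeError):
    """Raised when no switching radius reaches the target native CV."""


@dataclass(frozen=True)
class PocketEntry:
    position_index: int
    human_label: str
    archaeal_label: str
    conserved: bool
    role: str


@dataclass
class PocketTable:
    """The 25 ordered binding-site positions shared by the two variants."""

    entries: list[PocketEntry]

    def validate(self) -> None:
        if len(self.entries) != 25:
            raise ValueError(f"pocket table must have 25 entries, got {len(self.entries)}")
        non_conserved = [e for e in self.entries if not e.conserved]
        if len(non_conserved) != 10:
            raise ValueError("exactly 10 positions must be non-conserved")
        pairs = {(e.human_label, e.archaeal_label) for e in non_conserved}
        required = {("D243", "T200"), ("D316", "L272"), ("E136", "D95"),
                    ("E137", "H96"), ("N292", "W248")}
        if not required <= pairs:
            raise ValueError(f"missing substitution pairs: {required - pairs}")
        conserved_pairs = {(e.human_label, e.archaeal_label)
                           for e in self.entries if e.conserved}
        if ("E180", "E141") not in conserved_pairs:
            raise ValueError("(E180, E141) must be conserved")
        if not any(h == "E323" for h, _ in conserved_pairs):
            raise ValueError("the E323 analog must be conserved")
        for e in self.entries:
            if e.role not in ROLES:
                raise ValueError(f"unknown role {e.role!r}")

    def __iter__(self):
        return iter(self.entries)


def default_pocket_table() -> PocketTable:
    """Canonical 25-position table.

    The published site comparison names six substitution pairs and two conserved
    acidic positions; the remaining positions are acknowledged inventions
    chosen to be chemically unremarkable (bulk tunnel lining).
    """
    E = PocketEntry
    entries = [
        E(0,  "E136", "D95",  False, "gateA"),
        E(1,  "E137", "H96",  False, "gateA"),
        E(2,  "E180", "E141", True,  "gateB"),
        E(3,  "D243", "T200", False, "anchor_amine"),
        E(4,  "N292", "W248", False, "steric"),
        E(5,  "D316", "L272", False, "anchor_guanidino"),
        E(6,  "E323", "E279", True,  "anchor_guanidino"),
        # tunnel lining, ordered bottom (-z) to top (+z); label-only swaps
        # at the non-conserved positions, basic residues placed z-symmetric
        E(7,  "I288", "V244", False, "bulk"),
        E(8,  "K105", "R64",  False, "bulk"),
        E(9,  "R177", "K138", False, "bulk"),
        E(10, "K150", "R111", False, "bulk"),
        E(11, "G239", "G196", True,  "bulk"),
        E(12, "S240", "S197", True,  "bulk"),
        E(13, "K104", "K63",  True,  "bulk"),
        E(14, "V129", "I88",  False, "bulk"),
        E(15, "W327", "W283", True,  "bulk"),
        E(16, "Y305", "Y261", True,  "bulk"),
        E(17, "A102", "A61",  True,  "bulk"),
        E(18, "K287", "K243", True,  "bulk"),
        E(19, "G314", "G270", True,  "bulk"),
        E(20, "S315", "S271", True,  "bulk"),
        E(21, "K317", "K273", True,  "bulk"),
        E(22, "R283", "R240", True,  "bulk"),
        E(23, "K319", "K275", True,  "bulk"),
        E(24, "F249", "F206", True,  "bulk"),
    ]
    table = PocketTable(entries)
    table.validate()
    return table


def pocket_identity(table: PocketTable) -> float:
    """Binding-site identity as a percentage of conserved positions."""
    if not isinstance(table, PocketTable):
        raise TypeError("expected a PocketTable")
    entries = table.entries
    if len(entries) == 0:
        raise ValueError("empty pocket table")
    conserved = sum(e.conserved for e in entries)
    return 100.0 * conserved / len(entries)


@dataclass
class BeadSpec:
    bead_id: int
    residue_label: str
    chain_tag: str          # one of A, B, ligand, scaffold
    position: np.ndarray    # 3-vector, Å
    charge: float           # e
    lj_epsilon: float       # kJ/mol
    lj_radius: float        # Å (per-bead sigma; pairs combine arithmetically)
    mass: float             # amu
    restraint_k: float      # kJ/mol/Å², 0 = unrestrained

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.lj_epsilon < 0 or self.lj_radius <= 0 or self.mass <= 0:
            raise ValueError("invalid LJ/mass parameters")
        if self.restraint_k < 0:
            raise ValueError("restraint_k must be >= 0")


@dataclass(frozen=True)
class SwitchingParams:
    """Rational switching function s(r) = (1-x^n)/(1-x^m), x = (r-d0)/r0."""

    r0: float
    d0: float = 0.0
    n_exp: int = 6
    m_exp: int = 12

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.d0 < 0:
            raise ValueError("require r0 > 0 and d0 >= 0")
        for e in (self.n_exp, self.m_exp):
            if e <= 0 or e % 2:
                raise ValueError("exponents must be even positive integers")
        if self.m_exp <= self.n_exp:
            raise ValueError("require m_exp > n_exp")


@dataclass
class ToySystem:
    variant: str
    beads: list[BeadSpec]
    bonds: list[tuple]                  # (i, j, k kJ/mol/Å², r0 Å)
    ligand_bead_ids: np.ndarray
    pocket_map: dict                    # residue_label -> bead id array
    gateA_bead_ids: np.ndarray
    gateB_bead_ids: np.ndarray
    simulation_temperature: float
    native_positions: np.ndarray
    table: PocketTable
    config: ToyConfig
    seed: int
    site_bead_ids: np.ndarray = field(default=None)
    scaffold_bead_ids: np.ndarray = field(default=None)
    amine_bead_id: int = -1
    guanidinium_bead_id: int = -1
    switching: SwitchingParams | None = None
    native_cv: float | None = None

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def positions(self) -> np.ndarray:
        return np.array([b.position for b in self.beads])

    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.beads])

    def charges(self) -> np.ndarray:
        return np.array([b.charge for b in self.beads])

    def cv_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Ligand-bead × site-bead index arrays defining the contacts CV."""
        li = np.repeat(self.ligand_bead_ids, len(self.site_bead_ids))
        sj = np.tile(self.site_bead_ids, len(self.ligand_bead_ids))
        return li.astype(np.int64), sj.astype(np.int64)

    def ligand_com(self, positions: np.ndarray | None = None) -> np.ndarray:
        pos = self.positions() if positions is None else positions
        m = self.masses()[self.ligand_bead_ids]
        return (pos[self.ligand_bead_ids] * m[:, None]).sum(0) / m.sum()


# per-variant parameter deltas at the named non-conserved positions ----------

def _residue_params(entry: PocketEntry, variant: str, cfg: ToyConfig) -> dict:
    g = cfg.geometry
    human = variant == "human-like"
    params = {"charge": 0.0, "eps": g.bead_epsilon, "sigma": 3.2, "reach": None}
    role = entry.role
    if role == "gateA":
        if entry.human_label == "E136":
            params["reach"] = g.gate_charge_radius_a + (0.0 if human else g.d95_radial_shift)
            params["charge"] = -1.0
        else:  # E137 / H96
            params["reach"] = g.gate_charge_radius_a2
            params["charge"] = -1.0 if human else 0.0
    elif role == "gateB":
        params["reach"] = g.gate_charge_radius_b
        params["charge"] = -1.0
    elif role == "anchor_amine":
        params["reach"] = g.anchor_radius
        params["charge"] = -1.0 if human else 0.0
    elif role == "anchor_guanidino":
        if entry.conserved:
            params["reach"] = g.anchor_radius_e323
            params["charge"] = -1.0        # E323 analog kept in both variants
        else:
            params["reach"] = g.anchor_radius_d316
            params["charge"] = -1.0 if human else 0.0
    elif role == "bulk" and entry.human_label[0] in "KR":
        # basic lining positions: outward-facing cations that keep the
        # pocket closer to electroneutral (identical in both variants)
        params["reach"] = g.cation_radius
        params["charge"] = 1.0
    elif role == "steric":
        params["reach"] = g.steric_radius
        if human:
            params["eps"] = g.n292_epsilon  # N292 h-bond-like well
        else:
            params["sigma"] = 3.2 * g.w248_radius_scale  # W248 steric bulk
    scale = g.charge_scale
    if role in ("anchor_amine", "anchor_guanidino"):
        scale *= g.anchor_charge_scale
    params["charge"] *= scale
    return params


# residue placement: axial position, azimuth (deg) per table index -----------

_PLACEMENT = {
    0: ("gate", +1, 0.0), 1: ("gate", +1, 180.0), 2: ("gate", -1, 90.0),
    3: ("special", 5.2, 30.0), 4: ("special", 3.8, 210.0),
    5: ("special", -5.0, 150.0), 6: ("special", -5.8, 270.0),
}


def _residue_geometry(entry: PocketEntry, cfg: ToyConfig) -> tuple[float, float]:
    """Return (z, azimuth_deg) of the residue cluster centre."""
    g = cfg.geometry
    idx = entry.position_index
    if idx in _PLACEMENT:
        kind, a, az = _PLACEMENT[idx]
        if kind == "gate":
            return a * g.gate_z, az
        return a, az
    # bulk lining: 18 positions evenly spread along the tunnel
    k = idx - 7
    z = -g.tunnel_length / 2 + g.tunnel_length * k / 17.0
    az = (137.508 * idx) % 360.0
    return z, az


def build_complex(variant: str,
                  geometry_overrides: dict | None = None,
                  seed: int = 0,
                  config: ToyConfig | None = None) -> ToySystem:
    """Build a coarse-grained pocket + ligand + scaffold complex.

    Deterministic for fixed ``(variant, overrides, seed)``.  Only documented
    geometry keys may be overridden.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    cfg = copy.deepcopy(config) if config is not None else default_config()
    if geometry_overrides:
        valid = set(vars(cfg.geometry))
        unknown = set(geometry_overrides) - valid
        if unknown:
            raise KeyError(f"unknown geometry override keys: {sorted(unknown)}")
        for k, v in geometry_overrides.items():
            setattr(cfg.geometry, k, v)
    g = cfg.geometry
    table = default_pocket_table()

    beads: list[BeadSpec] = []
    pocket_map: dict[str, np.ndarray] = {}
    gate_a, gate_b = [], []
    human = variant == "human-like"

    for entry in table:
        label = entry.human_label if human else entry.archaeal_label
        n_beads = HEAVY_ATOMS[entry.human_label[0]]
        z, az = _residue_geometry(entry, cfg)
        theta = math.radians(az)
        centre = np.array([g.wall_radius * math.cos(theta),
                           g.wall_radius * math.sin(theta), z])
        params = _residue_params(entry, variant, cfg)
        rng = np.random.default_rng([seed, entry.position_index])
        jitter = rng.normal(size=(n_beads - 1, 3))
        jitter[:, :2] *= g.cluster_spread
        jitter[:, 2] *= g.axial_spread
        chain = "A" if az < 180.0 else "B"
        ids = []
        for b in range(n_beads):
            if b == 0 and params["reach"] is not None:
                pos = np.array([params["reach"] * math.cos(theta),
                                params["reach"] * math.sin(theta), z])
            elif b == 0:
                pos = centre.copy()
            else:
                pos = centre + jitter[b - 1]
                # tunnel lining cannot penetrate the cavity: keep jittered
                # beads clear of the ligand axis inside the tunnel
                rho = math.hypot(pos[0], pos[1])
                clearance = 0.95 * g.wall_radius
                if rho < clearance:
                    pos[:2] *= clearance / max(rho, 1e-9)
            beads.append(BeadSpec(
                bead_id=len(beads), residue_label=label, chain_tag=chain,
                position=pos, charge=params["charge"] if b == 0 else 0.0,
                lj_epsilon=params["eps"], lj_radius=params["sigma"],
                mass=14.0, restraint_k=g.pocket_restraint_k))
            ids.append(beads[-1].bead_id)
        pocket_map[label] = np.array(ids)
        if entry.role == "gateA":
            gate_a.extend(ids)
        elif entry.role == "gateB":
            gate_b.extend(ids)

    site_ids = np.arange(len(beads))

    # ligand: guanidinium (bead 0, -z end) ... amine (bead 8, +z end)
    lig_ids = []
    for i in range(9):
        zi = (i - 4) * g.ligand_bond_length
        if i == 0:
            label, q, m, sig = "LIG-GU", 1.0, 59.0, 3.6
        elif i == 8:
            label, q, m, sig = "LIG-AM", 1.0, 30.0, 3.2
        else:
            label, q, m, sig = f"LIG-C{i}", 0.0, 14.0, 3.2
        beads.append(BeadSpec(
            bead_id=len(beads), residue_label=label, chain_tag="ligand",
            position=np.array([0.0, 0.0, zi]),
            charge=q, lj_epsilon=g.bead_epsilon, lj_radius=sig, mass=m, restraint_k=0.0))
        lig_ids.append(beads[-1].bead_id)
    lig_ids = np.array(lig_ids)

    # NAD scaffold: restrained neutral cluster near the guanidino end
    nad_rng = np.random.default_rng([seed, 1000])
    nad_theta = math.radians(200.0)
    nad_centre = np.array([6.5 * math.cos(nad_theta), 6.5 * math.sin(nad_theta), -6.8])
    nad_ids = []
    for b in range(6):
        pos = nad_centre + nad_rng.normal(scale=0.8, size=3)
        beads.append(BeadSpec(
            bead_id=len(beads), residue_label="NAD", chain_tag="scaffold",
            position=pos, charge=0.0, lj_epsilon=g.bead_epsilon, lj_radius=3.4,
            mass=110.0, restraint_k=g.scaffold_restraint_k))
        nad_ids.append(beads[-1].bead_id)

    # ligand connectivity: 1-2 bonds plus 1-3 pseudo-bonds (semi-rigid chain)
    bonds = []
    for a, b in zip(lig_ids[:-1], lig_ids[1:]):
        bonds.append((int(a), int(b), 800.0, g.ligand_bond_length))
    for a, b in zip(lig_ids[:-2], lig_ids[2:]):
        bonds.append((int(a), int(b), 100.0, 2.0 * g.ligand_bond_length))

    ids = [b.bead_id for b in beads]
    if len(set(ids)) != len(ids):
        raise AssertionError("bead ids not unique")

    positions = np.array([b.position for b in beads])
    sim_T = 300.0 if human else 348.0
    system = ToySystem(
        variant=variant, beads=beads, bonds=bonds, ligand_bead_ids=lig_ids,
        pocket_map=pocket_map, gateA_bead_ids=np.array(gate_a),
        gateB_bead_ids=np.array(gate_b), simulation_temperature=sim_T,
        native_positions=positions.copy(), table=table, config=cfg, seed=seed,
        site_bead_ids=site_ids, scaffold_bead_ids=np.array(nad_ids),
        amine_bead_id=int(lig_ids[-1]), guanidinium_bead_id=int(lig_ids[0]))
    return system


def select_binding_site(system: ToySystem, cutoff: float) -> list[str]:
    """Residues with any bead within ``cutoff`` of any ligand bead (native pose)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pos = system.native_positions
    lig = pos[system.ligand_bead_ids]
    labels = []
    for label, ids in system.pocket_map.items():
        d = np.linalg.norm(pos[ids][:, None, :] - lig[None, :, :], axis=-1)
        if d.min() < cutoff:
            labels.append(label)
    return labels


def _native_coordination(system: ToySystem, params: SwitchingParams) -> float:
    from .colvars import coordination
    li, sj = system.cv_pairs()
    return coordination(system.native_positions, (li, sj), params)


def calibrate_switching(system: ToySystem,
                        target_native_cv: float = 650.0,
                        tolerance: float = 50.0) -> SwitchingParams:
    """Bisect the switching radius so the native-pose CV hits the target.

    The coordination number is monotonically non-decreasing in r0, so a
    bisection on r0 in [3, 7] Å (n=6, m=12, d0=0 fixed) is exact.  Raises
    :class:`CalibrationError` when the target is unreachable in bounds.
    """
    if target_native_cv <= 0:
        raise ValueError("target_native_cv must be positive")
    cal = system.config.calibration
    lo, hi = cal.r0_min, cal.r0_max
    make = lambda r0: SwitchingParams(r0=r0, d0=0.0, n_exp=cal.n_exp, m_exp=cal.m_exp)
    f_lo = _native_coordination(system, make(lo)) - target_native_cv
    f_hi = _native_coordination(system, make(hi)) - target_native_cv
    if f_lo > tolerance or f_hi < -tolerance:
        raise CalibrationError(
            f"native CV spans [{f_lo + target_native_cv:.1f}, "
            f"{f_hi + target_native_cv:.1f}] on r0 in [{lo}, {hi}] Å; "
            f"target {target_native_cv} unreachable")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = _native_coordination(system, make(mid)) - target_native_cv
        if abs(f_mid) <= tolerance or (hi - lo) < 1e-7:
            break
        if f_mid > 0:
            hi = mid
        else:
            lo = mid
    params = make(0.5 * (lo + hi))
    value = _native_coordination(system, params)
    if not (target_native_cv - tolerance <= value <= target_native_cv + tolerance):
        raise CalibrationError(f"calibration failed: native CV {value:.1f}")
    return params


def calibrate(system: ToySystem, target: float | None = None,
              tolerance: float | None = None) -> ToySystem:
    """Calibrate and attach switching parameters and the native CV in place."""
    cal = system.config.calibration
    params = calibrate_switching(
        system,
        cal.target_native_cv if target is None else target,
        cal.tolerance if tolerance is None else tolerance)
    system.switching = params
    system.native_cv = _native_coordination(system, params)
    return system


@dataclass
class GeometryReport:
    d_star: float           # Å, displacement at which the CV first drops below 200
    native_cv: float
    ok: bool
    message: str
    displacements: np.ndarray
    cv_profile: np.ndarray


def validate_geometry(system: ToySystem, params: SwitchingParams,
                      threshold: float = 200.0,
                      d_max: float = 20.0, step: float = 0.1) -> GeometryReport:
    """Check that the 200-contact isosurface sits ~11 Å out along the exit axis.

    The ligand is rigidly translated along +z; the report flags geometries
    whose crossing distance d* falls outside [9, 13] Å and names the axial
    site-bead spread as the parameter to adjust.
    """
    from .colvars import coordination
    li, sj = system.cv_pairs()
    pos = system.native_positions.copy()
    displacements = np.arange(0.0, d_max + step / 2, step)
    cv = np.empty_like(displacements)
    for k, d in enumerate(displacements):
        trial = pos.copy()
        trial[system.ligand_bead_ids, 2] += d
        cv[k] = coordination(trial, (li, sj), params)
    below = np.nonzero(cv < threshold)[0]
    if len(below) == 0:
        return GeometryReport(math.nan, cv[0], False,
                              "CV never drops below threshold within scan range",
                              displacements, cv)
    d_star = float(displacements[below[0]])
    ok = 9.0 <= d_star <= 13.0
    msg = ("ok" if ok else
           f"d* = {d_star:.1f} Å outside [9, 13]; adjust geometry.axial_spread")
    return GeometryReport(d_star, float(cv[0]), ok, msg, displacements, cv)
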