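"""File formats: bead-model PDB/XYZ, HILLS/COLVAR tables, campaign manifests.

PDB encoding (one HETATM per bead): the residue label maps to
resName/resSeq (e.g. ``D243`` → ``ASP 243``), chain tags A/B/ligand/
scaffold map to chainID A/B/L/S, the occupancy column carries the bead
charge and the B-factor column the restraint constant.  HILLS and COLVAR
files follow the whitespace-separated ``#! FIELDS …`` dialect used by
common enhanced-sampling post-processing tools.
"""
from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import config_hash
from .system import BeadSpec, ToySystem

__version__ = "0.1.0"

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}
_THREE_TO_ONE = {v: k for k, v in _ONE_TO_THREE.items()}
_CHAIN_OUT = {"A": "A", "B": "B", "ligand": "L", "scaffold": "S"}
_CHAIN_IN = {v: k for k, v in _CHAIN_OUT.items()}


class PDBParseError(ValueError):
    pass


def _encode_residue(label: str) -> tuple[str, int, str]:
    """residue_label -> (resName, resSeq, atom name stem)."""
    if label.startswith("LIG"):
        return "GC7", 900, label.split("-", 1)[1][:3]
    if label == "NAD":
        return "NAD", 901, "NB"
    return _ONE_TO_THREE[label[0]], int(label[1:]), label[0]


def _decode_residue(res_name: str, res_seq: int, atom: str) -> str:
    if res_name == "GC7":
        return f"LIG-{atom.rstrip('0123456789') if atom in ('AM', 'GU') else atom}"
    if res_name == "NAD":
        return "NAD"
    return f"{_THREE_TO_ONE[res_name]}{res_seq}"


def write_pdb(system_or_beads, path: str | Path,
              positions: np.ndarray | None = None) -> None:
    """Write one HETATM record per bead (fixed PDB columns)."""
    beads = (system_or_beads.beads if isinstance(system_or_beads, ToySystem)
             else system_or_beads)
    with open(path, "w") as fh:
        fh.write(_pdb_block(beads, positions))
        fh.write("END\n")


def _pdb_block(beads, positions=None) -> str:
    lines = []
    counters: dict[tuple, int] = {}
    for k, b in enumerate(beads):
        res_name, res_seq, stem = _encode_residue(b.residue_label)
        key = (res_name, res_seq)
        counters[key] = counters.get(key, 0) + 1
        if b.residue_label.startswith("LIG"):
            name = stem  # AM / GU / C1.. are already unique
        else:
            name = f"{stem}{counters[key]}"[:4]
        pos = b.position if positions is None else positions[k]
        lines.append(
            f"HETATM{b.bead_id + 1:5d} {name:<4s}{res_name:>4s} "
            f"{_CHAIN_OUT[b.chain_tag]}{res_seq:4d}    "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
            f"{b.charge:6.2f}{b.restraint_k:6.2f}          \n")
    return "".join(lines)


def read_pdb(path: str | Path) -> list[BeadSpec]:
    """Parse a bead-model PDB back into BeadSpec records.

    LJ parameters and masses are not stored in PDB; parsed beads carry
    placeholder values for those fields.
    """
    beads = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.startswith("HETATM"):
                continue
            try:
                serial = int(line[6:11])
                atom = line[12:16].strip()
                res_name = line[17:21].strip()
                chain = line[21]
                res_seq = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                charge = float(line[54:60])
                restraint = float(line[60:66])
            except (ValueError, IndexError) as exc:
                raise PDBParseError(f"line {ln}: malformed HETATM record "
                                    f"({exc})") from exc
            beads.append(BeadSpec(
                bead_id=serial - 1,
                residue_label=_decode_residue(res_name, res_seq, atom),
                chain_tag=_CHAIN_IN.get(chain, chain),
                position=np.array([x, y, z]), charge=charge,
                lj_epsilon=0.4, lj_radius=3.2, mass=14.0,
                restraint_k=restraint))
    return beads


def write_pdb_trajectory(system: ToySystem, frames: np.ndarray,
                         path: str | Path) -> None:
    with open(path, "w") as fh:
        for m, frame in enumerate(frames, 1):
            fh.write(f"MODEL     {m:4d}\n")
            fh.write(_pdb_block(system.beads, frame))
            fh.write("ENDMDL\n")
        fh.write("END\n")


_XYZ_ELEMENT = {"A": "C", "B": "C", "ligand": "N", "scaffold": "P"}


def write_xyz(system: ToySystem, path: str | Path,
              frames: np.ndarray | None = None, comment: str = "") -> None:
    """Single- or multi-frame XYZ (element chosen per chain tag)."""
    if frames is None:
        frames = system.positions()[None]
    elif frames.ndim == 2:
        frames = frames[None]
    elements = [_XYZ_ELEMENT[b.chain_tag] for b in system.beads]
    with open(path, "w") as fh:
        for k, frame in enumerate(frames):
            fh.write(f"{len(elements)}\n{comment} frame {k}\n")
            for el, p in zip(elements, frame):
                fh.write(f"{el} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


# ---------------------------------------------------------------------------
# HILLS / COLVAR tables

def write_hills(hills, path: str | Path) -> None:
    times = [h.deposit_time for h in hills]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("hill deposit times must be non-decreasing")
    with open(path, "w") as fh:
        fh.write("#! FIELDS time cv sigma height\n")
        for h in hills:
            fh.write(f"{h.deposit_time:.6f} {h.center:.10g} "
                     f"{h.sigma:.10g} {h.height:.10g}\n")


def read_hills(path: str | Path):
    from .metad import Hill
    hills = []
    last_t = -np.inf
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path} line {ln}: expected 4 columns")
            t, c, s, h = map(float, parts)
            if t < last_t:
                raise ValueError(f"{path} line {ln}: non-monotone time")
            last_t = t
            hills.append(Hill(center=c, sigma=s, height=h, deposit_time=t))
    return hills


_COLVAR_FIELDS = ["time", "cv", "bias", "com_x", "com_y", "com_z",
                  "dist_gateA", "dist_gateB", "amine_gateA"]


def write_colvar(trace, path: str | Path) -> None:
    """COLVAR table: time, cv, bias plus the recorded geometric observables."""
    t = np.asarray(trace.times)
    if np.any(np.diff(t) < 0):
        raise ValueError("non-monotone times in trace")
    cols = np.column_stack([t, trace.cv, trace.bias, trace.ligand_com,
                            trace.min_dist_gateA, trace.min_dist_gateB,
                            trace.amine_gateA_dist])
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(_COLVAR_FIELDS) + "\n")
        for row in cols:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_colvar(path: str | Path):
    from .metad import ReplicaTrace
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#! FIELDS"):
            raise ValueError(f"{path}: missing #! FIELDS header")
        names = header.split()[2:]
        data = np.loadtxt(fh, ndmin=2)
    cols = {name: data[:, k] for k, name in enumerate(names)}
    t = cols["time"]
    if np.any(np.diff(t) < 0):
        raise ValueError(f"{path}: non-monotone time column")
    return ReplicaTrace(
        times=t, cv=cols["cv"], bias=cols["bias"],
        ligand_com=np.column_stack([cols["com_x"], cols["com_y"], cols["com_z"]]),
        min_dist_gateA=cols["dist_gateA"], min_dist_gateB=cols["dist_gateB"],
        amine_gateA_dist=cols["amine_gateA"])


# ---------------------------------------------------------------------------
# Campaign persistence and run manifests

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_campaign(result, system: ToySystem, params, out_dir: str | Path) -> Path:
    """Write HILLS/COLVAR per replica, an outcome table and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    rows = []
    for o in result.outcomes:
        hills_path = out / f"HILLS_rep{o.replica_id:02d}.dat"
        colvar_path = out / f"COLVAR_rep{o.replica_id:02d}.dat"
        write_hills(o.hills, hills_path)
        write_colvar(o.trace, colvar_path)
        files += [hills_path, colvar_path]
        rows.append((o.replica_id, o.seed, o.residence_time, o.censored,
                     o.path_label, o.com_at_unbind, o.n_hills,
                     o.intermediate_state, o.accel_factor))
    outcomes = pd.DataFrame(rows, columns=[
        "replica_id", "seed", "residence_time", "censored", "path_label",
        "com_at_unbind", "n_hills", "intermediate_state", "accel_factor"])
    outcomes_path = out / "outcomes.csv"
    outcomes.to_csv(outcomes_path, index=False)
    files.append(outcomes_path)
    manifest = {
        "tool_version": __version__,
        "variant": result.variant,
        "master_seed": result.master_seed,
        "config_hash": config_hash(system.config),
        "created": datetime.datetime.now().isoformat(timespec="seconds"),
        "metad_params": vars(params).copy(),
        "replica_seeds": [o.seed for o in result.outcomes],
        "failures": result.failures,
        "files": {f.name: _sha256(f) for f in files},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def load_campaign(out_dir: str | Path):
    """Rebuild a campaign result (outcomes + traces) from its files."""
    from .metad import CampaignResult, ReplicaOutcome
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    outcomes_df = pd.read_csv(out / "outcomes.csv")
    outcomes = []
    for _, row in outcomes_df.iterrows():
        rid = int(row.replica_id)
        trace = read_colvar(out / f"COLVAR_rep{rid:02d}.dat")
        hills = read_hills(out / f"HILLS_rep{rid:02d}.dat")
        outcomes.append(ReplicaOutcome(
            replica_id=rid, seed=int(row.seed),
            residence_time=float(row.residence_time),
            censored=bool(row.censored), path_label=str(row.path_label),
            com_at_unbind=float(row.com_at_unbind), n_hills=int(row.n_hills),
            hills=hills, trace=trace,
            accel_factor=float(row.accel_factor),
            intermediate_state=bool(row.intermediate_state)))
    return CampaignResult(manifest["variant"], manifest["master_seed"],
                          outcomes, manifest.get("failures", []), out)
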