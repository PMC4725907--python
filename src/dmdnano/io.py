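"""Trajectory file formats, run manifests and the replicate protocol.

Trajectories are written as extended XYZ (one block per frame, the comment
line carrying time, energies and the cubic box edge) plus a JSON sidecar
with the molecule map, bead metadata, configuration and seed — enough to
re-run or re-analyze the file without the original Python objects.  PDB
snapshots (one HETATM per bead, one chain letter per molecule) support
visualization.

``run_replicates`` mirrors the production protocol: several independent
simulations from different seeds, each analyzed over its last-half window,
aggregated into replicate means and standard deviations.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import analysis
from .engine import RunConfig, Trajectory, run
from .system_builder import (BEAD_CLASSES, SystemConfig, SystemState,
                             assemble_system)

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_pdb_snapshot",
    "RunManifest",
    "simulate_protocol",
    "run_replicates",
]

#: element symbol per bead class, for XYZ/PDB viewers only
_CLASS_ELEMENT = ("C", "S", "N", "K", "P", "F", "B", "O")

#: staged desk-scale protocol defaults (reduced time): a strongly coupled
#: thermalization stage removes the heat of chain collapse, then a weakly
#: coupled production stage lets whole molecules and clusters diffuse
PROTOCOL = {
    "equil_t": 2500.0,
    "equil_rate": 0.05,
    "prod_t": 14000.0,
    "prod_rate": 1e-4,
    "rescale_dt": 25.0,
    "frame_dt": 500.0,
}


class TrajectoryParseError(ValueError):
    """Malformed trajectory file (reported with a line number)."""


def write_trajectory(traj: Trajectory, path) -> None:
    """Extended-XYZ + JSON sidecar; lossless to 1e-6 A."""
    path = Path(path)
    sys = traj.system
    symbols = [_CLASS_ELEMENT[c] for c in sys.class_of]
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_beads}\n")
            fh.write(
                f"time={traj.times[f]:.6f} ke={traj.kinetic[f]:.8f} "
                f"pe={traj.potential[f]:.8f} box={traj.box_edge:.6f}\n")
            P = traj.positions[f]
            V = traj.velocities[f]
            for i in range(traj.n_beads):
                fh.write(
                    f"{symbols[i]} {P[i, 0]:.8f} {P[i, 1]:.8f} {P[i, 2]:.8f} "
                    f"{V[i, 0]:.8f} {V[i, 1]:.8f} {V[i, 2]:.8f}\n")
    sidecar = {
        "n_beads": int(traj.n_beads),
        "box_edge": float(traj.box_edge),
        "mol_of": sys.mol_of.tolist(),
        "species_of_mol": list(sys.species_of_mol),
        "class_of": sys.class_of.tolist(),
        "class_names": list(BEAD_CLASSES),
        "mass": sys.mass.tolist(),
        "residue_of": sys.residue_of.tolist(),
        "is_backbone": sys.is_backbone.astype(int).tolist(),
        "donors": sys.donors.tolist(),
        "acceptors": sys.acceptors.tolist(),
        "config": dataclasses.asdict(traj.config) if traj.config else None,
        "system_config": (dataclasses.asdict(sys.config)
                          if sys.config else None),
        "n_events": int(traj.n_events),
        "hb_counts": traj.hb_counts.tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar))


def read_trajectory(path) -> Trajectory:
    """Read an extended-XYZ trajectory written by :func:`write_trajectory`."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise TrajectoryParseError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    times, frames, vels, kes, pes = [], [], [], [], []
    box = float(meta["box_edge"])
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n = int(lines[ln].strip())
        except ValueError:
            raise TrajectoryParseError(
                f"{path}:{ln + 1}: expected bead count") from None
        if ln + 1 + n >= len(lines) + 1:
            raise TrajectoryParseError(
                f"{path}:{ln + 1}: truncated frame (need {n} beads)")
        header = dict(tok.split("=", 1)
                      for tok in lines[ln + 1].split() if "=" in tok)
        try:
            times.append(float(header["time"]))
            kes.append(float(header["ke"]))
            pes.append(float(header["pe"]))
        except KeyError as exc:
            raise TrajectoryParseError(
                f"{path}:{ln + 2}: missing header field {exc}") from None
        P = np.zeros((n, 3))
        V = np.zeros((n, 3))
        for i in range(n):
            parts = lines[ln + 2 + i].split()
            if len(parts) < 7:
                raise TrajectoryParseError(
                    f"{path}:{ln + 3 + i}: malformed bead line")
            P[i] = [float(x) for x in parts[1:4]]
            V[i] = [float(x) for x in parts[4:7]]
        frames.append(P)
        vels.append(V)
        ln += 2 + n
    if not frames:
        raise TrajectoryParseError(f"{path}: no frames")
    if len(meta["mol_of"]) != len(frames[0]):
        raise TrajectoryParseError(
            f"{path}: sidecar molecule map ({len(meta['mol_of'])}) does not "
            f"match bead count ({len(frames[0])})")
    n = len(frames[0])
    state = SystemState(
        positions=frames[0].copy(), velocities=vels[0].copy(),
        box_edge=box, time=times[0],
        mol_of=np.asarray(meta["mol_of"]),
        species_of_mol=list(meta["species_of_mol"]),
        class_of=np.asarray(meta["class_of"]),
        mass=np.asarray(meta["mass"]),
        radius=np.ones(n), charge=np.zeros(n),
        donors=np.asarray(meta.get("donors", np.zeros(n, int))),
        acceptors=np.asarray(meta.get("acceptors", np.zeros(n, int))),
        eps_scale=np.ones(n),
        residue_of=np.asarray(meta["residue_of"]),
        is_backbone=np.asarray(meta["is_backbone"], dtype=bool),
        bond_idx=np.zeros((0, 2), dtype=np.int64),
        bond_range=np.zeros((0, 2)))
    config = RunConfig(**meta["config"]) if meta.get("config") else None
    return Trajectory(
        times=np.asarray(times), positions=np.stack(frames),
        velocities=np.stack(vels), kinetic=np.asarray(kes),
        potential=np.asarray(pes),
        hb_counts=np.asarray(meta.get("hb_counts",
                                      np.zeros((len(frames), 3), int))),
        box_edge=box, system=state, config=config,
        n_events=int(meta.get("n_events", 0)))


def write_pdb_snapshot(state: SystemState, path) -> None:
    """One HETATM per bead; molecules get cycling chain identifiers."""
    chains = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    with open(path, "w") as fh:
        fh.write(f"CRYST1{state.box_edge:9.3f}{state.box_edge:9.3f}"
                 f"{state.box_edge:9.3f}  90.00  90.00  90.00 P 1\n")
        for i in range(state.n_beads):
            mol = int(state.mol_of[i])
            el = _CLASS_ELEMENT[state.class_of[i]]
            res = max(int(state.residue_of[i]), 1)
            x, y, z = state.positions[i]
            fh.write(
                f"HETATM{i + 1:5d} {el:<4}{'BEA':<4}"
                f"{chains[mol % 26]}{res:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2}\n")
        fh.write("END\n")


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _hash_config(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True).encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance of a replicate campaign; re-runnable from config + seeds."""

    config: dict
    config_hash: str
    seeds: list
    trajectory_paths: list = field(default_factory=list)
    trajectory_hashes: list = field(default_factory=list)
    failures: list = field(default_factory=list)
    software_version: str = "dmdnano 0.1.0"
    created: str = ""

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))

    def verify(self) -> bool:
        for p, h in zip(self.trajectory_paths, self.trajectory_hashes):
            if not Path(p).exists() or _hash_file(Path(p)) != h:
                return False
        return True


def simulate_protocol(system_config: SystemConfig, seed: int,
                      protocol: dict | None = None) -> Trajectory:
    """Assemble and run one staged replicate (thermalize, then produce).

    Returns the production-stage trajectory; its provenance records both
    stages.  The analysis window convention (last half) applies to the
    production stage.
    """
    p = dict(PROTOCOL)
    if protocol:
        p.update(protocol)
    state = assemble_system(dataclasses.replace(system_config, seed=seed))
    equil = run(state, config=RunConfig(
        t_max=p["equil_t"], frame_dt=p["equil_t"] / 2,
        thermostat_rate=p["equil_rate"], seed=seed,
        temperature=system_config.temperature))
    prod = run(equil.final_state, config=RunConfig(
        t_max=p["prod_t"], frame_dt=p["frame_dt"],
        thermostat_rate=p["prod_rate"], rescale_dt=p["rescale_dt"],
        seed=(seed + 7919) % (2 ** 31), temperature=system_config.temperature))
    prod.extra["protocol"] = p
    prod.extra["equil_events"] = equil.n_events
    return prod


def run_replicates(system_config: SystemConfig, n_replicates: int = 10,
                   base_seed: int = 1, workdir=None,
                   protocol: dict | None = None):
    """Independent replicates (seeds base_seed..base_seed+n-1) + aggregation.

    Each replicate is simulated with the staged protocol and analyzed over
    its last-half window.  Failed replicates are recorded in the manifest
    and aggregation proceeds over the completed ones.  Returns
    ``(manifest, aggregate, per_replicate_stats)``.
    """
    workdir = Path(workdir) if workdir else None
    cfg_dict = dataclasses.asdict(system_config)
    manifest = RunManifest(
        config=cfg_dict, config_hash=_hash_config(cfg_dict),
        seeds=[base_seed + k for k in range(n_replicates)],
        created=datetime.datetime.now().isoformat())
    stats = []
    for seed in manifest.seeds:
        try:
            traj = simulate_protocol(system_config, seed, protocol)
        except Exception as exc:   # noqa: BLE001 - recorded, not silenced
            manifest.failures.append({"seed": seed, "error": repr(exc)})
            continue
        window = analysis.steady_state_window(traj)
        stats.append(analysis.cluster_stats(traj, window))
        if workdir is not None:
            workdir.mkdir(parents=True, exist_ok=True)
            out = workdir / f"replicate_{seed}.xyz"
            write_trajectory(traj, out)
            manifest.trajectory_paths.append(str(out))
            manifest.trajectory_hashes.append(_hash_file(out))
    if not stats:
        raise RuntimeError("all replicates failed")
    aggregate = analysis.aggregate_replicates(stats)
    if workdir is not None:
        manifest.save(workdir / "manifest.json")
        (workdir / "aggregate.json").write_text(json.dumps(aggregate,
                                                           indent=2))
    return manifest, aggregate, stats
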