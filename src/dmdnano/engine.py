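"""Event-driven discrete molecular dynamics engine.

Between events every bead moves ballistically; an event is a pair of beads
reaching a discontinuity of their stepwise pair potential (hard core, well
boundary, bond wall, hydrogen-bond reaction distance), a thermostat
reassignment, or bookkeeping (cell crossing, frame emission).  Collisions
exchange an impulse along the line of centers only, conserving energy,
linear momentum and the pair's angular momentum about its center of mass;
an outward step of height dU is crossed only if the radial kinetic energy
(1/2) mu v_r^2 exceeds dU, otherwise the pair reflects.

Temperature is maintained by an Anderson thermostat: each bead's velocity
is redrawn from the Maxwell-Boltzmann distribution at exponentially
distributed intervals.  Rate 0 gives NVE dynamics.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .constants import KB
from .potentials import (HBondRule, PairTable, default_hbond_rule,
                         default_pair_table)
from .system_builder import BEAD_CLASSES, SystemState

__all__ = [
    "Event",
    "RunConfig",
    "Trajectory",
    "predict_pair_event",
    "resolve_collision",
    "thermostat_events",
    "run",
    "total_energy",
]

_KMAX = 8


@dataclass(frozen=True)
class Event:
    """One scheduled discontinuity."""

    time: float
    kind: str                      # core_bounce, shell_cross_in, ...
    participants: tuple
    boundary: float | None = None  # boundary distance (A) for pair events


@dataclass(frozen=True)
class RunConfig:
    """Engine run parameters (reduced time units)."""

    t_max: float = 1000.0
    frame_dt: float = 100.0
    max_events: int = 2_000_000_000
    temperature: float = 300.0
    thermostat_rate: float = 0.01   # per bead per reduced time; 0 = NVE
    seed: int = 0
    hbonds: bool = True
    debug_energy: bool = False
    debug_watch: tuple = (-1, -1)
    #: interval (reduced time) of global kinetic-energy rescaling to the
    #: target temperature; 0 disables.  Used by the aggregation protocol to
    #: drain the heat of assembly under very weak Anderson coupling.
    rescale_dt: float = 0.0


@dataclass
class Trajectory:
    """Frames plus full provenance (config + seed re-runnable)."""

    times: np.ndarray          # (F,)
    positions: np.ndarray      # (F, N, 3)
    velocities: np.ndarray     # (F, N, 3)
    kinetic: np.ndarray        # (F,) kcal/mol
    potential: np.ndarray      # (F,) kcal/mol
    hb_counts: np.ndarray      # (F, 3): peptide-ligand, pep-pep, lig-lig
    box_edge: float
    system: SystemState        # initial state (metadata source)
    config: RunConfig | None = None
    n_events: int = 0
    final_state: SystemState | None = None
    extra: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]

    def temperature(self) -> np.ndarray:
        """Instantaneous kinetic temperature per frame (K)."""
        n_dof = 3 * self.n_beads
        return 2.0 * self.kinetic / (n_dof * KB)

    def __post_init__(self):
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")


def predict_pair_event(r, v, boundaries):
    """Earliest time at which |r + v t| hits one of ``boundaries``.

    Returns (t, boundary) or None if the pair separates past every
    boundary.  ``r``/``v`` are relative (minimum-image) displacement and
    velocity vectors.
    """
    r = np.asarray(r, dtype=float)
    v = np.asarray(v, dtype=float)
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(v))):
        raise ValueError("NaN/inf in pair kinematics")
    r2 = float(r @ r)
    b = float(r @ v)
    v2 = float(v @ v)
    if v2 == 0.0:
        return None
    best = math.inf
    best_d = None
    for d in np.atleast_1d(np.asarray(boundaries, dtype=float)):
        t = _kernels._cross_time(r2, b, v2, d * d)
        if 0.0 <= t < best:
            best = t
            best_d = float(d)
    if best_d is None:
        return None
    return best, best_d


def resolve_collision(v_i, v_j, m_i, m_j, n_hat, dU):
    """Resolve a pair event at a step of height ``dU`` (kcal/mol).

    The impulse acts along the unit line of centers ``n_hat`` (from j to i).
    ``dU == 0`` denotes a hard wall (elastic reflection of the radial
    component); otherwise crossing happens iff the radial kinetic energy
    exceeds ``dU``, else the pair reflects.  Returns (v_i', v_j', crossed).
    """
    v_i = np.asarray(v_i, dtype=float)
    v_j = np.asarray(v_j, dtype=float)
    n = np.asarray(n_hat, dtype=float)
    n = n / np.linalg.norm(n)
    mu = m_i * m_j / (m_i + m_j)
    vr = float((v_i - v_j) @ n)
    if dU == 0.0:
        vrp = -vr
        dv = mu * (vrp - vr)
        return v_i + dv * n / m_i, v_j - dv * n / m_j, False
    if dU < 0.0 or vr * vr > 2.0 * dU / mu:
        vrp = math.copysign(math.sqrt(max(vr * vr - 2.0 * dU / mu, 0.0)), vr)
        crossed = True
    else:
        vrp = -vr
        crossed = False
    dv = mu * (vrp - vr)
    return v_i + dv * n / m_i, v_j - dv * n / m_j, crossed


def thermostat_events(rate: float, seed: int, n_beads: int, t_max: float):
    """Yield (time, bead) Anderson reassignments in causal order."""
    if rate < 0:
        raise ValueError("thermostat rate must be >= 0")
    if rate == 0:
        return
    rng = np.random.default_rng(seed)
    heap = [(rng.exponential(1.0 / rate), i) for i in range(n_beads)]
    heapq.heapify(heap)
    while heap:
        t, i = heapq.heappop(heap)
        if t > t_max:
            continue
        yield Event(time=t, kind="thermostat", participants=(i,))
        heapq.heappush(heap, (t + rng.exponential(1.0 / rate), i))


# ---------------------------------------------------------------------------
# kernel state assembly


def _build_tables(table: PairTable):
    nc = len(BEAD_CLASSES)
    nb = np.zeros(nc * nc, dtype=np.int64)
    br2 = np.zeros((nc * nc, _KMAX))
    lvl = np.zeros((nc * nc, _KMAX))
    for ia, a in enumerate(BEAD_CLASSES):
        for ib, b in enumerate(BEAD_CLASSES):
            pot = table.get(a, b)
            bounds = (pot.hardcore,) + pot.shell_radii
            m = len(bounds)
            if m > _KMAX:
                raise ValueError("too many shells for the kernel layout")
            p = ia * nc + ib
            nb[p] = m
            br2[p, :m] = np.square(bounds)
            lvl[p, :m - 1] = pot.shell_energies
    return nb, br2, lvl


def _build_bond_csr(state: SystemState):
    N = state.n_beads
    deg = np.zeros(N, dtype=np.int64)
    for i, j in state.bond_idx:
        deg[i] += 1
        deg[j] += 1
    bptr = np.zeros(N + 1, dtype=np.int64)
    bptr[1:] = np.cumsum(deg)
    bjarr = np.zeros(bptr[-1], dtype=np.int64)
    blo2 = np.zeros(bptr[-1])
    bhi2 = np.zeros(bptr[-1])
    fill = bptr[:-1].copy()
    for (i, j), (lo, hi) in zip(state.bond_idx, state.bond_range):
        for a, b in ((i, j), (j, i)):
            bjarr[fill[a]] = b
            blo2[fill[a]] = lo * lo
            bhi2[fill[a]] = hi * hi
            fill[a] += 1
    return bptr, bjarr, blo2, bhi2


def _interaction_range(state: SystemState, table: PairTable,
                       rule: HBondRule | None) -> float:
    present = {BEAD_CLASSES[c] for c in np.unique(state.class_of)}
    rmax = 0.0
    for a in present:
        for b in present:
            rmax = max(rmax, table.get(a, b).cutoff)
    if len(state.bond_range):
        rmax = max(rmax, float(state.bond_range[:, 1].max()))
    if rule is not None:
        rmax = max(rmax, rule.bond_range[1])
    return rmax


def _pack_state(state: SystemState, table: PairTable, config: RunConfig,
                rule: HBondRule | None):
    N = state.n_beads
    L = state.box_edge
    rmax = _interaction_range(state, table, rule)
    # cells of width >= rmax / n_layers; the neighbor search scans n_layers
    # cell layers in every direction so any interacting pair is covered
    M = int(min(2 * L // rmax, 48))
    if M < 2:
        raise ValueError(
            f"box edge {L} too small for interaction range {rmax}")
    n_layers = int(math.ceil(rmax * M / L))
    nb, br2, lvl = _build_tables(table)
    # per-class-pair hydrogen-bond reaction distance: at least 0.5 A beyond
    # the pair hard core so the reaction boundary never coincides with it
    ncls = len(BEAD_CLASSES)
    hbr2 = np.zeros(ncls * ncls)
    if rule is not None:
        for pidx in range(ncls * ncls):
            hc = math.sqrt(br2[pidx, 0])
            hbr2[pidx] = max(rule.bond_range[1], hc + 0.5) ** 2
    bptr, bjarr, blo2, bhi2 = _build_bond_csr(state)
    is_pep = state.is_peptide_mol[state.mol_of].astype(np.int64)
    nF = int(math.floor(config.t_max / config.frame_dt + 1e-9)) + 1
    arrays = dict(
        pos=state.positions.copy(), vel=state.velocities.copy(),
        ptime=np.zeros(N), mass=state.mass.copy(),
        cls=state.class_of.astype(np.int64), scl=state.eps_scale.copy(),
        is_pep=is_pep,
        bptr=bptr, bjarr=bjarr, blo2=blo2, bhi2=bhi2,
        nb=nb, br2=br2, lvl=lvl, hbr2=hbr2,
        don=state.donors.astype(np.int64), acc=state.acceptors.astype(np.int64),
        hbp=np.full((N, _kernels.HBMAX), -1, dtype=np.int64),
        hbrole=np.zeros((N, _kernels.HBMAX), dtype=np.int64),
        hbn=np.zeros(N, dtype=np.int64),
        don_used=np.zeros(N, dtype=np.int64),
        acc_used=np.zeros(N, dtype=np.int64),
        chead=np.full(M * M * M, -1, dtype=np.int64),
        cnext=np.full(N, -1, dtype=np.int64),
        cprev=np.full(N, -1, dtype=np.int64),
        ccell=np.zeros((N, 3), dtype=np.int64),
        ev_t=np.full(N, np.inf), ev_j=np.full(N, -1, dtype=np.int64),
        ev_d2=np.zeros(N), ev_ty=np.full(N, -99, dtype=np.int64),
        ev_snap=np.zeros(N, dtype=np.int64),
        e2_t=np.full(N, np.inf), e2_j=np.full(N, -1, dtype=np.int64),
        e2_d2=np.zeros(N), e2_ty=np.full(N, -99, dtype=np.int64),
        e2_snap=np.zeros(N, dtype=np.int64),
        bound_t=np.full(N, np.inf),
        cc_t=np.full(N, np.inf), cc_dim=np.zeros(N, dtype=np.int64),
        cc_dir=np.zeros(N, dtype=np.int64),
        th_t=np.full(N, np.inf), cnt=np.zeros(N, dtype=np.int64),
        iparams=np.array([len(BEAD_CLASSES), M, config.seed % (2 ** 31),
                          config.max_events, 1 if rule is not None else 0,
                          n_layers, 1 if config.debug_energy else 0,
                          config.debug_watch[0], config.debug_watch[1]],
                         dtype=np.int64),
        fparams=np.array([L, L / M, KB * config.temperature,
                          config.thermostat_rate, config.t_max,
                          config.frame_dt,
                          (rule.bond_range[1] ** 2 if rule else 0.0),
                          (-rule.bond_energy if rule else 0.0),
                          config.rescale_dt]),
        fpos=np.zeros((nF, N, 3)), fvel=np.zeros((nF, N, 3)),
        ft=np.zeros(nF), fke=np.zeros(nF), fpe=np.zeros(nF),
        fhb=np.zeros((nF, 3), dtype=np.int64),
        diag=np.zeros(12, dtype=np.int64),
    )
    return arrays


def run(system: SystemState, table: PairTable | None = None,
        config: RunConfig | None = None,
        hbond_rule: HBondRule | None = None) -> Trajectory:
    """Integrate ``system`` and return its trajectory.

    Deterministic given ``config.seed``.  Raises RuntimeError on an internal
    event-time regression (which would indicate a scheduling bug).
    """
    table = table if table is not None else default_pair_table()
    config = config or RunConfig()
    if config.hbonds and hbond_rule is None:
        hbond_rule = default_hbond_rule()
    if not config.hbonds:
        hbond_rule = None
    a = _pack_state(system, table, config, hbond_rule)
    status, n_events, nframes, pe, t_final, pe_check = _kernels.run_kernel(
        a["pos"], a["vel"], a["ptime"], a["mass"], a["cls"], a["scl"],
        a["is_pep"], a["bptr"], a["bjarr"], a["blo2"], a["bhi2"],
        a["nb"], a["br2"], a["lvl"], a["hbr2"], a["don"], a["acc"],
        a["hbp"], a["hbrole"], a["hbn"], a["don_used"], a["acc_used"],
        a["chead"], a["cnext"], a["cprev"], a["ccell"],
        a["ev_t"], a["ev_j"], a["ev_d2"], a["ev_ty"], a["ev_snap"],
        a["e2_t"], a["e2_j"], a["e2_d2"], a["e2_ty"], a["e2_snap"],
        a["bound_t"],
        a["cc_t"], a["cc_dim"], a["cc_dir"], a["th_t"], a["cnt"],
        a["iparams"], a["fparams"],
        a["fpos"], a["fvel"], a["ft"], a["fke"], a["fpe"], a["fhb"],
        a["diag"])
    if status == 2:
        raise RuntimeError(
            f"event-time regression at t={t_final} after {n_events} events")
    # final synchronous state
    dt = t_final - a["ptime"]
    final_pos = (a["pos"] + a["vel"] * dt[:, None]) % system.box_edge
    final = system.copy()
    final.positions = final_pos
    final.velocities = a["vel"].copy()
    final.time = t_final
    hb_pairs = [(int(i), int(a["hbp"][i, s]))
                for i in range(system.n_beads)
                for s in range(int(a["hbn"][i])) if a["hbp"][i, s] > i]
    return Trajectory(
        times=a["ft"][:nframes].copy(),
        positions=a["fpos"][:nframes].copy(),
        velocities=a["fvel"][:nframes].copy(),
        kinetic=a["fke"][:nframes].copy(),
        potential=a["fpe"][:nframes].copy(),
        hb_counts=a["fhb"][:nframes].copy(),
        box_edge=system.box_edge, system=system, config=config,
        n_events=int(n_events), final_state=final,
        extra={"status": int(status), "kernel_pe": float(pe),
               "kernel_pe_check": float(pe_check),
               "hb_pairs": hb_pairs,
               "diag": a["diag"].copy(),
               "counters": {"iterations": int(a["diag"][0]),
                            "stale": int(a["diag"][1]),
                            "spurious": int(a["diag"][2]),
                            "cell_crossings": int(a["diag"][3]),
                            "thermostat": int(a["diag"][4])}})


def total_energy(state: SystemState, table: PairTable | None = None,
                 hb_pairs=(), hbond_rule: HBondRule | None = None):
    """Reference (kinetic, potential) by direct O(N^2) shell lookup."""
    table = table if table is not None else default_pair_table()
    ke = 0.5 * float((state.mass[:, None] * state.velocities ** 2).sum())
    N = state.n_beads
    L = state.box_edge
    bonded = {tuple(sorted(p)) for p in map(tuple, state.bond_idx)}
    pe = 0.0
    pos = state.positions
    for i in range(N):
        d = pos[i + 1:] - pos[i]
        d -= L * np.round(d / L)
        r = np.sqrt((d ** 2).sum(axis=1))
        for jo, rij in enumerate(r):
            j = i + 1 + jo
            if (i, j) in bonded:
                continue
            pot = table.get(BEAD_CLASSES[state.class_of[i]],
                            BEAD_CLASSES[state.class_of[j]])
            edges = (pot.hardcore,) + pot.shell_radii
            if rij >= edges[-1]:
                continue
            for k in range(1, len(edges)):
                if rij < edges[k]:
                    pe += (pot.shell_energies[k - 1] *
                           state.eps_scale[i] * state.eps_scale[j])
                    break
    if hb_pairs:
        rule = hbond_rule or default_hbond_rule()
        pe += rule.bond_energy * len(tuple(hb_pairs))
    return ke, pe
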