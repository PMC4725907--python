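"""Synthetic trajectories and closed-form oracles for testing the analysis
stack without running production simulations.

The clustered-trajectory generator builds frames with a prescribed number
of clusters of known composition and spatial spread; the construction
guarantees that the transitive 5.5 A contact clustering has exactly the
generated ground truth (members of a cluster are chained at sub-cutoff
spacing, clusters are separated by more than twice their extent plus the
cutoff).  Distributional choices (uniform jitter, ring placement) are
recorded in the emitted metadata and make no claim of kinetic realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from .constants import KB
from .engine import RunConfig, Trajectory
from .system_builder import (BEAD_CLASSES, SystemConfig, SystemState,
                             build_species)

__all__ = [
    "ClusterSpec",
    "TwoBodySpec",
    "make_clustered_trajectory",
    "make_core_shell_trajectory",
    "bound_fraction_oracle",
    "make_ss_template",
    "make_ideal_gas",
    "union_find_clusters",
]


@dataclass(frozen=True)
class ClusterSpec:
    """Prescription for a synthetic clustered system.

    ``clusters`` is a list of (n_peptides, n_ligands, spread) with spread in
    Angstrom; ``separation`` is the center-to-center distance between
    cluster anchors and must exceed twice the maximum cluster extent plus
    the contact cutoff, so ground-truth clusters can never merge.
    """

    clusters: tuple
    separation: float = 40.0
    n_frames: int = 3
    jitter: float = 0.3
    seed: int = 0
    ligand_species: str = "curcumin"
    cutoff: float = 5.5
    spacing: float = 3.0          # intra-cluster molecule chaining distance

    def __post_init__(self):
        object.__setattr__(self, "clusters",
                           tuple(tuple(c) for c in self.clusters))

    def max_extent(self) -> float:
        worst = 0.0
        for n_p, n_l, *rest in self.clusters:
            spread = rest[0] if rest else 0.0
            n = n_p + n_l
            side = math.ceil(n ** (1.0 / 3.0))
            half_diag = self.spacing * (side - 1) * math.sqrt(3.0) / 2.0
            worst = max(worst, half_diag + spread + 5.0)
        return worst


@dataclass(frozen=True)
class TwoBodySpec:
    """Square-well two-body system for engine validation."""

    sigma: float = 4.0            # hardcore (A)
    lam: float = 1.5              # outer radius = lam * sigma
    epsilon: float = 2.0          # well depth (kcal/mol)
    box_edge: float = 40.0
    temperature: float = 300.0

    def __post_init__(self):
        if self.lam <= 1.0 or self.epsilon <= 0:
            raise ValueError("need lam > 1 and epsilon > 0")


def _peptide_blob(center):
    """A compact stand-in peptide: 3 backbone-class beads."""
    base = np.array([[-1.5, 0, 0], [0.0, 1.2, 0], [1.5, 0, 0]])
    return center + base


def make_clustered_trajectory(spec: ClusterSpec):
    """Synthetic Trajectory plus ground-truth molecule labels.

    Peptides are 3-bead backbone blobs; ligands use the real ligand bead
    classes placed compactly.  Within a cluster, molecules are chained at
    ``spec.spacing`` (< cutoff) so the cluster is contact-connected by
    construction; consecutive clusters sit on a cubic grid ``separation``
    apart.  Per-frame jitter moves whole molecules by at most ``jitter``.
    """
    if spec.separation <= 2 * spec.max_extent() + spec.cutoff:
        raise ValueError("separation too small: clusters could merge")
    for cl in spec.clusters:
        spread = cl[2] if len(cl) > 2 else 0.0
        if spread + spec.jitter > (spec.cutoff - spec.spacing) / 2 - 0.2:
            raise ValueError(
                "spread + jitter too large: intra-cluster connectivity "
                "would not be guaranteed")
    rng = np.random.default_rng(spec.seed)
    lig_topo = build_species(spec.ligand_species)
    lig_rel = np.array([[0.6 * k, 0.3 * (k % 2), 0.0]
                        for k in range(lig_topo.n_beads)])

    mol_positions = []   # per molecule: (n_beads, 3) template
    mol_species = []
    labels = []
    n_grid = max(1, math.ceil(len(spec.clusters) ** (1 / 3)))
    box = max(n_grid * spec.separation,
              2 * (spec.max_extent() + spec.cutoff) + 1.0) + spec.separation
    for c, cl in enumerate(spec.clusters):
        n_p, n_l = cl[0], cl[1]
        spread = cl[2] if len(cl) > 2 else 0.0
        gx, gy, gz = (c % n_grid, (c // n_grid) % n_grid, c // n_grid ** 2)
        center = (np.array([gx, gy, gz]) + 0.5) * spec.separation
        n_mol = n_p + n_l
        side = math.ceil(n_mol ** (1.0 / 3.0))
        half = 0.5 * spec.spacing * (side - 1)
        # serpentine walk over a compact cubic grid: consecutive molecules
        # always sit one grid spacing apart (< cutoff), so the cluster is
        # contact-connected by construction
        layer = [(gx if gy % 2 == 0 else side - 1 - gx, gy)
                 for gy in range(side) for gx in range(side)]
        path = []
        for gz in range(side):
            cells = layer if gz % 2 == 0 else layer[::-1]
            path.extend((gx, gy, gz) for gx, gy in cells)
        for k in range(n_mol):
            gx, gy, gz = path[k]
            anchor = center + spec.spacing * np.array([gx, gy, gz]) - half
            anchor += rng.uniform(-spread, spread, size=3)
            if k < n_p:
                mol_positions.append(_peptide_blob(anchor))
                mol_species.append("IAPP")
            else:
                mol_positions.append(anchor + lig_rel)
                mol_species.append(spec.ligand_species)
            labels.append(c)

    n_mol = len(mol_species)
    beads_per = [len(p) for p in mol_positions]
    N = sum(beads_per)
    mol_of = np.repeat(np.arange(n_mol), beads_per)
    class_of = np.zeros(N, dtype=np.int64)
    mass = np.ones(N)
    residue_of = np.full(N, -1, dtype=np.int64)
    is_backbone = np.zeros(N, dtype=bool)
    k = 0
    for m, s in enumerate(mol_species):
        if s == "IAPP":
            class_of[k:k + 3] = 0
            mass[k:k + 3] = 100.0
            residue_of[k:k + 3] = (1, 2, 3)
            is_backbone[k:k + 3] = True
            k += 3
        else:
            for b in build_species(s).beads:
                class_of[k] = BEAD_CLASSES.index(b.klass)
                mass[k] = b.mass
                k += 1

    frames = []
    for f in range(spec.n_frames):
        pos = np.zeros((N, 3))
        k = 0
        for m, tmpl in enumerate(mol_positions):
            shift = rng.uniform(-spec.jitter, spec.jitter, size=3)
            pos[k:k + len(tmpl)] = tmpl + shift
            k += len(tmpl)
        frames.append(np.mod(pos, box))
    positions = np.stack(frames)

    state = SystemState(
        positions=positions[0].copy(), velocities=np.zeros((N, 3)),
        box_edge=box, time=0.0, mol_of=mol_of, species_of_mol=mol_species,
        class_of=class_of, mass=mass, radius=np.ones(N), charge=np.zeros(N),
        donors=np.zeros(N, dtype=np.int64),
        acceptors=np.zeros(N, dtype=np.int64), eps_scale=np.ones(N),
        residue_of=residue_of, is_backbone=is_backbone,
        bond_idx=np.zeros((0, 2), dtype=np.int64),
        bond_range=np.zeros((0, 2)),
        config=None)
    times = np.arange(spec.n_frames, dtype=float)
    traj = Trajectory(
        times=times, positions=positions,
        velocities=np.zeros_like(positions),
        kinetic=np.zeros(spec.n_frames), potential=np.zeros(spec.n_frames),
        hb_counts=np.zeros((spec.n_frames, 3), dtype=np.int64),
        box_edge=box, system=state, config=None,
        extra={"generator": "make_clustered_trajectory",
               "spec": {"clusters": spec.clusters,
                        "separation": spec.separation,
                        "jitter_distribution": "uniform(+-jitter) per molecule",
                        "seed": spec.seed}})
    return traj, np.asarray(labels)


def make_core_shell_trajectory(core_radius: float = 3.0,
                               shell_radius: float = 8.0,
                               n_core: int = 12, n_shell: int = 12,
                               seed: int = 0):
    """Single cluster with ligand beads at the core and peptides outside.

    Core ligand molecules (aliphatic bead slightly inside, oxygen slightly
    outside) sit on a sphere of ``core_radius``; single-bead 'peptides' on a
    sphere of ``shell_radius``.  The gap is below the contact cutoff so the
    whole construct is one cluster.
    """
    rng = np.random.default_rng(seed)
    box = 60.0
    center = np.full(3, box / 2)

    def sphere_points(n, r):
        # Fibonacci sphere: deterministic, well-spread
        k = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * k / n)
        theta = math.pi * (1 + 5 ** 0.5) * k
        return r * np.stack([np.sin(phi) * np.cos(theta),
                             np.sin(phi) * np.sin(theta),
                             np.cos(phi)], axis=1)

    if n_shell != n_core:
        raise ValueError("core and shell bead counts must match so that "
                         "every shell bead touches its core partner")
    pos, class_of, mass, mol_of, species, residue, isbb = \
        [], [], [], [], [], [], []
    mol = 0
    for p in sphere_points(n_core, core_radius):
        u = p / np.linalg.norm(p)
        pos.append(center + p - 0.5 * u)        # aliphatic C, nearer core
        class_of.append(6)
        mass.append(50.0)
        mol_of.append(mol)
        residue.append(-1)
        isbb.append(False)
        pos.append(center + p + 0.5 * u)        # oxygen, nearer surface
        class_of.append(7)
        mass.append(70.0)
        mol_of.append(mol)
        residue.append(-1)
        isbb.append(False)
        species.append("curcumin")
        mol += 1
    for p in sphere_points(n_shell, shell_radius):
        pos.append(center + p)
        class_of.append(0)
        mass.append(100.0)
        mol_of.append(mol)
        residue.append(1)
        isbb.append(True)
        species.append("IAPP")
        mol += 1
    pos = np.asarray(pos)
    N = len(pos)
    state = SystemState(
        positions=pos.copy(), velocities=np.zeros((N, 3)), box_edge=box,
        time=0.0, mol_of=np.asarray(mol_of), species_of_mol=species,
        class_of=np.asarray(class_of, dtype=np.int64), mass=np.asarray(mass),
        radius=np.ones(N), charge=np.zeros(N),
        donors=np.zeros(N, dtype=np.int64),
        acceptors=np.zeros(N, dtype=np.int64), eps_scale=np.ones(N),
        residue_of=np.asarray(residue, dtype=np.int64),
        is_backbone=np.asarray(isbb),
        bond_idx=np.zeros((0, 2), dtype=np.int64), bond_range=np.zeros((0, 2)))
    positions = pos[None, :, :]
    return Trajectory(
        times=np.array([0.0]), positions=positions,
        velocities=np.zeros_like(positions), kinetic=np.zeros(1),
        potential=np.zeros(1), hb_counts=np.zeros((1, 3), dtype=np.int64),
        box_edge=box, system=state,
        extra={"generator": "make_core_shell_trajectory"})


def uniform_table(hardcore: float, shell_radii=(), shell_energies=()):
    """PairTable assigning one StepPotential to every class pair."""
    from .potentials import PairTable, StepPotential
    pot = StepPotential(hardcore, tuple(shell_radii), tuple(shell_energies))
    table = PairTable()
    for i, a in enumerate(BEAD_CLASSES):
        for b in BEAD_CLASSES[i:]:
            table.set(a, b, pot)
    return table


def ideal_gas_table():
    """No interactions beyond a vanishing hard core."""
    return uniform_table(1e-3, (2e-3,), (0.0,))


def square_well_table(spec: TwoBodySpec):
    """Single square well matching a TwoBodySpec."""
    return uniform_table(spec.sigma, (spec.lam * spec.sigma,),
                         (-spec.epsilon,))


def make_two_body_state(spec: TwoBodySpec, seed: int = 0) -> SystemState:
    """Two beads in a box, ready for a square-well engine run."""
    st = make_ideal_gas(2, spec.box_edge, spec.temperature, seed=seed)
    st.radius[:] = spec.sigma / 2
    return st


def bound_fraction_oracle(spec: TwoBodySpec) -> float:
    """Equilibrium probability that a square-well pair is bound.

    Configurational integral over the relative coordinate:
    Z_in = int_sigma^{lam sigma} 4 pi r^2 e^{eps/kT} dr,
    Z_out = V - (4/3) pi (lam sigma)^3, P = Z_in / (Z_in + Z_out).
    """
    kT = KB * spec.temperature
    boltz = math.exp(spec.epsilon / kT)
    z_in, _ = integrate.quad(
        lambda r: 4 * math.pi * r * r * boltz, spec.sigma,
        spec.lam * spec.sigma)
    v = spec.box_edge ** 3
    z_out = v - (4.0 / 3.0) * math.pi * (spec.lam * spec.sigma) ** 3
    return z_in / (z_in + z_out)


def make_ss_template(kind: str, n_residues: int,
                     bond: float = 3.8) -> np.ndarray:
    """Backbone-bead template chain sitting at the center of the H or E
    assignment windows (helix: theta 95 deg, tau 50 deg; extended:
    theta 127.5 deg, tau 180 deg)."""
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    if kind == "helix":
        theta, tau = 95.0, 50.0
    elif kind == "extended":
        theta, tau = 127.5, 180.0
    else:
        raise ValueError(f"unknown template kind {kind!r}")
    th = math.radians(theta)
    ta = math.radians(-tau)        # construction convention verified against
    #                                the assigner's dihedral sign
    xyz = np.zeros((n_residues, 3))
    xyz[1] = (bond, 0.0, 0.0)
    xyz[2] = xyz[1] + bond * np.array(
        [math.cos(math.pi - th), math.sin(math.pi - th), 0.0])
    for i in range(3, n_residues):
        a, b_, c = xyz[i - 3], xyz[i - 2], xyz[i - 1]
        bc = c - b_
        bc /= np.linalg.norm(bc)
        nrm = np.cross(b_ - a, bc)
        nrm /= np.linalg.norm(nrm)
        m = np.cross(nrm, bc)
        xyz[i] = (c + bc * (bond * math.cos(math.pi - th))
                  + m * (bond * math.sin(math.pi - th) * math.cos(ta))
                  + nrm * (bond * math.sin(math.pi - th) * math.sin(ta)))
    return xyz


def make_ideal_gas(n: int, box: float, temperature: float,
                   seed: int = 0) -> SystemState:
    """Non-interacting point beads (hardcore negligible, no wells)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, box, size=(n, 3))
    mass = np.full(n, 50.0)
    vel = rng.normal(size=(n, 3)) * np.sqrt(KB * temperature / mass)[:, None]
    return SystemState(
        positions=pos, velocities=vel, box_edge=box, time=0.0,
        mol_of=np.arange(n), species_of_mol=["gas"] * n,
        class_of=np.zeros(n, dtype=np.int64), mass=mass,
        radius=np.full(n, 1e-3), charge=np.zeros(n),
        donors=np.zeros(n, dtype=np.int64),
        acceptors=np.zeros(n, dtype=np.int64), eps_scale=np.ones(n),
        residue_of=np.full(n, -1, dtype=np.int64),
        is_backbone=np.zeros(n, dtype=bool),
        bond_idx=np.zeros((0, 2), dtype=np.int64),
        bond_range=np.zeros((0, 2)))


def union_find_clusters(n_molecules: int, mol_pairs) -> np.ndarray:
    """Brute-force union-find over molecule contact pairs (test oracle)."""
    parent = list(range(n_molecules))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in mol_pairs:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = [find(m) for m in range(n_molecules)]
    relabel = {}
    out = np.zeros(n_molecules, dtype=int)
    for m, r in enumerate(roots):
        if r not in relabel:
            relabel[r] = len(relabel)
        out[m] = relabel[r]
    return out
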