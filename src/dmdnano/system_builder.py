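"""Coarse-grained species library and simulation-box assembly.

The peptide model is two beads per residue (backbone + sidechain; glycine is
a single backbone bead).  Human IAPP (amylin) is the only peptide species:
37 residues, amidated C-terminus, disulfide crosslink between the cysteine
sidechains of residues 2 and 7, amyloidogenic segment 22-29.  Three small
molecules are provided as 2-5 bead graphs carrying the interaction features
that matter for nanoassembly: hydrophobicity/aromaticity (via bead class and
a per-bead well-depth scale), hydrogen-bond donor/acceptor capacities, and
charge.

Boxes are cubic and periodic.  The box edge scales as n^(1/3) so peptide
number density is identical for every system size (~6.4 mM at the default
63.7 A single-peptide edge).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import AVOGADRO, KB

__all__ = [
    "BEAD_CLASSES",
    "BeadSpec",
    "MoleculeTopology",
    "SystemConfig",
    "SystemState",
    "PlacementError",
    "IAPP_SEQUENCE",
    "build_species",
    "species_library",
    "species_library_to_yaml",
    "species_library_from_yaml",
    "box_edge",
    "peptide_concentration",
    "dls_mixture_concentration",
    "assemble_system",
]

#: canonical bead classes (index order is the engine's integer encoding)
BEAD_CLASSES = (
    "backbone",
    "sidechain_hydrophobic",
    "sidechain_polar",
    "sidechain_charged",
    "sidechain_aromatic",
    "ligand_aromatic",
    "ligand_aliphatic",
    "ligand_polar_O",
)

IAPP_SEQUENCE = "KCNTATCATQRLANFLVHSSNNFGAILSSTNVGSNTY"
AMYLOIDOGENIC_RANGE = (22, 29)
DISULFIDE_RESIDUES = (2, 7)

# average residue masses (amu); backbone bead takes BACKBONE_MASS, the
# sidechain bead the remainder.  Glycine is a single 57 amu bead.
_RESIDUE_MASS = {
    "G": 57.05, "A": 71.08, "S": 87.08, "C": 103.14, "T": 101.10,
    "V": 99.13, "L": 113.16, "I": 113.16, "N": 114.10, "Q": 128.13,
    "K": 128.17, "R": 156.19, "H": 137.14, "F": 147.18, "Y": 163.18,
}
BACKBONE_MASS = 56.0

_HYDROPHOBIC = set("LFIVA")
#: residues whose sidechain carries the aromatic class
_AROMATIC_RESIDUES = {15, 18, 23, 37}
_CHARGED_RESIDUES = {1, 11}

# hardcore radii per class (A); pair hardcore = sum of radii
_CLASS_RADIUS = {
    "backbone": 1.9,
    "sidechain_hydrophobic": 2.2,
    "sidechain_polar": 2.0,
    "sidechain_charged": 2.1,
    "sidechain_aromatic": 2.3,
    "ligand_aromatic": 2.2,
    "ligand_aliphatic": 1.9,
    "ligand_polar_O": 1.7,
}

# sidechain hydrogen-bond capacities by residue letter (donors, acceptors)
_SC_HBOND = {
    "S": (1, 1), "T": (1, 1), "N": (1, 1), "Q": (1, 1), "C": (0, 1),
    "K": (1, 0), "R": (1, 0), "H": (1, 1), "Y": (1, 1),
}

# bond-length windows (A).  Generous tolerances keep the event-driven bond
# vibration rate low while preserving connectivity.
BB_BOND = (3.04, 4.56)            # consecutive backbone beads, 3.8 +/- 20%
BB_ANGLE = (4.50, 7.40)           # backbone i,i+2 pseudo-angle constraint
SC_BOND = (2.10, 3.50)            # backbone -> sidechain, 2.8 +/- 25%
DISULFIDE_BOND = (3.8, 6.8)       # Cys2-Cys7 sidechain crosslink

#: per-species well-depth multipliers on ligand hydrophobic/aromatic beads
#: (the hydrophobicity ladder; see potentials module)
LIGAND_EPS_SCALE = {"curcumin": 1.30, "resveratrol": 0.80, "aspirin": 0.55}


class PlacementError(RuntimeError):
    """Raised when random placement cannot find an overlap-free box."""


@dataclass(frozen=True)
class BeadSpec:
    """One coarse-grained bead: class, mass, size, charge, H-bond capacity."""

    bead_id: str
    klass: str
    mass: float
    hardcore_radius: float
    charge: float = 0.0
    hbond_donors: int = 0
    hbond_acceptors: int = 0
    eps_scale: float = 1.0

    def __post_init__(self):
        if self.klass not in BEAD_CLASSES:
            raise ValueError(f"unknown bead class {self.klass!r}")
        if self.mass <= 0 or self.hardcore_radius <= 0:
            raise ValueError("mass and hardcore_radius must be positive")
        if not (0 <= self.hbond_donors <= 4 and 0 <= self.hbond_acceptors <= 4):
            raise ValueError("H-bond capacities must be in 0..4")


@dataclass(frozen=True)
class MoleculeTopology:
    """Bead graph of one species: beads, bonds, constraints, residue map."""

    species_name: str
    beads: tuple
    bonds: tuple            # (i, j, d_min, d_max)
    residue_map: tuple = ()  # bead index -> 1-based residue (peptides only)
    amyloidogenic_range: tuple | None = None
    permanent_crosslinks: tuple = ()

    def __post_init__(self):
        n = len(self.beads)
        for i, j, lo, hi in list(self.bonds) + list(self.permanent_crosslinks):
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError("bond indices out of range")
            if not lo < hi:
                raise ValueError("bond d_min must be < d_max")
        if self.is_peptide:
            if len(self.residue_map) != n:
                raise ValueError("peptide beads must map to residues")

    @property
    def is_peptide(self) -> bool:
        return bool(self.residue_map)

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def n_residues(self) -> int:
        return max(self.residue_map) if self.residue_map else 0

    @property
    def mass(self) -> float:
        return sum(b.mass for b in self.beads)

    def all_bonds(self):
        """Bonds plus permanent crosslinks."""
        return tuple(self.bonds) + tuple(self.permanent_crosslinks)

    def to_dict(self) -> dict:
        return {
            "species_name": self.species_name,
            "beads": [vars(b) | {} for b in self.beads],
            "bonds": [list(b) for b in self.bonds],
            "residue_map": list(self.residue_map),
            "amyloidogenic_range": list(self.amyloidogenic_range)
            if self.amyloidogenic_range else None,
            "permanent_crosslinks": [list(b) for b in self.permanent_crosslinks],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MoleculeTopology":
        return cls(
            species_name=d["species_name"],
            beads=tuple(BeadSpec(**b) for b in d["beads"]),
            bonds=tuple(tuple(b) for b in d["bonds"]),
            residue_map=tuple(d.get("residue_map") or ()),
            amyloidogenic_range=tuple(d["amyloidogenic_range"])
            if d.get("amyloidogenic_range") else None,
            permanent_crosslinks=tuple(
                tuple(b) for b in d.get("permanent_crosslinks", ())),
        )


def _sidechain_class(res_index: int, letter: str) -> str:
    if res_index in _AROMATIC_RESIDUES:
        return "sidechain_aromatic"
    if res_index in _CHARGED_RESIDUES:
        return "sidechain_charged"
    if letter in _HYDROPHOBIC:
        return "sidechain_hydrophobic"
    return "sidechain_polar"


def _build_iapp() -> MoleculeTopology:
    beads, bonds, resmap = [], [], []
    bb_index = {}
    sc_index = {}
    for r, letter in enumerate(IAPP_SEQUENCE, start=1):
        # the protonated N-terminus is modelled as a charged-class bead so
        # that screened electrostatics is a pure class-pair property
        klass_bb = "sidechain_charged" if r == 1 else "backbone"
        mass = _RESIDUE_MASS["G"] if letter == "G" else BACKBONE_MASS
        bb_index[r] = len(beads)
        beads.append(BeadSpec(
            bead_id=f"BB{r}", klass=klass_bb, mass=mass,
            hardcore_radius=_CLASS_RADIUS[klass_bb],
            charge=1.0 if r == 1 else 0.0,
            hbond_donors=1, hbond_acceptors=0 if r == 1 else 1))
        resmap.append(r)
        if r > 1:
            bonds.append((bb_index[r - 1], bb_index[r], *BB_BOND))
        if r > 2:
            bonds.append((bb_index[r - 2], bb_index[r], *BB_ANGLE))
        if letter == "G":
            continue
        klass = _sidechain_class(r, letter)
        donors, acceptors = _SC_HBOND.get(letter, (0, 0))
        if r in (15, 23):  # phenylalanine rings carry no hydroxyl/amine
            donors, acceptors = 0, 0
        sc_index[r] = len(beads)
        beads.append(BeadSpec(
            bead_id=f"SC{r}", klass=klass,
            mass=_RESIDUE_MASS[letter] - BACKBONE_MASS,
            hardcore_radius=_CLASS_RADIUS[klass],
            charge=1.0 if r in _CHARGED_RESIDUES else 0.0,
            hbond_donors=donors, hbond_acceptors=acceptors))
        resmap.append(r)
        bonds.append((bb_index[r], sc_index[r], *SC_BOND))
    crosslink = (sc_index[DISULFIDE_RESIDUES[0]], sc_index[DISULFIDE_RESIDUES[1]],
                 *DISULFIDE_BOND)
    return MoleculeTopology(
        species_name="IAPP", beads=tuple(beads), bonds=tuple(bonds),
        residue_map=tuple(resmap), amyloidogenic_range=AMYLOIDOGENIC_RANGE,
        permanent_crosslinks=(crosslink,))


def _ligand_bead(species, i, klass, mass, donors=0, acceptors=0):
    scale = LIGAND_EPS_SCALE[species] if klass in (
        "ligand_aromatic", "ligand_aliphatic") else 1.0
    return BeadSpec(
        bead_id=f"{species[:3].upper()}{i}", klass=klass, mass=mass,
        hardcore_radius=_CLASS_RADIUS[klass], hbond_donors=donors,
        hbond_acceptors=acceptors, eps_scale=scale)


def _build_curcumin() -> MoleculeTopology:
    # two phenol rings joined by a 3-bead keto-enol linker with one carbonyl O
    s = "curcumin"
    beads = (
        _ligand_bead(s, 1, "ligand_aromatic", 98.0, donors=1, acceptors=1),
        _ligand_bead(s, 2, "ligand_aliphatic", 50.0),
        _ligand_bead(s, 3, "ligand_polar_O", 72.38, acceptors=1),
        _ligand_bead(s, 4, "ligand_aliphatic", 50.0),
        _ligand_bead(s, 5, "ligand_aromatic", 98.0, donors=1, acceptors=1),
    )
    bond = (2.9, 3.9)
    bonds = tuple((i, i + 1, *bond) for i in range(4)) + tuple(
        (i, i + 2, 4.4, 6.7) for i in range(3))
    return MoleculeTopology(species_name=s, beads=beads, bonds=bonds)


def _build_resveratrol() -> MoleculeTopology:
    # trihydroxy-stilbene: two rings (3 OH total) joined by a CH=CH bridge
    s = "resveratrol"
    beads = (
        _ligand_bead(s, 1, "ligand_aromatic", 76.0, donors=2, acceptors=2),
        _ligand_bead(s, 2, "ligand_aliphatic", 38.12),
        _ligand_bead(s, 3, "ligand_aliphatic", 38.12),
        _ligand_bead(s, 4, "ligand_aromatic", 76.0, donors=1, acceptors=1),
    )
    bond = (2.70, 3.70)
    bonds = tuple((i, i + 1, *bond) for i in range(3)) + tuple(
        (i, i + 2, 4.2, 6.3) for i in range(2))
    return MoleculeTopology(species_name=s, beads=beads, bonds=bonds)


def _build_aspirin() -> MoleculeTopology:
    # phenyl ring + acetyl/carboxyl oxygens lumped into one polar-O bead
    s = "aspirin"
    beads = (
        _ligand_bead(s, 1, "ligand_aromatic", 105.0),
        _ligand_bead(s, 2, "ligand_polar_O", 75.16, donors=1, acceptors=2),
    )
    return MoleculeTopology(species_name=s, beads=beads,
                            bonds=((0, 1, 2.50, 3.50),))


_BUILDERS = {
    "IAPP": _build_iapp,
    "aspirin": _build_aspirin,
    "curcumin": _build_curcumin,
    "resveratrol": _build_resveratrol,
}


def build_species(name: str) -> MoleculeTopology:
    """Return the canonical topology for IAPP, aspirin, curcumin or resveratrol."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown species {name!r}; supported: {sorted(_BUILDERS)}") from None
    return builder()


def species_library() -> dict:
    """All four shipped topologies keyed by species name."""
    return {name: build_species(name) for name in _BUILDERS}


def species_library_to_yaml(path) -> None:
    """Serialize the shipped species library to a YAML document."""
    import yaml
    doc = {name: topo.to_dict() for name, topo in species_library().items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def species_library_from_yaml(path) -> dict:
    """Load a species library written by :func:`species_library_to_yaml`."""
    import yaml
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return {name: MoleculeTopology.from_dict(d) for name, d in doc.items()}


def box_edge(n_peptides: int, base_edge: float) -> float:
    """Cubic box edge holding ``n_peptides`` at the 1-peptide reference density."""
    if n_peptides < 1 or base_edge <= 0:
        raise ValueError("n_peptides >= 1 and base_edge > 0 required")
    return base_edge * n_peptides ** (1.0 / 3.0)


def peptide_concentration(n_peptides: int, edge: float) -> float:
    """Peptide molarity (mM) of ``n_peptides`` chains in a cubic box of ``edge`` A."""
    if edge <= 0:
        raise ValueError("edge must be positive")
    if n_peptides < 0:
        raise ValueError("n_peptides must be >= 0")
    volume_l = (edge * 1e-10) ** 3 * 1e3  # A^3 -> m^3 -> L
    return n_peptides / (AVOGADRO * volume_l) * 1e3


def dls_mixture_concentration(stock_conc: float, stock_volume: float,
                              final_volume: float) -> float:
    """Working concentration after topping a stock aliquot up to final_volume."""
    if stock_volume <= 0 or final_volume <= 0:
        raise ValueError("volumes must be positive")
    if stock_volume > final_volume:
        raise ValueError("stock_volume must not exceed final_volume")
    return stock_conc * stock_volume / final_volume


@dataclass(frozen=True)
class SystemConfig:
    """Simulation-box recipe: peptide count, ligand stoichiometry, seed."""

    n_peptides: int = 1
    ligand_species: str | None = None
    ligands_per_peptide: int = 2
    base_edge: float = 63.7
    temperature: float = 300.0
    seed: int = 0
    event_budget: int = 1_000_000
    thermostat_rate: float = 0.01
    #: ligand-only boxes: peptide count 0 with explicit n_ligands
    n_ligands: int | None = None
    box_override: float | None = None

    def __post_init__(self):
        if self.n_peptides < 0:
            raise ValueError("n_peptides must be >= 0")
        if self.ligands_per_peptide < 0:
            raise ValueError("ligands_per_peptide must be >= 0")
        if self.base_edge <= 0:
            raise ValueError("base_edge must be positive")

    @property
    def edge(self) -> float:
        if self.box_override is not None:
            return self.box_override
        return box_edge(max(self.n_peptides, 1), self.base_edge)

    @property
    def total_ligands(self) -> int:
        if self.n_ligands is not None:
            return self.n_ligands
        return self.n_peptides * self.ligands_per_peptide if self.ligand_species else 0


@dataclass
class SystemState:
    """Flattened bead-level state of one simulation box (periodic, cubic)."""

    positions: np.ndarray        # (N, 3) A, inside [0, L)
    velocities: np.ndarray       # (N, 3) A / reduced time
    box_edge: float
    time: float
    mol_of: np.ndarray           # bead -> molecule index
    species_of_mol: list         # molecule -> species name
    class_of: np.ndarray         # bead -> BEAD_CLASSES index
    mass: np.ndarray
    radius: np.ndarray
    charge: np.ndarray
    donors: np.ndarray
    acceptors: np.ndarray
    eps_scale: np.ndarray
    residue_of: np.ndarray       # 1-based residue, -1 for ligand beads
    is_backbone: np.ndarray
    bond_idx: np.ndarray         # (B, 2) int bead pairs
    bond_range: np.ndarray       # (B, 2) float (d_min, d_max)
    topologies: dict = field(default_factory=dict)
    config: SystemConfig | None = None

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_molecules(self) -> int:
        return len(self.species_of_mol)

    @property
    def is_peptide_mol(self) -> np.ndarray:
        return np.array([s == "IAPP" for s in self.species_of_mol])

    def copy(self) -> "SystemState":
        return replace(
            self, positions=self.positions.copy(),
            velocities=self.velocities.copy(), mol_of=self.mol_of.copy())


def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _build_peptide_conformer(topo: MoleculeTopology,
                             rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding backbone walk satisfying bond/angle/disulfide windows."""
    n_res = topo.n_residues
    bb_of = {}
    sc_of = {}
    for bead, r in enumerate(topo.residue_map):
        if topo.beads[bead].bead_id.startswith("BB"):
            bb_of[r] = bead
        else:
            sc_of[r] = bead
    radii = np.array([b.hardcore_radius for b in topo.beads])
    coords = np.zeros((topo.n_beads, 3))

    for attempt in range(500):
        placed = []          # bead indices placed so far
        ok = True
        bb_pos = {}
        # backbone walk
        for r in range(1, n_res + 1):
            if r == 1:
                p = np.zeros(3)
            elif r == 2:
                d = rng.normal(size=3)
                p = bb_pos[1] + 3.8 * d / np.linalg.norm(d)
            else:
                p = None
                for _ in range(120):
                    d = rng.normal(size=3)
                    cand = bb_pos[r - 1] + 3.8 * d / np.linalg.norm(d)
                    if not (BB_ANGLE[0] + 0.1 <
                            np.linalg.norm(cand - bb_pos[r - 2]) <
                            BB_ANGLE[1] - 0.1):
                        continue
                    # keep residues 3..7 close enough to close the disulfide
                    if 3 <= r <= DISULFIDE_RESIDUES[1]:
                        reach = 3.8 * (DISULFIDE_RESIDUES[1] - r)
                        if np.linalg.norm(cand - bb_pos[2]) > 5.5 + reach:
                            continue
                    clash = False
                    for b in placed:
                        if topo.residue_map[b] >= r - 1:
                            continue
                        if (np.linalg.norm(cand - coords[b]) <
                                radii[bb_of[r]] + radii[b]):
                            clash = True
                            break
                    if not clash:
                        p = cand
                        break
                if p is None:
                    ok = False
                    break
            bb_pos[r] = p
            coords[bb_of[r]] = p
            placed.append(bb_of[r])
        if not ok:
            continue
        # sidechains
        for r in range(1, n_res + 1):
            if r not in sc_of:
                continue
            bead = sc_of[r]
            p = None
            for _ in range(200):
                d = rng.normal(size=3)
                cand = bb_pos[r] + 2.8 * d / np.linalg.norm(d)
                if r == DISULFIDE_RESIDUES[1]:
                    dss = np.linalg.norm(cand - coords[sc_of[DISULFIDE_RESIDUES[0]]])
                    if not (DISULFIDE_BOND[0] + 0.2 < dss < DISULFIDE_BOND[1] - 0.2):
                        continue
                clash = False
                for b in placed:
                    if b == bb_of[r]:
                        continue
                    if np.linalg.norm(cand - coords[b]) < radii[bead] + radii[b]:
                        clash = True
                        break
                if not clash:
                    p = cand
                    break
            if p is None:
                ok = False
                break
            coords[bead] = p
            placed.append(bead)
        if ok:
            return coords - coords.mean(axis=0)
    raise PlacementError("could not build a peptide conformer")


def _build_ligand_conformer(topo: MoleculeTopology,
                            rng: np.random.Generator) -> np.ndarray:
    """Planar zig-zag chain at the midpoints of all bond/angle windows.

    The random orientation is applied later during placement, so the
    conformer itself is deterministic.
    """
    chain_bonds = [b for b in topo.bonds if b[1] == b[0] + 1]
    angle_bonds = [b for b in topo.bonds if b[1] == b[0] + 2]
    b_len = 0.5 * (chain_bonds[0][2] + chain_bonds[0][3])
    if angle_bonds:
        d13 = 0.5 * (angle_bonds[0][2] + angle_bonds[0][3])
    else:
        d13 = 2.0 * b_len
    s = min(d13 / 2.0, b_len)
    h = math.sqrt(max(b_len ** 2 - s ** 2, 0.0))
    coords = np.zeros((topo.n_beads, 3))
    for k in range(topo.n_beads):
        coords[k] = (k * s, (k % 2) * h, 0.0)
    for i, j, lo, hi in topo.bonds:
        dist = np.linalg.norm(coords[i] - coords[j])
        if not (lo < dist < hi):
            raise PlacementError(
                f"inconsistent bond windows for {topo.species_name}")
    return coords - coords.mean(axis=0)


def assemble_system(config: SystemConfig,
                    max_tries_per_molecule: int = 3000) -> SystemState:
    """Randomly place molecules in the periodic box without hardcore overlap.

    Positions and orientations are uniform; placement is rejection-sampled
    (the clash-removal role of the original minimization step).  Velocities
    are Maxwell-Boltzmann at ``config.temperature``, shifted to zero total
    momentum and rescaled to the exact target kinetic temperature.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lib = species_library()
    molecules = ["IAPP"] * config.n_peptides
    if config.total_ligands:
        if config.ligand_species is None:
            raise ValueError("n_ligands given without ligand_species")
        molecules += [config.ligand_species] * config.total_ligands
    if not molecules:
        raise ValueError("empty system")
    L = config.edge

    beads_per_mol = [lib[s].n_beads for s in molecules]
    N = sum(beads_per_mol)
    positions = np.zeros((N, 3))
    placed_n = 0
    radius_list = []
    for mi, sname in enumerate(molecules):
        topo = lib[sname]
        base = (_build_peptide_conformer(topo, rng) if topo.is_peptide
                else _build_ligand_conformer(topo, rng))
        radii = np.array([b.hardcore_radius for b in topo.beads])
        for attempt in range(max_tries_per_molecule):
            rot = _random_rotation(rng)
            shift = rng.uniform(0, L, size=3)
            cand = base @ rot.T + shift
            if placed_n:
                prev = positions[:placed_n]
                dr = _min_image(cand[:, None, :] - prev[None, :, :], L)
                dist = np.sqrt((dr ** 2).sum(axis=2))
                limit = radii[:, None] + np.asarray(radius_list)[None, :]
                if (dist < limit).any():
                    continue
            positions[placed_n:placed_n + topo.n_beads] = cand % L
            radius_list.extend(radii)
            placed_n += topo.n_beads
            break
        else:
            raise PlacementError(
                f"could not place molecule {mi} ({sname}) after "
                f"{max_tries_per_molecule} attempts; box too dense")

    # flatten metadata
    mol_of = np.repeat(np.arange(len(molecules)), beads_per_mol)
    class_of = np.zeros(N, dtype=np.int64)
    mass = np.zeros(N)
    radius = np.zeros(N)
    charge = np.zeros(N)
    donors = np.zeros(N, dtype=np.int64)
    acceptors = np.zeros(N, dtype=np.int64)
    eps_scale = np.ones(N)
    residue_of = np.full(N, -1, dtype=np.int64)
    is_backbone = np.zeros(N, dtype=bool)
    bond_idx = []
    bond_range = []
    offset = 0
    for sname in molecules:
        topo = lib[sname]
        for k, b in enumerate(topo.beads):
            g = offset + k
            class_of[g] = BEAD_CLASSES.index(b.klass)
            mass[g] = b.mass
            radius[g] = b.hardcore_radius
            charge[g] = b.charge
            donors[g] = b.hbond_donors
            acceptors[g] = b.hbond_acceptors
            eps_scale[g] = b.eps_scale
            if topo.is_peptide:
                residue_of[g] = topo.residue_map[k]
                is_backbone[g] = b.bead_id.startswith("BB")
        for i, j, lo, hi in topo.all_bonds():
            bond_idx.append((offset + i, offset + j))
            bond_range.append((lo, hi))
        offset += topo.n_beads

    velocities = rng.normal(size=(N, 3)) * np.sqrt(
        KB * config.temperature / mass)[:, None]
    p_total = (mass[:, None] * velocities).sum(axis=0)
    velocities -= p_total / mass.sum()
    ke = 0.5 * (mass[:, None] * velocities ** 2).sum()
    target = 1.5 * N * KB * config.temperature
    velocities *= math.sqrt(target / ke)

    return SystemState(
        positions=positions, velocities=velocities, box_edge=L, time=0.0,
        mol_of=mol_of, species_of_mol=list(molecules), class_of=class_of,
        mass=mass, radius=radius, charge=charge, donors=donors,
        acceptors=acceptors, eps_scale=eps_scale, residue_of=residue_of,
        is_backbone=is_backbone,
        bond_idx=np.array(bond_idx, dtype=np.int64).reshape(-1, 2),
        bond_range=np.array(bond_range, dtype=float).reshape(-1, 2),
        topologies={s: lib[s] for s in set(molecules)}, config=config)
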