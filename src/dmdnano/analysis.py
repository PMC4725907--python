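"""Aggregation statistics from trajectories.

Implements the full observable stack for peptide/ligand mixtures: atomic
(bead) contacts under a strict 5.5 A minimum-image rule, residue-ligand
contact frequencies, ligand binding fractions, inter-chain contact counts,
transitive contact clustering, cluster-size and composition histograms,
radial core/corona profiles around cluster centers of mass, a pseudo-angle /
pseudo-dihedral secondary-structure assignment for the two-bead peptide
model, and steady-state (last-half) window selection.

All statistics honour the periodic box via the minimum-image convention;
clusters are unwrapped across the boundary before centers of mass are
taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

__all__ = [
    "ContactMap",
    "ClusterAssignment",
    "ClusterStats",
    "RadialProfile",
    "SSAssignment",
    "FrameView",
    "contacts",
    "residue_ligand_contact_frequency",
    "binding_fraction",
    "interchain_contacts",
    "cluster_frame",
    "cluster_stats",
    "aggregate_replicates",
    "radial_profile",
    "secondary_structure",
    "ss_content",
    "hbond_stack_census",
    "steady_state_window",
]

DEFAULT_CUTOFF = 5.5

# secondary-structure thresholds (degrees) on the backbone pseudo-dihedral
# tau(i) = dihedral(i-1, i, i+1, i+2) and pseudo-angle theta(i) =
# angle(i-1, i, i+1); helix/strand require minimum run lengths
HELIX_TAU = (30.0, 70.0)
HELIX_THETA = (85.0, 105.0)
HELIX_MIN_RUN = 3
STRAND_TAU = 150.0           # |tau| >= this
STRAND_THETA = (110.0, 145.0)
STRAND_MIN_RUN = 2
TURN_THETA_MAX = 85.0        # direction reversal
TURN_MAX_RUN = 3


@dataclass
class FrameView:
    """One trajectory frame plus the bead-level metadata analysis needs."""

    positions: np.ndarray
    box_edge: float
    mol_of: np.ndarray
    species_of_mol: list
    class_of: np.ndarray
    residue_of: np.ndarray
    is_backbone: np.ndarray
    mass: np.ndarray
    time: float = 0.0
    frame_id: int = 0
    hb_pairs: np.ndarray | None = None   # (k, 2) reacted donor/acceptor pairs

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_molecules(self) -> int:
        return len(self.species_of_mol)

    @property
    def is_peptide_mol(self) -> np.ndarray:
        return np.array([s == "IAPP" for s in self.species_of_mol])

    @property
    def is_peptide_bead(self) -> np.ndarray:
        return self.is_peptide_mol[self.mol_of]


def frame_view(traj, f: int) -> FrameView:
    """FrameView for frame ``f`` of an engine Trajectory."""
    sys = traj.system
    return FrameView(
        positions=traj.positions[f], box_edge=traj.box_edge,
        mol_of=sys.mol_of, species_of_mol=sys.species_of_mol,
        class_of=sys.class_of, residue_of=sys.residue_of,
        is_backbone=sys.is_backbone, mass=sys.mass,
        time=float(traj.times[f]), frame_id=f)


def iter_frames(traj, window=None):
    lo, hi = window if window is not None else (0, traj.n_frames)
    for f in range(lo, hi):
        yield frame_view(traj, f)


@dataclass
class ContactMap:
    """Inter-molecular bead pairs closer (strictly) than the cutoff."""

    frame_id: int
    pairs: np.ndarray            # (m, 2) bead indices, i < j
    cutoff: float = DEFAULT_CUTOFF
    n_molecules: int = 0
    mol_of: np.ndarray | None = None

    def molecule_pairs(self) -> dict:
        """Counts of contacting bead pairs per molecule pair."""
        out: dict = {}
        for i, j in self.pairs:
            a, b = sorted((int(self.mol_of[i]), int(self.mol_of[j])))
            out[(a, b)] = out.get((a, b), 0) + 1
        return out


@dataclass
class ClusterAssignment:
    """Partition of molecules into transitive contact clusters."""

    frame_id: int
    labels: np.ndarray           # molecule -> cluster label

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def members(self, label: int) -> np.ndarray:
        return np.nonzero(self.labels == label)[0]


def contacts(frame: FrameView, cutoff: float = DEFAULT_CUTOFF) -> ContactMap:
    """Strict-inequality minimum-image contact map (inter-molecular only)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pos = np.mod(frame.positions, frame.box_edge)
    tree = cKDTree(pos, boxsize=frame.box_edge)
    cand = tree.query_pairs(cutoff, output_type="ndarray")
    if len(cand):
        d = pos[cand[:, 0]] - pos[cand[:, 1]]
        d -= frame.box_edge * np.round(d / frame.box_edge)
        dist = np.sqrt((d ** 2).sum(axis=1))
        keep = (dist < cutoff) & (frame.mol_of[cand[:, 0]] !=
                                  frame.mol_of[cand[:, 1]])
        cand = cand[keep]
    pairs = np.sort(cand.reshape(-1, 2), axis=1)
    return ContactMap(frame_id=frame.frame_id, pairs=pairs, cutoff=cutoff,
                      n_molecules=frame.n_molecules, mol_of=frame.mol_of)


def cluster_frame(cmap: ContactMap) -> ClusterAssignment:
    """Connected components of the molecule-level contact graph."""
    n = cmap.n_molecules
    if len(cmap.pairs):
        mp = cmap.mol_of[cmap.pairs]
        g = sparse.coo_matrix(
            (np.ones(len(mp)), (mp[:, 0], mp[:, 1])), shape=(n, n))
        g = g + g.T
    else:
        g = sparse.coo_matrix((n, n))
    _, labels = sparse.csgraph.connected_components(g, directed=False)
    return ClusterAssignment(frame_id=cmap.frame_id, labels=labels)


def residue_ligand_contact_frequency(traj, window=None,
                                     cutoff: float = DEFAULT_CUTOFF,
                                     n_residues: int = 37) -> np.ndarray:
    """Fraction of frames in which each residue touches any ligand bead.

    A residue is "in contact" in a frame when at least one of its beads is
    within the cutoff of at least one ligand bead (pooled over all peptide
    chains: the frequency counts chain-residue pairs).
    """
    freq = np.zeros(n_residues)
    n_frames = 0
    n_chains = 1
    for fv in iter_frames(traj, window):
        is_pep = fv.is_peptide_bead
        if not (~is_pep).any():
            n_frames += 1
            continue
        cm = contacts(fv, cutoff)
        n_frames += 1
        pep_mols = np.nonzero(fv.is_peptide_mol)[0]
        n_chains = max(n_chains, len(pep_mols))
        hit = set()
        for i, j in cm.pairs:
            for a, b in ((i, j), (j, i)):
                if is_pep[a] and not is_pep[b]:
                    hit.add((fv.mol_of[a], fv.residue_of[a]))
        for mol, res in hit:
            freq[res - 1] += 1
    if n_frames == 0:
        raise ValueError("empty window")
    return freq / (n_frames * n_chains)


def binding_fraction(traj, window=None, mode: str = "per_ligand",
                     cutoff: float = DEFAULT_CUTOFF) -> float:
    """Fraction of time ligands touch the peptide.

    ``per_ligand``: mean over ligands of the fraction of frames with >= 1
    peptide contact.  ``any_ligand``: fraction of frames in which any ligand
    touches any peptide.
    """
    if mode not in ("per_ligand", "any_ligand"):
        raise ValueError(f"unknown mode {mode!r}")
    bound = None
    n_frames = 0
    for fv in iter_frames(traj, window):
        is_pep_mol = fv.is_peptide_mol
        lig_mols = np.nonzero(~is_pep_mol)[0]
        if len(lig_mols) == 0:
            raise ValueError("no ligands in trajectory")
        if bound is None:
            bound = np.zeros(fv.n_molecules)
        cm = contacts(fv, cutoff)
        is_pep = fv.is_peptide_bead
        touched = set()
        for i, j in cm.pairs:
            if is_pep[i] != is_pep[j]:
                touched.add(int(fv.mol_of[j] if is_pep[i] else fv.mol_of[i]))
        for m in touched:
            bound[m] += 1
        n_frames += 1
    if n_frames == 0:
        raise ValueError("empty window")
    lig_mols = np.nonzero(~traj.system.is_peptide_mol)[0]
    frac = bound[lig_mols] / n_frames
    if mode == "per_ligand":
        return float(frac.mean())
    # any_ligand: a frame counts when at least one ligand was bound; recount
    any_bound = 0
    for fv in iter_frames(traj, window):
        cm = contacts(fv, cutoff)
        is_pep = fv.is_peptide_bead
        if any(is_pep[i] != is_pep[j] for i, j in cm.pairs):
            any_bound += 1
    return any_bound / n_frames


def interchain_contacts(traj, window=None, region=None,
                        cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Per-frame count of inter-peptide bead contacts (optionally a
    residue-interval restriction applied to both partners)."""
    if region is not None:
        lo, hi = region
        if not (1 <= lo <= hi <= 37):
            raise ValueError("region outside 1..37")
    series = []
    for fv in iter_frames(traj, window):
        cm = contacts(fv, cutoff)
        is_pep = fv.is_peptide_bead
        n = 0
        for i, j in cm.pairs:
            if is_pep[i] and is_pep[j]:
                if region is not None:
                    ri, rj = fv.residue_of[i], fv.residue_of[j]
                    if not (lo <= ri <= hi and lo <= rj <= hi):
                        continue
                n += 1
        series.append(n)
    return np.asarray(series)


@dataclass
class ClusterStats:
    """Windowed cluster statistics.

    ``size_hist[s]`` is the mass-weighted probability that a peptide chain
    sits in a cluster with s peptides, <s n_s> / N_peptides.  ``count_hist``
    is over the number of peptide-containing clusters per frame.
    ``composition`` maps (n_peptides, n_ligands) -> number of cluster
    observations (pooled over frames; ligand-only clusters included).
    """

    window: tuple
    n_frames: int
    n_peptides: int
    count_hist: dict = field(default_factory=dict)
    size_hist: dict = field(default_factory=dict)
    composition: dict = field(default_factory=dict)

    @property
    def mean_cluster_count(self) -> float:
        tot = sum(self.count_hist.values())
        return sum(k * v for k, v in self.count_hist.items()) / tot

    @property
    def modal_size(self) -> int:
        return max(self.size_hist, key=self.size_hist.get)

    @property
    def modal_count(self) -> int:
        return max(self.count_hist, key=self.count_hist.get)

    def ligand_peptide_ratio(self) -> float:
        """Pooled ligand:peptide ratio over peptide-containing clusters."""
        nl = sum(k[1] * v for k, v in self.composition.items() if k[0] > 0)
        np_ = sum(k[0] * v for k, v in self.composition.items() if k[0] > 0)
        if np_ == 0:
            raise ValueError("no peptide-containing clusters in window")
        return nl / np_


def cluster_stats(traj, window=None, cutoff: float = DEFAULT_CUTOFF,
                  precomputed=None) -> ClusterStats:
    """Histogram cluster counts, mass-weighted sizes and compositions."""
    if window is None:
        window = (0, traj.n_frames)
    is_pep_mol = traj.system.is_peptide_mol
    n_pep = int(is_pep_mol.sum())
    st = ClusterStats(window=tuple(window), n_frames=0, n_peptides=n_pep)
    size_acc: dict = {}
    for fv in iter_frames(traj, window):
        ca = (precomputed[fv.frame_id] if precomputed is not None
              else cluster_frame(contacts(fv, cutoff)))
        st.n_frames += 1
        npep_of = np.zeros(ca.n_clusters, dtype=int)
        nlig_of = np.zeros(ca.n_clusters, dtype=int)
        for mol, lab in enumerate(ca.labels):
            if is_pep_mol[mol]:
                npep_of[lab] += 1
            else:
                nlig_of[lab] += 1
        n_pep_clusters = int((npep_of > 0).sum())
        st.count_hist[n_pep_clusters] = st.count_hist.get(n_pep_clusters, 0) + 1
        for s, nl in zip(npep_of, nlig_of):
            key = (int(s), int(nl))
            st.composition[key] = st.composition.get(key, 0) + 1
        for s in npep_of[npep_of > 0]:
            # mass weighting: a cluster of s peptides holds s chains
            size_acc[int(s)] = size_acc.get(int(s), 0) + int(s)
    if st.n_frames == 0:
        raise ValueError("empty window")
    total = st.n_frames * n_pep
    st.size_hist = {s: v / total for s, v in sorted(size_acc.items())}
    return st


def aggregate_replicates(stats_list):
    """Replicate means and standard deviations of the headline numbers.

    Returns a dict with mean/sd of the per-replicate mean cluster count,
    modal size, and the pooled size histogram.  With a single replicate the
    sd fields are None.
    """
    counts = np.array([s.mean_cluster_count for s in stats_list])
    sizes = np.array([float(s.modal_size) for s in stats_list])
    pooled: dict = {}
    for s in stats_list:
        for k, v in s.size_hist.items():
            pooled[k] = pooled.get(k, 0.0) + v / len(stats_list)
    out = {
        "n_replicates": len(stats_list),
        "mean_cluster_count": float(counts.mean()),
        "sd_cluster_count": float(counts.std(ddof=1)) if len(counts) > 1 else None,
        "mean_modal_size": float(sizes.mean()),
        "sd_modal_size": float(sizes.std(ddof=1)) if len(sizes) > 1 else None,
        "pooled_size_hist": dict(sorted(pooled.items())),
    }
    return out


@dataclass
class RadialProfile:
    """Normalized distance-from-center histograms per bead selector."""

    bin_edges: np.ndarray
    profiles: dict               # selector name -> normalized frequencies

    def peak_bin(self, selector: str) -> int:
        return int(np.argmax(self.profiles[selector]))

    def peak_radius(self, selector: str) -> float:
        k = self.peak_bin(selector)
        return 0.5 * (self.bin_edges[k] + self.bin_edges[k + 1])


def _unwrap_cluster(fv: FrameView, mols, cmap: ContactMap) -> np.ndarray:
    """Coordinates of the cluster's beads unwrapped across the box.

    Molecules are placed relative to an arbitrary seed molecule by walking
    the molecule contact graph and shifting each newcomer by the minimum
    image relative to a bead of an already-placed neighbour.
    """
    L = fv.box_edge
    mols = list(mols)
    mol_set = set(mols)
    beads_of = {m: np.nonzero(fv.mol_of == m)[0] for m in mols}
    # adjacency via contact pairs with a representative bead pair
    adj: dict = {m: [] for m in mols}
    for i, j in cmap.pairs:
        a, b = int(fv.mol_of[i]), int(fv.mol_of[j])
        if a in mol_set and b in mol_set and a != b:
            adj[a].append((b, i, j))
            adj[b].append((a, j, i))
    pos = np.mod(fv.positions, L).copy()
    out = {}
    seed = mols[0]
    # unwrap the seed molecule internally around its first bead
    rel = pos[beads_of[seed]] - pos[beads_of[seed][0]]
    rel -= L * np.round(rel / L)
    out[seed] = pos[beads_of[seed][0]] + rel
    visited = {seed}
    queue = [seed]
    while queue:
        cur = queue.pop()
        cur_beads = beads_of[cur]
        idx_of = {b: k for k, b in enumerate(cur_beads)}
        for nbr, bi, bj in adj[cur]:
            if nbr in visited:
                continue
            # bi belongs to cur, bj to nbr; place nbr so that bj sits at the
            # minimum image of bi's unwrapped position
            bi_xyz = out[cur][idx_of[bi]]
            d = pos[bj] - pos[bi]
            d -= L * np.round(d / L)
            nbr_beads = beads_of[nbr]
            rel = pos[nbr_beads] - pos[bj]
            rel -= L * np.round(rel / L)
            out[nbr] = bi_xyz + d + rel
            visited.add(nbr)
            queue.append(nbr)
    if len(visited) != len(mols):
        raise ValueError("cluster members are not contact-connected")
    coords = np.vstack([out[m] for m in mols])
    beads = np.concatenate([beads_of[m] for m in mols])
    return coords, beads


_SELECTORS = {
    "peptide": lambda fv, beads: fv.is_peptide_bead[beads],
    "ligand": lambda fv, beads: ~fv.is_peptide_bead[beads],
    "ligand_aliphatic_C": lambda fv, beads: fv.class_of[beads] == 6,
    "ligand_O": lambda fv, beads: fv.class_of[beads] == 7,
}


def radial_profile(traj, window=None, selector=None, bin_width: float = 1.0,
                   cutoff: float = DEFAULT_CUTOFF,
                   max_radius: float = 40.0) -> RadialProfile:
    """Radial distributions from cluster centers of mass.

    ``selector`` is (n_peptides, n_ligands-or-None): only clusters whose
    composition matches are pooled.  Distances are measured after unwrapping
    each cluster across the periodic boundary; the center of mass is
    mass-weighted.
    """
    edges = np.arange(0.0, max_radius + bin_width, bin_width)
    acc = {name: np.zeros(len(edges) - 1) for name in _SELECTORS}
    matched = 0
    for fv in iter_frames(traj, window):
        cm = contacts(fv, cutoff)
        ca = cluster_frame(cm)
        is_pep_mol = fv.is_peptide_mol
        for lab in range(ca.n_clusters):
            mols = ca.members(lab)
            n_p = int(is_pep_mol[mols].sum())
            n_l = len(mols) - n_p
            if selector is not None:
                want_p, want_l = selector
                if n_p != want_p:
                    continue
                if want_l is not None and n_l != want_l:
                    continue
            coords, beads = _unwrap_cluster(fv, mols, cm)
            m = fv.mass[beads]
            com = (coords * m[:, None]).sum(axis=0) / m.sum()
            r = np.linalg.norm(coords - com, axis=1)
            matched += 1
            for name, sel in _SELECTORS.items():
                mask = sel(fv, beads)
                if mask.any():
                    h, _ = np.histogram(r[mask], bins=edges)
                    acc[name] += h
    if matched == 0:
        raise ValueError("no clusters match the selector in the window")
    profiles = {}
    for name, h in acc.items():
        tot = h.sum()
        if tot > 0:
            profiles[name] = h / tot
    return RadialProfile(bin_edges=edges, profiles=profiles)


# ---------------------------------------------------------------------------
# secondary structure


@dataclass
class SSAssignment:
    """Per-chain, per-residue labels in {H, E, T, C}."""

    labels: list                 # list (per chain) of str arrays

    def counts(self) -> np.ndarray:
        """(n_chains, 4) counts of H, E, T, C."""
        out = np.zeros((len(self.labels), 4), dtype=int)
        for c, lab in enumerate(self.labels):
            for k, letter in enumerate("HETC"):
                out[c, k] = int((lab == letter).sum())
        return out


def _angles_dihedrals(xyz: np.ndarray):
    """Pseudo-angle theta(i) and pseudo-dihedral tau(i) along a CG backbone.

    theta(i) uses beads (i-1, i, i+1); tau(i) uses (i-1, i, i+1, i+2);
    1-based residue i maps to 0-based array positions.  Undefined entries
    are NaN.
    """
    n = len(xyz)
    theta = np.full(n, np.nan)
    tau = np.full(n, np.nan)
    b = xyz[1:] - xyz[:-1]
    for i in range(1, n - 1):
        u, v = -b[i - 1], b[i]
        c = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
        theta[i] = np.degrees(np.arccos(np.clip(c, -1, 1)))
    for i in range(1, n - 2):
        b1, b2, b3 = b[i - 1], b[i], b[i + 1]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        x = n1 @ n2
        y = m1 @ n2
        tau[i] = np.degrees(np.arctan2(y, x))
    return theta, tau


def _label_chain(xyz: np.ndarray) -> np.ndarray:
    n = len(xyz)
    lab = np.full(n, "C", dtype="<U1")
    if n < 4:
        return lab
    theta, tau = _angles_dihedrals(xyz)
    helix_ok = np.zeros(n, dtype=bool)
    strand_ok = np.zeros(n, dtype=bool)
    for i in range(n):
        if np.isnan(tau[i]) or np.isnan(theta[i]):
            continue
        if HELIX_TAU[0] <= tau[i] <= HELIX_TAU[1] and \
                HELIX_THETA[0] <= theta[i] <= HELIX_THETA[1]:
            helix_ok[i] = True
        if abs(tau[i]) >= STRAND_TAU and \
                STRAND_THETA[0] <= theta[i] <= STRAND_THETA[1]:
            strand_ok[i] = True

    def runs(mask, min_run, letter):
        i = 0
        while i < n:
            if mask[i]:
                j = i
                while j < n and mask[j]:
                    j += 1
                if j - i >= min_run:
                    lab[i:j] = letter
                i = j
            else:
                i += 1

    runs(strand_ok, STRAND_MIN_RUN, "E")
    runs(helix_ok, HELIX_MIN_RUN, "H")   # helix wins ties
    # turns: short direction reversals not already assigned
    rev = np.zeros(n, dtype=bool)
    for i in range(n):
        if not np.isnan(theta[i]) and theta[i] < TURN_THETA_MAX:
            rev[i] = lab[i] == "C"
    i = 0
    while i < n:
        if rev[i]:
            j = i
            while j < n and rev[j]:
                j += 1
            if j - i <= TURN_MAX_RUN:
                lab[i:j] = "T"
            i = j
        else:
            i += 1
    return lab


def secondary_structure(frame: FrameView) -> SSAssignment:
    """Assign H/E/T/C per residue from backbone pseudo-geometry.

    Operates on the backbone-bead trace of each peptide chain; a chain
    shorter than 4 residues is all-coil.  Positions are unwrapped along the
    chain before angles are computed.
    """
    labels = []
    is_pep = frame.is_peptide_mol
    L = frame.box_edge
    for mol in np.nonzero(is_pep)[0]:
        beads = np.nonzero((frame.mol_of == mol) & frame.is_backbone)[0]
        order = np.argsort(frame.residue_of[beads])
        beads = beads[order]
        xyz = np.mod(frame.positions[beads], L).copy()
        for k in range(1, len(xyz)):
            d = xyz[k] - xyz[k - 1]
            xyz[k] = xyz[k - 1] + d - L * np.round(d / L)
        labels.append(_label_chain(xyz))
    return SSAssignment(labels=labels)


def ss_content(traj, window=None) -> dict:
    """Mean residues per chain in H/E/T/C over the window."""
    acc = np.zeros(4)
    n = 0
    for fv in iter_frames(traj, window):
        ss = secondary_structure(fv)
        counts = ss.counts()
        if len(counts) == 0:
            raise ValueError("no peptide chains")
        acc += counts.mean(axis=0)
        n += 1
    if n == 0:
        raise ValueError("empty window")
    acc /= n
    return dict(zip("HETC", acc))


def hbond_stack_census(frame: FrameView, hbond_range=(3.0, 4.5),
                       stack_cutoff: float = DEFAULT_CUTOFF,
                       donors=None, acceptors=None) -> dict:
    """Counts of peptide-ligand H-bonds, peptide-peptide H-bonds and
    aromatic stacking contacts in one frame.

    If the frame carries the engine's reacted-pair registry
    (``frame.hb_pairs``) those pairs are counted; otherwise hydrogen bonds
    are re-estimated geometrically: donor/acceptor bead pairs within the
    bond range, matched greedily in bead-index order under the per-bead
    capacities.
    """
    is_pep = frame.is_peptide_bead
    arom = np.isin(frame.class_of, (4, 5))
    cm = contacts(frame, stack_cutoff)
    stack = sum(1 for i, j in cm.pairs if arom[i] and arom[j])
    if frame.hb_pairs is not None:
        hb = np.asarray(frame.hb_pairs).reshape(-1, 2)
    else:
        if donors is None or acceptors is None:
            raise ValueError(
                "geometric H-bond census needs donor/acceptor capacities")
        pos = np.mod(frame.positions, frame.box_edge)
        tree = cKDTree(pos, boxsize=frame.box_edge)
        cand = tree.query_pairs(hbond_range[1], output_type="ndarray")
        d = pos[cand[:, 0]] - pos[cand[:, 1]]
        d -= frame.box_edge * np.round(d / frame.box_edge)
        dist = np.sqrt((d ** 2).sum(axis=1))
        keep = (dist >= hbond_range[0]) & (dist < hbond_range[1]) & (
            frame.mol_of[cand[:, 0]] != frame.mol_of[cand[:, 1]])
        cand = np.sort(cand[keep], axis=1)
        cand = cand[np.lexsort((cand[:, 1], cand[:, 0]))]
        dleft = np.asarray(donors).copy()
        aleft = np.asarray(acceptors).copy()
        out = []
        for i, j in cand:
            if dleft[i] > 0 and aleft[j] > 0:
                dleft[i] -= 1
                aleft[j] -= 1
                out.append((i, j))
            elif dleft[j] > 0 and aleft[i] > 0:
                dleft[j] -= 1
                aleft[i] -= 1
                out.append((j, i))
        hb = np.asarray(out, dtype=int).reshape(-1, 2)
    pl = sum(1 for i, j in hb if is_pep[i] != is_pep[j])
    pp = sum(1 for i, j in hb if is_pep[i] and is_pep[j])
    return {"peptide_ligand_hbonds": int(pl),
            "peptide_peptide_hbonds": int(pp),
            "stacking_contacts": int(stack)}


def steady_state_window(traj, detect_plateau: bool = False):
    """Last-half frame window (floor split), optionally with a plateau scan.

    Returns ``(lo, hi)``; with ``detect_plateau`` a dict additionally
    reports the first frame after which the potential-energy linear trend is
    statistically flat (never overriding the default window).
    """
    n = traj.n_frames
    if n < 2:
        raise ValueError("need at least 2 frames")
    window = (n // 2, n)
    if not detect_plateau:
        return window
    from scipy import stats as sps
    start = 0
    for f in range(0, n - 3):
        res = sps.linregress(traj.times[f:], traj.potential[f:])
        if res.pvalue > 0.05:
            start = f
            break
    return {"window": window, "plateau_start_frame": start}
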