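"""Contacts, clustering, histograms, radial profiles, secondary structure."""

import numpy as np
import pytest

from dmdnano import analysis as an
from dmdnano import fixtures as fx
from dmdnano.system_builder import SystemState


def _bare_frame(positions, mol_of, box=50.0, species=None, **kw):
    n = len(positions)
    mol_of = np.asarray(mol_of)
    nmol = mol_of.max() + 1
    return an.FrameView(
        positions=np.asarray(positions, dtype=float), box_edge=box,
        mol_of=mol_of,
        species_of_mol=species or ["IAPP"] * nmol,
        class_of=kw.get("class_of", np.zeros(n, dtype=int)),
        residue_of=kw.get("residue_of", np.ones(n, dtype=int)),
        is_backbone=kw.get("is_backbone", np.ones(n, dtype=bool)),
        mass=kw.get("mass", np.ones(n)))


class TestContacts:
    def test_strict_cutoff(self):
        fv = _bare_frame([[10, 10, 10], [15.4, 10, 10]], [0, 1])
        assert len(an.contacts(fv).pairs) == 1
        fv = _bare_frame([[10, 10, 10], [15.5, 10, 10]], [0, 1])
        assert len(an.contacts(fv).pairs) == 0     # exactly 5.5 A: excluded

    def test_intramolecular_excluded(self):
        fv = _bare_frame([[10, 10, 10], [12, 10, 10]], [0, 0])
        assert len(an.contacts(fv).pairs) == 0

    def test_minimum_image(self):
        fv = _bare_frame([[1, 25, 25], [48, 25, 25]], [0, 1])  # 3 A via wrap
        assert len(an.contacts(fv).pairs) == 1

    def test_matches_brute_force(self):
        rng = np.random.default_rng(42)
        pos = rng.uniform(0, 30, size=(100, 3))
        mol_of = np.repeat(np.arange(50), 2)
        fv = _bare_frame(pos, mol_of, box=30.0)
        got = {tuple(p) for p in an.contacts(fv).pairs}
        want = set()
        for i in range(100):
            for j in range(i + 1, 100):
                if mol_of[i] == mol_of[j]:
                    continue
                d = pos[i] - pos[j]
                d -= 30.0 * np.round(d / 30.0)
                if np.sqrt((d ** 2).sum()) < 5.5:
                    want.add((i, j))
        assert got == want

    def test_bad_cutoff(self):
        fv = _bare_frame([[1, 1, 1]], [0])
        with pytest.raises(ValueError):
            an.contacts(fv, cutoff=-1.0)


class TestClustering:
    def test_no_contacts_all_singletons(self):
        cm = an.ContactMap(frame_id=0, pairs=np.zeros((0, 2), dtype=int),
                           n_molecules=5, mol_of=np.arange(5))
        ca = an.cluster_frame(cm)
        assert ca.n_clusters == 5

    def test_transitivity(self):
        # A-B and B-C contacts put A, B, C in one cluster
        fv = _bare_frame([[10, 10, 10], [14, 10, 10], [18, 10, 10]],
                         [0, 1, 2])
        ca = an.cluster_frame(an.contacts(fv))
        assert ca.n_clusters == 1

    def test_random_graphs_match_union_find(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(3, 25))
            m = int(rng.integers(0, 2 * n))
            pairs = rng.integers(0, n, size=(m, 2))
            pairs = pairs[pairs[:, 0] != pairs[:, 1]]
            cm = an.ContactMap(frame_id=0, pairs=pairs, n_molecules=n,
                               mol_of=np.arange(n))
            got = an.cluster_frame(cm).labels
            want = fx.union_find_clusters(n, pairs)
            # same partition up to label names
            remap = {}
            ok = True
            for g, w in zip(got, want):
                ok &= remap.setdefault(g, w) == w
            assert ok


class TestResidueContacts:
    def test_exact_fractions_from_handbuilt_frames(self):
        """3 frames: residue-1 sidechain touches the ligand in all, residue 2
        in two, residue 3 never -> frequencies 1, 2/3, 0."""
        lig = [24.0, 10, 10]
        frames = []
        for k, r2_x in enumerate([22.0, 22.0, 40.0]):
            pos = np.array([
                [20.0, 10, 10],   # residue 1 bead, 4 A from ligand
                [r2_x, 10, 10],   # residue 2 bead
                [10.0, 10, 10],   # residue 3 bead, far
                lig,
            ])
            frames.append(pos)
        traj = _traj_from_frames(frames, mol_of=[0, 0, 0, 1],
                                 species=["IAPP", "curcumin"],
                                 residue_of=[1, 2, 3, -1])
        freq = an.residue_ligand_contact_frequency(traj, n_residues=3)
        assert freq[0] == pytest.approx(1.0)
        assert freq[1] == pytest.approx(2 / 3)
        assert freq[2] == 0.0

    def test_ligand_free_all_zero(self):
        frames = [np.array([[1.0, 1, 1], [3.0, 1, 1]])]
        traj = _traj_from_frames(frames, mol_of=[0, 1],
                                 species=["IAPP", "IAPP"],
                                 residue_of=[1, 1])
        assert an.residue_ligand_contact_frequency(traj, n_residues=2).sum() == 0


def _traj_from_frames(frames, mol_of, species, residue_of=None,
                      box=50.0, class_of=None, is_backbone=None, mass=None):
    from dmdnano.engine import Trajectory
    n = len(frames[0])
    mol_of = np.asarray(mol_of)
    state = SystemState(
        positions=np.asarray(frames[0], dtype=float),
        velocities=np.zeros((n, 3)), box_edge=box, time=0.0,
        mol_of=mol_of, species_of_mol=list(species),
        class_of=np.asarray(class_of if class_of is not None
                            else np.zeros(n, dtype=int)),
        mass=np.asarray(mass if mass is not None else np.ones(n)),
        radius=np.ones(n), charge=np.zeros(n),
        donors=np.zeros(n, dtype=int), acceptors=np.zeros(n, dtype=int),
        eps_scale=np.ones(n),
        residue_of=np.asarray(residue_of if residue_of is not None
                              else np.ones(n, dtype=int)),
        is_backbone=np.asarray(is_backbone if is_backbone is not None
                               else np.ones(n, dtype=bool)),
        bond_idx=np.zeros((0, 2), dtype=np.int64),
        bond_range=np.zeros((0, 2)))
    P = np.stack([np.asarray(f, dtype=float) for f in frames])
    F = len(frames)
    return Trajectory(
        times=np.arange(F, dtype=float), positions=P,
        velocities=np.zeros_like(P), kinetic=np.zeros(F),
        potential=np.zeros(F), hb_counts=np.zeros((F, 3), dtype=int),
        box_edge=box, system=state)


class TestBindingFraction:
    def _two_ligand_traj(self):
        """Ligand 1 bound in 2/4 frames, ligand 2 bound in 4/4."""
        frames = []
        for k in range(4):
            l1_x = 14.0 if k < 2 else 40.0
            frames.append(np.array([
                [10.0, 10, 10],          # peptide bead
                [l1_x, 10, 10],          # ligand 1
                [10.0, 14, 10],          # ligand 2, always bound
            ]))
        return _traj_from_frames(frames, mol_of=[0, 1, 2],
                                 species=["IAPP", "aspirin", "aspirin"])

    def test_per_ligand_and_any_ligand(self):
        traj = self._two_ligand_traj()
        assert an.binding_fraction(traj, mode="per_ligand") == pytest.approx(0.75)
        assert an.binding_fraction(traj, mode="any_ligand") == pytest.approx(1.0)

    def test_never_bound(self):
        frames = [np.array([[5.0, 5, 5], [30.0, 30, 30]])]
        traj = _traj_from_frames(frames, mol_of=[0, 1],
                                 species=["IAPP", "aspirin"])
        assert an.binding_fraction(traj, mode="per_ligand") == 0.0
        assert an.binding_fraction(traj, mode="any_ligand") == 0.0

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            an.binding_fraction(self._two_ligand_traj(), mode="sometimes")


class TestInterchainContacts:
    def test_monomer_all_zero(self):
        frames = [np.array([[1.0, 1, 1], [3.0, 1, 1]])] * 3
        traj = _traj_from_frames(frames, mol_of=[0, 0], species=["IAPP"])
        assert an.interchain_contacts(traj).sum() == 0

    def test_fused_dimer_constant_contacts(self):
        # two 2-bead peptides with exactly 3 cross pairs under 5.5 A
        pos = np.array([[10.0, 10, 10], [13.0, 10, 10],
                        [10.0, 13, 10], [13.0, 13, 10]])
        # cross-molecule pairs: (0,2)=3, (0,3)=sqrt(18)=4.24, (1,2)=4.24,
        # (1,3)=3 -> 4 contacts
        traj = _traj_from_frames([pos] * 2, mol_of=[0, 0, 1, 1],
                                 species=["IAPP", "IAPP"],
                                 residue_of=[1, 25, 1, 25])
        series = an.interchain_contacts(traj)
        assert list(series) == [4, 4]

    def test_region_subset_monotone(self):
        pos = np.array([[10.0, 10, 10], [13.0, 10, 10],
                        [10.0, 13, 10], [13.0, 13, 10]])
        traj = _traj_from_frames([pos] * 2, mol_of=[0, 0, 1, 1],
                                 species=["IAPP", "IAPP"],
                                 residue_of=[1, 25, 1, 25])
        full = an.interchain_contacts(traj)
        region = an.interchain_contacts(traj, region=(22, 29))
        assert np.all(region <= full)
        assert list(region) == [1, 1]      # only the 25-25 pair

    def test_region_validation(self):
        traj = _traj_from_frames([np.zeros((2, 3))], [0, 1],
                                 ["IAPP", "IAPP"])
        with pytest.raises(ValueError):
            an.interchain_contacts(traj, region=(0, 50))


class TestClusterStats:
    def test_forced_332_fixture(self):
        spec = fx.ClusterSpec(clusters=((3, 6, 0.3), (3, 6, 0.3), (2, 4, 0.3)),
                              seed=1)
        traj, _ = fx.make_clustered_trajectory(spec)
        st = an.cluster_stats(traj)
        assert st.count_hist == {3: traj.n_frames}
        assert st.size_hist[3] == pytest.approx(0.75)
        assert st.size_hist[2] == pytest.approx(0.25)
        assert (3, 6) in st.composition and (2, 4) in st.composition
        assert st.ligand_peptide_ratio() == pytest.approx(2.0)

    def test_octamer_fixture(self):
        traj, _ = fx.make_clustered_trajectory(
            fx.ClusterSpec(clusters=((8, 0, 0.2),), seed=2))
        st = an.cluster_stats(traj)
        assert st.modal_count == 1
        assert st.size_hist == {8: pytest.approx(1.0)}

    def test_normalization_and_mass_conservation(self):
        spec = fx.ClusterSpec(clusters=((3, 2, 0.3), (1, 0, 0.2), (4, 1, 0.3)),
                              seed=3, n_frames=4)
        traj, _ = fx.make_clustered_trajectory(spec)
        st = an.cluster_stats(traj)
        assert sum(st.size_hist.values()) == pytest.approx(1.0)
        # sum_s s*n_s = N_peptides each frame
        total = sum(k[0] * v for k, v in st.composition.items())
        assert total == st.n_peptides * st.n_frames

    def test_replicate_aggregation(self):
        stats = []
        for seed in (1, 2):
            traj, _ = fx.make_clustered_trajectory(
                fx.ClusterSpec(clusters=((3, 6, 0.3), (2, 4, 0.3)), seed=seed))
            stats.append(an.cluster_stats(traj))
        agg = an.aggregate_replicates(stats)
        assert agg["n_replicates"] == 2
        assert agg["sd_cluster_count"] is not None
        assert sum(agg["pooled_size_hist"].values()) == pytest.approx(1.0)
        single = an.aggregate_replicates(stats[:1])
        assert single["sd_cluster_count"] is None


class TestRadialProfile:
    def test_single_bead_cluster(self):
        frames = [np.array([[25.0, 25, 25]])]
        traj = _traj_from_frames(frames, mol_of=[0], species=["IAPP"])
        rp = an.radial_profile(traj)
        assert rp.profiles["peptide"][0] == pytest.approx(1.0)

    def test_core_corona_ordering(self):
        traj = fx.make_core_shell_trajectory()
        rp = an.radial_profile(traj)
        assert rp.peak_radius("ligand") < rp.peak_radius("peptide")
        assert rp.peak_radius("ligand_aliphatic_C") < rp.peak_radius("ligand_O")
        for prof in rp.profiles.values():
            assert prof.sum() == pytest.approx(1.0)

    def test_translation_and_wrap_invariance(self):
        base = fx.make_core_shell_trajectory()
        shifted = fx.make_core_shell_trajectory()
        shifted.positions = (shifted.positions +
                             np.array([57.0, 3.0, 59.0])) % shifted.box_edge
        a = an.radial_profile(base)
        b = an.radial_profile(shifted)
        for k in a.profiles:
            np.testing.assert_allclose(a.profiles[k], b.profiles[k])

    def test_no_match_raises(self):
        traj = fx.make_core_shell_trajectory()
        with pytest.raises(ValueError):
            an.radial_profile(traj, selector=(99, None))


class TestSecondaryStructure:
    def test_helix_template_interior_h(self):
        xyz = fx.make_ss_template("helix", 20)
        lab = an._label_chain(xyz)
        assert set(lab[2:18]) == {"H"}

    def test_extended_template_interior_e(self):
        xyz = fx.make_ss_template("extended", 20)
        lab = an._label_chain(xyz)
        assert set(lab[2:18]) == {"E"}

    def test_short_chain_all_coil(self):
        assert list(an._label_chain(np.random.default_rng(0)
                                    .uniform(0, 5, (3, 3)))) == ["C"] * 3

    def test_partition_sums_to_chain_length(self):
        # a peptide frame with arbitrary geometry: labels cover all residues
        rng = np.random.default_rng(5)
        walk = np.cumsum(rng.normal(scale=2.2, size=(37, 3)), axis=0) + 100.0
        fv = an.FrameView(
            positions=walk % 200.0, box_edge=200.0,
            mol_of=np.zeros(37, dtype=int), species_of_mol=["IAPP"],
            class_of=np.zeros(37, dtype=int),
            residue_of=np.arange(1, 38), is_backbone=np.ones(37, dtype=bool),
            mass=np.ones(37))
        ss = an.secondary_structure(fv)
        assert ss.counts().sum() == 37

    def test_ss_content_means(self):
        xyz = fx.make_ss_template("helix", 37)
        traj = _traj_from_frames([xyz + 50.0] * 2, mol_of=[0] * 37,
                                 species=["IAPP"],
                                 residue_of=list(range(1, 38)), box=200.0)
        content = an.ss_content(traj)
        assert content["H"] == 34          # interior residues (n - 3)
        assert sum(content.values()) == 37


class TestCensusAndWindow:
    def test_stacking_and_hbond_counts(self):
        # two aromatic beads in contact + a donor/acceptor pair in range
        pos = np.array([[10.0, 10, 10], [14.0, 10, 10],
                        [30.0, 30, 30], [33.5, 30, 30]])
        fv = an.FrameView(
            positions=pos, box_edge=50.0,
            mol_of=np.array([0, 1, 2, 3]),
            species_of_mol=["curcumin"] * 4,
            class_of=np.array([5, 5, 7, 7]),
            residue_of=np.full(4, -1), is_backbone=np.zeros(4, dtype=bool),
            mass=np.ones(4))
        out = an.hbond_stack_census(
            fv, donors=np.array([0, 0, 1, 0]),
            acceptors=np.array([0, 0, 0, 1]))
        assert out["stacking_contacts"] == 1
        assert out["peptide_ligand_hbonds"] == 0
        assert (out["peptide_peptide_hbonds"] == 0)

    def test_census_respects_capacity(self):
        # three acceptors around one single-capacity donor: one bond only
        pos = np.array([[10.0, 10, 10], [13.5, 10, 10],
                        [10.0, 13.5, 10], [6.5, 10, 10]])
        fv = an.FrameView(
            positions=pos, box_edge=50.0, mol_of=np.arange(4),
            species_of_mol=["IAPP"] * 4, class_of=np.zeros(4, dtype=int),
            residue_of=np.ones(4, dtype=int),
            is_backbone=np.ones(4, dtype=bool), mass=np.ones(4))
        out = an.hbond_stack_census(
            fv, donors=np.array([1, 0, 0, 0]), acceptors=np.array([0, 1, 1, 1]))
        assert out["peptide_peptide_hbonds"] == 1

    def test_registry_preferred(self):
        fv = an.FrameView(
            positions=np.zeros((2, 3)), box_edge=10.0,
            mol_of=np.array([0, 1]), species_of_mol=["IAPP", "curcumin"],
            class_of=np.array([0, 5]), residue_of=np.array([1, -1]),
            is_backbone=np.array([True, False]), mass=np.ones(2),
            hb_pairs=np.array([[0, 1]]))
        out = an.hbond_stack_census(fv)
        assert out["peptide_ligand_hbonds"] == 1

    @pytest.mark.parametrize("n,expected", [
        (100, (50, 100)), (2, (1, 2)), (101, (50, 101))])
    def test_last_half_window(self, n, expected):
        traj = _traj_from_frames([np.zeros((1, 3))] * n, [0], ["IAPP"])
        traj.times = np.arange(n, dtype=float)
        assert an.steady_state_window(traj) == expected

    def test_window_requires_frames(self):
        traj = _traj_from_frames([np.zeros((1, 3))], [0], ["IAPP"])
        with pytest.raises(ValueError):
            an.steady_state_window(traj)
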