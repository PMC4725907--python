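"""Event prediction, collision resolution, conservation laws, thermostat."""

import numpy as np
import pytest
from scipy import stats as sps

from dmdnano import engine, fixtures as fx
from dmdnano import system_builder as sb
from dmdnano.constants import KB


class TestPredictPairEvent:
    def test_head_on_linear_kinematics(self):
        out = engine.predict_pair_event([10.0, 0, 0], [-1.0, 0, 0], [6.0])
        assert out is not None
        t, d = out
        assert t == pytest.approx(4.0)
        assert d == 6.0

    def test_tangential_no_event(self):
        assert engine.predict_pair_event([10.0, 0, 0], [0, 1.0, 0], [6.0]) is None

    def test_outward_crossing(self):
        t, d = engine.predict_pair_event([5.0, 0, 0], [1.0, 0, 0], [6.0, 8.0])
        assert t == pytest.approx(1.0)
        assert d == 6.0

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            engine.predict_pair_event([np.nan, 0, 0], [1, 0, 0], [6.0])

    def test_matches_time_scan_oracle(self):
        """Roots agree with a brute-force |r + v t| distance scan."""
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(300):
            r = rng.uniform(-8, 8, 3)
            v = rng.uniform(-1, 1, 3)
            bounds = np.sort(rng.uniform(2.0, 10.0, 3))
            out = engine.predict_pair_event(r, v, bounds)
            ts = np.arange(0.0, 40.0, 1e-4)
            dist = np.linalg.norm(r[None, :] + ts[:, None] * v[None, :],
                                  axis=1)
            hits = []
            for d in bounds:
                sign = np.sign(dist - d)
                flips = np.nonzero(np.diff(sign) != 0)[0]
                if len(flips):
                    hits.append(ts[flips[0]])
            oracle = min(hits) if hits else None
            if oracle is None:
                assert out is None or out[0] > 40.0
            else:
                assert out is not None
                assert out[0] == pytest.approx(oracle, abs=1e-3)
                checked += 1
        assert checked > 100


class TestResolveCollision:
    def test_equal_mass_head_on_exchange(self):
        vi, vj, crossed = engine.resolve_collision(
            [1.0, 0, 0], [-1.0, 0, 0], 2.0, 2.0, [-1.0, 0, 0], 0.0)
        # reflecting boundary with dU=0 exchanges the radial velocities
        np.testing.assert_allclose(vi, [-1.0, 0, 0])
        np.testing.assert_allclose(vj, [1.0, 0, 0])

    def test_forbidden_crossing_reflects(self):
        vi, vj, crossed = engine.resolve_collision(
            [0.1, 0, 0], [0, 0, 0], 1.0, 1.0, [1.0, 0, 0], dU=10.0)
        assert not crossed
        # radial relative velocity flips; energy unchanged
        assert (vi - vj) @ np.array([1.0, 0, 0]) == pytest.approx(-0.1)
        assert vi @ vi + vj @ vj == pytest.approx(0.1 ** 2)

    def test_capture_gains_well_depth(self):
        m1, m2, eps = 3.0, 5.0, 1.7
        v1, v2 = np.array([-0.4, 0.2, 0]), np.array([0.3, -0.1, 0])
        n = np.array([1.0, 0, 0])
        w1, w2, crossed = engine.resolve_collision(v1, v2, m1, m2, n, -eps)
        assert crossed
        ke_before = 0.5 * m1 * v1 @ v1 + 0.5 * m2 * v2 @ v2
        ke_after = 0.5 * m1 * w1 @ w1 + 0.5 * m2 * w2 @ w2
        assert ke_after - ke_before == pytest.approx(eps)

    def test_momentum_conserved(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            m1, m2 = rng.uniform(1, 100, 2)
            v1, v2 = rng.normal(size=3), rng.normal(size=3)
            n = rng.normal(size=3)
            dU = rng.uniform(-2, 2)
            w1, w2, _ = engine.resolve_collision(v1, v2, m1, m2, n, dU)
            np.testing.assert_allclose(m1 * w1 + m2 * w2, m1 * v1 + m2 * v2,
                                       atol=1e-12)

    def test_angular_momentum_of_pair_conserved(self):
        """Impulse along the line of centers leaves L about the pair COM."""
        rng = np.random.default_rng(4)
        m1, m2 = 2.0, 7.0
        r1, r2 = np.array([1.0, 2.0, 0.5]), np.array([4.0, 2.0, 0.5])
        n = (r1 - r2) / np.linalg.norm(r1 - r2)
        v1, v2 = rng.normal(size=3), rng.normal(size=3)
        com = (m1 * r1 + m2 * r2) / (m1 + m2)
        w1, w2, _ = engine.resolve_collision(v1, v2, m1, m2, n, -0.8)

        def ang(v1_, v2_):
            return (m1 * np.cross(r1 - com, v1_) +
                    m2 * np.cross(r2 - com, v2_))

        np.testing.assert_allclose(ang(w1, w2), ang(v1, v2), atol=1e-12)


class TestThermostatStream:
    def test_zero_rate_no_events(self):
        assert list(engine.thermostat_events(0.0, 1, 10, 100.0)) == []

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            list(engine.thermostat_events(-1.0, 1, 10, 100.0))

    def test_causal_order_and_rate(self):
        events = list(engine.thermostat_events(0.5, 7, 20, 200.0))
        times = [e.time for e in events]
        assert times == sorted(times)
        # expect ~ rate * n * t events
        assert len(events) == pytest.approx(0.5 * 20 * 200, rel=0.2)


class TestEngineRuns:
    def test_two_sphere_nve_energy_exact(self):
        spec = fx.TwoBodySpec(epsilon=1.0)
        state = fx.make_two_body_state(spec, seed=5)
        traj = engine.run(state, table=fx.square_well_table(spec),
                          config=engine.RunConfig(
                              t_max=20000.0, frame_dt=1000.0,
                              thermostat_rate=0.0, seed=5, hbonds=False))
        E = traj.kinetic + traj.potential
        assert (E.max() - E.min()) / abs(E[0]) < 1e-9

    def test_determinism(self):
        st = sb.assemble_system(sb.SystemConfig(
            n_peptides=1, ligand_species="aspirin", ligands_per_peptide=2,
            seed=9))
        cfg = engine.RunConfig(t_max=100.0, frame_dt=50.0, seed=4)
        a = engine.run(st, config=cfg)
        b = engine.run(st, config=cfg)
        np.testing.assert_array_equal(a.positions, b.positions)
        assert a.n_events == b.n_events

    def test_nve_conservation_full_system(self):
        """Energy drift below 1e-8 relative on a peptide+ligand box."""
        st = sb.assemble_system(sb.SystemConfig(
            n_peptides=1, ligand_species="curcumin", seed=12))
        traj = engine.run(st, config=engine.RunConfig(
            t_max=400.0, frame_dt=100.0, thermostat_rate=0.0, seed=2))
        E = traj.kinetic + traj.potential
        assert (E.max() - E.min()) / abs(E[0]) < 1e-8
        # incremental potential equals the O(N^2) reference
        assert traj.extra["kernel_pe"] == pytest.approx(
            traj.extra["kernel_pe_check"], abs=1e-8)

    def test_momentum_conserved_nve(self):
        st = sb.assemble_system(sb.SystemConfig(n_peptides=1, seed=3))
        traj = engine.run(st, config=engine.RunConfig(
            t_max=200.0, frame_dt=100.0, thermostat_rate=0.0, seed=2))
        m = st.mass[:, None]
        for f in range(traj.n_frames):
            p = (m * traj.velocities[f]).sum(axis=0)
            np.testing.assert_allclose(p, [0, 0, 0], atol=1e-9)

    def test_no_hardcore_overlap_in_frames(self):
        st = sb.assemble_system(sb.SystemConfig(
            n_peptides=2, ligand_species="resveratrol", seed=8))
        traj = engine.run(st, config=engine.RunConfig(
            t_max=300.0, frame_dt=100.0, seed=1))
        bonded = {tuple(sorted(map(int, p))) for p in st.bond_idx}
        L = traj.box_edge
        for f in range(traj.n_frames):
            pos = traj.positions[f]
            for i in range(st.n_beads):
                d = pos[i + 1:] - pos[i]
                d -= L * np.round(d / L)
                r = np.sqrt((d ** 2).sum(axis=1))
                lim = st.radius[i] + st.radius[i + 1:]
                for off in np.nonzero(r < lim - 1e-6)[0]:
                    assert (i, int(i + 1 + off)) in bonded

    def test_total_energy_trivial_states(self):
        spec = fx.TwoBodySpec(epsilon=2.0)
        st = fx.make_two_body_state(spec)
        table = fx.square_well_table(spec)
        st.positions = np.array([[5.0, 5, 5], [25.0, 5, 5]])
        _, pe = engine.total_energy(st, table)
        assert pe == 0.0                       # beyond the cutoff
        st.positions = np.array([[5.0, 5, 5], [10.0, 5, 5]])
        _, pe = engine.total_energy(st, table)
        assert pe == pytest.approx(-2.0)       # one pair inside the well


@pytest.fixture(scope="module")
def gas_run():
    state = fx.make_ideal_gas(300, 60.0, 300.0, seed=6)
    return engine.run(state, table=fx.ideal_gas_table(),
                      config=engine.RunConfig(
                          t_max=400.0, frame_dt=20.0,
                          thermostat_rate=0.1, seed=6, hbonds=False))


class TestThermostatPhysics:

    def test_equipartition(self, gas_run):
        temps = gas_run.temperature()[5:]
        assert temps.mean() == pytest.approx(300.0, rel=0.02)

    def test_maxwell_boltzmann_speeds(self, gas_run):
        """KS test of sampled speeds against the Maxwell distribution."""
        mass = gas_run.system.mass[0]
        scale = np.sqrt(KB * 300.0 / mass)
        speeds = np.linalg.norm(
            gas_run.velocities[5:], axis=2).ravel()[:10000]
        stat, p = sps.kstest(speeds, sps.maxwell.cdf, args=(0, scale))
        assert p > 0.01

    def test_rate_zero_is_nve(self):
        state = fx.make_ideal_gas(50, 60.0, 300.0, seed=7)
        traj = engine.run(state, table=fx.ideal_gas_table(),
                          config=engine.RunConfig(
                              t_max=200.0, frame_dt=50.0,
                              thermostat_rate=0.0, seed=7, hbonds=False))
        np.testing.assert_allclose(traj.kinetic, traj.kinetic[0], rtol=1e-12)

    def test_kinetic_energy_chi_squared_moments(self, gas_run):
        """Stationary KE fluctuations match the chi^2 form for 3N dof."""
        n_dof = 3 * gas_run.n_beads
        kT = KB * 300.0
        ke = gas_run.kinetic[5:]
        mean_expected = 0.5 * n_dof * kT
        sd_expected = np.sqrt(0.5 * n_dof) * kT
        n = len(ke)
        assert abs(ke.mean() - mean_expected) < 3 * sd_expected / np.sqrt(n)
        assert ke.std() == pytest.approx(sd_expected, rel=0.5)


class TestBoundFraction:
    def test_two_body_square_well_vs_configurational_integral(self):
        """Time-averaged bound fraction against the closed-form oracle."""
        spec = fx.TwoBodySpec(sigma=4.0, lam=1.5, epsilon=2.0,
                              box_edge=40.0, temperature=300.0)
        expected = fx.bound_fraction_oracle(spec)
        state = fx.make_two_body_state(spec, seed=17)
        traj = engine.run(state, table=fx.square_well_table(spec),
                          config=engine.RunConfig(
                              t_max=250000.0, frame_dt=25.0,
                              thermostat_rate=0.1, seed=17, hbonds=False))
        d = traj.positions[:, 0] - traj.positions[:, 1]
        d -= traj.box_edge * np.round(d / traj.box_edge)
        bound = (np.linalg.norm(d, axis=1) < spec.lam * spec.sigma)
        frac = bound.mean()
        # block averages over 20 segments give the standard error
        blocks = np.array_split(bound.astype(float), 20)
        means = np.array([b.mean() for b in blocks])
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(frac - expected) < max(3 * se, 0.02)


class TestHBondRegistry:
    def test_capacity_never_exceeded(self):
        st = sb.assemble_system(sb.SystemConfig(
            n_peptides=1, ligand_species="resveratrol",
            ligands_per_peptide=4, seed=5))
        traj = engine.run(st, config=engine.RunConfig(
            t_max=500.0, frame_dt=100.0, thermostat_rate=0.02, seed=5))
        counts = np.zeros(st.n_beads, dtype=int)
        for i, j in traj.extra["hb_pairs"]:
            counts[i] += 1
            counts[j] += 1
        assert np.all(counts <= st.donors + st.acceptors)

    def test_hbonds_form_in_peptide_systems(self):
        st = sb.assemble_system(sb.SystemConfig(n_peptides=2, seed=6))
        traj = engine.run(st, config=engine.RunConfig(
            t_max=500.0, frame_dt=250.0, thermostat_rate=0.05, seed=6))
        assert traj.hb_counts[-1].sum() > 0
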