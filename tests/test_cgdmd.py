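"""Event-driven dynamics: two-body closed forms, a brute-force oracle,
conservation laws, and the thermostat."""

import numpy as np
import pytest
from scipy.stats import kstest, maxwell

from crossbeta.cgdmd import (
    CGModelParams,
    CGSystem,
    Topology,
    build_cg_system,
    concentration,
    measure_temperature,
    run_dmd,
)
from crossbeta.cgdmd.engine import Trajectory, EngineError
from crossbeta.cgdmd.system import maxwell_boltzmann_velocities


# ---------------------------------------------------------------------------
# hand-built two/few-bead systems


def free_beads_system(
    positions,
    velocities,
    masses,
    box=100.0,
    core=None,
    well_r=None,
    well_eps=0.0,
    bond=None,
    params=None,
):
    """Minimal CGSystem around explicit beads and one pair interaction."""
    n = len(positions)
    params = params or CGModelParams.from_files()
    core2 = np.zeros((n, n))
    well_r2 = np.zeros((n, n))
    eps = np.zeros((n, n))
    lo2 = np.zeros((n, n))
    hi2 = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if core is not None:
                core2[i, j] = core**2
            if well_r is not None:
                well_r2[i, j] = well_r**2
                eps[i, j] = well_eps
            if bond is not None:
                lo2[i, j] = bond[0] ** 2
                hi2[i, j] = bond[1] ** 2
                core2[i, j] = 0.0
                well_r2[i, j] = 0.0
                eps[i, j] = 0.0
    topology = Topology(sequence="G", n_peptides=1)  # placeholder indexing
    sys_ = CGSystem.__new__(CGSystem)
    sys_.topology = topology
    sys_.params = params
    sys_.positions = np.asarray(positions, dtype=float)
    sys_.velocities = np.asarray(velocities, dtype=float)
    sys_.masses = np.asarray(masses, dtype=float)
    sys_.box_edge = box
    sys_.temperature_K = 310.0
    sys_.bonds = []
    sys_.core2 = core2
    sys_.well_r2 = well_r2
    sys_.well_eps = eps
    sys_.bond_lo2 = lo2
    sys_.bond_hi2 = hi2
    return sys_


class TestTwoBodyClosedForms:
    def test_equal_mass_head_on_exchange(self):
        sys_ = free_beads_system(
            positions=[[-5.0, 0, 0], [5.0, 0, 0]],
            velocities=[[1.0, 0, 0], [-1.0, 0, 0]],
            masses=[2.0, 2.0],
            core=2.0,
        )
        run_dmd(sys_, t_end=6.0, thermostat_rate=0.0, frame_interval=6.0, seed=0)
        # velocities exchanged exactly at contact
        np.testing.assert_allclose(sys_.velocities[0], [-1.0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(sys_.velocities[1], [1.0, 0, 0], atol=1e-12)

    def test_well_capture_gains_depth(self):
        eps = 0.7
        m = (1.5, 3.0)
        sys_ = free_beads_system(
            positions=[[-6.0, 0, 0], [6.0, 0, 0]],
            velocities=[[0.5, 0, 0], [-0.25, 0, 0]],
            masses=m,
            core=1.0,
            well_r=4.0,
            well_eps=eps,
        )
        ke0 = sys_.kinetic_energy()
        # capture when the 12 Å gap closes to 4 Å at rate 0.75 → t ≈ 10.67
        traj = run_dmd(
            sys_, t_end=12.0, thermostat_rate=0.0, frame_interval=1.0, seed=0
        )
        assert traj.metadata["n_events"] >= 1
        # at some point the pair was inside: kinetic energy rose by exactly eps
        # total energy conserved throughout
        E = traj.total_energy()
        np.testing.assert_allclose(E, E[0], atol=1e-9)
        ke_in_well = ke0 + eps
        # reconstruct KE right after capture from conservation
        assert max(traj.kinetic) == pytest.approx(ke_in_well, abs=1e-9)

    def test_analytic_capture_time(self):
        sys_ = free_beads_system(
            positions=[[0.0, 0, 0], [12.0, 0, 0]],
            velocities=[[1.0, 0, 0], [0.0, 0, 0]],
            masses=[1.0, 1.0],
            core=1.0,
            well_r=4.0,
            well_eps=0.5,
        )
        traj = run_dmd(
            sys_, t_end=7.9, thermostat_rate=0.0, frame_interval=7.9, seed=0
        )
        # capture at t = (12-4)/1 = 8 has NOT happened yet at 7.9
        assert traj.potential[-1] == 0.0
        sys2 = free_beads_system(
            positions=[[0.0, 0, 0], [12.0, 0, 0]],
            velocities=[[1.0, 0, 0], [0.0, 0, 0]],
            masses=[1.0, 1.0],
            core=1.0,
            well_r=4.0,
            well_eps=0.5,
        )
        traj2 = run_dmd(
            sys2, t_end=8.1, thermostat_rate=0.0, frame_interval=8.1, seed=0
        )
        assert traj2.potential[-1] == pytest.approx(-0.5)

    def test_bond_reflection_keeps_pair_in_window(self):
        sys_ = free_beads_system(
            positions=[[0.0, 0, 0], [1.5, 0, 0]],
            velocities=[[0.3, 0.1, 0], [-0.2, 0, 0.2]],
            masses=[1.0, 2.0],
            bond=(1.4, 1.6),
        )
        run_dmd(sys_, t_end=50.0, thermostat_rate=0.0, frame_interval=50.0, seed=0)
        d = np.linalg.norm(sys_.positions[1] - sys_.positions[0])
        assert 1.4 - 1e-9 <= d <= 1.6 + 1e-9


def brute_force_events(sys_, t_end, dt=2e-5):
    """Tiny-step oracle: scan every pair each step, bisect each crossing.

    Returns the (time, sorted pair) event list. Independent of the
    event-driven scheduler: it advances all beads with tiny ballistic steps
    and detects boundary crossings by sign change.
    """
    pos = sys_.positions.copy()
    vel = sys_.velocities.copy()
    n = len(pos)
    inv_mass = 1.0 / sys_.masses
    inside = np.zeros((n, n), dtype=bool)
    d0 = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    inside |= (sys_.well_r2 > 0) & (d0**2 < sys_.well_r2)
    events = []
    t = 0.0

    def boundary(i, j, d):
        # returns signed distance to the next boundary for the pair state
        if sys_.bond_hi2[i, j] > 0:
            return min(
                d - np.sqrt(sys_.bond_lo2[i, j]), np.sqrt(sys_.bond_hi2[i, j]) - d
            )
        if sys_.well_r2[i, j] > 0:
            if inside[i, j]:
                return min(
                    d - np.sqrt(sys_.core2[i, j]) if sys_.core2[i, j] > 0 else np.inf,
                    np.sqrt(sys_.well_r2[i, j]) - d,
                )
            return d - np.sqrt(sys_.well_r2[i, j])
        if sys_.core2[i, j] > 0:
            return d - np.sqrt(sys_.core2[i, j])
        return np.inf

    while t < t_end:
        step = min(dt, t_end - t)
        new_pos = pos + vel * step
        hit = None
        for i in range(n):
            for j in range(i + 1, n):
                b0 = boundary(i, j, np.linalg.norm(pos[j] - pos[i]))
                b1 = boundary(i, j, np.linalg.norm(new_pos[j] - new_pos[i]))
                if b0 > 0 and b1 <= 0:
                    # bisect the crossing time
                    lo, hi = 0.0, step
                    for _ in range(60):
                        mid = 0.5 * (lo + hi)
                        dmid = np.linalg.norm(
                            (pos[j] + vel[j] * mid) - (pos[i] + vel[i] * mid)
                        )
                        if boundary(i, j, dmid) > 0:
                            lo = mid
                        else:
                            hi = mid
                    if hit is None or lo < hit[0]:
                        hit = (lo, i, j)
        if hit is None:
            pos = new_pos
            t += step
            continue
        tau, i, j = hit
        pos = pos + vel * tau
        t += tau
        events.append((t, (i, j)))
        # apply the same impulse rules as the engine
        r = pos[j] - pos[i]
        d = np.linalg.norm(r)
        u = r / d
        vr = float((vel[j] - vel[i]) @ u)
        mu = 1.0 / (inv_mass[i] + inv_mass[j])
        if sys_.bond_hi2[i, j] > 0 or (
            sys_.core2[i, j] > 0
            and np.isclose(d, np.sqrt(sys_.core2[i, j]), atol=1e-6)
        ):
            dvr = -2.0 * vr
        elif not inside[i, j]:  # well entry
            eps = sys_.well_eps[i, j]
            disc = vr * vr + 2 * eps / mu
            if disc > 0:
                dvr = np.sign(vr) * np.sqrt(disc) - vr
                inside[i, j] = inside[j, i] = True
            else:
                dvr = -2.0 * vr
        else:  # well exit attempt
            eps = sys_.well_eps[i, j]
            disc = vr * vr - 2 * eps / mu
            if disc > 0:
                dvr = np.sign(vr) * np.sqrt(disc) - vr
                inside[i, j] = inside[j, i] = False
            else:
                dvr = -2.0 * vr
        imp = mu * dvr
        vel[j] = vel[j] + imp * inv_mass[j] * u
        vel[i] = vel[i] - imp * inv_mass[i] * u
        pos = pos + vel * 1e-9  # nudge off the boundary
        t += 1e-9
    sys_.positions = pos
    sys_.velocities = vel
    return events


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_four_bead_event_sequence_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(-3, 3, size=(4, 3))
        vel = rng.normal(0, 0.3, size=(4, 3)) - 0.25 * pos  # drift inward
        sys_e = free_beads_system(
            positions=pos, velocities=vel, masses=[1.0, 2.0, 1.5, 3.0],
            core=1.5, well_r=3.0, well_eps=0.4,
        )
        sys_b = free_beads_system(
            positions=pos.copy(), velocities=vel.copy(),
            masses=[1.0, 2.0, 1.5, 3.0], core=1.5, well_r=3.0, well_eps=0.4,
        )
        t_end = 15.0
        traj = run_dmd(
            sys_e, t_end=t_end, thermostat_rate=0.0, frame_interval=t_end,
            seed=0, collect_events=True,
        )
        engine_events = traj.metadata["events"]
        oracle = brute_force_events(sys_b, t_end)
        assert len(engine_events) >= 3  # the trajectory is genuinely eventful
        assert len(engine_events) == len(oracle)
        for (te, pe), (to, po) in zip(engine_events, oracle):
            assert pe == po
            assert te == pytest.approx(to, abs=1e-6)
        # final states agree
        np.testing.assert_allclose(sys_e.positions, sys_b.positions, atol=1e-4)
        np.testing.assert_allclose(sys_e.velocities, sys_b.velocities, atol=1e-6)


class TestSystemSetup:
    def test_concentration_paper_conditions(self):
        assert concentration(48, 200.0) == pytest.approx(9.96, abs=0.01)

    def test_concentration_linearity(self):
        assert concentration(96, 200.0) == pytest.approx(
            2 * concentration(48, 200.0)
        )

    def test_concentration_volume_scaling(self):
        assert concentration(48, 400.0) == pytest.approx(
            concentration(48, 200.0) / 8
        )

    def test_full_system_bead_count_and_no_overlap(self, cg_params):
        system = build_cg_system("GNYTMFI", 48, 200.0, 310.0, cg_params, seed=0)
        assert system.n_beads == 48 * 7 * 4
        system.validate_constraints()

    def test_single_chain_momentum_zero(self, cg_params):
        system = build_cg_system("GNYTMFI", 1, 60.0, 310.0, cg_params, seed=1)
        p = (system.masses[:, None] * system.velocities).sum(axis=0)
        assert np.linalg.norm(p) < 1e-10

    def test_same_seed_identical_systems(self, cg_params):
        a = build_cg_system("GAIDWVK", 4, 60.0, 303.0, cg_params, seed=5)
        b = build_cg_system("GAIDWVK", 4, 60.0, 303.0, cg_params, seed=5)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.velocities, b.velocities)

    def test_overcrowded_box_raises(self, cg_params):
        with pytest.raises(Exception, match="box|place"):
            build_cg_system("GNYTMFI", 40, 32.0, 310.0, cg_params, seed=0)


class TestTemperature:
    def test_mb_sampling_recovers_temperature(self, cg_params):
        rng = np.random.default_rng(0)
        masses = np.full(10_000, 20.0)
        kT = cg_params.kT(310.0)
        vel = maxwell_boltzmann_velocities(masses, kT, rng)
        assert measure_temperature(vel, masses, cg_params) == pytest.approx(
            310.0, rel=0.03
        )

    def test_zero_velocities_zero_kelvin(self, cg_params):
        vel = np.zeros((10, 3))
        assert measure_temperature(vel, np.ones(10), cg_params) == 0.0

    def test_speed_doubling_quadruples_temperature(self, cg_params):
        rng = np.random.default_rng(1)
        masses = np.full(500, 10.0)
        vel = maxwell_boltzmann_velocities(masses, 0.3, rng)
        t1 = measure_temperature(vel, masses, cg_params)
        t2 = measure_temperature(2 * vel, masses, cg_params)
        assert t2 == pytest.approx(4 * t1, rel=1e-12)


class TestConservationAndThermostat:
    def test_energy_conservation_long_run(self, cg_params):
        system = build_cg_system("GAIDWVK", 4, 60.0, 310.0, cg_params, seed=2)
        traj = run_dmd(
            system, t_end=500.0, thermostat_rate=0.0, frame_interval=10.0,
            seed=0, max_events=100_000,
        )
        assert traj.metadata["n_events"] >= 90_000
        E = traj.total_energy()
        assert np.max(np.abs(E - E[0])) / abs(E[0]) < 1e-6
        system.validate_constraints(tol=1e-9)

    def test_thermostat_holds_set_point(self, cg_params):
        system = build_cg_system("GAIDWVK", 6, 70.0, 303.0, cg_params, seed=3)
        traj = run_dmd(
            system, t_end=300.0, thermostat_rate=0.2, frame_interval=10.0, seed=4
        )
        ke = np.array(traj.kinetic[5:])  # discard brief equilibration
        T = 2 * ke / (3 * system.n_beads) * cg_params.energy_scale_K
        assert T.mean() == pytest.approx(303.0, rel=0.03)

    def test_ghost_velocities_are_maxwell_boltzmann(self, cg_params):
        # single free bead, frequent ghost collisions: speeds after refresh
        # follow the Maxwell distribution at the set temperature
        sys_ = free_beads_system(
            positions=np.zeros((1, 3)) + 1.0,
            velocities=np.zeros((1, 3)),
            masses=[20.0],
            params=cg_params,
        )
        kT = cg_params.kT(310.0)
        sys_.temperature_K = 310.0
        traj = run_dmd(
            sys_, t_end=2000.0, thermostat_rate=1.0, frame_interval=500.0,
            seed=6, collect_events=True,
        )
        speeds = [np.linalg.norm(v) for _, _, v in traj.metadata["ghosts"]]
        assert len(speeds) > 500
        scale = np.sqrt(kT / 20.0)
        stat = kstest(speeds, maxwell(scale=scale).cdf)
        assert stat.pvalue > 0.01

    def test_invalid_t_end(self, cg_params):
        system = build_cg_system("GA", 1, 40.0, 310.0, cg_params, seed=0)
        with pytest.raises(EngineError):
            run_dmd(system, t_end=-1.0)


class TestTrajectory:
    def test_frame_times_strictly_increasing(self):
        traj = Trajectory()
        traj.append(1.0, np.zeros((2, 3)), 0.0, 0.0)
        with pytest.raises(EngineError):
            traj.append(1.0, np.zeros((2, 3)), 0.0, 0.0)

    def test_hdf5_round_trip(self, cg_params, tmp_path):
        system = build_cg_system("GA", 2, 40.0, 310.0, cg_params, seed=0)
        traj = run_dmd(system, t_end=20.0, frame_interval=5.0, seed=0)
        path = tmp_path / "t.h5"
        traj.save_hdf5(path)
        back = Trajectory.load_hdf5(path)
        assert back.times == traj.times
        np.testing.assert_allclose(back.positions[-1], traj.positions[-1])
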