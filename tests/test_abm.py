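"""Unit and property tests of the agent-based simulator."""

import math

import numpy as np
import pytest

from channelnet import (
    ConfigError,
    DegenerateContactError,
    ModelParams,
    SimConfig,
    TrajectorySet,
    find_neighbors,
    net_force,
    pair_force,
    run_simulation,
    step,
)
from channelnet.abm import _pairwise_net_forces, min_image, wrap_angle

L = 100.0


class TestPairForce:
    def test_contact_magnitude_is_f_base_and_adhesive(self, params, agent_factory):
        # exact contact: gap = 0, e^0 = 1, adhesive branch pulls i toward j
        a = agent_factory(0, 10.0, 10.0)
        b = agent_factory(1, 18.0, 10.0)  # distance 8 = R_i + R_j
        f = pair_force(a, b, params, L)
        assert np.hypot(*f) == pytest.approx(params.f_base, abs=1e-12)
        assert f[0] > 0  # i sits left of j and is pulled toward j (+x)

    def test_antisymmetry_exact(self, params, agent_factory):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = agent_factory(0, *rng.uniform(0, L, 2), role="leader")
            b = agent_factory(1, *rng.uniform(0, L, 2))
            fab = pair_force(a, b, params, L)
            fba = pair_force(b, a, params, L)
            np.testing.assert_array_equal(fab, -fba)

    def test_gap_alpha_magnitude_matches_independent_exponential(
        self, params, agent_factory
    ):
        # gap = alpha: magnitude F_base * e^-1, via independent evaluation
        gap = params.alpha
        a = agent_factory(0, 20.0, 50.0)
        b = agent_factory(1, 20.0 + 8.0 + gap, 50.0)
        f = pair_force(a, b, params, L)
        expected = params.f_base * math.exp(-1.0)
        assert np.hypot(*f) == pytest.approx(expected, rel=1e-12)

    def test_zero_beyond_cutoff(self, params, agent_factory):
        a = agent_factory(0, 10.0, 10.0)
        b = agent_factory(1, 10.0 + params.r_cut + 0.5, 10.0)
        np.testing.assert_array_equal(pair_force(a, b, params, L), [0.0, 0.0])

    def test_repulsive_when_overlapping(self, params, agent_factory):
        a = agent_factory(0, 10.0, 10.0)
        b = agent_factory(1, 14.0, 10.0)  # distance 4 < 8: overlap
        f = pair_force(a, b, params, L)
        assert f[0] < 0  # pushes i away from j (toward smaller x)

    def test_leader_scales_force(self, params, agent_factory):
        a = agent_factory(0, 10.0, 10.0)
        b = agent_factory(1, 18.0, 10.0)
        lead = agent_factory(1, 18.0, 10.0, role="leader")
        f_follow = np.hypot(*pair_force(a, b, params, L))
        f_lead = np.hypot(*pair_force(a, lead, params, L))
        assert f_lead == pytest.approx(params.leader_factor * f_follow)

    def test_minimum_image_across_boundary(self, params, agent_factory):
        a = agent_factory(0, 0.5, 50.0)
        b = agent_factory(1, L - 0.5, 50.0)  # periodic distance 1: overlap
        f = pair_force(a, b, params, L)
        assert f[0] > 0  # repelled away from j, which sits just left across wrap

    def test_coincident_centers_raises(self, params, agent_factory):
        a = agent_factory(0, 10.0, 10.0)
        b = agent_factory(1, 10.0, 10.0)
        with pytest.raises(DegenerateContactError):
            pair_force(a, b, params, L)


class TestFindNeighbors:
    def test_single_agent_empty(self, agent_factory):
        assert find_neighbors([agent_factory(0, 5, 5)], 10.0, L) == [[]]

    def test_periodic_pair(self, agent_factory):
        states = [agent_factory(0, 0.5, 5.0), agent_factory(1, L - 0.5, 5.0)]
        assert find_neighbors(states, 2.0, L) == [[1], [0]]

    @pytest.mark.parametrize("n,r_cut", [(20, 10.0), (50, 15.0), (200, 30.0)])
    def test_matches_all_pairs_oracle(self, agent_factory, n, r_cut):
        # brute-force all-pairs minimum-image search as independent oracle
        for seed in range(7):
            rng = np.random.default_rng(seed)
            pos = rng.uniform(0, L, size=(n, 2))
            states = [agent_factory(i, *pos[i]) for i in range(n)]
            got = find_neighbors(states, r_cut, L)
            for i in range(n):
                expect = sorted(
                    j for j in range(n)
                    if j != i
                    and np.hypot(*min_image(pos[i] - pos[j], L)) <= r_cut
                )
                assert got[i] == expect

    def test_r_cut_half_domain_invalid(self, agent_factory):
        with pytest.raises(ConfigError):
            find_neighbors([agent_factory(0, 5, 5)], L / 2, L)


class TestNetForce:
    def test_no_neighbors_zero(self, params, agent_factory):
        a = agent_factory(0, 5, 5)
        np.testing.assert_array_equal(net_force(a, [a], [], params, L), [0, 0])

    def test_mirrored_neighbors_cancel(self, params, agent_factory):
        center = agent_factory(0, 50, 50)
        left = agent_factory(1, 40, 50)
        right = agent_factory(2, 60, 50)
        f = net_force(center, [center, left, right], [1, 2], params, L)
        np.testing.assert_allclose(f, [0, 0], atol=1e-14)

    def test_collinear_sum_equals_pair_sum(self, params, agent_factory):
        a = agent_factory(0, 30, 50)
        b = agent_factory(1, 42, 50)
        c = agent_factory(2, 55, 50)
        f = net_force(a, [a, b, c], [1, 2], params, L)
        expected = pair_force(a, b, params, L) + pair_force(a, c, params, L)
        np.testing.assert_allclose(f, expected, rtol=1e-15)


class TestStep:
    def test_isolated_agent_moves_v0_dt_along_heading(self, params, agent_factory):
        theta = 0.7
        a = agent_factory(0, 50.0, 50.0, heading=theta, speed=0.5)
        rng = np.random.default_rng(0)
        (new,) = step([a], params, rng, L)
        expected = np.array([50.0, 50.0]) + 0.5 * params.dt * np.array(
            [math.cos(theta), math.sin(theta)]
        )
        np.testing.assert_allclose(new.position, expected, rtol=1e-15)
        assert new.heading == pytest.approx(theta)

    def test_deterministic_given_rng_state(self, agent_factory):
        p = ModelParams(noise_eta=0.4)
        rng1 = np.random.default_rng(42)
        rng2 = np.random.default_rng(42)
        states = [agent_factory(i, 10 * i + 5, 20, heading=0.3 * i) for i in range(5)]
        out1 = step(states, p, rng1, L)
        out2 = step(states, p, rng2, L)
        for s1, s2 in zip(out1, out2):
            np.testing.assert_array_equal(s1.position, s2.position)
            assert s1.heading == s2.heading

    def test_overlapping_pair_separates(self, params, agent_factory):
        # pure force response: v0 = 0, no noise -> repulsion must separate
        a = agent_factory(0, 50.0, 50.0, speed=0.0)
        b = agent_factory(1, 53.0, 50.0, speed=0.0)  # gap = -5
        rng = np.random.default_rng(0)
        before = 3.0
        out = step([a, b], params, rng, L)
        after = np.hypot(*min_image(out[0].position - out[1].position, L))
        assert after > before

    def test_heading_stays_wrapped(self, agent_factory):
        p = ModelParams(noise_eta=2.0)
        states = [agent_factory(i, 10 * i + 5, 50, heading=3.0) for i in range(8)]
        rng = np.random.default_rng(1)
        for _ in range(20):
            states = step(states, p, rng, L)
        for s in states:
            assert -math.pi <= s.heading < math.pi


class TestRunSimulation:
    def test_zero_steps_records_initial_frame_only(self):
        cfg = SimConfig(n_agents=10, n_steps=0, seed=5)
        traj = run_simulation(cfg)
        assert traj.n_frames == 1
        assert len(traj.frames) == 10
        assert (traj.frames["time"] == 0.0).all()

    def test_identical_config_identical_output(self, small_config):
        t1 = run_simulation(small_config)
        t2 = run_simulation(small_config)
        assert t1.frames.equals(t2.frames)

    def test_zero_noise_isolated_agent_path_length(self):
        p = ModelParams(noise_eta=0.0)
        cfg = SimConfig(
            domain_size=500.0, n_agents=1, n_steps=100, record_every=1,
            seed=2, params=p, v0=0.4,
        )
        traj = run_simulation(cfg)
        xy = traj.frames[["x", "y"]].to_numpy()
        steps = np.diff(xy, axis=0)
        steps -= 500.0 * np.round(steps / 500.0)
        path = np.hypot(steps[:, 0], steps[:, 1]).sum()
        assert path == pytest.approx(100 * 0.4 * p.dt, rel=1e-9)

    def test_leader_fraction_assignment(self):
        cfg = SimConfig(n_agents=40, leader_fraction=0.25, n_steps=0, seed=9)
        traj = run_simulation(cfg)
        assert (traj.frames["role"] == "leader").sum() == 10

    def test_positions_inside_domain(self, small_config):
        traj = run_simulation(small_config)
        xy = traj.frames[["x", "y"]].to_numpy()
        assert (xy >= 0).all() and (xy < small_config.domain_size).all()

    def test_frames_consecutive_and_shared(self, small_config):
        traj = run_simulation(small_config)
        per_agent = traj.frames.groupby("agent_id")["frame"].apply(list)
        expected = list(range(traj.n_frames))
        assert all(f == expected for f in per_agent)

    @pytest.mark.parametrize(
        "field,value",
        [("n_agents", 0), ("record_every", 0), ("leader_fraction", 1.5),
         ("domain_size", -1.0)],
    )
    def test_invalid_config_raises(self, field, value):
        cfg = SimConfig(**{field: value})
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_momentum_balance_forces_sum_to_zero(self):
        # pairwise antisymmetry: total interaction force vanishes
        rng = np.random.default_rng(8)
        pos = rng.uniform(0, L, size=(30, 2))
        p = ModelParams()
        forces, _ = _pairwise_net_forces(
            pos, np.full(30, 4.0), np.zeros(30, bool),
            np.zeros(30), p, L, np.random.default_rng(0),
        )
        np.testing.assert_allclose(forces.sum(axis=0), [0, 0], atol=1e-10)

    def test_stability_bound_displacement_under_radius(self):
        # reference run: no agent moves farther than its radius per step
        cfg = SimConfig(n_agents=200, n_steps=50, record_every=1, seed=3)
        traj = run_simulation(cfg)
        for _, sub in traj.frames.groupby("agent_id"):
            xy = sub.sort_values("frame")[["x", "y"]].to_numpy()
            d = np.diff(xy, axis=0)
            d -= cfg.domain_size * np.round(d / cfg.domain_size)
            assert np.hypot(d[:, 0], d[:, 1]).max() <= cfg.agent_radius


class TestSerialization:
    def test_config_yaml_round_trip(self, tmp_path, small_config):
        path = tmp_path / "cfg.yaml"
        small_config.to_yaml(path)
        back = SimConfig.from_yaml(path)
        assert back == small_config

    def test_trajectory_csv_round_trip(self, tmp_path, small_config):
        traj = run_simulation(small_config)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = TrajectorySet.from_csv(path)
        assert back.frames.equals(traj.frames)
        assert back.config == small_config

    def test_wrap_angle_range(self):
        angles = np.linspace(-12, 12, 1001)
        wrapped = wrap_angle(angles)
        assert (wrapped >= -np.pi).all() and (wrapped < np.pi).all()
        np.testing.assert_allclose(
            np.cos(wrapped), np.cos(angles), atol=1e-12
        )
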