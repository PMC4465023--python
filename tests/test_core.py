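"""Unit and property tests for the per-tick dynamical equations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from peercourse import ConnectionMatrix, ModelParams, PopulationState, step
from peercourse.core import (
    cost,
    peer_influence,
    reward,
    self_contribution,
    sigmoid,
    update_antisocial,
    update_connections,
)


def make_state(e, t=0, e0=None, history_sum=None):
    e = np.asarray(e, dtype=float)
    e0 = e if e0 is None else np.asarray(e0, dtype=float)
    return PopulationState(
        time=t,
        antisocial=e,
        intrinsic_prosocial=1.0 - e0,
        history_sum=e.copy() if history_sum is None else np.asarray(history_sum, float),
    )


class TestSigmoid:
    def test_midpoint_is_half(self, params):
        assert sigmoid(params.turning_point, params) == pytest.approx(0.5)

    def test_asymptotics(self, params):
        assert sigmoid(-1e6, params) == pytest.approx(0.0, abs=1e-12)
        assert sigmoid(1e6, params) == pytest.approx(1.0, abs=1e-12)

    def test_one_steepness_scale_above_midpoint(self, params):
        t = params.turning_point + params.sigmoid_steepness
        assert sigmoid(t, params) == pytest.approx(1 / (np.exp(-1) + 1), rel=1e-12)

    def test_strictly_increasing(self, params):
        ts = np.arange(0, params.n_steps + 1)
        vals = np.array([sigmoid(t, params) for t in ts])
        assert np.all(np.diff(vals) > 0)
        assert np.all((vals > 0) & (vals < 1))


class TestReward:
    def test_zero_at_time_zero(self, params):
        state = make_state([0.3, 0.5, 0.7])
        assert np.all(reward(state, 0, params) == 0)

    def test_plateau_value_for_average_agent(self, params):
        # gamma*t_p/(r*T) = 0.2*120/(0.5*300) = 0.16, below the linear 0.4
        state = make_state([0.5])
        assert reward(state, 300, params) == pytest.approx(0.16)

    def test_cap_binds_for_very_antisocial_agent(self, params):
        # r = 0.05: gamma*t_p/(r*T) = 1.6, so the cap at 1 binds
        state = make_state([0.95])
        assert reward(state, params.turning_point, params) == pytest.approx(1.0)

    def test_nondecreasing_and_constant_after_turning_point(self, params):
        state = make_state([0.2, 0.5, 0.8])
        vals = np.array([reward(state, t, params) for t in range(0, 301, 5)])
        assert np.all(np.diff(vals, axis=0) >= 0)
        after = np.array([reward(state, t, params) for t in (120, 150, 300)])
        assert np.allclose(after, after[0])

    def test_zero_prosocial_level_rejected(self, params):
        state = PopulationState(
            time=0,
            antisocial=np.array([0.5, 0.5]),
            intrinsic_prosocial=np.array([0.5, 0.0]),
            history_sum=np.array([0.5, 0.5]),
        )
        with pytest.raises(ValueError):
            reward(state, 10, params)


class TestCost:
    def test_fully_antisocial_history_zero_cost(self, params):
        t = 7
        state = make_state([1.0], t=t, history_sum=[float(t + 1)])
        assert cost(state, t, params) == pytest.approx(0.0)

    def test_half_history_at_turning_point(self, params):
        t = params.turning_point
        state = make_state([0.5], t=t, history_sum=[0.5 * (t + 1)])
        assert cost(state, t, params) == pytest.approx(0.25)

    def test_zero_history_equals_sigmoid(self, params):
        t = params.turning_point + int(params.sigmoid_steepness)
        state = make_state([0.0], t=t, history_sum=[0.0])
        assert cost(state, t, params) == pytest.approx(sigmoid(t, params))

    def test_time_mismatch_rejected(self, params):
        state = make_state([0.5], t=3, history_sum=[2.0])
        with pytest.raises(ValueError):
            cost(state, 4, params)


class TestPeerInfluence:
    def test_zero_when_levels_equal(self, params):
        state = make_state([0.4, 0.4, 0.4])
        conn = ConnectionMatrix(np.ones((3, 3)) - np.eye(3))
        assert np.all(peer_influence(state, conn, params) == 0)

    def test_direct_evaluation(self, params):
        state = make_state([0.1, 0.6])
        conn = ConnectionMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        d = peer_influence(state, conn, params)
        assert d[0, 1] == pytest.approx(0.05)  # c * A * (e_j - e_i) = 0.1*1*0.5
        assert d[1, 0] == pytest.approx(-0.05)

    def test_antisymmetric_under_symmetric_connections(self, params, rng):
        e = rng.uniform(0, 1, 6)
        w = rng.uniform(0, 1, (6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        d = peer_influence(make_state(e), ConnectionMatrix(w), params)
        assert np.allclose(d, -d.T)
        assert np.all(np.diagonal(d) == 0)

    def test_dimension_mismatch_rejected(self, params):
        state = make_state([0.1, 0.6])
        conn = ConnectionMatrix(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            peer_influence(state, conn, params)


class TestSelfContribution:
    @pytest.mark.parametrize(
        "g, e, expected",
        [
            (0.0, 0.3, 0.0),
            (1.0, 0.0, 1.0),
            (-0.5, 0.4, -0.2),
            (0.5, 1.0, 0.0),
            (-0.9, 0.0, 0.0),
        ],
    )
    def test_hand_values(self, g, e, expected):
        assert self_contribution(np.array([g]), np.array([e]))[0] == pytest.approx(
            expected
        )

    @given(
        g=st.floats(-0.999, 0.999),
        e=st.floats(0.0, 1.0),
    )
    def test_keeps_level_in_unit_interval(self, g, e):
        d = float(self_contribution(np.array([g]), np.array([e]))[0])
        assert abs(d) <= abs(g)
        assert 0.0 <= e + d <= 1.0


class TestUpdateAntisocial:
    def test_two_agent_hand_example(self):
        params = ModelParams(n_agents=2, influence_rate=0.1)
        state = make_state([0.2, 0.6])
        conn = ConnectionMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        d = peer_influence(state, conn, params)  # diagonal zero: g = 0
        e_next = update_antisocial(state, d, params)
        assert np.allclose(e_next, [0.22, 0.58])

    def test_fixed_point_when_levels_equal_and_no_net_reward(self, params):
        n = params.n_agents
        state = make_state(np.full(n, 0.37))
        conn = ConnectionMatrix(np.ones((n, n)) - np.eye(n))
        d = peer_influence(state, conn, params)
        assert np.allclose(update_antisocial(state, d, params), 0.37)

    def test_mean_conserved_with_frozen_symmetric_connections(self, params, rng):
        # antisymmetry of d_ij under symmetric A conserves sum(e) exactly
        n = 8
        w = rng.uniform(0, 1, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        conn = ConnectionMatrix(w)
        p = ModelParams(n_agents=n, seed=0)
        e = rng.uniform(0, 1, n)
        total = e.sum()
        state = make_state(e)
        for _ in range(200):
            d = peer_influence(state, conn, p)
            e = update_antisocial(state, d, p)
            state = make_state(e)
        assert e.sum() == pytest.approx(total, abs=1e-12)

    def test_out_of_range_result_is_loud(self):
        params = ModelParams(n_agents=2)
        state = make_state([0.99, 0.2])
        d = np.array([[2.1, 0.0], [0.0, 0.0]])  # forces e_0 past 1
        with pytest.raises(FloatingPointError):
            update_antisocial(state, d, params)


class TestUpdateConnections:
    def test_window_boundary_excluded(self, params):
        # |e_j - e_i| == mimicry_window exactly: no change
        e = np.array([0.3, 0.5])
        g = np.array([0.8, 0.8])
        conn = ConnectionMatrix(np.array([[0.0, 0.4], [0.4, 0.0]]))
        out = update_connections(conn, e, g, params)
        assert np.array_equal(out.weights, conn.weights)

    def test_absorbing_bounds(self, params):
        # with g = +0.9: dA_01 = +0.225 (peer above), dA_10 = -0.225 (peer below)
        e = np.array([0.30, 0.35])
        conn = ConnectionMatrix(np.array([[0.0, 1.0], [0.0, 0.0]]))
        out = update_connections(conn, e, np.array([0.9, 0.9]), params)
        assert out.weights[0, 1] == pytest.approx(1.0)  # 1 is absorbing upward
        assert out.weights[1, 0] == pytest.approx(0.0)  # 0 is absorbing downward

    def test_hand_example(self):
        params = ModelParams(mimicry_window=0.2)
        e = np.array([0.4, 0.5])
        g = np.array([0.5, 0.0])
        conn = ConnectionMatrix(np.array([[0.0, 0.5], [0.5, 0.0]]))
        out = update_connections(conn, e, g, params)
        # dA = (0.5/0.2)*0.1 = 0.25; A' = 0.5 + 0.25*0.5 = 0.625
        assert out.weights[0, 1] == pytest.approx(0.625)
        assert out.weights[1, 0] == pytest.approx(0.5)  # g_1 = 0: row 1 frozen

    def test_directionality_row_driven_by_own_net_reward(self, params):
        e = np.array([0.4, 0.5])
        g = np.array([0.5, -0.5])
        conn = ConnectionMatrix(np.array([[0.0, 0.5], [0.5, 0.0]]))
        out = update_connections(conn, e, g, params)
        assert out.weights[0, 1] > 0.5  # agent 0: positive g, more antisocial peer
        assert out.weights[1, 0] > 0.5  # agent 1: negative g, less antisocial peer

    @given(
        a=st.floats(0.0, 1.0),
        delta=st.floats(-1.0, 1.0),
    )
    def test_bound_map_preserves_unit_interval(self, a, delta):
        # the two-branch update maps [0,1] into [0,1] for any dA in [-1,1]
        new = a + delta * (1 - a) if delta >= 0 else a + delta * a
        assert -1e-15 <= new <= 1 + 1e-15

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_random_updates_stay_in_bounds(self, seed):
        params = ModelParams()
        rng = np.random.default_rng(seed)
        n = 5
        w = rng.uniform(0, 1, (n, n))
        np.fill_diagonal(w, 0)
        e = rng.uniform(0, 1, n)
        g = rng.uniform(-1, 1, n) * 0.999
        out = update_connections(ConnectionMatrix(w), e, g, params)
        assert np.all(out.weights >= 0) and np.all(out.weights <= 1)
        assert np.all(np.diagonal(out.weights) == 0)


class TestStep:
    def test_diagnostics_identity(self, params):
        state = make_state(np.linspace(0.2, 0.8, params.n_agents))
        w = np.full((params.n_agents,) * 2, 0.3)
        np.fill_diagonal(w, 0)
        _, _, diag = step(state, ConnectionMatrix(w), params)
        assert np.allclose(diag.net_reward, diag.reward - diag.cost)
        assert np.all(np.abs(diag.self_contribution) <= np.abs(diag.net_reward))

    def test_step_composes_sub_operations(self, params, rng):
        n = params.n_agents
        e = rng.uniform(0.1, 0.9, n)
        state = make_state(e)
        w = rng.uniform(0, 1, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        conn = ConnectionMatrix(w)

        new_state, new_conn, diag = step(state, conn, params)

        d = peer_influence(state, conn, params)
        a = reward(state, 0, params)
        b = cost(state, 0, params)
        g = a - b
        conn_expected = update_connections(conn, e, g, params)
        np.fill_diagonal(d, self_contribution(g, e))
        e_expected = update_antisocial(state, d, params)

        assert np.array_equal(new_state.antisocial, e_expected)
        assert np.array_equal(new_conn.weights, conn_expected.weights)
        assert new_state.time == 1
        assert np.array_equal(new_state.history_sum, e + e_expected)

    def test_reward_off_levels_decay(self):
        # gamma -> 0 makes g = -b <= 0, so identical agents only decay
        params = ModelParams(n_agents=2, reward_rate=1e-9)
        state = make_state([0.6, 0.6])
        conn = ConnectionMatrix(np.array([[0.0, 0.5], [0.5, 0.0]]))
        levels = [state.antisocial.copy()]
        for _ in range(250):
            state, conn, _ = step(state, conn, params)
            levels.append(state.antisocial.copy())
        levels = np.array(levels)
        assert np.all(np.diff(levels, axis=0) <= 0)
        assert np.all(levels[-1] < 0.1)

    def test_consensus_without_reward_and_cost(self, params, rng):
        # pure peer imitation on a frozen positive symmetric network
        # contracts the spread monotonically to below 1e-6
        n = 6
        p = ModelParams(n_agents=n)
        w = rng.uniform(0.2, 1.0, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        conn = ConnectionMatrix(w)
        e = rng.uniform(0, 1, n)
        state = make_state(e)
        spread = [e.max() - e.min()]
        for _ in range(3000):
            d = peer_influence(state, conn, p)
            e = update_antisocial(state, d, p)
            state = make_state(e)
            spread.append(e.max() - e.min())
            if spread[-1] < 1e-6:
                break
        assert spread[-1] < 1e-6
        assert all(s1 <= s0 for s0, s1 in zip(spread, spread[1:]))


class TestBoundedness:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_benchmark_trajectories_stay_in_bounds(self, seed):
        from peercourse import run

        traj = run(ModelParams(seed=seed), snapshot_times=(150,))
        assert np.all(traj.antisocial >= 0) and np.all(traj.antisocial <= 1)
        _, w = traj.network_snapshots[0]
        assert np.all(w >= 0) and np.all(w <= 1)
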