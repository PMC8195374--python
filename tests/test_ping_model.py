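"""Unit and property tests for the PING network core."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gammaecho as ge
from gammaecho.ping_model import (
    ROLE_EXCITATORY,
    SPIKE_THRESHOLD,
    SimulationState,
    initial_state,
)


class TestSigmoidGate:
    @pytest.mark.parametrize(
        "v,expected",
        [
            (0.0, 0.5),
            (30.0, 1.0 / (1.0 + np.exp(-15.0))),
            (-65.0, 1.0 / (1.0 + np.exp(32.5))),
        ],
    )
    def test_closed_form(self, v, expected):
        assert ge.sigmoid_gate(v) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(-60, 60), st.floats(0.01, 20))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, v, dv):
        # restricted to the range where float64 resolves the increase
        assert ge.sigmoid_gate(v + dv) > ge.sigmoid_gate(v)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            ge.sigmoid_gate(np.nan)
        with pytest.raises(ValueError):
            ge.sigmoid_gate(np.inf)


class TestConnectivity:
    def test_block_structure_and_bounds(self, default_config):
        conn = ge.build_connectivity(default_config, seed=3)
        n_e = default_config.n_e
        w = conn.weights
        # E->E block identically zero under defaults
        assert np.all(w[:n_e, :n_e] == 0.0)
        # every entry bounded by its block's base strength
        assert w[:n_e, n_e:].max() <= default_config.c_ie
        assert w[n_e:, :n_e].max() <= default_config.c_ei
        assert w[n_e:, n_e:].max() <= default_config.c_ii
        assert np.all(w >= 0)
        assert np.all(np.diag(w) == 0.0)

    def test_deterministic_given_seed(self, small_config):
        a = ge.build_connectivity(small_config, seed=11).weights
        b = ge.build_connectivity(small_config, seed=11).weights
        assert np.array_equal(a, b)
        c = ge.build_connectivity(small_config, seed=12).weights
        assert not np.array_equal(a, c)

    def test_negative_strength_rejected(self):
        with pytest.raises(ValueError):
            ge.NetworkConfig(c_ie=-0.001)

    def test_weights_look_uniform(self, default_config):
        # realized I->E weights should fill (0, c_ie) roughly uniformly
        conn = ge.build_connectivity(default_config, seed=5)
        w = conn.weights[: default_config.n_e, default_config.n_e :].ravel()
        assert w.mean() == pytest.approx(default_config.c_ie / 2, rel=0.05)


class TestSynapticCurrent:
    def _state(self, conn, v):
        n = len(conn.cell_roles)
        n_e = conn.n_e
        return SimulationState(
            v=np.full(n, float(v)),
            u=np.zeros(n),
            s_ampa=np.zeros(n_e),
            s_gaba=np.zeros(n - n_e),
        )

    def test_zero_gates_zero_current(self, small_connectivity):
        state = self._state(small_connectivity, -65.0)
        i_syn = ge.synaptic_current(state, small_connectivity, ge.SynapseKinetics())
        assert np.all(i_syn == 0.0)

    def test_gaba_reversal_on_e_cancels(self):
        # single I->E connection at the E-cell GABA reversal gives zero drive
        cfg = ge.NetworkConfig(n_e=1, n_i=1)
        conn = ge.ConnectivityMatrix(
            weights=np.array([[0.0, 0.006], [0.0, 0.0]]),
            cell_roles=cfg.roles(),
        )
        state = SimulationState(
            v=np.array([-70.0, -65.0]),
            u=np.zeros(2),
            s_ampa=np.zeros(1),
            s_gaba=np.ones(1),
        )
        i_syn = ge.synaptic_current(state, conn, ge.SynapseKinetics())
        assert i_syn[0] == pytest.approx(0.0, abs=1e-15)

    def test_ampa_arithmetic(self):
        # E->I with C=0.003, s=0.5, v_I=-65: 0.003*0.5*(0-(-65)) = 0.0975
        cfg = ge.NetworkConfig(n_e=1, n_i=1)
        conn = ge.ConnectivityMatrix(
            weights=np.array([[0.0, 0.0], [0.003, 0.0]]),
            cell_roles=cfg.roles(),
        )
        state = SimulationState(
            v=np.array([-65.0, -65.0]),
            u=np.zeros(2),
            s_ampa=np.array([0.5]),
            s_gaba=np.zeros(1),
        )
        i_syn = ge.synaptic_current(state, conn, ge.SynapseKinetics())
        assert i_syn[1] == pytest.approx(0.0975, rel=1e-12)

    def test_shape_mismatch_rejected(self, small_connectivity):
        state = self._state(small_connectivity, -65.0)
        state.v = state.v[:-1]
        with pytest.raises(ValueError):
            ge.synaptic_current(state, small_connectivity, ge.SynapseKinetics())


class TestStep:
    def _isolated_e(self):
        cfg = ge.NetworkConfig(n_e=1, n_i=1, c_ei=0.0, c_ie=0.0, c_ii=0.0)
        conn = ge.build_connectivity(cfg, seed=0)
        return cfg, conn

    def test_euler_arithmetic_from_rest(self):
        # isolated E cell, I=0, v=-65, u=b*v: v' = 0.04*4225 - 325 + 140 + 13 = -3
        cfg, conn = self._isolated_e()
        state = SimulationState(
            v=np.array([-65.0, -65.0]),
            u=np.array([-13.0, -13.0]),
            s_ampa=np.zeros(1),
            s_gaba=np.zeros(1),
        )
        new, spiked = ge.step(state, (0.0, 0.0), conn, config=cfg, dt=1.0)
        assert new.v[0] == pytest.approx(-68.0)
        assert not spiked.any()

    def test_reset_rule(self):
        # a cell pushed over threshold is reset to c with u incremented by d
        cfg, conn = self._isolated_e()
        state = SimulationState(
            v=np.array([29.0, -65.0]),
            u=np.array([0.0, -13.0]),
            s_ampa=np.zeros(1),
            s_gaba=np.zeros(1),
        )
        new, spiked = ge.step(state, (0.0, 0.0), conn, config=cfg, dt=1.0)
        assert spiked[0]
        assert new.v[0] == cfg.cell_params_e.c
        # u was updated by Euler then incremented by d
        expected_u = 0.0 + cfg.cell_params_e.a * (cfg.cell_params_e.b * 29.0 - 0.0)
        assert new.u[0] == pytest.approx(expected_u + cfg.cell_params_e.d)

    def test_repetitive_firing_constant_drive(self):
        # isolated RS cell with I=12.25 fires repetitively (>=1 spike / 100 ms)
        cfg, conn = self._isolated_e()
        state = initial_state(ge.NetworkConfig(n_e=1, n_i=1, v0_spread=0.0), rng=0)
        dt = 0.1
        spikes = 0
        for _ in range(int(1000 / dt)):
            state, spiked = ge.step(state, (12.25, 0.0), conn, config=cfg, dt=dt)
            spikes += int(spiked[0])
        assert spikes >= 10

    def test_nan_state_rejected(self):
        cfg, conn = self._isolated_e()
        state = SimulationState(
            v=np.array([np.nan, -65.0]),
            u=np.zeros(2),
            s_ampa=np.zeros(1),
            s_gaba=np.zeros(1),
        )
        with pytest.raises(FloatingPointError, match="cell 0"):
            ge.step(state, (0.0, 0.0), conn, config=cfg)


class TestSimulate:
    def test_bit_identical_given_seed(self, small_config):
        stim = ge.constant_drive(duration_ms=500)
        a = ge.simulate(small_config, stim, seed=4)
        b = ge.simulate(small_config, stim, seed=4)
        assert np.array_equal(a.mean_field, b.mean_field)
        for sa, sb in zip(a.spikes, b.spikes):
            assert np.array_equal(sa, sb)

    def test_zero_input_settles_near_rest(self, small_config):
        # with I=0 the quadratic dynamics have a stable fixed point near -70 mV
        stim = ge.constant_drive(0.0, 0.0, duration_ms=2000)
        res = ge.simulate(small_config, stim, seed=1)
        late = res.mean_field[1000:]
        assert np.all(np.abs(late + 70.0) < 5.0)
        for s in res.spikes:
            assert np.all(s <= 500.0)  # at most an initial transient spike

    def test_gating_bounds_throughout(self, small_config):
        stim = ge.constant_drive(duration_ms=300)
        conn = ge.build_connectivity(small_config, seed=2)
        state = initial_state(small_config, rng=2)
        for _ in range(300):
            state, _ = ge.step(state, (12.25, 5.25), conn, config=small_config)
            assert np.all((state.s_ampa >= 0) & (state.s_ampa <= 1))
            assert np.all((state.s_gaba >= 0) & (state.s_gaba <= 1))

    def test_mean_field_bounds_and_spike_times(self, small_config):
        stim = ge.constant_drive(duration_ms=1000)
        res = ge.simulate(small_config, stim, seed=3)
        assert np.all((res.mean_field >= -90) & (res.mean_field <= SPIKE_THRESHOLD))
        assert len(res.mean_field) == len(res.time)
        for s in res.spikes:
            assert np.all((s >= 0) & (s <= 1000.0))

    def test_short_stimulus_rejected(self, small_config):
        stim = ge.constant_drive(duration_ms=100)
        with pytest.raises(ValueError, match="stimulus"):
            ge.simulate(small_config, stim, duration_ms=200)


class TestMeanField:
    def test_average_over_e_cells_only(self, small_config):
        stim = ge.constant_drive(duration_ms=200)
        res = ge.simulate(small_config, stim, seed=5, record_traces=True)
        expected = res.v_traces[:, : small_config.n_e].mean(axis=1)
        assert np.allclose(ge.mean_field(res), expected)
        with_i = res.v_traces.mean(axis=1)
        assert not np.allclose(expected, with_i)

    def test_two_cells_average(self):
        res = ge.SimulationResult(
            time=np.array([1.0]),
            spikes=[np.array([]), np.array([]), np.array([])],
            mean_field=np.array([0.0]),
            config=ge.NetworkConfig(n_e=2, n_i=1),
            seed=None,
            v_traces=np.array([[-60.0, -70.0, -50.0]]),
        )
        assert ge.mean_field(res)[0] == pytest.approx(-65.0)


class TestTwoCellOracle:
    """Coarse-step integration against an independent fine-step reference."""

    @staticmethod
    def _reference(dt, dur_ms=1000.0, i_e=12.25, i_i=5.25, w_ei=0.003, w_ie=0.006):
        # straightforward scalar Euler integration of the same equations
        a = np.array([0.02, 0.1])
        d = np.array([8.0, 2.0])
        v = np.array([-65.0, -65.0])
        u = 0.2 * v
        s = np.zeros(2)  # [ampa gate of E, gaba gate of I]
        counts = np.zeros(2, dtype=int)
        n = int(round(dur_ms / dt))
        for _ in range(n):
            i_syn = np.array(
                [w_ie * s[1] * (-70.0 - v[0]), w_ei * s[0] * (0.0 - v[1])]
            )
            v_new = v + dt * (0.04 * v * v + 5 * v + 140 - u + np.array([i_e, i_i]) + i_syn)
            u = u + dt * a * (0.2 * v - u)
            gate = 1.0 / (1.0 + np.exp(-v / 2.0))
            s = np.clip(
                s + dt * (12.0 * gate * (1 - s) - np.array([0.5, 0.1]) * s), 0, 1
            )
            fired = v_new > 30.0
            counts += fired
            v = np.where(fired, -65.0, v_new)
            u = np.where(fired, u + d, u)
        return counts

    def test_package_path_matches_reference_at_same_dt(self):
        """The simulate() loop agrees exactly with an independent scalar loop."""
        cfg = ge.NetworkConfig(n_e=1, n_i=1, c_ii=0.0, v0_spread=0.0)
        conn = ge.ConnectivityMatrix(
            weights=np.array([[0.0, 0.006], [0.003, 0.0]]), cell_roles=cfg.roles()
        )
        state = SimulationState(
            v=np.array([-65.0, -65.0]), u=np.array([-13.0, -13.0]),
            s_ampa=np.zeros(1), s_gaba=np.zeros(1),
        )
        counts = np.zeros(2, dtype=int)
        for _ in range(1000):
            state, spiked = ge.step(state, (12.25, 5.25), conn, config=cfg, dt=1.0)
            counts += spiked
        ref = self._reference(1.0)
        assert np.array_equal(counts, ref)

    def test_e_cell_rate_stable_under_refinement(self):
        """RS spike count is insensitive to the Euler step (FS is not)."""
        coarse = self._reference(1.0)
        fine = self._reference(0.01)
        assert abs(int(coarse[0]) - int(fine[0])) <= 1


class TestSerialization:
    def test_npz_json_round_trip(self, tmp_path, small_config):
        stim = ge.constant_drive(duration_ms=300)
        res = ge.simulate(small_config, stim, seed=9)
        res.save(tmp_path / "run")
        back = ge.SimulationResult.load(tmp_path / "run")
        assert np.array_equal(back.mean_field, res.mean_field)
        assert back.config == res.config
        for a, b in zip(res.spikes, back.spikes):
            assert np.array_equal(np.sort(a), np.sort(b))

    def test_raster_frame_columns(self, small_config):
        res = ge.simulate(small_config, ge.constant_drive(duration_ms=200), seed=1)
        df = res.raster_frame()
        assert list(df.columns) == ["cell_id", "spike_time_ms"]
        assert len(df) == sum(len(s) for s in res.spikes)


class TestConfig:
    def test_resize_preserves_ratio(self):
        cfg = ge.NetworkConfig().with_total_size(200)
        assert (cfg.n_e, cfg.n_i) == (160, 40)

    def test_resize_rejects_bad_total(self):
        with pytest.raises(ValueError):
            ge.NetworkConfig().with_total_size(123)

    def test_default_cell_parameters(self):
        cfg = ge.NetworkConfig()
        pe, pi = cfg.cell_params_e, cfg.cell_params_i
        assert (pe.a, pe.b, pe.c, pe.d) == (0.02, 0.2, -65.0, 8.0)
        assert (pi.a, pi.b, pi.c, pi.d) == (0.1, 0.2, -65.0, 2.0)

    def test_reset_above_threshold_rejected(self):
        with pytest.raises(ValueError):
            ge.CellParameters(a=0.02, b=0.2, c=35.0, d=8.0, role=ROLE_EXCITATORY)
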