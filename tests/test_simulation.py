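"""Current assembly against loop oracles; engine-level invariants."""

from __future__ import annotations

import numpy as np
import pytest

from spikepc import (
    SimulationConfig,
    WeightMatrix,
    build_network,
    error_currents,
    gist_current,
    present_stimulus,
    representation_currents,
)
from spikepc.simulation import assemble_currents


@pytest.fixture
def toy_net():
    return build_network([6, 4, 3], n_gist=2, P_c=0.5, seed=12)


class TestErrorCurrents:
    def test_perfect_prediction_silences_both(self):
        rng = np.random.default_rng(0)
        W = WeightMatrix(rng.random((4, 6)))
        X_above = rng.random(4)
        X_same = W.values.T @ X_above
        ip, im = error_currents(X_same, X_above, W)
        assert np.allclose(ip, 0) and np.allclose(im, 0)

    def test_antisymmetry(self):
        """Positive and negative error drives cancel exactly elementwise."""
        rng = np.random.default_rng(1)
        W = WeightMatrix(rng.random((5, 7)))
        ip, im = error_currents(rng.random(7), rng.random(5), W)
        assert np.allclose(ip + im, 0.0)

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(2)
        W = WeightMatrix(rng.random((3, 4)))
        xs, xa = rng.random(4), rng.random(3)
        ip, _ = error_currents(xs, xa, W)
        for j in range(4):
            expected = xs[j] - sum(W.values[i, j] * xa[i] for i in range(3))
            assert ip[j] == pytest.approx(expected)

    def test_shape_mismatch_rejected(self):
        W = WeightMatrix(np.ones((3, 4)))
        with pytest.raises(ValueError):
            error_currents(np.ones(4), np.ones(4), W)


class TestRepresentationCurrents:
    def test_silent_errors_no_ffg_give_zero(self):
        W = WeightMatrix(np.ones((4, 6)))
        I = representation_currents(
            np.zeros(6), np.zeros(6), W,
            X_E_same_plus=np.zeros(4), X_E_same_minus=np.zeros(4),
            ffg_enabled=False,
        )
        assert np.allclose(I, 0.0)

    def test_top_area_ignores_same_area_terms(self):
        """The top area has no top-down input, so no same-area error terms."""
        rng = np.random.default_rng(3)
        W = WeightMatrix(rng.random((4, 6)))
        ep, em = rng.random(6), rng.random(6)
        I_top = representation_currents(ep, em, W, is_top=True, ffg_enabled=False)
        assert np.allclose(I_top, W.values @ ep - W.values @ em)

    def test_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(4)
        W = WeightMatrix(rng.random((4, 6)))
        Wg = WeightMatrix(rng.random((4, 2)))
        ep, em = rng.random(6), rng.random(6)
        sp, sm = rng.random(4), rng.random(4)
        xg = rng.random(2)
        I = representation_currents(ep, em, W, sp, sm, xg, Wg)
        for i in range(4):
            expected = (
                sum(W.values[i, j] * (ep[j] - em[j]) for j in range(6))
                - sp[i] + sm[i]
                + sum(Wg.values[i, k] * xg[k] for k in range(2))
            )
            assert I[i] == pytest.approx(expected)


class TestGistCurrent:
    def test_zero_input_traces(self):
        W = WeightMatrix(np.ones((2, 5)))
        assert np.allclose(gist_current(np.zeros(5), W), 0.0)

    def test_scalar_case(self):
        assert gist_current(np.array([3.0]), WeightMatrix(np.array([[0.5]])))[0] \
            == pytest.approx(1.5)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        W = WeightMatrix(rng.random((3, 6)))
        x = rng.random(6)
        I = gist_current(x, W)
        for i in range(3):
            assert I[i] == pytest.approx(sum(W.values[i, j] * x[j] for j in range(6)))


class TestPresentStimulus:
    def test_zero_weights_zero_floor_gives_total_silence(self, toy_net):
        """Without drive above rheobase and with zero weights nothing fires."""
        for W in toy_net.W_inter:
            W.values[:] = 0.0
        toy_net.W_input_gist.values[:] = 0.0
        cfg = SimulationConfig(T=200.0, t_w=50.0)
        buf = present_stimulus(toy_net, np.zeros(6), cfg)
        assert all(c.sum() == 0 for c in buf.spike_counts.values())
        assert all(np.allclose(v, 0) for v in buf.window_means.values())

    def test_antisymmetric_error_drive_every_step(self, toy_net):
        """I_E+ = -I_E- at every step of a live presentation."""
        currents = np.full(6, 2500.0)
        cfg = SimulationConfig(T=100.0, t_w=20.0)
        toy_net.reset_state()
        for _ in range(100):
            I = assemble_currents(toy_net, currents, cfg)
            for l in (0, 1):
                assert np.allclose(I[f"E+{l}"] + I[f"E-{l}"], 0.0)
            for name in toy_net.population_names():
                pop = toy_net.population(name)
                from spikepc import detect_spikes_and_reset, step_membrane, update_glutamate, update_trace
                step_membrane(pop.state, toy_net.params, I[name], cfg.dt)
                detect_spikes_and_reset(pop.state, toy_net.params)
                update_glutamate(pop.trace, pop.state.spiked, cfg.dt)
                update_trace(pop.trace, cfg.dt)

    def test_both_pathways_disabled_only_input_spikes(self, toy_net):
        cfg = SimulationConfig(T=300.0, t_w=100.0, pc_enabled=False,
                               ffg_enabled=False)
        buf = present_stimulus(toy_net, np.full(6, 3000.0), cfg)
        assert buf.spike_counts["R0"].sum() > 0
        for name, counts in buf.spike_counts.items():
            if name != "R0":
                assert counts.sum() == 0

    def test_ffg_toggle_changes_only_gist_terms_at_first_step(self, toy_net):
        currents = np.full(6, 2000.0)
        toy_net.reset_state()
        I_on = assemble_currents(toy_net, currents, SimulationConfig())
        I_off = assemble_currents(toy_net, currents,
                                  SimulationConfig(ffg_enabled=False))
        for name in I_on:
            if name == "G":
                continue  # the gist population itself is silenced
            if name.startswith("R") and name != "R0":
                gist_term = toy_net.trace_gain * (
                    toy_net.W_gist_R[int(name[1:]) - 1].values @ toy_net.G.trace.X
                )
                assert np.allclose(I_on[name] - I_off[name], gist_term)
            else:
                assert np.array_equal(I_on[name], I_off[name])

    def test_deterministic_rasters(self, toy_net):
        cfg = SimulationConfig(T=150.0, t_w=50.0, record_full_traces=True)
        currents = np.linspace(600, 3000, 6)
        a = present_stimulus(toy_net, currents, cfg)
        b = present_stimulus(toy_net, currents, cfg)
        for name in a.spikes:
            assert np.array_equal(a.spikes[name], b.spikes[name])

    def test_input_length_checked(self, toy_net):
        with pytest.raises(ValueError):
            present_stimulus(toy_net, np.zeros(5), SimulationConfig())

    def test_current_assembly_matches_per_synapse_loop(self, toy_net):
        """Whole-network assembly equals a naive per-synapse accumulation."""
        rng = np.random.default_rng(6)
        # give the traces non-trivial values
        for pop in toy_net.populations():
            pop.trace.X[:] = rng.random(pop.trace.n)
        cfg = SimulationConfig()
        I = assemble_currents(toy_net, np.zeros(6), cfg)
        g = toy_net.trace_gain
        sizes = [6, 4, 3]
        L = 2
        for l in range(L):
            W = toy_net.W_inter[l].values
            xr = toy_net.R[l].trace.X
            xa = toy_net.R[l + 1].trace.X
            for j in range(sizes[l]):
                pred = sum(W[i, j] * xa[i] for i in range(sizes[l + 1]))
                assert I[f"E+{l}"][j] == pytest.approx(g * (xr[j] - pred))
        for l in (1, 2):
            W = toy_net.W_inter[l - 1].values
            ep = toy_net.E_plus[l - 1].trace.X
            em = toy_net.E_minus[l - 1].trace.X
            Wg = toy_net.W_gist_R[l - 1].values
            xg = toy_net.G.trace.X
            for i in range(sizes[l]):
                val = sum(W[i, j] * (ep[j] - em[j]) for j in range(sizes[l - 1]))
                val += sum(Wg[i, k] * xg[k] for k in range(xg.size))
                if l != L:
                    val += -toy_net.E_plus[l].trace.X[i] + toy_net.E_minus[l].trace.X[i]
                assert I[f"R{l}"][i] == pytest.approx(g * val)


class TestSimulationConfig:
    def test_window_must_fit_in_duration(self):
        with pytest.raises(ValueError):
            SimulationConfig(T=100.0, t_w=200.0)

    def test_dt_must_divide_duration(self):
        with pytest.raises(ValueError):
            SimulationConfig(dt=3.0, T=100.0, t_w=10.0)
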