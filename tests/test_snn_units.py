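import numpy as np
import pytest

from sbpsnn.snn import (HomeostasisState, LIFParams, LIFState, SBPParams,
                        STDPParams, STPParams, STPState, homeostatic_adjust,
                        init_small_world, lif_step, loss_mse, rbm_bp_update,
                        rbm_loss, sbp_backpropagate, small_world_weights,
                        stdp_delta, stp_update)


class TestLIF:
    P = LIFParams(tau_m=0.02, v_rest=0.0, v_reset=0.0, v_th=1.0,
                  t_ref=0.002, r_m=1.0)

    def _first_spike_time(self, current, dt=0.001):
        state = LIFState()
        for i in range(1, 20000):
            state, spiked = lif_step(state, current, self.P, dt)
            if spiked:
                return i * dt
        return None

    def test_subthreshold_never_spikes(self):
        state = LIFState()
        for _ in range(5000):
            state, spiked = lif_step(state, 0.9, self.P, 0.001)
            assert not spiked

    @pytest.mark.parametrize("current", np.linspace(1.2, 5.0, 10))
    def test_first_spike_time_matches_closed_form(self, current):
        dt = 0.001
        ri = self.P.r_m * current
        expected = self.P.tau_m * np.log(ri / (ri - (self.P.v_th - self.P.v_rest)))
        measured = self._first_spike_time(current, dt)
        assert measured is not None
        assert abs(measured - expected) <= 2 * dt

    def test_refractory_clamps_membrane(self):
        state = LIFState(v=0.3, refrac=0.01)
        new, spiked = lif_step(state, 100.0, self.P, 0.001)
        assert not spiked and new.v == 0.3
        assert new.refrac == pytest.approx(0.009)

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError, match="dt must be positive"):
            lif_step(LIFState(), 1.0, self.P, 0.0)


class TestSTP:
    P = STPParams(U=0.2, tau_f=0.2, tau_d=0.3)

    def test_rest_fixed_point(self):
        state = STPState(u=0.5, R=0.4)
        for _ in range(100):
            state, eff = stp_update(state, False, self.P, 0.1)
            assert eff == 0.0
        assert state.u == pytest.approx(0.0, abs=1e-6)
        assert state.R == pytest.approx(1.0, abs=1e-6)

    def test_first_spike_from_rest_releases_U_w(self):
        _state, eff = stp_update(STPState(), True, self.P, 1e-9, w=2.0)
        assert eff == pytest.approx(self.P.U * 2.0, rel=1e-6)

    def test_regular_train_matches_hand_recursion(self):
        """20 Hz train reproduced by explicitly iterating the recursion."""
        dt = 0.05
        fdec, ddec = np.exp(-dt / self.P.tau_f), np.exp(-dt / self.P.tau_d)
        u = 0.0
        R = 1.0
        state = STPState()
        for _ in range(10):
            u = u * fdec
            R = 1.0 - (1.0 - R) * ddec
            u = u + self.P.U * (1 - u)
            expected = u * R
            R = R * (1 - u)
            state, eff = stp_update(state, True, self.P, dt)
            assert eff == pytest.approx(expected, rel=1e-9)

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError, match="invalid STP state"):
            stp_update(STPState(u=1.5, R=0.5), True, self.P, 0.01)


class TestSTDP:
    P = STDPParams(a_plus=0.01, a_minus=0.01, tau_plus=0.02, tau_minus=0.02)

    def test_sign_rule(self):
        assert stdp_delta(0.005, self.P) > 0
        assert stdp_delta(-0.005, self.P) < 0
        assert stdp_delta(0.0, self.P) == 0.0

    def test_decay_to_zero(self):
        assert stdp_delta(10.0, self.P) == pytest.approx(0.0, abs=1e-12)
        assert stdp_delta(-10.0, self.P) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_parameters_give_antisymmetric_window(self):
        for t in (0.001, 0.01, 0.05):
            assert abs(stdp_delta(t, self.P)) == pytest.approx(
                abs(stdp_delta(-t, self.P)), rel=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            stdp_delta(np.nan, self.P)


class TestHomeostasis:
    def test_on_target_rate_unchanged(self):
        s = HomeostasisState(1.0, 1.0)
        out = homeostatic_adjust(s, 20.0, 20.0)
        assert out.v_th == 1.0

    def test_silent_neuron_threshold_decreases_to_floor(self):
        s = HomeostasisState(1.0, 1.0)
        prev = s.v_th
        for _ in range(200):
            s = homeostatic_adjust(s, 0.0, 20.0)
            assert s.v_th <= prev
            prev = s.v_th
        assert s.v_th == pytest.approx(0.5)

    def test_hyperactive_neuron_reaches_upper_bound(self):
        s = HomeostasisState(1.0, 1.0)
        for _ in range(200):
            s = homeostatic_adjust(s, 40.0, 20.0)
        assert s.v_th == pytest.approx(2.0)

    def test_bad_target_rejected(self):
        with pytest.raises(ValueError):
            homeostatic_adjust(HomeostasisState(1.0, 1.0), 5.0, 0.0)


class TestLoss:
    def test_zero_at_match(self):
        assert loss_mse([0.2, 0.8], [0.2, 0.8]) == 0.0

    def test_swapped_one_hot(self):
        assert loss_mse([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        assert loss_mse([0.8, 0.3], [1.0, 0.0]) == pytest.approx(0.065)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            loss_mse([1.0], [1.0, 0.0])


class TestSBPMirror:
    P = SBPParams(rho_ltp=0.5, rho_ltd=0.25)

    def test_zero_deltas_zero_output(self):
        out = sbp_backpropagate(np.zeros((3, 2)), np.ones((4, 3), bool), self.P)
        assert np.all(out == 0)

    def test_off_switch(self):
        dW = np.array([[1.0], [-2.0]])
        out = sbp_backpropagate(dW, np.ones((3, 2), bool),
                                SBPParams(rho_ltp=0.0, rho_ltd=0.0))
        assert np.all(out == 0)

    def test_single_delta_mirrored_with_proportion(self):
        dW = np.zeros((2, 1))
        dW[0, 0] = 0.4                       # potentiating delta +d on j=0
        active = np.zeros((3, 2), bool)
        active[1, 0] = True                  # one active input synapse i=1 -> j=0
        out = sbp_backpropagate(dW, active, self.P)
        assert out[1, 0] == pytest.approx(0.5 * 0.4)
        assert np.count_nonzero(out) == 1

    def test_depressing_part_uses_rho_ltd(self):
        dW = np.array([[-1.0, 0.5]])         # j=0: pot 0.5, dep -1.0
        active = np.ones((1, 1), bool)
        out = sbp_backpropagate(dW, active, self.P)
        assert out[0, 0] == pytest.approx(0.5 * 0.5 + 0.25 * (-1.0))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sbp_backpropagate(np.zeros((3, 2)), np.ones((4, 5), bool), self.P)


class TestRBMReference:
    def _random_net(self, rng, n_in=5, n_hid=4, n_out=3, n_batch=6):
        w1 = rng.standard_normal((n_in, n_hid)) * 0.5
        w2 = rng.standard_normal((n_hid, n_out)) * 0.5
        x = rng.standard_normal((n_batch, n_in))
        o = rng.random((n_batch, n_out))
        return [w1, w2], (x, o)

    def test_zero_learning_rate_zero_deltas(self, rng):
        weights, batch = self._random_net(rng)
        d1, d2 = rbm_bp_update(weights, batch, eta=0.0)
        assert np.all(d1 == 0) and np.all(d2 == 0)

    @pytest.mark.parametrize("trial", range(20))
    def test_gradient_matches_central_finite_differences(self, trial):
        rng = np.random.default_rng(trial)
        weights, batch = self._random_net(rng)
        eta = 1.0
        deltas = rbm_bp_update(weights, batch, eta)
        eps = 1e-6
        for wi, (w, d) in enumerate(zip(weights, deltas)):
            idx = (rng.integers(w.shape[0]), rng.integers(w.shape[1]))
            wp = [a.copy() for a in weights]
            wm = [a.copy() for a in weights]
            wp[wi][idx] += eps
            wm[wi][idx] -= eps
            num = (rbm_loss(wp, *batch) - rbm_loss(wm, *batch)) / (2 * eps)
            assert d[idx] == pytest.approx(-eta * num, rel=1e-5, abs=1e-10)


class TestSmallWorldInit:
    def test_infinite_radius_no_longrange_is_complete(self, rng):
        pos = rng.standard_normal((10, 3)) * 10
        w, mask, local = small_world_weights(pos, pos, radius=1e9, p_long=0.0,
                                             rng=np.random.default_rng(0))
        assert mask.all() and local.all()

    def test_local_positive_fraction_near_80_percent(self, rng):
        pos_pre = rng.standard_normal((40, 3)) * 5
        pos_post = rng.standard_normal((40, 3)) * 5
        w, mask, local = small_world_weights(pos_pre, pos_post, radius=1e9,
                                             p_long=0.0,
                                             rng=np.random.default_rng(1))
        signs = np.sign(w[local & (w != 0)])
        assert len(signs) >= 500
        frac_pos = (signs > 0).mean()
        assert 0.75 <= frac_pos <= 0.85

    def test_empty_graph_rejected(self, rng):
        pos = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        with pytest.raises(ValueError, match="zero connections"):
            small_world_weights(pos, pos + 1000, radius=1.0, p_long=0.0,
                                rng=np.random.default_rng(0))

    def test_grid_init_shapes_and_dale_signs(self, montage):
        from sbpsnn.encode import build_node_grid
        grid = build_node_grid(montage)
        w_in, mask, local, w_out, sign, pos = init_small_world(
            grid, n_out=4, seed=0)
        assert w_in.shape == (100, 200) and w_out.shape == (200, 4)
        assert (sign > 0).sum() == (sign < 0).sum() == 100
        assert np.all(w_out[sign > 0] >= 0)
        assert np.all(w_out[sign < 0] <= 0)
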