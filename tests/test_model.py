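"""ODE core: Hill kinetics, vector field, integration, relaxation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pflswitch import equilibria, model, protocols
from pflswitch.params import KineticParameters, SystemState
from tests.conftest import grid27, random_valid_params


class TestHill:
    def test_zero_input_gives_zero(self):
        assert model.hill(0.0, 2.5, 3.0) == 0.0

    @pytest.mark.parametrize("n", [1.0, 2.0, 4.0, 7.5])
    def test_half_saturation_identity(self, n):
        assert model.hill(3.7, 3.7, n) == pytest.approx(0.5)

    def test_direct_arithmetic(self):
        # 2^4 / (1^4 + 2^4) = 16/17
        assert model.hill(2.0, 1.0, 4.0) == pytest.approx(16.0 / 17.0)

    @pytest.mark.parametrize("K,n", [(0.0, 2.0), (-1.0, 2.0), (1.0, 0.5)])
    def test_domain_errors(self, K, n):
        with pytest.raises(ValueError):
            model.hill(1.0, K, n)

    @given(st.floats(0, 1e6), st.floats(1e-3, 1e3), st.floats(1, 8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_and_monotone(self, x, K, n):
        # mathematically in [0, 1); float rounding can saturate at 1.0
        y = model.hill(x, K, n)
        assert 0.0 <= y <= 1.0
        assert model.hill(x * 1.5 + 1e-9, K, n) >= y


class TestRhs:
    def test_origin_fixed_without_basal(self):
        p = KineticParameters(basal_Tw=0, basal_P=0, basal_T=0)
        assert np.allclose(model.rhs([0, 0, 0], 0.0, p), 0.0)

    def test_feedback_ablation_removes_T_dependence(self, dox_ref):
        p = dox_ref.replace(v_feedback=0.0)
        d1 = model.rhs([1.0, 1.0, 0.5], 0.3, p)
        d2 = model.rhs([1.0, 1.0, 7.5], 0.3, p)
        assert d1[0] == pytest.approx(d2[0] + p.deg_T * (7.5 - 0.5) * 0)  # dTw equal
        assert d1[0] == d2[0]

    def test_injection_mode_adds_stimulus_to_sensed_tnc(self, injection):
        state = [2.0, 0.5, 0.5]
        with_stim = model.rhs(state, 3.0, injection, mode="tnc_injection")
        shifted = model.rhs([2.0, 0.5, 3.5], 0.0, injection, mode="tnc_injection")
        # same sensed TNC, but degradation acts on the endogenous level only
        assert with_stim[0] + injection.deg_Tw * 2.0 == pytest.approx(
            shifted[0] + injection.deg_Tw * 2.0
        )

    def test_negative_state_rejected(self, dox_ref):
        with pytest.raises(ValueError):
            model.rhs([-0.1, 0.0, 0.0], 0.0, dox_ref)

    def test_finite_difference_matches_trajectory(self, dox_ref):
        """The vector field must be the time derivative of the integrated
        trajectory (central finite difference at t > 0)."""
        init = SystemState(0.5, 0.3, 0.2)
        t = np.linspace(0.0, 1.0, 2001)
        traj = model.integrate(dox_ref, protocols.constant(0.8, 1.0), init, t)
        i = 1000
        fd = (traj.states[i + 1] - traj.states[i - 1]) / (t[i + 1] - t[i - 1])
        an = model.rhs(traj.states[i], 0.8, dox_ref)
        assert np.allclose(fd, an, rtol=1e-4, atol=1e-6)

    def test_jacobian_matches_numerical(self, dox_ref):
        state = np.array([1.3, 0.7, 2.1])
        J = model.jacobian(state, 0.4, dox_ref)
        eps = 1e-6
        for j in range(3):
            dx = np.zeros(3)
            dx[j] = eps
            col = (model.rhs(state + dx, 0.4, dox_ref)
                   - model.rhs(state - dx, 0.4, dox_ref)) / (2 * eps)
            assert np.allclose(J[:, j], col, rtol=1e-5, atol=1e-7)


class TestIntegrate:
    def test_zero_everything_stays_zero(self):
        p = KineticParameters(basal_Tw=0, basal_P=0, basal_T=0,
                              vmax_dox=0, v_feedback=0, vmax_TwP=0, vmax_PT=0)
        traj = model.integrate(p, protocols.null_protocol(5.0),
                               SystemState(0, 0, 0), np.linspace(0, 5, 20))
        assert np.allclose(traj.states, 0.0)

    def test_fixed_point_is_stationary(self, dox_ref):
        fp = equilibria.find_fixed_points(dox_ref, 0.4, "dox")[0]
        t = np.linspace(0, 50, 51)
        traj = model.integrate(dox_ref, protocols.constant(0.4, 50.0), fp.state, t,
                               rtol=1e-8)
        assert np.allclose(traj.states, fp.state.as_array(), rtol=1e-7, atol=1e-9)

    def test_step_reaches_high_branch(self, dox_ref):
        """A super-threshold step must land within 1% of the high steady
        state found independently by root finding."""
        low = equilibria.find_fixed_points(dox_ref, 0.0, "dox")[0].state
        high = equilibria.find_fixed_points(dox_ref, 1.0, "dox")[-1]
        traj = model.integrate(dox_ref, protocols.dox_step(1.0, 0.0, 200.0),
                               low, np.linspace(0.0, 200.0, 50))
        assert traj.final_state.T == pytest.approx(high.T, rel=1e-2)

    def test_grid_outside_protocol_rejected(self, dox_ref):
        with pytest.raises(ValueError):
            model.integrate(dox_ref, protocols.null_protocol(1.0),
                            SystemState(0, 0, 0), [0.0, 2.0])

    def test_deterministic_bitwise(self, dox_ref):
        init = SystemState(0.1, 0.1, 0.1)
        t = np.linspace(0, 10, 101)
        proto = protocols.dox_step(1.0, 2.0, 10.0)
        a = model.integrate(dox_ref, proto, init, t)
        b = model.integrate(dox_ref, proto, init, t)
        assert np.array_equal(a.states, b.states)

    @pytest.mark.parametrize("seed", range(4))
    def test_non_negativity_random_models(self, seed):
        rng = np.random.default_rng(seed)
        p = random_valid_params(rng)
        init = SystemState(*rng.uniform(0, 5, 3))
        traj = model.integrate(p, protocols.dox_step(1.0, 0.0, 30.0), init,
                               np.linspace(0, 30, 121))
        assert np.all(traj.states >= -1e-10)


class TestRelax:
    def test_fixed_point_returned_unchanged(self, dox_ref):
        fp = equilibria.find_fixed_points(dox_ref, 0.0, "dox")[0]
        r = model.relax_to_steady(dox_ref, 0.0, fp.state)
        assert r.converged
        assert np.allclose(r.state.as_array(), fp.state.as_array(), atol=1e-6)

    def test_bistable_initial_condition_dependence(self, dox_ref):
        """Inside the bistable window, low and high initial conditions must
        relax to the two distinct stable equilibria."""
        stim = 0.5
        fps = [fp for fp in equilibria.find_fixed_points(dox_ref, stim, "dox")
               if fp.stable]
        assert len(fps) == 2
        lo = model.relax_to_steady(dox_ref, stim, SystemState(0, 0, 0)).state
        ub = dox_ref.production_bound()
        hi = model.relax_to_steady(dox_ref, stim, SystemState(*ub)).state
        assert lo.T == pytest.approx(fps[0].T, rel=1e-4, abs=1e-6)
        assert hi.T == pytest.approx(fps[1].T, rel=1e-4)
        assert hi.T > lo.T * 5

    def test_open_cascade_unique_steady_state(self, open_cascade):
        """With the feedback ablated the steady state is unique and has a
        closed form: solve Tw, then P, then T sequentially."""
        p, stim = open_cascade, 0.7
        tw = (p.basal_Tw + p.vmax_dox * model.hill(stim, p.km_dox, p.n_dox)) / p.deg_Tw
        pp, tt = equilibria.downstream_equilibrium(tw, p)
        expected = np.array([tw, pp, tt])
        for init in grid27(p):
            r = model.relax_to_steady(p, stim, init)
            assert r.converged
            assert np.allclose(r.state.as_array(), expected, rtol=1e-6, atol=1e-8)
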