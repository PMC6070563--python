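"""Hysteresis metrics, dTNC irreversibility, phase diagrams."""

import math

import numpy as np
import pytest

from pflswitch import equilibria, model, protocols, switch
from tests.conftest import random_valid_params

GRID = np.linspace(0.0, 2.0, 81)


def slow_ramp_delta_tnc(params, s_max, mode, ramp_time):
    """Independent oracle: integrate an explicit slow up-then-down ramp and
    compare TNC at the start and end (both at zero stimulus)."""
    seg_up = protocols.Segment(0.0, ramp_time, 0.0, s_max)
    seg_down = protocols.Segment(ramp_time, 2 * ramp_time, s_max, 0.0)
    # settle at zero stimulus after the ramp returns
    seg_tail = protocols.Segment(2 * ramp_time, 2.5 * ramp_time, 0.0)
    proto = protocols.StimulusProtocol(mode, (seg_up, seg_down, seg_tail))
    init = equilibria.find_fixed_points(params, 0.0, mode)[0].state
    t = np.linspace(0.0, 2.5 * ramp_time, 201)
    traj = model.integrate(params, proto, init, t)
    return float(traj.gene("T")[-1] - traj.gene("T")[0])


class TestHysteresis:
    def test_feedback_ablation_reversible(self, open_cascade):
        h = switch.hysteresis(open_cascade, GRID)
        assert h.delta_tnc == pytest.approx(0.0, abs=switch.EPS_REV)
        assert h.width == 0.0
        assert h.reversible

    def test_reference_model_reversible_with_hysteresis(self, dox_ref):
        h = switch.hysteresis(dox_ref, GRID, method="continuation")
        assert h.reversible
        assert h.bistable
        assert 0 < h.theta_off < h.theta_on
        assert h.width > 0

    def test_strong_feedback_irreversible(self, dox_ref):
        h = switch.hysteresis(dox_ref.replace(v_feedback=80.0), GRID,
                              method="continuation")
        assert h.delta_tnc > switch.EPS_REV
        assert math.isnan(h.theta_off)
        assert not h.reversible

    def test_grid_must_start_at_zero(self, dox_ref):
        with pytest.raises(ValueError):
            switch.hysteresis(dox_ref, np.linspace(0.1, 1.0, 10))

    @pytest.mark.parametrize("v_feedback", [0.0, 35.0, 80.0])
    def test_quasi_static_matches_slow_ramp(self, dox_ref, v_feedback):
        """The quasi-static dTNC must agree with a slow explicit ramp whose
        duration is much longer than every relaxation time."""
        p = dox_ref.replace(v_feedback=v_feedback)
        h = switch.hysteresis(p, GRID, method="relax")
        ramp = slow_ramp_delta_tnc(p, GRID[-1], "dox", ramp_time=600.0)
        assert ramp == pytest.approx(h.delta_tnc, rel=0.02, abs=2e-3)

    def test_delta_tnc_non_negative_random_models(self):
        for seed in range(5):
            p = random_valid_params(np.random.default_rng(seed))
            h = switch.hysteresis(p, np.linspace(0, 2, 41), method="continuation")
            assert h.delta_tnc >= -switch.EPS_REV


class TestPulse:
    def test_null_pulse(self, injection):
        assert switch.delta_tnc_for_pulse(injection, 0.0) == 0.0

    def test_reversible_anchor_any_amplitude(self, injection):
        p = injection.replace(km_feedback=10.0, v_feedback=15.0)
        for tnc_max in (1.0, 3.0, 10.0):
            d = switch.delta_tnc_for_pulse(p, tnc_max, method="continuation")
            assert d == pytest.approx(0.0, abs=switch.EPS_REV)

    def test_irreversible_anchor_at_pulse_3(self, injection):
        p = injection.replace(km_feedback=5.0, v_feedback=30.0)
        assert switch.delta_tnc_for_pulse(p, 3.0, method="continuation") > switch.EPS_REV


class TestPulseTrajectory:
    """Time-domain counterpart of the quasi-static pulse: integrate an
    actual slow trapezoidal exogenous-TNC pulse through the ODE."""

    def _run_pulse(self, params, tnc_max):
        proto = protocols.tnc_pulse(tnc_max, t_rise=40.0, t_plateau=20.0,
                                    t_fall=40.0, t_tail=60.0)
        init = equilibria.find_fixed_points(params, 0.0, "tnc_injection")[0].state
        t = np.linspace(0.0, proto.t_end, 161)
        return model.integrate(params, proto, init, t), init

    def test_irreversible_preset_latches(self, injection):
        p = injection.replace(km_feedback=5.0, v_feedback=30.0)
        traj, init = self._run_pulse(p, 3.0)
        assert traj.final_state.T > init.T + 1.0

    def test_reversible_preset_returns_to_baseline(self, injection):
        p = injection.replace(km_feedback=10.0, v_feedback=15.0)
        traj, init = self._run_pulse(p, 3.0)
        assert traj.final_state.T == pytest.approx(init.T, abs=switch.EPS_REV)


class TestClassifyPhase:
    def test_ablated_feedback_is_phase_one(self, open_cascade):
        assert switch.classify_phase(open_cascade) == "I"

    @pytest.mark.parametrize("km,v,phase", [(5.0, 30.0, "II"), (10.0, 15.0, "I")])
    def test_injection_anchors(self, injection, km, v, phase):
        p = injection.replace(km_feedback=km, v_feedback=v)
        assert switch.classify_phase(p, mode="tnc_injection") == phase


class TestPhaseDiagram:
    def test_single_cell_matches_classify(self, dox_ref):
        pd_ = switch.phase_diagram(
            dox_ref, ("v_feedback", [80.0]), ("km_feedback", [5.0]),
            stimulus_grid=GRID)
        assert pd_.phases.shape == (1, 1)
        assert pd_.phases[0, 0] == switch.classify_phase(dox_ref.replace(
            v_feedback=80.0), stimulus_grid=GRID)

    def test_two_phases_high_v_corner(self, dox_ref):
        pd_ = switch.phase_diagram(
            dox_ref,
            ("v_feedback", np.linspace(0.0, 80.0, 6)),
            ("twist_stability", np.linspace(4.0, 16.0, 5)),
            stimulus_grid=GRID)
        labels = set(pd_.phases.ravel())
        assert labels == {"I", "II"}
        assert pd_.phases[-1, -1] == "II"  # strongest feedback, most stable Twist1
        assert pd_.phases[0, 0] == "I"

    def test_boundary_monotone_in_km(self, injection):
        """The critical feedback strength for irreversibility must not
        decrease as the feedback half-saturation rises."""
        v_grid = np.linspace(5.0, 50.0, 10)
        km_grid = np.array([3.0, 5.0, 8.0, 12.0])
        pd_ = switch.phase_diagram(injection, ("v_feedback", v_grid),
                                   ("km_feedback", km_grid), mode="tnc_injection")
        crit = []
        for j in range(km_grid.size):
            col = pd_.phases[:, j]
            idx = np.nonzero(col == "II")[0]
            crit.append(v_grid[idx[0]] if idx.size else np.inf)
        assert all(a <= b + 1e-9 for a, b in zip(crit, crit[1:]))

    def test_bad_axis_name_rejected(self, dox_ref):
        with pytest.raises(ValueError):
            switch.phase_diagram(dox_ref, ("not_a_param", [1.0]),
                                 ("v_feedback", [1.0]))

    def test_deterministic(self, dox_ref):
        args = (dox_ref, ("v_feedback", [0.0, 80.0]), ("km_feedback", [5.0]))
        a = switch.phase_diagram(*args, stimulus_grid=GRID)
        b = switch.phase_diagram(*args, stimulus_grid=GRID)
        assert np.array_equal(a.delta_tnc, b.delta_tnc)


class TestWidthCurve:
    def test_reference_progression(self, dox_ref):
        """Width grows with feedback strength ('enlarged the hysteresis
        width') while the activation threshold stays put, until the loop
        turns irreversible (open-ended)."""
        vgrid = np.array([0.0, 16.0, 32.0, 36.0, 40.0, 48.0, 64.0, 80.0])
        wc = switch.hysteresis_width_curve(dox_ref, vgrid, stimulus_grid=GRID)
        closed = ~wc.open_ended
        assert np.all(np.diff(wc.width[closed]) >= -1e-9)
        assert wc.open_ended[-1]
        w = wc.width[closed]
        assert w[0] == 0.0 and w[-1] > 0.1
        # theta_on stability among bistable, still-reversible points
        th = wc.theta_on[closed & ~np.isnan(wc.theta_on)]
        assert th.size >= 2
        assert (th.max() - th.min()) / th.max() < 0.20
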