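"""ODE core of the three-gene positive-feedback loop.

The loop is a Hill-activation cascade with linear degradation:

    dTw/dt = basal_Tw + vmax_dox * h(D;  km_dox, n_dox)
                      + v_feedback * h(T_sensed; km_feedback, n_feedback)
                      - deg_Tw * Tw
    dP/dt  = basal_P + vmax_TwP * h(Tw; km_TwP, n_TwP) - deg_P * P
    dT/dt  = basal_T + vmax_PT  * h(P;  km_PT,  n_PT)  - deg_T * T

with h(x; K, n) = x^n / (K^n + x^n).  In ``dox`` mode the stimulus D is
the doxycycline level and the sensed TNC is the endogenous level T; in
``tnc_injection`` mode D = 0 and the feedback senses T plus the exogenous
stimulus (secreted and injected protein pool together).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .params import KineticParameters, SystemState, Trajectory
from .protocols import StimulusProtocol, constant

MODES = ("dox", "tnc_injection")

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10

#: steady-state convergence threshold on max |dx/dt| (a.u. / day)
EPS_SS = 1e-8


class IntegrationError(RuntimeError):
    """Raised when the stiff solver fails; carries the failing time."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (t = {t_fail:g})")
        self.t_fail = t_fail


def hill(x, K: float, n: float):
    """Hill activation fraction ``x^n / (K^n + x^n)``.

    Accepts scalars or arrays; monotone non-decreasing in ``x`` and in
    ``[0, 1)`` on the valid domain ``x >= 0, K > 0, n >= 1``.
    """
    if K <= 0:
        raise ValueError(f"half-saturation K must be > 0, got {K}")
    if n < 1:
        raise ValueError(f"Hill coefficient n must be >= 1, got {n}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("hill input x must be >= 0")
    # work in (x/K)^n to avoid overflow for large x
    r = np.power(x / K, n)
    out = r / (1.0 + r)
    out = np.where(np.isinf(r), 1.0, out)
    return float(out) if out.ndim == 0 else out


def _hill_deriv(x: float, K: float, n: float) -> float:
    """d/dx of the Hill fraction at x >= 0."""
    if x == 0:
        return 0.0 if n > 1 else 1.0 / K
    r = (x / K) ** n
    if np.isinf(r):
        return 0.0
    return n * r / (x * (1.0 + r) ** 2)


def _split_inputs(stimulus: float, T: float, mode: str) -> tuple[float, float]:
    """Map (stimulus, endogenous T) to (dox level D, sensed TNC)."""
    if mode == "dox":
        return stimulus, T
    if mode == "tnc_injection":
        return 0.0, T + stimulus
    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def rhs(
    state,
    stimulus: float,
    params: KineticParameters,
    mode: str = "dox",
) -> np.ndarray:
    """Time derivatives (a.u./day) of (Tw, P, T) at the given state."""
    arr = state.as_array() if isinstance(state, SystemState) else np.asarray(state, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"negative state components: {arr}")
    Tw, P, T = arr
    p = params
    D, T_sensed = _split_inputs(stimulus, T, mode)
    dTw = (
        p.basal_Tw
        + p.vmax_dox * hill(D, p.km_dox, p.n_dox)
        + p.v_feedback * hill(T_sensed, p.km_feedback, p.n_feedback)
        - p.deg_Tw * Tw
    )
    dP = p.basal_P + p.vmax_TwP * hill(Tw, p.km_TwP, p.n_TwP) - p.deg_P * P
    dT = p.basal_T + p.vmax_PT * hill(P, p.km_PT, p.n_PT) - p.deg_T * T
    return np.array([dTw, dP, dT])


def jacobian(
    state,
    stimulus: float,
    params: KineticParameters,
    mode: str = "dox",
) -> np.ndarray:
    """Analytic 3x3 Jacobian of :func:`rhs` with respect to (Tw, P, T)."""
    arr = state.as_array() if isinstance(state, SystemState) else np.asarray(state, dtype=float)
    Tw, P, T = np.maximum(arr, 0.0)
    p = params
    _, T_sensed = _split_inputs(stimulus, T, mode)
    J = np.zeros((3, 3))
    # Tw row: feedback through sensed TNC (dT_sensed/dT = 1 in both modes)
    J[0, 0] = -p.deg_Tw
    J[0, 2] = p.v_feedback * _hill_deriv(T_sensed, p.km_feedback, p.n_feedback)
    J[1, 0] = p.vmax_TwP * _hill_deriv(Tw, p.km_TwP, p.n_TwP)
    J[1, 1] = -p.deg_P
    J[2, 1] = p.vmax_PT * _hill_deriv(P, p.km_PT, p.n_PT)
    J[2, 2] = -p.deg_T
    return J


def _solve_segment(params, mode, level_fn, y0, t0, t1, t_eval, rtol, atol):
    def f(t, y):
        return rhs(np.maximum(y, 0.0), level_fn(t), params, mode)

    def jac(t, y):
        return jacobian(y, level_fn(t), params, mode)

    sol = solve_ivp(
        f,
        (t0, t1),
        y0,
        method="LSODA",
        jac=jac,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(sol.message, sol.t[-1] if sol.t.size else t0)
    return sol


def integrate(
    params: KineticParameters,
    protocol: StimulusProtocol,
    initial: SystemState,
    t_grid,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate the loop ODE under a piecewise stimulus protocol.

    Integration restarts at protocol breakpoints so step discontinuities do
    not degrade the stiff solver.  Output states are clipped at zero (the
    solver can undershoot by ~atol).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("empty time grid")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be > 0")
    if t_grid[0] < protocol.t_start - 1e-12 or t_grid[-1] > protocol.t_end + 1e-12:
        raise ValueError(
            f"t_grid [{t_grid[0]}, {t_grid[-1]}] outside protocol span "
            f"[{protocol.t_start}, {protocol.t_end}]"
        )

    states = np.empty((t_grid.size, 3))
    y = initial.as_array()
    breaks = protocol.breakpoints(t_grid[0], t_grid[-1])
    idx = 0
    if t_grid[0] == breaks[0]:
        states[0] = y
        idx = 1
    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        # pick this interval's segment via its midpoint (breakpoints are
        # ambiguous for step protocols) and evaluate levels through it
        tm = 0.5 * (t0 + t1)
        seg = next((s for s in protocol.segments if s.t_start <= tm <= s.t_end), None)
        if seg is None:
            lvl = lambda t: 0.0  # noqa: E731 - gap in coverage means zero input
        else:
            lvl = lambda t, s=seg: s.value(min(max(t, t0), t1))
        sel = (t_grid > t0) & (t_grid <= t1)
        t_eval = np.append(t_grid[sel], t1) if (not t_grid[sel].size or t_grid[sel][-1] < t1) else t_grid[sel]
        sol = _solve_segment(params, protocol.mode, lvl, y, t0, t1, t_eval, rtol, atol)
        n = t_grid[sel].size
        if n:
            states[idx : idx + n] = np.maximum(sol.y[:, :n].T, 0.0)
            idx += n
        y = np.maximum(sol.y[:, -1], 0.0)
    return Trajectory(t_grid, states, protocol.levels(t_grid), mode=protocol.mode)


@dataclass(frozen=True)
class RelaxationResult:
    state: SystemState
    converged: bool
    t_elapsed: float


def relax_to_steady(
    params: KineticParameters,
    stimulus_level: float,
    initial: SystemState,
    mode: str = "dox",
    eps_ss: float = EPS_SS,
    t_max: float = 2000.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> RelaxationResult:
    """Integrate under constant stimulus until the dynamics stall.

    Convergence means the max-norm of the vector field falls below
    ``eps_ss`` (a.u./day).  Non-convergence within ``t_max`` days returns a
    flagged result rather than raising — sweeps must be able to continue
    past a slow grid point.
    """
    y = initial.as_array()
    if np.max(np.abs(rhs(y, stimulus_level, params, mode))) < eps_ss:
        return RelaxationResult(SystemState.from_array(y), True, 0.0)

    def f(t, yy):
        return rhs(np.maximum(yy, 0.0), stimulus_level, params, mode)

    def jac(t, yy):
        return jacobian(yy, stimulus_level, params, mode)

    t = 0.0
    chunk = 25.0
    while t < t_max:
        t1 = min(t + chunk, t_max)
        sol = solve_ivp(f, (t, t1), y, method="LSODA", jac=jac, rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(sol.message, sol.t[-1] if sol.t.size else t)
        y = np.maximum(sol.y[:, -1], 0.0)
        t = t1
        if np.max(np.abs(rhs(y, stimulus_level, params, mode))) < eps_ss:
            return RelaxationResult(SystemState.from_array(y), True, t)
        chunk = min(chunk * 2, 400.0)
    return RelaxationResult(SystemState.from_array(y), False, t)


def simulate_constant(
    params: KineticParameters,
    level: float,
    initial: SystemState,
    t_grid,
    mode: str = "dox",
    **kw,
) -> Trajectory:
    """Convenience wrapper: integrate under a constant stimulus."""
    t_grid = np.asarray(t_grid, dtype=float)
    proto = constant(level, float(t_grid[-1]), mode=mode, t_start=float(min(t_grid[0], 0.0)))
    return integrate(params, proto, initial, t_grid, **kw)
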