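"""Hysteresis thresholds, the irreversibility measure dTNC, phase diagrams.

The central quantity is dTNC (``delta_tnc``): after a quasi-static sweep of
the stimulus from zero past the activation threshold and back to zero, the
difference between the final and initial TNC levels at zero stimulus.
dTNC = 0 marks a reversible switch (phase I); dTNC > 0 an irreversible one
(phase II) — the loop stays on even after the stimulus is gone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import equilibria
from .params import KineticParameters

#: a.u. threshold separating "dTNC = 0" (reversible) from "dTNC > 0"
EPS_REV = 1e-3
#: adjacent-point ratio defining a discontinuous jump along a branch
JUMP_RATIO = 5.0

PHASE_REVERSIBLE = "I"
PHASE_IRREVERSIBLE = "II"

#: derived-axis name: vmax_dox / deg_Tw, the Twist1 stability ratio,
#: realised by co-varying vmax_dox at fixed deg_Tw
TWIST_STABILITY_AXIS = "twist_stability"


@dataclass(frozen=True)
class HysteresisResult:
    theta_on: float
    theta_off: float
    tnc_initial: float
    tnc_final: float
    up: equilibria.ResponseCurve
    down: equilibria.ResponseCurve
    eps_rev: float = EPS_REV

    @property
    def width(self) -> float:
        """theta_on - theta_off; 0 for a monostable (jump-free) response,
        nan when the loop never switches off (irreversible, open-ended)."""
        if math.isnan(self.theta_on):
            return 0.0
        return self.theta_on - self.theta_off

    @property
    def delta_tnc(self) -> float:
        return self.tnc_final - self.tnc_initial

    @property
    def reversible(self) -> bool:
        return self.delta_tnc <= self.eps_rev

    @property
    def bistable(self) -> bool:
        return not math.isnan(self.theta_on)


def _detect_jump(grid: np.ndarray, levels: np.ndarray,
                 ratio: float = JUMP_RATIO, floor: float = 1e-9) -> float:
    """Stimulus at the first discontinuous jump along a branch, reported as
    the midpoint of the bracketing grid interval; nan if none.

    Branch levels are stored in ascending stimulus order, and steady levels
    are non-decreasing in stimulus on either branch, so the up-sweep's
    activation and the down-sweep's deactivation both appear as a rising
    jump between adjacent grid points.
    """
    for i in range(grid.size - 1):
        lo, hi = levels[i], levels[i + 1]
        if hi > ratio * max(lo, floor) and hi - lo > floor:
            return float(0.5 * (grid[i] + grid[i + 1]))
    return math.nan


def hysteresis(
    params: KineticParameters,
    stimulus_grid,
    mode: str = "dox",
    method: str = "relax",
    eps_rev: float = EPS_REV,
    jump_ratio: float = JUMP_RATIO,
) -> HysteresisResult:
    """Up-then-down quasi-static sweep with switching metrics.

    The grid must start at 0 so the dTNC endpoints are defined.  The down
    sweep is seeded from the up sweep's terminal state, so an irreversible
    loop stays on the high branch all the way back to zero stimulus.
    """
    grid = np.asarray(stimulus_grid, dtype=float)
    if grid[0] != 0.0:
        raise ValueError("stimulus grid must start at 0 for dTNC endpoints")
    up = equilibria.sweep(params, grid, "up", mode=mode, method=method)
    down = equilibria.sweep(
        params, grid, "down", mode=mode, method=method,
        initial=_terminal_state(up),
    )
    theta_on = _detect_jump(grid, up.T, ratio=jump_ratio)
    theta_off = _detect_jump(grid, down.T, ratio=jump_ratio)
    if math.isnan(theta_on):
        # monostable response: no switching, dTNC = 0 by construction
        return HysteresisResult(math.nan, math.nan, float(up.T[0]), float(up.T[0]),
                                up, down, eps_rev)
    return HysteresisResult(theta_on, theta_off, float(up.T[0]), float(down.T[0]),
                            up, down, eps_rev)


def _terminal_state(up: equilibria.ResponseCurve):
    from .params import SystemState

    return SystemState(float(up.Tw[-1]), float(up.P[-1]), float(up.T[-1]))


def default_stimulus_grid(params: KineticParameters, mode: str = "dox",
                          n: int = 61, s_max: float | None = None) -> np.ndarray:
    """A [0, s_max] grid for standard sweeps.

    The input saturates around its half-saturation constant, so a few
    multiples of km_dox (dox mode) or km_feedback (injection mode) cover
    every reachable threshold.
    """
    if s_max is None:
        s_max = 5.0 * (params.km_dox if mode == "dox" else params.km_feedback)
    return np.linspace(0.0, s_max, n)


def delta_tnc_for_pulse(
    params: KineticParameters,
    tnc_max: float,
    mode: str = "tnc_injection",
    n_grid: int = 61,
    method: str = "relax",
) -> float:
    """dTNC after a quasi-static exogenous pulse 0 -> tnc_max -> 0."""
    if tnc_max < 0:
        raise ValueError("tnc_max must be >= 0")
    if tnc_max == 0:
        return 0.0
    grid = np.linspace(0.0, tnc_max, n_grid)
    return hysteresis(params, grid, mode=mode, method=method).delta_tnc


def classify_phase(
    params: KineticParameters,
    mode: str = "dox",
    eps_rev: float = EPS_REV,
    stimulus_grid=None,
    method: str = "continuation",
) -> str:
    """Phase I (reversible, dTNC = 0) or phase II (irreversible, dTNC > 0)
    under the standard stimulus sweep."""
    grid = default_stimulus_grid(params, mode) if stimulus_grid is None else stimulus_grid
    h = hysteresis(params, grid, mode=mode, method=method, eps_rev=eps_rev)
    return PHASE_REVERSIBLE if h.delta_tnc <= eps_rev else PHASE_IRREVERSIBLE


def _apply_axis(params: KineticParameters, name: str, value: float) -> KineticParameters:
    if name == TWIST_STABILITY_AXIS:
        return params.replace(vmax_dox=value * params.deg_Tw)
    if name not in KineticParameters.field_names():
        raise ValueError(
            f"axis {name!r} is neither a kinetic parameter nor {TWIST_STABILITY_AXIS!r}"
        )
    return params.replace(**{name: value})


@dataclass
class PhaseDiagram:
    axis1_name: str
    axis1_grid: np.ndarray
    axis2_name: str
    axis2_grid: np.ndarray
    delta_tnc: np.ndarray  # shape (len(axis1), len(axis2))
    eps_rev: float = EPS_REV

    @property
    def phases(self) -> np.ndarray:
        return np.where(self.delta_tnc <= self.eps_rev, PHASE_REVERSIBLE, PHASE_IRREVERSIBLE)

    def to_frame(self):
        import pandas as pd

        a1, a2 = np.meshgrid(self.axis1_grid, self.axis2_grid, indexing="ij")
        return pd.DataFrame(
            {
                self.axis1_name: a1.ravel(),
                self.axis2_name: a2.ravel(),
                "delta_tnc": self.delta_tnc.ravel(),
                "phase": self.phases.ravel(),
            }
        )


def phase_diagram(
    base_params: KineticParameters,
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    mode: str = "dox",
    eps_rev: float = EPS_REV,
    stimulus_grid=None,
    method: str = "continuation",
) -> PhaseDiagram:
    """dTNC over a 2-D parameter grid with reversible/irreversible labels.

    Axes name kinetic parameters, or the derived Twist1-stability ratio
    ``twist_stability`` (= vmax_dox / deg_Tw at fixed deg_Tw).  Cells are
    independent, evaluated with the fast continuation sweep by default.
    """
    name1, grid1 = axis1
    name2, grid2 = axis2
    grid1 = np.asarray(grid1, dtype=float)
    grid2 = np.asarray(grid2, dtype=float)
    delta = np.empty((grid1.size, grid2.size))
    for i, v1 in enumerate(grid1):
        p1 = _apply_axis(base_params, name1, v1)
        for j, v2 in enumerate(grid2):
            p = _apply_axis(p1, name2, v2)
            sg = default_stimulus_grid(p, mode) if stimulus_grid is None else stimulus_grid
            delta[i, j] = hysteresis(p, sg, mode=mode, method=method).delta_tnc
    return PhaseDiagram(name1, grid1, name2, grid2, delta, eps_rev)


@dataclass
class WidthCurve:
    v_feedback_grid: np.ndarray
    width: np.ndarray
    theta_on: np.ndarray
    theta_off: np.ndarray
    open_ended: np.ndarray  # theta_off undefined: irreversible regime


def hysteresis_width_curve(
    base_params: KineticParameters,
    v_feedback_grid,
    mode: str = "dox",
    stimulus_grid=None,
    method: str = "continuation",
) -> WidthCurve:
    """Hysteresis width (theta_on - theta_off) as the feedback strength
    grows.  Once the loop turns irreversible, theta_off is undefined and
    the width is reported as theta_on minus the grid origin (open-ended)."""
    vgrid = np.asarray(v_feedback_grid, dtype=float)
    widths = np.empty(vgrid.size)
    t_on = np.empty(vgrid.size)
    t_off = np.empty(vgrid.size)
    open_ended = np.zeros(vgrid.size, dtype=bool)
    for i, v in enumerate(vgrid):
        p = base_params.replace(v_feedback=v)
        sg = default_stimulus_grid(p, mode) if stimulus_grid is None else stimulus_grid
        h = hysteresis(p, sg, mode=mode, method=method)
        t_on[i], t_off[i] = h.theta_on, h.theta_off
        if not h.bistable:
            widths[i] = 0.0
        elif math.isnan(h.theta_off):
            widths[i] = h.theta_on - sg[0]
            open_ended[i] = True
        else:
            widths[i] = h.width
    return WidthCurve(vgrid, widths, t_on, t_off, open_ended)
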