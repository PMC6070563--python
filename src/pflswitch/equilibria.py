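"""Fixed points, quasi-static stimulus-response branches, ultrasensitivity.

At equilibrium the downstream genes are explicit functions of Twist1:
``P*(Tw)`` and ``T*(Tw)`` follow from setting their production equal to
degradation.  Substituting back into the Twist1 balance leaves a single
scalar self-consistency equation, which is scanned exhaustively on a
bracketed grid — this finds *all* equilibria (1 to 3 for a bistable
switch), unlike Newton iterations from random starts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import model
from .params import KineticParameters, SystemState

#: residual tolerance for a polished root of the scalar equation
EPS_ROOT = 1e-9
#: relative spacing below which two roots are considered duplicates
EPS_DUP = 1e-6
#: default number of scan-grid points (log-spaced above zero)
SCAN_POINTS = 2000


@dataclass(frozen=True)
class FixedPoint:
    state: SystemState
    stable: bool
    leading_eigenvalue: float

    @property
    def Tw(self) -> float:
        return self.state.Tw

    @property
    def T(self) -> float:
        return self.state.T


@dataclass
class ResponseCurve:
    """Steady-state branch levels along a stimulus grid.

    Levels are stored aligned to the *increasing* grid regardless of the
    traversal direction of the quasi-static protocol that produced them.
    """

    direction: str
    stimulus_grid: np.ndarray
    Tw: np.ndarray
    P: np.ndarray
    T: np.ndarray
    converged: np.ndarray
    mode: str = "dox"

    def __post_init__(self) -> None:
        self.stimulus_grid = np.asarray(self.stimulus_grid, dtype=float)
        if np.any(np.diff(self.stimulus_grid) <= 0):
            raise ValueError("stimulus grid must be strictly increasing")

    def gene(self, name: str) -> np.ndarray:
        return {"Tw": self.Tw, "P": self.P, "T": self.T}[name]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "stimulus": self.stimulus_grid,
                "direction": self.direction,
                "Tw": self.Tw,
                "P": self.P,
                "T": self.T,
                "converged": self.converged,
            }
        )


def downstream_equilibrium(Tw, params: KineticParameters):
    """Equilibrium (P*, T*) given Twist1 — the open part of the cascade."""
    p = params
    P = (p.basal_P + p.vmax_TwP * model.hill(Tw, p.km_TwP, p.n_TwP)) / p.deg_P
    T = (p.basal_T + p.vmax_PT * model.hill(P, p.km_PT, p.n_PT)) / p.deg_T
    return P, T


def _tw_residual(Tw, stimulus: float, params: KineticParameters, mode: str):
    """Scalar self-consistency residual: production(Tw) - deg_Tw * Tw."""
    p = params
    _, T = downstream_equilibrium(Tw, params)
    D, T_sensed = (stimulus, T) if mode == "dox" else (0.0, T + stimulus)
    return (
        p.basal_Tw
        + p.vmax_dox * model.hill(D, p.km_dox, p.n_dox)
        + p.v_feedback * model.hill(T_sensed, p.km_feedback, p.n_feedback)
        - p.deg_Tw * Tw
    )


def find_fixed_points(
    params: KineticParameters,
    stimulus_level: float,
    mode: str = "dox",
    n_scan: int = SCAN_POINTS,
    eps_root: float = EPS_ROOT,
    eps_dup: float = EPS_DUP,
) -> list[FixedPoint]:
    """All equilibria at a constant stimulus, sorted by Twist1 level.

    The Twist1 scan bracket is [0, production bound]; every sign change of
    the scalar residual is polished with Brent's method, duplicates merged
    within ``eps_dup`` (relative), and stability read off the full 3x3
    Jacobian spectrum.
    """
    if mode not in model.MODES:
        raise ValueError(f"unknown mode {mode!r}")
    upper = params.production_bound()[0] * (1 + 1e-9) + 1e-12
    # log-spaced scan above zero plus the origin itself
    grid = np.concatenate(([0.0], np.geomspace(upper * 1e-12, upper, n_scan)))
    res = _tw_residual(grid, stimulus_level, params, mode)

    roots: list[float] = []
    for i in range(grid.size - 1):
        r0, r1 = res[i], res[i + 1]
        if r0 == 0.0:
            roots.append(grid[i])
        elif r0 * r1 < 0:
            roots.append(
                brentq(
                    _tw_residual,
                    grid[i],
                    grid[i + 1],
                    args=(stimulus_level, params, mode),
                    xtol=eps_root,
                    rtol=4 * np.finfo(float).eps,
                )
            )
    if res[-1] == 0.0:
        roots.append(grid[-1])
    if not roots:  # cannot happen for valid parameters: residual is
        # positive at 0 and negative at the production bound
        raise RuntimeError("no equilibrium found — parameter domain violated?")

    roots = sorted(roots)
    merged: list[float] = []
    for r in roots:
        if merged and abs(r - merged[-1]) <= eps_dup * max(1.0, abs(merged[-1])):
            continue
        merged.append(r)

    out = []
    for tw in merged:
        P, T = downstream_equilibrium(tw, params)
        state = SystemState(max(tw, 0.0), float(P), float(T))
        J = model.jacobian(state, stimulus_level, params, mode)
        lead = float(np.max(np.linalg.eigvals(J).real))
        out.append(FixedPoint(state, lead < 0, lead))
    return out


def stable_fixed_points(params, stimulus_level, mode="dox", **kw) -> list[FixedPoint]:
    return [fp for fp in find_fixed_points(params, stimulus_level, mode, **kw) if fp.stable]


def _nearest_stable(fps: list[FixedPoint], prev: SystemState) -> FixedPoint:
    stables = [fp for fp in fps if fp.stable]
    if not stables:  # fall back to least unstable (grazing a saddle-node)
        stables = sorted(fps, key=lambda fp: fp.leading_eigenvalue)[:1]
    return min(stables, key=lambda fp: abs(fp.Tw - prev.Tw))


def sweep(
    params: KineticParameters,
    stimulus_grid,
    direction: str = "up",
    mode: str = "dox",
    method: str = "relax",
    eps_ss: float = model.EPS_SS,
    t_max: float = 2000.0,
    initial: SystemState | None = None,
) -> ResponseCurve:
    """Quasi-static stimulus sweep along a branch.

    Each grid point is solved seeded with the previous point's steady
    state: by ODE relaxation (``method="relax"``, the literal quasi-static
    protocol) or by branch continuation on the fixed-point set
    (``method="continuation"``, picking the stable equilibrium nearest the
    previous state — orders of magnitude faster and used for phase
    diagrams).  The up sweep starts from the low state, the down sweep
    from the high state, unless ``initial`` overrides the seed.
    """
    grid = np.asarray(stimulus_grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("stimulus grid must be strictly increasing")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    order = range(grid.size) if direction == "up" else range(grid.size - 1, -1, -1)

    if initial is None:
        fps = find_fixed_points(params, grid[0 if direction == "up" else -1], mode)
        stables = [fp for fp in fps if fp.stable]
        seed = (stables[0] if direction == "up" else stables[-1]).state
    else:
        seed = initial

    levels = np.empty((grid.size, 3))
    converged = np.zeros(grid.size, dtype=bool)
    state = seed
    for i in order:
        if method == "relax":
            r = model.relax_to_steady(
                params, grid[i], state, mode=mode, eps_ss=eps_ss, t_max=t_max
            )
            state, converged[i] = r.state, r.converged
        elif method == "continuation":
            fp = _nearest_stable(find_fixed_points(params, grid[i], mode), state)
            state, converged[i] = fp.state, fp.stable
        else:
            raise ValueError(f"unknown sweep method {method!r}")
        levels[i] = state.as_array()
    return ResponseCurve(direction, grid, levels[:, 0], levels[:, 1], levels[:, 2],
                         converged, mode=mode)


@dataclass(frozen=True)
class UltrasensitivityResult:
    """Effective Hill exponent of the up-sweep TNC branch vs the open-loop
    (feedback-ablated) control."""

    n_eff: float
    n_eff_control: float
    ec10: float
    ec90: float
    discontinuous: bool


def _effective_hill(grid: np.ndarray, y: np.ndarray) -> tuple[float, float, float, bool]:
    lo, hi = y.min(), y.max()
    if hi <= lo:
        raise ValueError("branch is flat — effective Hill exponent undefined")
    norm = (y - lo) / (hi - lo)
    if norm[0] > 0.1 or norm[-1] < 0.9:
        raise ValueError("branch does not span 10%-90% of its range on this grid")

    def crossing(level: float) -> tuple[float, int]:
        i = int(np.argmax(norm >= level))
        if i == 0:
            return float(grid[0]), 0
        x0, x1, y0, y1 = grid[i - 1], grid[i], norm[i - 1], norm[i]
        return float(x0 + (level - y0) / (y1 - y0) * (x1 - x0)), i

    ec10, i10 = crossing(0.1)
    ec90, i90 = crossing(0.9)
    if i10 == i90 or ec10 <= 0:
        # both crossings inside one grid interval: a discontinuous jump,
        # the EC90 = EC10 all-or-none limit
        return math.inf, ec10, ec90, True
    return math.log(81.0) / math.log(ec90 / ec10), ec10, ec90, False


def ultrasensitivity_gain(
    params: KineticParameters,
    stimulus_grid,
    mode: str = "dox",
    method: str = "continuation",
) -> UltrasensitivityResult:
    """Steepness of the stimulus response, as the effective Hill exponent
    ``n_eff = log(81) / log(EC90 / EC10)`` of the up-sweep TNC branch,
    compared against the matched feedback-ablated control (v_feedback = 0).

    An infinite ``n_eff`` (flagged ``discontinuous``) means the 10% and 90%
    crossings collapse into one grid interval — the all-or-none limit.
    """
    grid = np.asarray(stimulus_grid, dtype=float)
    up = sweep(params, grid, "up", mode=mode, method=method)
    n_eff, ec10, ec90, disc = _effective_hill(grid, up.T)
    ctrl = sweep(params.replace(v_feedback=0.0), grid, "up", mode=mode, method=method)
    n_ctrl, _, _, _ = _effective_hill(grid, ctrl.T)
    return UltrasensitivityResult(n_eff, n_ctrl, ec10, ec90, disc)
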