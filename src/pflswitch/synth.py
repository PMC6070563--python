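"""Synthetic datasets emulating the loop's experimental readouts.

Three dataset shapes cover everything the analysis consumes:

* induction time courses — log2 fold changes of the three genes after a
  doxycycline step, as densitometry of an induction western blot would
  give (MRC5-like and IMR90-like presets reproduce the 8-day and ~4-day
  TNC induction delays);
* exogenous-TNC dose-response tables — steady-state fold changes of
  Twist1 and endogenous TNC over a dose panel, activating only above the
  calibrated threshold dose;
* single-cell ON/OFF snapshots — bimodal triple-gene intensities drawn
  from the two stable states inside a bistable stimulus window.

Measurement noise is log-normal (Gaussian on the log2 scale, default
sigma 0.2), a conventional error model for blot densitometry.  Every
generator is a pure function of (parameters, protocol, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import equilibria, model, protocols
from .params import GENES, KineticParameters, SystemState

DEFAULT_NOISE_SD = 0.2
#: default sampling days for induction time courses
DEFAULT_TIMES = (0.0, 1.0, 3.0, 5.0, 8.0, 11.0, 15.0)
DEFAULT_DOSES = (0.0, 0.1, 1.0, 2.0, 5.0)

_LOG2_FLOOR = protocols.ABSOLUTE_FLOOR


def _resolve_preset(preset):
    """Accept a preset name or explicit KineticParameters; return
    (params, meta)."""
    from . import presets as _presets

    if isinstance(preset, KineticParameters):
        return preset, {}
    name = str(preset).lower().replace("-", "_")
    return _presets.load_params(name), _presets.load_meta(name)


def _baseline(params: KineticParameters, mode: str) -> SystemState:
    """Pre-stimulus resting state: the lowest stable equilibrium at zero
    stimulus."""
    fps = [fp for fp in equilibria.find_fixed_points(params, 0.0, mode) if fp.stable]
    return fps[0].state


def _log2_fold(levels: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    ref = np.maximum(baseline, _LOG2_FLOOR)
    return np.log2(np.maximum(levels, _LOG2_FLOOR) / ref)


@dataclass
class TimeCourseDataset:
    """Replicated log2 fold-change measurements of all three genes along a
    stimulus protocol.  ``data`` has shape (3 genes, n_reps, n_times)."""

    cell_line: str
    protocol: protocols.StimulusProtocol
    times: np.ndarray
    data: np.ndarray
    noise_sd: float
    seed: int

    def observations(self) -> np.ndarray:
        return self.data

    def predict(self, params: KineticParameters) -> np.ndarray:
        """Noise-free model log2 fold changes at the sample times, shaped
        to broadcast against the replicate axis."""
        return simulate_log2_timecourse(params, self.protocol, self.times)[:, None, :]

    def to_frame(self):
        import pandas as pd

        genes, reps, times = self.data.shape
        rows = [
            {"cell_line": self.cell_line, "gene": GENES[g], "replicate": r,
             "time": self.times[t], "log2_fold": self.data[g, r, t]}
            for g in range(genes) for r in range(reps) for t in range(times)
        ]
        return pd.DataFrame(rows)


def simulate_log2_timecourse(
    params: KineticParameters,
    protocol: protocols.StimulusProtocol,
    times,
) -> np.ndarray:
    """Noise-free log2 fold changes (3, n_times) under a protocol, relative
    to the pre-stimulus resting state."""
    times = np.asarray(times, dtype=float)
    if times[0] < protocol.t_start or times[-1] > protocol.t_end:
        raise ValueError("sample times outside the protocol span")
    base = _baseline(params, protocol.mode)
    grid = np.unique(np.concatenate(([protocol.t_start], times)))
    traj = model.integrate(params, protocol, base, grid)
    idx = np.searchsorted(grid, times)
    levels = traj.states[idx].T  # (3, n_times)
    return _log2_fold(levels, base.as_array()[:, None])


def generate_timecourse(
    preset,
    protocol: protocols.StimulusProtocol | None = None,
    times=None,
    noise_sd: float = DEFAULT_NOISE_SD,
    n_reps: int = 3,
    seed: int = 0,
) -> TimeCourseDataset:
    """Synthetic induction time course for a preset name ('mrc5', 'imr90')
    or explicit parameters.  With the default step protocol the preset's
    calibrated dox level is applied from day 0."""
    params, meta = _resolve_preset(preset)
    if protocol is None:
        level = meta.get("dox_level", 1.0)
        t_end = max(DEFAULT_TIMES) if times is None else max(times)
        protocol = protocols.dox_step(level, 0.0, float(t_end))
    times = np.asarray(DEFAULT_TIMES if times is None else times, dtype=float)
    clean = simulate_log2_timecourse(params, protocol, times)
    rng = np.random.default_rng(seed)
    data = clean[:, None, :] + rng.normal(0.0, noise_sd, (3, n_reps, times.size)) \
        if noise_sd > 0 else np.repeat(clean[:, None, :], n_reps, axis=1)
    label = preset if isinstance(preset, str) else "custom"
    return TimeCourseDataset(label, protocol, times, data, noise_sd, seed)


@dataclass
class DoseResponseDataset:
    """Replicated linear fold changes of Twist1 and endogenous TNC over an
    exogenous-TNC dose panel.  ``tw_fold`` and ``t_fold`` have shape
    (n_reps, n_doses); fold change at dose 0 is exactly 1 (each replicate
    is normalised to its own zero-dose lane)."""

    doses: np.ndarray
    tw_fold: np.ndarray
    t_fold: np.ndarray
    dose_scale: float
    noise_sd: float
    seed: int

    def observations(self) -> np.ndarray:
        return np.log2(np.stack([self.tw_fold, self.t_fold]))

    def predict(self, params: KineticParameters) -> np.ndarray:
        folds = dose_response_folds(params, self.doses, self.dose_scale)
        return np.log2(folds)[:, None, :]

    def to_frame(self):
        import pandas as pd

        reps, doses = self.tw_fold.shape
        rows = [
            {"dose": self.doses[d], "replicate": r,
             "Tw_fold": self.tw_fold[r, d], "T_fold": self.t_fold[r, d]}
            for r in range(reps) for d in range(doses)
        ]
        return pd.DataFrame(rows)


def dose_response_folds(
    params: KineticParameters,
    doses,
    dose_scale: float = 1.0,
) -> np.ndarray:
    """Noise-free steady-state fold changes (2, n_doses) of Twist1 and
    endogenous TNC, each dose applied independently from the resting
    state (separate dishes, not a sweep)."""
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0")
    base = _baseline(params, "tnc_injection")
    folds = np.empty((2, doses.size))
    for i, dose in enumerate(doses):
        r = model.relax_to_steady(params, dose * dose_scale, base, mode="tnc_injection")
        folds[0, i] = r.state.Tw / max(base.Tw, _LOG2_FLOOR)
        folds[1, i] = r.state.T / max(base.T, _LOG2_FLOOR)
    return folds


def generate_dose_response(
    preset="dermal_injection",
    doses=DEFAULT_DOSES,
    noise_sd: float = DEFAULT_NOISE_SD,
    n_reps: int = 3,
    seed: int = 0,
    dose_scale: float | None = None,
) -> DoseResponseDataset:
    """Synthetic dose-response table for the injection model.  Doses are in
    ug of exogenous protein, mapped to stimulus a.u. by the preset's single
    ``dose_scale`` factor."""
    params, meta = _resolve_preset(preset)
    if dose_scale is None:
        dose_scale = float(meta.get("dose_scale", 1.0))
    doses = np.asarray(doses, dtype=float)
    clean = dose_response_folds(params, doses, dose_scale)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, (2, n_reps, doses.size)) if noise_sd > 0 else 0.0
    noisy = clean[:, None, :] * 2.0**noise
    # zero-dose lane is each replicate's own normalisation reference
    noisy[:, :, doses == 0.0] = 1.0
    return DoseResponseDataset(doses, noisy[0], noisy[1], dose_scale, noise_sd, seed)


@dataclass
class SingleCellSnapshot:
    """Per-cell intensities (n_cells, 3) drawn from a bistable mixture.

    ``on`` records the generating ON/OFF assignment; ``threshold_T`` is the
    unstable saddle's TNC level, the natural classification boundary."""

    intensities: np.ndarray
    on: np.ndarray
    fraction_on: float
    threshold_T: float
    seed: int

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.intensities, columns=list(GENES))
        df["on"] = self.on
        return df


def generate_single_cell_snapshot(
    params: KineticParameters,
    stimulus: float,
    n_cells: int,
    cell_to_cell_cv: float = 0.2,
    fraction_on: float = 0.5,
    seed: int = 0,
    mode: str = "dox",
) -> SingleCellSnapshot:
    """Bimodal ON/OFF snapshot at a bistable stimulus.

    Each cell is assigned ON with probability ``fraction_on``; its three
    intensities are the corresponding stable fixed point scaled by
    independent log-normal factors of coefficient of variation
    ``cell_to_cell_cv`` (median 1).  All three genes are concordant within
    a cell by construction — the hallmark of an all-or-none switch.
    """
    if not 0.0 <= fraction_on <= 1.0:
        raise ValueError("fraction_on must be in [0, 1]")
    fps = equilibria.find_fixed_points(params, stimulus, mode)
    stable = [fp for fp in fps if fp.stable]
    if len(stable) != 2:
        raise ValueError(
            f"stimulus {stimulus} is not inside the bistable window: found "
            f"{len(stable)} stable state(s); pick a stimulus where the up- and "
            f"down-sweep branches coexist (between theta_off and theta_on)"
        )
    unstable = [fp for fp in fps if not fp.stable]
    threshold_T = unstable[0].T if unstable else 0.5 * (stable[0].T + stable[1].T)
    rng = np.random.default_rng(seed)
    on = rng.random(n_cells) < fraction_on
    states = np.where(on[:, None], stable[1].state.as_array(), stable[0].state.as_array())
    sigma = np.sqrt(np.log1p(cell_to_cell_cv**2))
    factors = rng.lognormal(mean=0.0, sigma=sigma, size=(n_cells, 3))
    return SingleCellSnapshot(states * factors, on, fraction_on, float(threshold_T), seed)


def estimate_fraction_on(snapshot: SingleCellSnapshot) -> float:
    """Fraction of cells above the saddle-point TNC threshold."""
    return float(np.mean(snapshot.intensities[:, 2] > snapshot.threshold_T))


def bimodality_coefficient(x) -> float:
    """Sarle's bimodality coefficient; > ~0.555 suggests bimodality.

    b = (skew^2 + 1) / (kurtosis + 3 (n-1)^2 / ((n-2)(n-3))) with excess
    kurtosis; the uniform distribution scores exactly 0.555.
    """
    from scipy import stats

    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    g1 = stats.skew(x, bias=False)
    g2 = stats.kurtosis(x, bias=False)  # excess
    return float((g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))
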