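"""Kinetic parameters and state containers for the three-gene feedback loop.

The loop couples an inducible transcription factor (Twist1), its downstream
target (Prrx1), and a secreted matrix protein (TNC) that closes the loop by
feeding back onto Twist1 production.  All concentrations are in arbitrary
units (a.u.), time is in days.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

GENES = ("Tw", "P", "T")

#: names of the half-saturation constants (must stay positive)
_KM_FIELDS = ("km_dox", "km_feedback", "km_TwP", "km_PT")
#: names of the Hill coefficients (must be >= 1)
_HILL_FIELDS = ("n_dox", "n_feedback", "n_TwP", "n_PT")
#: names of the degradation rates (must stay strictly positive)
_DEG_FIELDS = ("deg_Tw", "deg_P", "deg_T")


class ParameterError(ValueError):
    """Raised when a kinetic parameter violates its physical domain."""


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the positive-feedback-loop ODE.

    Production terms are Hill activations; degradation is first order.
    ``vmax_dox``/``km_dox``/``n_dox`` shape the doxycycline input into
    Twist1, ``v_feedback``/``km_feedback``/``n_feedback`` the TNC->Twist1
    feedback, and the ``*_TwP`` / ``*_PT`` triples the Twist1->Prrx1 and
    Prrx1->TNC cascade steps.  ``vmax_dox`` and ``deg_Tw`` play the role of
    the Twist1 production/degradation constants whose ratio measures
    Twist1 stability.
    """

    basal_Tw: float = 0.0
    basal_P: float = 0.0
    basal_T: float = 0.0
    vmax_dox: float = 1.0
    km_dox: float = 1.0
    n_dox: float = 1.0
    v_feedback: float = 1.0
    km_feedback: float = 1.0
    n_feedback: float = 2.0
    vmax_TwP: float = 1.0
    km_TwP: float = 1.0
    n_TwP: float = 2.0
    vmax_PT: float = 1.0
    km_PT: float = 1.0
    n_PT: float = 2.0
    deg_Tw: float = 1.0
    deg_P: float = 1.0
    deg_T: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        bad: list[str] = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                bad.append(f"{f.name}={v} (must be finite and >= 0)")
        for name in _KM_FIELDS:
            if getattr(self, name) <= 0:
                bad.append(f"{name}={getattr(self, name)} (must be > 0)")
        for name in _HILL_FIELDS:
            if getattr(self, name) < 1:
                bad.append(f"{name}={getattr(self, name)} (must be >= 1)")
        for name in _DEG_FIELDS:
            if getattr(self, name) <= 0:
                bad.append(f"{name}={getattr(self, name)} (must be > 0)")
        if bad:
            raise ParameterError("invalid kinetic parameters: " + "; ".join(bad))

    # -- convenience -------------------------------------------------------

    def replace(self, **changes: float) -> "KineticParameters":
        """Return a copy with the given fields replaced (validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "KineticParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    @property
    def twist_stability(self) -> float:
        """Ratio of Twist1 maximal induced production to degradation."""
        return self.vmax_dox / self.deg_Tw

    def production_bound(self) -> np.ndarray:
        """Upper bound on each equilibrium level: max production / degradation."""
        tw = (self.basal_Tw + self.vmax_dox + self.v_feedback) / self.deg_Tw
        p = (self.basal_P + self.vmax_TwP) / self.deg_P
        t = (self.basal_T + self.vmax_PT) / self.deg_T
        return np.array([tw, p, t])


@dataclass(frozen=True)
class SystemState:
    """Concentrations of the three loop components (a.u.)."""

    Tw: float
    P: float
    T: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite state: {self}")
        if np.any(arr < 0):
            raise ValueError(f"negative state: {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.Tw, self.P, self.T], dtype=float)

    @classmethod
    def from_array(cls, a: np.ndarray, clip: bool = True) -> "SystemState":
        a = np.asarray(a, dtype=float)
        if clip:
            a = np.maximum(a, 0.0)
        return cls(float(a[0]), float(a[1]), float(a[2]))

    def __iter__(self) -> Iterator[float]:
        return iter((self.Tw, self.P, self.T))


@dataclass
class Trajectory:
    """A solved time course: times (days), states (n x 3), stimulus per time."""

    times: np.ndarray
    states: np.ndarray
    stimulus: np.ndarray
    mode: str = "dox"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        self.stimulus = np.asarray(self.stimulus, dtype=float)
        if self.states.shape != (self.times.size, 3):
            raise ValueError(
                f"states shape {self.states.shape} does not match "
                f"{self.times.size} time points"
            )
        if self.stimulus.shape != self.times.shape:
            raise ValueError("stimulus length does not match times")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def gene(self, name: str) -> np.ndarray:
        """Time series of one gene ('Tw', 'P' or 'T')."""
        return self.states[:, GENES.index(name)]

    @property
    def final_state(self) -> SystemState:
        return SystemState.from_array(self.states[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "stimulus": self.stimulus,
                "Tw": self.states[:, 0],
                "P": self.states[:, 1],
                "T": self.states[:, 2],
            }
        )
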