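"""Stimulus protocols and trajectory-level kinetic summaries.

A protocol is a piecewise description of the external input over time:
either the doxycycline level driving Twist1 induction (``mode="dox"``) or
the exogenous-TNC level added to the sensed feedback signal
(``mode="tnc_injection"``).  Kinetic summaries (induction delay, activation
order) mirror how induction experiments are read out from fold-change
time courses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import GENES, Trajectory

#: guard against division by a ~zero baseline when computing fold changes
ABSOLUTE_FLOOR = 1e-6


@dataclass(frozen=True)
class Segment:
    """One piece of a protocol: constant ``level``, or a linear ramp when
    ``level_end`` differs from ``level``."""

    t_start: float
    t_end: float
    level: float
    level_end: float | None = None

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError(f"segment must have t_end > t_start: {self}")
        if self.level < 0 or (self.level_end is not None and self.level_end < 0):
            raise ValueError(f"segment levels must be >= 0: {self}")

    def value(self, t: float) -> float:
        if self.level_end is None or self.level_end == self.level:
            return self.level
        frac = (t - self.t_start) / (self.t_end - self.t_start)
        return self.level + (self.level_end - self.level) * min(max(frac, 0.0), 1.0)

    @property
    def max_level(self) -> float:
        return max(self.level, self.level_end if self.level_end is not None else self.level)


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise stimulus time course.

    Segments must be contiguous and non-overlapping; levels outside the
    covered span are zero.  ``tnc_max`` is the peak level, the pulse
    amplitude for pulse protocols.
    """

    mode: str
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if self.mode not in ("dox", "tnc_injection"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for a, b in zip(self.segments, self.segments[1:]):
            if not math.isclose(a.t_end, b.t_start, rel_tol=0, abs_tol=1e-12):
                raise ValueError("segments must be contiguous and non-overlapping")

    @property
    def tnc_max(self) -> float:
        return max((s.max_level for s in self.segments), default=0.0)

    @property
    def t_start(self) -> float:
        return self.segments[0].t_start if self.segments else 0.0

    @property
    def t_end(self) -> float:
        return self.segments[-1].t_end if self.segments else 0.0

    def level(self, t: float) -> float:
        for seg in self.segments:
            if seg.t_start <= t <= seg.t_end:
                return seg.value(t)
        return 0.0

    def levels(self, times: np.ndarray) -> np.ndarray:
        return np.array([self.level(t) for t in np.asarray(times, dtype=float)])

    def breakpoints(self, t0: float, t1: float) -> np.ndarray:
        """Sorted segment boundaries within [t0, t1], including the ends."""
        pts = {t0, t1}
        for seg in self.segments:
            for t in (seg.t_start, seg.t_end):
                if t0 < t < t1:
                    pts.add(t)
        return np.array(sorted(pts))


def constant(level: float, t_end: float, mode: str = "dox", t_start: float = 0.0) -> StimulusProtocol:
    """A constant stimulus over [t_start, t_end]."""
    if level == 0:
        return null_protocol(t_end, mode=mode, t_start=t_start)
    return StimulusProtocol(mode, (Segment(t_start, t_end, level),))


def null_protocol(t_end: float, mode: str = "dox", t_start: float = 0.0) -> StimulusProtocol:
    return StimulusProtocol(mode, (Segment(t_start, t_end, 0.0),))


def dox_step(level: float, t_on: float, t_end: float) -> StimulusProtocol:
    """Doxycycline step: zero before ``t_on``, constant ``level`` afterwards.

    Mirrors Tet-ON induction where the drug is added once and maintained.
    """
    if t_on >= t_end:
        raise ValueError("t_on must precede t_end")
    if level < 0:
        raise ValueError("level must be >= 0")
    if level == 0:
        return null_protocol(t_end)
    segs = []
    if t_on > 0:
        segs.append(Segment(0.0, t_on, 0.0))
    segs.append(Segment(t_on, t_end, level))
    return StimulusProtocol("dox", tuple(segs))


def tnc_pulse(
    tnc_max: float,
    t_rise: float,
    t_plateau: float,
    t_fall: float,
    t_tail: float = 0.0,
) -> StimulusProtocol:
    """Trapezoidal exogenous-TNC pulse: ramp up, hold at ``tnc_max``, ramp
    down, optionally followed by a zero-stimulus tail of length ``t_tail``.

    Abstracts a single protein injection whose local concentration rises,
    plateaus, and is cleared.
    """
    if min(t_rise, t_plateau, t_fall, t_tail) < 0:
        raise ValueError("durations must be >= 0")
    if tnc_max < 0:
        raise ValueError("tnc_max must be >= 0")
    total = t_rise + t_plateau + t_fall + t_tail
    if tnc_max == 0:
        return null_protocol(max(total, 1.0), mode="tnc_injection")
    segs: list[Segment] = []
    t = 0.0
    if t_rise > 0:
        segs.append(Segment(t, t + t_rise, 0.0, tnc_max))
        t += t_rise
    if t_plateau > 0:
        segs.append(Segment(t, t + t_plateau, tnc_max))
        t += t_plateau
    if t_fall > 0:
        segs.append(Segment(t, t + t_fall, tnc_max, 0.0))
        t += t_fall
    if t_tail > 0:
        segs.append(Segment(t, t + t_tail, 0.0))
    return StimulusProtocol("tnc_injection", tuple(segs))


def concat(first: StimulusProtocol, second: StimulusProtocol) -> StimulusProtocol:
    """Concatenate two protocols in time (the second is shifted to start
    where the first ends)."""
    if first.mode != second.mode:
        raise ValueError("cannot concatenate protocols with different modes")
    offset = first.t_end - second.t_start
    shifted = tuple(
        Segment(s.t_start + offset, s.t_end + offset, s.level, s.level_end)
        for s in second.segments
    )
    return StimulusProtocol(first.mode, first.segments + shifted)


# -- kinetic summaries -----------------------------------------------------


def induction_delay(
    traj: Trajectory,
    gene: str,
    fold_threshold: float = 2.0,
    floor: float = ABSOLUTE_FLOOR,
) -> float:
    """First time a gene exceeds ``fold_threshold`` times its initial level.

    The crossing is linearly interpolated between samples; the trajectory is
    assumed to start at the pre-stimulus steady state, matching fold-change
    normalisation of induction blots.  Returns ``nan`` when the threshold is
    never crossed.  A ~zero baseline falls back to the absolute threshold
    ``fold_threshold * floor``.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    y = traj.gene(gene)
    baseline = max(y[0], floor)
    target = fold_threshold * baseline
    above = y > target
    if not above.any():
        return math.nan
    i = int(np.argmax(above))
    if i == 0:
        return float(traj.times[0])
    t0, t1 = traj.times[i - 1], traj.times[i]
    y0, y1 = y[i - 1], y[i]
    return float(t0 + (target - y0) / (y1 - y0) * (t1 - t0))


def activation_order(traj: Trajectory, fold_threshold: float = 2.0) -> list[str]:
    """Genes ranked by induction delay (shortest first); genes that never
    activate are omitted.  Ties keep the upstream-first listing order."""
    delays = [(induction_delay(traj, g, fold_threshold), i, g) for i, g in enumerate(GENES)]
    activated = [(d, i, g) for d, i, g in delays if not math.isnan(d)]
    activated.sort(key=lambda x: (x[0], x[1]))
    return [g for _, _, g in activated]
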