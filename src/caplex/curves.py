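"""Sampled time-series containers used throughout the package.

A :class:`Curve` carries a strictly increasing time grid in seconds, one
value per sample, a unit tag and an optional lexicon code label.  Signals,
enhancements, relaxation-rate changes, concentrations and impulse responses
are all curves; the unit tag is what distinguishes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .codes import LexiconCode


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing sample times in seconds, first sample >= 0."""

    times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("time grid needs at least two 1-D samples")
        if t[0] < 0:
            raise ValueError("time grid must start at t >= 0")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "times", t)

    @classmethod
    def uniform(cls, interval_s: float, duration_s: float, start_s: float = 0.0) -> "TimeGrid":
        n = int(round(duration_s / interval_s)) + 1
        return cls(start_s + interval_s * np.arange(n))

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        """Mean sample spacing in seconds."""
        return float(np.mean(np.diff(self.times)))

    def is_uniform(self, rtol: float = 1e-8) -> bool:
        d = np.diff(self.times)
        return bool(np.allclose(d, d[0], rtol=rtol))

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class Curve:
    """One sampled time-series: grid + values + unit (+ optional label)."""

    grid: TimeGrid
    values: np.ndarray
    unit: str = ""
    label: LexiconCode | None = field(default=None, compare=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.times.shape:
            raise ValueError("values and grid must have equal length")
        object.__setattr__(self, "values", v)

    @property
    def times(self) -> np.ndarray:
        return self.grid.times

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "Curve":
        return replace(self, values=np.asarray(values, dtype=float),
                       unit=self.unit if unit is None else unit)

    def area(self) -> float:
        """Trapezoidal integral over the full grid (units: value * s)."""
        return float(np.trapezoid(self.values, self.times))

    def resample(self, grid: TimeGrid) -> "Curve":
        """Linear interpolation onto another grid (zero outside support)."""
        vals = np.interp(grid.times, self.times, self.values, left=0.0, right=0.0)
        return Curve(grid, vals, self.unit, self.label)
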