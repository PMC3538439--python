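"""Core containers for uniformly sampled single-molecule traces.

A :class:`TimeSeries` is the universal currency of the package: a scalar
signal sampled at a fixed interval, in whatever unit the assay produces
(radians for rotary motors, nanometres for linear steppers, photon counts
for fluorescence). :class:`StateSequence` carries the hidden discrete state
behind each sample, and :class:`PiecewiseConstant` is the idealized,
step-like description of a trace: a constant spline with knots at the
transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TimeSeries:
    """A uniformly sampled scalar trace.

    Parameters
    ----------
    values : array_like
        Sample values; must be finite, length >= 1.
    sample_interval : float
        Time between samples in seconds (> 0).
    unit_label : str
        Free-text unit of the values ("rad", "nm", "counts", ...).
    """

    values: np.ndarray
    sample_interval: float = 1.0
    unit_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("TimeSeries requires a 1-D array of length >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TimeSeries values must be finite")
        if not (self.sample_interval > 0):
            raise ValueError("sample_interval must be > 0")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.values.size) * self.sample_interval

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        """A copy of this series carrying new sample values."""
        return TimeSeries(np.asarray(values, dtype=float),
                          self.sample_interval, self.unit_label)


@dataclass
class StateSequence:
    """Discrete hidden-state labels (1..K), one per sample."""

    labels: np.ndarray
    n_states: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise ValueError("StateSequence requires a 1-D array of length >= 1")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.labels.min() < 1 or self.labels.max() > self.n_states:
            raise ValueError("labels must lie in 1..n_states")

    def __len__(self) -> int:
        return self.labels.size


@dataclass
class PiecewiseConstant:
    """A constant spline: per-sample values plus its (knots, levels) view.

    ``knots`` are the 0-based indices where a new constant segment starts
    (the first segment starting at 0 is implicit); ``levels`` are the segment
    values, one more than the number of knots.
    """

    per_sample: np.ndarray
    knots: np.ndarray
    levels: np.ndarray
    converged: bool = True

    def __post_init__(self) -> None:
        self.per_sample = np.asarray(self.per_sample, dtype=float)
        self.knots = np.asarray(self.knots, dtype=int)
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.size != self.knots.size + 1:
            raise ValueError("levels must have exactly one more entry than knots")

    def __len__(self) -> int:
        return self.per_sample.size

    @property
    def n_levels(self) -> int:
        return self.levels.size

    @property
    def segment_bounds(self) -> np.ndarray:
        """Start indices of all segments, including the implicit 0."""
        return np.concatenate(([0], self.knots))

    @property
    def segment_lengths(self) -> np.ndarray:
        bounds = np.concatenate(([0], self.knots, [self.per_sample.size]))
        return np.diff(bounds)
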