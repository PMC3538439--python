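"""Classical running-window filters: mean, median, amplitude-weighted mean,
and the running two-sample t-test change detector.

These are the baselines that nonlinear piecewise-constant methods are
measured against. The running mean is the minimum-variance estimator for a
static level under Gaussian noise but smears abrupt transitions; the
running median passes noise-free steps unaltered and tolerates outlier
corruption in up to half of each window; the weighted (bilateral-style)
mean avoids averaging across large jumps; the running t-test flags windows
whose two halves have different means, assuming at most one transition per
window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trace import TimeSeries

__all__ = [
    "WindowSpec",
    "running_mean",
    "running_median",
    "weighted_running_mean",
    "running_ttest",
]


@dataclass
class WindowSpec:
    """Centered window of odd length 2*half_width + 1.

    ``edge_mode`` is either "reflect" (mirror padding, the default: it
    preserves constant signals exactly at the boundaries) or "truncate"
    (windows are clipped at the signal ends).
    """

    half_width: int
    edge_mode: str = "reflect"

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ValueError("half_width must be >= 0")
        if self.edge_mode not in ("reflect", "truncate"):
            raise ValueError("edge_mode must be 'reflect' or 'truncate'")

    @property
    def length(self) -> int:
        return 2 * self.half_width + 1

    def check(self, n: int) -> None:
        if self.length > n:
            raise ValueError(
                f"window length {self.length} exceeds signal length {n}")


def _windows(values: np.ndarray, w: WindowSpec) -> np.ndarray:
    """(n, window) matrix of window contents under reflect padding."""
    hw = w.half_width
    padded = np.pad(values, hw, mode="reflect") if hw else values
    return np.lib.stride_tricks.sliding_window_view(padded, w.length)


def running_mean(ts: TimeSeries, w: WindowSpec) -> TimeSeries:
    """Mean over a centered window around each sample."""
    w.check(len(ts))
    x = ts.values
    if w.edge_mode == "reflect":
        out = _windows(x, w).mean(axis=1)
    else:
        hw = w.half_width
        c = np.concatenate(([0.0], np.cumsum(x)))
        lo = np.maximum(np.arange(x.size) - hw, 0)
        hi = np.minimum(np.arange(x.size) + hw + 1, x.size)
        out = (c[hi] - c[lo]) / (hi - lo)
    return ts.with_values(out)


def running_median(ts: TimeSeries, w: WindowSpec) -> TimeSeries:
    """Median over a centered window around each sample."""
    w.check(len(ts))
    x = ts.values
    if w.edge_mode == "reflect":
        out = np.median(_windows(x, w), axis=1)
    else:
        hw = w.half_width
        out = np.array([np.median(x[max(i - hw, 0):i + hw + 1])
                        for i in range(x.size)])
    return ts.with_values(out)


def weighted_running_mean(ts: TimeSeries, w: WindowSpec,
                          amplitude_scale: float) -> TimeSeries:
    """Bilateral-style running mean weighted by amplitude differences.

    Sample j in the window around i receives weight
    exp(-(x_j - x_i)^2 / (2*scale^2)), so samples on the far side of a
    large transition contribute negligibly and the step is preserved.
    As ``amplitude_scale`` grows the filter converges to the plain
    running mean.
    """
    if not (amplitude_scale > 0):
        raise ValueError("amplitude_scale must be > 0")
    w.check(len(ts))
    x = ts.values
    if w.edge_mode == "reflect":
        win = _windows(x, w)
        wt = np.exp(-((win - x[:, None]) ** 2) /
                    (2.0 * amplitude_scale ** 2))
        out = (wt * win).sum(axis=1) / wt.sum(axis=1)
    else:
        hw = w.half_width
        out = np.empty_like(x)
        for i in range(x.size):
            seg = x[max(i - hw, 0):i + hw + 1]
            wt = np.exp(-((seg - x[i]) ** 2) / (2.0 * amplitude_scale ** 2))
            out[i] = (wt * seg).sum() / wt.sum()
    return ts.with_values(out)


_T_CAP = 1e12  # guard for zero pooled variance with unequal means


def running_ttest(ts: TimeSeries, w: WindowSpec, alpha: float = 0.01
                  ) -> tuple[TimeSeries, list[int]]:
    """Two-sample t statistic between the half-windows around each sample.

    The left arm is the ``half_width`` samples before i and the right arm
    the ``half_width`` samples after; the center sample is excluded. Change
    points are local maxima of |t| above the two-sided critical value at
    ``alpha`` with 2*half_width - 2 degrees of freedom, thinned by
    non-maximum suppression within one half-window.
    """
    hw = w.half_width
    if hw < 2:
        raise ValueError("half_width must be >= 2 for the t-test")
    w.check(len(ts))
    x = ts.values
    n = x.size
    t = np.zeros(n)
    # full windows only; edges keep t = 0
    for i in range(hw, n - hw):
        left = x[i - hw:i]
        right = x[i + 1:i + hw + 1]
        ml, mr = left.mean(), right.mean()
        vl = left.var(ddof=1)
        vr = right.var(ddof=1)
        sp2 = 0.5 * (vl + vr)
        if sp2 == 0.0:
            t[i] = 0.0 if ml == mr else np.sign(mr - ml) * _T_CAP
        else:
            t[i] = (mr - ml) / np.sqrt(sp2 * (2.0 / hw))
    df = 2 * hw - 2
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    at = np.abs(t)
    candidates = np.flatnonzero(at > crit)
    # non-maximum suppression within one half-window
    order = candidates[np.argsort(-at[candidates], kind="stable")]
    detected: list[int] = []
    for idx in order:
        if all(abs(idx - d) > hw for d in detected):
            detected.append(int(idx))
    detected.sort()
    return ts.with_values(t), detected
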