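"""Seeded generators for the signal classes seen in single-molecule assays.

These generators provide ground truth for every method in the package:

* step trains between stable levels driven by a Markov chain (the idealized
  conformational dynamics of a molecular machine);
* discretized Langevin / Ornstein--Uhlenbeck dynamics, i.e. an AR(1)
  recursion around a piecewise-constant forcing level, which models a bead
  of non-negligible mass tethered to a motor;
* Poisson photon-count noise whose variance tracks the molecular
  configuration, as in FRET-type intensity readouts;
* rotational steppers with a periodic arrangement of stable angles, the
  structure of rotary motors such as the bacterial flagellar motor or
  F1-ATPase.

Every generator is bit-reproducible given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .trace import StateSequence, TimeSeries

__all__ = [
    "MarkovParams",
    "LangevinParams",
    "PhotonModel",
    "gen_markov_states",
    "states_to_levels",
    "add_gaussian_noise",
    "add_poisson_photon",
    "gen_ou_trace",
    "gen_rotational_stepper",
]


@dataclass
class MarkovParams:
    """Transition matrix P (row-stochastic, K x K) and initial law pi0."""

    P: np.ndarray
    pi0: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.pi0 = np.asarray(self.pi0, dtype=float)
        K = self.P.shape[0]
        if self.P.ndim != 2 or self.P.shape != (K, K):
            raise ValueError("P must be a square matrix")
        if self.pi0.shape != (K,):
            raise ValueError("pi0 must have length K")
        if np.any(self.P < 0) or np.any(self.pi0 < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("rows of P must sum to 1")
        if not np.isclose(self.pi0.sum(), 1.0, atol=1e-12):
            raise ValueError("pi0 must sum to 1")

    @property
    def n_states(self) -> int:
        return self.P.shape[0]


@dataclass
class LangevinParams:
    """AR(1) discretization of first-order Langevin dynamics.

    ``a`` is the feedback of the previous sample on the current one
    (0 <= a < 1 for stationarity); ``eq_levels`` are per-state equilibrium
    positions; ``noise_sd`` is the per-sample Gaussian innovation scale.
    The physical constants of the underlying Langevin equation (potential
    stiffness, drag, temperature) are lumped into (a, noise_sd) by Euler
    discretization; only that pair is ever fitted.
    """

    a: float
    eq_levels: Optional[np.ndarray] = None
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (abs(self.a) < 1):
            raise ValueError("|a| < 1 required for stationarity")
        if not (self.noise_sd > 0):
            raise ValueError("noise_sd must be > 0")
        if self.eq_levels is not None:
            self.eq_levels = np.asarray(self.eq_levels, dtype=float)


@dataclass
class PhotonModel:
    """Poisson photon-count model: count_i ~ Poisson(f(r_i)).

    ``mean_fn`` maps the molecular separation r to the expected count and
    must be positive (and, physically, decreasing) over the r range.
    """

    mean_fn: Callable[[np.ndarray], np.ndarray]
    r_trace: np.ndarray

    def __post_init__(self) -> None:
        self.r_trace = np.asarray(self.r_trace, dtype=float)

    def means(self) -> np.ndarray:
        mu = np.asarray(self.mean_fn(self.r_trace), dtype=float)
        if mu.shape != self.r_trace.shape:
            mu = np.broadcast_to(mu, self.r_trace.shape).copy()
        if np.any(mu <= 0):
            raise ValueError("mean_fn must be > 0 over the whole r range")
        return mu


def gen_markov_states(params: MarkovParams, length: int, seed: int) -> StateSequence:
    """Draw a state path of the given length from a Markov chain.

    Labels are 1-based. The first label is drawn from ``pi0``, subsequent
    labels from the rows of ``P``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    K = params.n_states
    # cumulative rows let us vectorize each conditional draw
    cum_P = np.cumsum(params.P, axis=1)
    u = rng.random(length)
    labels = np.empty(length, dtype=int)
    labels[0] = np.searchsorted(np.cumsum(params.pi0), u[0], side="right")
    for i in range(1, length):
        labels[i] = np.searchsorted(cum_P[labels[i - 1]], u[i], side="right")
    labels = np.clip(labels, 0, K - 1) + 1
    return StateSequence(labels, K)


def states_to_levels(seq: StateSequence, levels: Sequence[float],
                     sample_interval: float = 1.0,
                     unit_label: str = "") -> TimeSeries:
    """Map a state path onto its per-state signal levels (a step train)."""
    levels = np.asarray(levels, dtype=float)
    if levels.size != seq.n_states:
        raise ValueError("need exactly one level per state")
    return TimeSeries(levels[seq.labels - 1], sample_interval, unit_label)


def add_gaussian_noise(ts: TimeSeries, sd: float, seed: int) -> TimeSeries:
    """Add independent N(0, sd^2) thermal noise to every sample."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return ts.with_values(ts.values.copy())
    rng = np.random.default_rng(seed)
    return ts.with_values(ts.values + rng.normal(0.0, sd, ts.values.size))


def add_poisson_photon(model: PhotonModel, seed: int,
                       sample_interval: float = 1.0) -> TimeSeries:
    """Draw an independent Poisson photon count per sample.

    The mean (and hence the variance) of the count follows the molecular
    configuration through ``mean_fn(r)``, so the noise is heteroscedastic.
    """
    mu = model.means()
    rng = np.random.default_rng(seed)
    counts = rng.poisson(mu).astype(float)
    return TimeSeries(counts, sample_interval, "counts")


def gen_ou_trace(mu: TimeSeries, params: LangevinParams, seed: int,
                 from_rest: bool = False) -> TimeSeries:
    """Simulate x_i = a*x_{i-1} + (1-a)*mu_i + eps_i around a forcing trace.

    ``mu`` is the (typically piecewise-constant) equilibrium trace. The
    initial sample is drawn from the stationary law around mu_1 (variance
    noise_sd^2 / (1 - a^2)); with ``from_rest=True`` it starts exactly at
    mu_1 for deterministic tests. At a = 0 this is exactly independent
    Gaussian noise about mu.
    """
    a = params.a
    sd = params.noise_sd
    rng = np.random.default_rng(seed)
    n = len(mu)
    eps = rng.normal(0.0, sd, n)
    x = np.empty(n)
    m = mu.values
    if from_rest:
        x[0] = m[0]
    else:
        x[0] = m[0] + eps[0] / np.sqrt(1.0 - a * a)
    if a == 0.0:
        # exact white-noise code path: x_i = mu_i + eps_i
        x[1:] = m[1:] + eps[1:]
    else:
        for i in range(1, n):
            x[i] = a * x[i - 1] + (1.0 - a) * m[i] + eps[i]
    return mu.with_values(x)


def _dwell_lengths(rng: np.random.Generator, means: np.ndarray,
                   continuous_time: bool) -> np.ndarray:
    """One dwell (in samples, >= 1) per step, geometric by default."""
    if continuous_time:
        d = rng.exponential(means)
        return np.maximum(1, np.rint(d)).astype(int)
    p = 1.0 / np.maximum(means, 1.0)
    return rng.geometric(p)


def gen_rotational_stepper(steps_per_rev: int, dwell_mean: float,
                           n_revolutions: int, seed: int,
                           mod_weights: Optional[Sequence[float]] = None,
                           angle_noise_sd: float = 0.0,
                           angle_jitter_sd: float = 0.0,
                           sample_interval: float = 1.0,
                           continuous_time: bool = False
                           ) -> tuple[TimeSeries, StateSequence]:
    """Simulate a rotary molecular motor stepping through periodic angles.

    The motor advances monotonically through ``steps_per_rev`` stable angles
    spaced 2*pi/steps_per_rev apart (optionally jittered by
    ``angle_jitter_sd``), dwelling at step k for a geometric number of
    samples with mean ``dwell_mean * mod_weights[k]``. Gaussian angular
    noise of scale ``angle_noise_sd`` is added on top. The returned angle
    trace is unwrapped (monotone staircase plus noise); wrapping to
    [0, 2*pi) is the density module's concern.

    Returns the noisy angle trace and the ground-truth per-sample state
    sequence (states 1..steps_per_rev, position within the revolution).
    """
    if steps_per_rev < 2:
        raise ValueError("steps_per_rev must be >= 2")
    if dwell_mean < 1:
        raise ValueError("dwell_mean must be >= 1 sample")
    if n_revolutions < 1:
        raise ValueError("n_revolutions must be >= 1")
    S = steps_per_rev
    if mod_weights is None:
        w = np.ones(S)
    else:
        w = np.asarray(mod_weights, dtype=float)
        if w.shape != (S,) or np.any(w <= 0):
            raise ValueError("mod_weights must be positive, one per step")
    rng = np.random.default_rng(seed)

    step_angles = 2.0 * np.pi * np.arange(S) / S
    if angle_jitter_sd > 0:
        step_angles = step_angles + rng.normal(0.0, angle_jitter_sd, S)

    n_steps = S * n_revolutions
    step_idx = np.arange(n_steps)
    within = step_idx % S
    dwell_means = dwell_mean * w[within]
    dwells = _dwell_lengths(rng, dwell_means, continuous_time)

    # unwrapped stable angle of each visited step
    unwrapped = step_angles[within] + 2.0 * np.pi * (step_idx // S)
    angles = np.repeat(unwrapped, dwells)
    labels = np.repeat(within + 1, dwells)
    if angle_noise_sd > 0:
        angles = angles + rng.normal(0.0, angle_noise_sd, angles.size)
    ts = TimeSeries(angles, sample_interval, "rad")
    return ts, StateSequence(labels, S)
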