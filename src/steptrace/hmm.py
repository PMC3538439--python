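"""Gaussian hidden Markov model fitting for state idealization.

The conformational state y_i of a molecular system is modelled as a
Markov chain on {1..K} with transition matrix P, and the observed sample
x_i as Gaussian about the state mean: x_i | y_i = k  ~  N(mu_k, sigma_k^2).
Parameters are estimated by expectation-maximization (Baum-Welch) from
random restarts (the likelihood surface is non-convex, so the best of
several converged fits is kept), the most probable state path by the
Viterbi dynamic program, and the number of states by minimizing
AIC = 2*NLL + 2*p over K, with p = K^2 + 2K - 1 free parameters
(K(K-1) transition, K-1 initial, K means, K standard deviations).

The sequential forward-backward and Viterbi recursions are compiled with
numba; all surrounding estimation logic is plain numpy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .trace import StateSequence, TimeSeries

__all__ = [
    "HMMParams",
    "FitReport",
    "n_free_params",
    "aic",
    "hmm_loglik",
    "hmm_fit",
    "viterbi",
    "path_logprob",
    "select_states",
]

_LOG_2PI = np.log(2.0 * np.pi)
_TINY = 1e-300


@dataclass
class HMMParams:
    """Transition matrix, initial distribution, Gaussian emissions."""

    trans: np.ndarray
    init: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.trans = np.asarray(self.trans, dtype=float)
        self.init = np.asarray(self.init, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        K = self.means.size
        if self.trans.shape != (K, K) or self.init.shape != (K,):
            raise ValueError("inconsistent parameter shapes")
        if np.any(self.sds <= 0):
            raise ValueError("emission sds must be > 0")
        if not np.allclose(self.trans.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("rows of trans must sum to 1")
        if not np.isclose(self.init.sum(), 1.0, atol=1e-10):
            raise ValueError("init must sum to 1")

    @property
    def n_states(self) -> int:
        return self.means.size


@dataclass
class FitReport:
    """Diagnostics of one best-of-restarts EM fit."""

    nll: float
    aic: float
    n_states: int
    n_iter: int
    converged: bool
    restart_seed: int
    variance_floored: bool = False


def n_free_params(K: int) -> int:
    """Free parameters of a K-state Gaussian HMM: K(K-1) + (K-1) + 2K."""
    return K * K + 2 * K - 1


def aic(nll: float, K: int) -> float:
    """Akaike information criterion, 2*NLL + 2*p; smaller is better."""
    return 2.0 * nll + 2.0 * n_free_params(K)


def _as_values(x) -> np.ndarray:
    if isinstance(x, TimeSeries):
        return x.values
    return np.asarray(x, dtype=float)


def _emission_probs(x: np.ndarray, params: HMMParams) -> np.ndarray:
    """(L, K) Gaussian emission densities, floored away from zero."""
    mu = params.means[None, :]
    sd = params.sds[None, :]
    logB = (-0.5 * (((x[:, None] - mu) / sd) ** 2)
            - np.log(sd) - 0.5 * _LOG_2PI)
    return np.maximum(np.exp(logB), _TINY)


@njit(cache=False)
def _fb_kernel(B, A, pi):  # pragma: no cover - exercised via wrappers
    """Scaled forward-backward. Returns (loglik, gamma, xi_sum)."""
    L, K = B.shape
    alpha = np.empty((L, K))
    c = np.empty(L)
    s = 0.0
    for k in range(K):
        alpha[0, k] = pi[k] * B[0, k]
        s += alpha[0, k]
    if s < _TINY:
        s = _TINY
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, L):
        s = 0.0
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += alpha[t - 1, j] * A[j, k]
            alpha[t, k] = acc * B[t, k]
            s += alpha[t, k]
        if s < _TINY:
            s = _TINY
        c[t] = s
        for k in range(K):
            alpha[t, k] /= s

    gamma = np.empty((L, K))
    xi_sum = np.zeros((K, K))
    beta = np.ones(K)
    for k in range(K):
        gamma[L - 1, k] = alpha[L - 1, k]
    for t in range(L - 2, -1, -1):
        bb = np.empty(K)
        for k in range(K):
            bb[k] = B[t + 1, k] * beta[k] / c[t + 1]
        new_beta = np.empty(K)
        for j in range(K):
            acc = 0.0
            for k in range(K):
                term = A[j, k] * bb[k]
                xi_sum[j, k] += alpha[t, j] * term
                acc += term
            new_beta[j] = acc
            gamma[t, j] = alpha[t, j] * acc
        beta = new_beta
    loglik = 0.0
    for t in range(L):
        loglik += np.log(c[t])
    return loglik, gamma, xi_sum


@njit(cache=False)
def _viterbi_kernel(logB, logA, logpi):  # pragma: no cover
    L, K = logB.shape
    delta = np.empty(K)
    for k in range(K):
        delta[k] = logpi[k] + logB[0, k]
    back = np.empty((L, K), dtype=np.int64)
    for t in range(1, L):
        new = np.empty(K)
        for k in range(K):
            best = -1e308
            arg = 0
            for j in range(K):
                v = delta[j] + logA[j, k]
                if v > best:
                    best = v
                    arg = j
            new[k] = best + logB[t, k]
            back[t, k] = arg
        delta = new
    path = np.empty(L, dtype=np.int64)
    best = -1e308
    for k in range(K):
        if delta[k] > best:
            best = delta[k]
            path[L - 1] = k
    for t in range(L - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def _forward_backward(x: np.ndarray, params: HMMParams):
    B = _emission_probs(x, params)
    return _fb_kernel(B, params.trans, params.init)


def hmm_loglik(ts, params: HMMParams) -> float:
    """Log likelihood of the data under the given parameters."""
    x = _as_values(ts)
    ll, _, _ = _forward_backward(x, params)
    return float(ll)


def posterior_probs(ts, params: HMMParams) -> np.ndarray:
    """(L, K) smoothed state posteriors from forward-backward."""
    x = _as_values(ts)
    _, gamma, _ = _forward_backward(x, params)
    return gamma


def _init_params(x: np.ndarray, K: int, rng: np.random.Generator) -> HMMParams:
    """Randomized but data-anchored start: jittered quantile means,
    pooled sd, sticky transitions."""
    q = (np.arange(K) + 0.5) / K
    means = np.quantile(x, q)
    spread = x.std() if x.std() > 0 else 1.0
    means = means + rng.normal(0.0, 0.25 * spread / max(K, 1), K)
    sds = np.full(K, max(spread, 1e-8))
    if K > 1:
        trans = np.full((K, K), 0.05 / (K - 1))
        np.fill_diagonal(trans, 0.95)
    else:
        trans = np.ones((1, 1))
    trans /= trans.sum(axis=1, keepdims=True)
    init = np.full(K, 1.0 / K)
    return HMMParams(trans, init, means, sds)


def _em_once(x: np.ndarray, K: int, restart_seed: int, tol: float,
             max_iter: int):
    rng = np.random.default_rng(restart_seed)
    var_floor = max(1e-6 * x.var(), _TINY)
    if K == 1:
        # closed form: EM converges in one iteration
        sd = np.sqrt(max(x.var(), var_floor, 1e-30))
        params = HMMParams(np.ones((1, 1)), np.ones(1),
                           np.array([x.mean()]), np.array([sd]))
        return params, -hmm_loglik(x, params), 1, True, False
    params = _init_params(x, K, rng)
    floored = False
    prev_nll = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll, gamma, xi_sum = _forward_backward(x, params)
        nll = -ll
        # M step
        Nk = np.maximum(gamma.sum(axis=0), 1e-12)
        means = (gamma * x[:, None]).sum(axis=0) / Nk
        var = (gamma * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / Nk
        if np.any(var < var_floor):
            floored = True
        var = np.maximum(var, var_floor)
        row = xi_sum.sum(axis=1, keepdims=True)
        trans = np.where(row > 1e-300, xi_sum / np.maximum(row, 1e-300),
                         1.0 / K)
        trans /= trans.sum(axis=1, keepdims=True)
        init = np.maximum(gamma[0], 1e-300)
        init /= init.sum()
        params = HMMParams(trans, init, means, np.sqrt(var))
        if np.isfinite(prev_nll):
            if (prev_nll - nll) / max(abs(prev_nll), 1.0) < tol:
                converged = True
                break
        prev_nll = nll
    final_nll = -hmm_loglik(x, params)
    return params, final_nll, n_iter, converged, floored


def hmm_fit(ts, K: int, n_restarts: int = 5, seed: int = 0,
            tol: float = 1e-8, max_iter: int = 500
            ) -> tuple[HMMParams, FitReport]:
    """Best-of-restarts EM fit of a K-state Gaussian HMM.

    Each restart begins from randomized, data-anchored parameters; the
    converged fit with the largest likelihood is returned. A variance
    floor of 1e-6 times the data variance guards against the usual EM
    degeneracy of a state collapsing onto one sample.
    """
    x = _as_values(ts)
    if K < 1:
        raise ValueError("K must be >= 1")
    if x.size < K:
        raise ValueError("need at least K samples")
    seeds = np.random.SeedSequence(seed).generate_state(max(n_restarts, 1))
    best = None
    for rs in seeds:
        rs = int(rs % (2 ** 31))
        params, nll, n_iter, conv, floored = _em_once(x, K, rs, tol, max_iter)
        if best is None or nll < best[1].nll:
            best = (params, FitReport(nll, aic(nll, K), K, n_iter, conv, rs,
                                      floored))
        if K == 1:
            break
    return best


def viterbi(ts, params: HMMParams) -> StateSequence:
    """Exact maximum a posteriori state path (labels 1..K)."""
    x = _as_values(ts)
    mu = params.means[None, :]
    sd = params.sds[None, :]
    logB = (-0.5 * (((x[:, None] - mu) / sd) ** 2)
            - np.log(sd) - 0.5 * _LOG_2PI)
    logA = np.log(np.maximum(params.trans, _TINY))
    logpi = np.log(np.maximum(params.init, _TINY))
    path = _viterbi_kernel(logB, logA, logpi)
    return StateSequence(np.asarray(path) + 1, params.n_states)


def path_logprob(ts, params: HMMParams, labels) -> float:
    """Joint log probability of the data and one specific state path."""
    x = _as_values(ts)
    lab = np.asarray(labels, dtype=int) - 1
    mu = params.means[lab]
    sd = params.sds[lab]
    lp = float(np.sum(-0.5 * (((x - mu) / sd) ** 2)
                      - np.log(sd) - 0.5 * _LOG_2PI))
    lp += np.log(max(params.init[lab[0]], _TINY))
    lp += float(np.sum(np.log(np.maximum(
        params.trans[lab[:-1], lab[1:]], _TINY))))
    return lp


def select_states(ts, K_max: int, n_restarts: int = 5, seed: int = 0,
                  tol: float = 1e-8, max_iter: int = 500
                  ) -> tuple[int, list[FitReport]]:
    """Choose the number of states by scanning K = 1..K_max and
    minimizing AIC."""
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    reports = []
    for K in range(1, K_max + 1):
        _, rep = hmm_fit(ts, K, n_restarts=n_restarts, seed=seed + K,
                         tol=tol, max_iter=max_iter)
        reports.append(rep)
    K_star = int(np.argmin([r.aic for r in reports])) + 1
    return K_star, reports
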