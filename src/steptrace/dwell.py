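"""Dwell-time extraction and model comparison for idealized traces.

Once a trace has been idealized into constant levels, the dwell time of
each level (how long the molecule stayed in that conformational state) is
a run length times the sample interval. Whether stepping is a simple
Poisson process is decided by fitting an exponential dwell model against
a heavier-tailed power law (Pareto) by maximum likelihood and comparing
Bayesian information criteria; quantile-quantile points support the
visual check. The first and last dwells of a trace are censored (their
true extent is unobserved) and are excluded from fits by default.

BIC here is -2*loglik + p*ln(n), lower is better. (Report conventions
that phrase BIC as an evidence score to be maximized flip the sign; a
"larger BIC" for one model there corresponds to a smaller value here.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import PiecewiseConstant

__all__ = [
    "DwellTable",
    "ModelFit",
    "extract_dwells",
    "fit_exponential",
    "fit_powerlaw",
    "compare_models",
    "qq_points",
]


@dataclass
class DwellTable:
    """State dwell durations (seconds) with level values and censor flags."""

    durations: np.ndarray
    level_values: np.ndarray
    censored: np.ndarray
    empty: bool = False

    def uncensored(self) -> np.ndarray:
        return self.durations[~self.censored]


@dataclass
class ModelFit:
    """A maximum-likelihood dwell model with its BIC."""

    model: str  # "exponential" or "powerlaw"
    rate: float | None
    alpha: float | None
    x_min: float | None
    loglik: float
    bic: float
    n: int


def extract_dwells(pwc: PiecewiseConstant, sample_interval: float = 1.0
                   ) -> DwellTable:
    """Dwell durations of each constant level of an idealized trace.

    A single-level trace has no complete dwell; it returns an empty table
    flagged ``empty``. Otherwise every level contributes one dwell and the
    first and last are flagged censored.
    """
    if sample_interval <= 0:
        raise ValueError("sample_interval must be > 0")
    lengths = pwc.segment_lengths
    if pwc.n_levels < 2:
        return DwellTable(np.empty(0), np.empty(0),
                          np.empty(0, dtype=bool), empty=True)
    durations = lengths * sample_interval
    censored = np.zeros(durations.size, dtype=bool)
    censored[0] = censored[-1] = True
    return DwellTable(durations, pwc.levels.copy(), censored)


def _fit_durations(dwells, include_censored: bool) -> np.ndarray:
    if isinstance(dwells, DwellTable):
        t = dwells.durations if include_censored else dwells.uncensored()
    else:
        t = np.asarray(dwells, dtype=float)
    return t


def fit_exponential(dwells, include_censored: bool = False) -> ModelFit:
    """ML exponential fit: rate = 1/mean, exact log likelihood."""
    t = _fit_durations(dwells, include_censored)
    if t.size < 2:
        raise ValueError("need at least 2 dwells to fit")
    if np.any(t <= 0):
        raise ValueError("durations must be > 0")
    rate = 1.0 / t.mean()
    loglik = t.size * np.log(rate) - rate * t.sum()
    bic = -2.0 * loglik + 1.0 * np.log(t.size)
    return ModelFit("exponential", float(rate), None, None,
                    float(loglik), float(bic), t.size)


def fit_powerlaw(dwells, x_min: float | None = None,
                 include_censored: bool = False) -> ModelFit:
    """ML continuous Pareto fit above x_min: alpha = 1 + n / sum ln(t/x_min).

    ``x_min`` defaults to the smallest fitted dwell; any dwell below
    x_min is an error.
    """
    t = _fit_durations(dwells, include_censored)
    if t.size < 2:
        raise ValueError("need at least 2 dwells to fit")
    if x_min is None:
        x_min = float(t.min())
    if not (x_min > 0):
        raise ValueError("x_min must be > 0")
    if np.any(t < x_min):
        raise ValueError("all durations must be >= x_min")
    logs = np.log(t / x_min)
    s = logs.sum()
    if s <= 0:
        raise ValueError("degenerate durations: all equal to x_min")
    alpha = 1.0 + t.size / s
    loglik = t.size * np.log((alpha - 1.0) / x_min) - alpha * s
    bic = -2.0 * loglik + 1.0 * np.log(t.size)
    return ModelFit("powerlaw", None, float(alpha), float(x_min),
                    float(loglik), float(bic), t.size)


def compare_models(fit_a: ModelFit, fit_b: ModelFit
                   ) -> tuple[float, str]:
    """(BIC_a - BIC_b, name of the preferred = lower-BIC model)."""
    if fit_a.n != fit_b.n:
        raise ValueError("fits must be on identical data (same n)")
    delta = fit_a.bic - fit_b.bic
    preferred = fit_a.model if delta <= 0 else fit_b.model
    return float(delta), preferred


def _model_ppf(fit: ModelFit, q: np.ndarray) -> np.ndarray:
    if fit.model == "exponential":
        return -np.log1p(-q) / fit.rate
    if fit.model == "powerlaw":
        return fit.x_min * (1.0 - q) ** (-1.0 / (fit.alpha - 1.0))
    raise ValueError(f"unknown model {fit.model!r}")


def qq_points(dwells, fit: ModelFit, include_censored: bool = False
              ) -> np.ndarray:
    """(n, 2) array of (theoretical, empirical) quantile pairs.

    Empirical quantiles are the sorted dwells at plotting positions
    (k - 0.5)/n; theoretical quantiles come from the fitted model's
    inverse CDF. A perfect model puts every point on the diagonal.
    """
    t = np.sort(_fit_durations(dwells, include_censored))
    n = t.size
    q = (np.arange(1, n + 1) - 0.5) / n
    theo = _model_ppf(fit, q)
    return np.column_stack([theo, t])
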