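"""Sub-pixel spot localization in camera frames.

A fluorophore or laser-illuminated bead at molecular scale is a point
source, so its camera image is the optical point-spread function, well
modelled as an isotropic two-dimensional Gaussian on a uniform
background:

    I(u, v) = background + amplitude * exp(-((u-x)^2 + (v-y)^2) / (2 sigma^2)).

Fitting this model to each frame (least squares under Gaussian noise, or
Poisson maximum likelihood for photon-limited frames) recovers the centre
with precision well below one pixel; chaining the fits over a movie gives
time-position and time-intensity traces, and for a bead on a rotary motor
the angle trace follows from a fitted circle centre and atan2.

Pixel centres sit at integer coordinates with the origin at the top-left
pixel centre.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize

from .trace import TimeSeries

__all__ = [
    "SpotFrame",
    "SpotFit",
    "gen_spot_frame",
    "load_frames",
    "fit_spot",
    "frames_to_trace",
    "fit_circle",
    "angles_from_positions",
]


@dataclass
class SpotFrame:
    """A single 2-D intensity frame (counts), pixel size in nm/pixel."""

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")


@dataclass
class SpotFit:
    """Isotropic 2-D Gaussian + uniform background parameters."""

    x: float
    y: float
    sigma: float
    amplitude: float
    background: float
    converged: bool = True

    @property
    def integrated_intensity(self) -> float:
        """Total counts above background: amplitude * 2*pi*sigma^2."""
        return float(self.amplitude * 2.0 * np.pi * self.sigma ** 2)


def _model_image(fit: SpotFit, shape: tuple[int, int]) -> np.ndarray:
    v, u = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                       indexing="ij")
    r2 = (u - fit.x) ** 2 + (v - fit.y) ** 2
    return fit.background + fit.amplitude * np.exp(-r2 / (2.0 * fit.sigma ** 2))


def gen_spot_frame(truth: SpotFit, shape: tuple[int, int],
                   noise: str = "none", seed: int = 0,
                   gaussian_sd: float = 1.0,
                   pixel_size: float = 1.0) -> SpotFrame:
    """Render a synthetic frame from ground-truth spot parameters.

    ``noise`` is "none", "poisson" (counts drawn per pixel with the model
    value as mean) or "gaussian" (additive N(0, gaussian_sd^2)).
    """
    if truth.sigma <= 0:
        raise ValueError("sigma must be > 0")
    mean = _model_image(truth, shape)
    if noise == "none":
        img = mean
    elif noise == "poisson":
        rng = np.random.default_rng(seed)
        img = rng.poisson(np.maximum(mean, 0.0)).astype(float)
    elif noise == "gaussian":
        rng = np.random.default_rng(seed)
        img = mean + rng.normal(0.0, gaussian_sd, mean.shape)
    else:
        raise ValueError("noise must be 'none', 'poisson' or 'gaussian'")
    return SpotFrame(img, pixel_size)


def load_frames(paths, pixel_size: float = 1.0) -> list[SpotFrame]:
    """Load an image stack as SpotFrames.

    ``paths`` is either a single multi-frame TIFF path or an iterable of
    per-frame CSV files (comma-separated pixel values, no header).
    """
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        import tifffile

        stack = tifffile.imread(paths)
        if stack.ndim == 2:
            stack = stack[None, :, :]
        return [SpotFrame(img.astype(float), pixel_size) for img in stack]
    return [SpotFrame(np.loadtxt(p, delimiter=","), pixel_size)
            for p in paths]


def _initial_guess(frame: SpotFrame) -> SpotFit:
    img = frame.pixels
    background = float(np.median(img))
    above = np.maximum(img - background, 0.0)
    total = above.sum()
    if total > 0:
        v, u = np.meshgrid(np.arange(img.shape[0]), np.arange(img.shape[1]),
                           indexing="ij")
        x0 = float((above * u).sum() / total)
        y0 = float((above * v).sum() / total)
    else:
        y0, x0 = (img.shape[0] - 1) / 2.0, (img.shape[1] - 1) / 2.0
    amp = max(float(img.max() - background), 1e-6)
    return SpotFit(x0, y0, 1.5, amp, background)


def fit_spot(frame: SpotFrame, init: Optional[SpotFit] = None,
             objective: str = "ls") -> SpotFit:
    """Fit the Gaussian-plus-background model to one frame.

    ``objective`` is "ls" (Gaussian least squares, the robust default) or
    "poisson" (Poisson maximum likelihood, appropriate at low counts).
    Initialization defaults to median background, background-subtracted
    intensity centroid and sigma = 1.5 px. On failure the initial guess is
    returned with ``converged=False``.
    """
    img = frame.pixels
    if img.shape[0] < 7 or img.shape[1] < 7:
        raise ValueError("frame must be at least 7x7 pixels")
    if init is None:
        init = _initial_guess(frame)
    p0 = np.array([init.x, init.y, max(init.sigma, 0.3),
                   max(init.amplitude, 1e-6), init.background])
    v, u = np.meshgrid(np.arange(img.shape[0]), np.arange(img.shape[1]),
                       indexing="ij")
    uu, vv, zz = u.ravel(), v.ravel(), img.ravel()

    def model(p):
        x, y, sig, amp, bg = p
        return bg + amp * np.exp(-((uu - x) ** 2 + (vv - y) ** 2)
                                 / (2.0 * sig ** 2))

    try:
        if objective == "ls":
            res = least_squares(lambda p: model(p) - zz, p0,
                                bounds=([-1.0, -1.0, 0.2, 0.0, -np.inf],
                                        [img.shape[1], img.shape[0],
                                         max(img.shape), np.inf, np.inf]),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
            p, ok = res.x, res.success
        elif objective == "poisson":
            def nll(p):
                mu = np.maximum(model(p), 1e-9)
                return float(np.sum(mu - zz * np.log(mu)))
            res = minimize(nll, p0, method="Nelder-Mead",
                           options={"xatol": 1e-9, "fatol": 1e-9,
                                    "maxiter": 20000})
            p, ok = res.x, res.success
        else:
            raise ValueError("objective must be 'ls' or 'poisson'")
    except ValueError:
        raise
    except Exception:
        return SpotFit(init.x, init.y, init.sigma, init.amplitude,
                       init.background, converged=False)
    if not ok:
        return SpotFit(*p, converged=False)
    return SpotFit(float(p[0]), float(p[1]), abs(float(p[2])),
                   float(p[3]), float(p[4]), converged=True)


def frames_to_trace(frames: Sequence[SpotFrame], sample_interval: float = 1.0,
                    objective: str = "ls"
                    ) -> tuple[TimeSeries, TimeSeries, TimeSeries]:
    """Fit every frame, chaining each fit as the next initialization.

    Returns (x, y, integrated intensity) traces in pixel units. A frame
    whose fit fails keeps the previous parameters (a flagged gap rather
    than an abort).
    """
    if len(frames) < 1:
        raise ValueError("need at least one frame")
    xs, ys, inten = [], [], []
    init: Optional[SpotFit] = None
    for frame in frames:
        fit = fit_spot(frame, init=init, objective=objective)
        if fit.converged:
            init = fit
        xs.append(fit.x)
        ys.append(fit.y)
        inten.append(fit.integrated_intensity)
    return (TimeSeries(np.array(xs), sample_interval, "px"),
            TimeSeries(np.array(ys), sample_interval, "px"),
            TimeSeries(np.array(inten), sample_interval, "counts"))


def fit_circle(x, y) -> tuple[float, float, float]:
    """Algebraic (Kasa) least-squares circle fit: returns (cx, cy, radius)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    A = np.column_stack([2.0 * x, 2.0 * y, np.ones_like(x)])
    b = x ** 2 + y ** 2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r = np.sqrt(max(c + cx ** 2 + cy ** 2, 0.0))
    return float(cx), float(cy), float(r)


def angles_from_positions(x_ts: TimeSeries, y_ts: TimeSeries) -> TimeSeries:
    """Unwrapped rotation angle of a bead track about its fitted circle."""
    cx, cy, _ = fit_circle(x_ts.values, y_ts.values)
    theta = np.unwrap(np.arctan2(y_ts.values - cy, x_ts.values - cx))
    return TimeSeries(theta, x_ts.sample_interval, "rad")
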