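import numpy as np
import pytest

from steptrace.trace import TimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def tv_dual_oracle(y, lam, weights=None):
    """Independent TV minimizer via the box-constrained dual QP.

    The dual of min 1/2 sum w (m - y)^2 + lam * TV(m) is a least-squares
    problem in the jump dual variables z with |z_j| <= lam, solved here by
    scipy's bounded-variable least squares; the primal is recovered as
    m = y - W^{-1} D^T z. Entirely independent of the package's dynamic
    program.
    """
    from scipy.optimize import lsq_linear

    y = np.asarray(y, dtype=float)
    n = y.size
    if n == 1 or lam == 0:
        return y.copy()
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    D = np.diff(np.eye(n), axis=0)
    A = D.T / np.sqrt(w)[:, None]
    b = np.sqrt(w) * y
    res = lsq_linear(A, b, bounds=(-lam, lam), method="bvls", tol=1e-15)
    return y - (D.T @ res.x) / w


def make_series(values, dt=1.0):
    return TimeSeries(np.asarray(values, dtype=float), dt)
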