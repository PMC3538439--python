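"""Step recovery under autocorrelated (bead-inertia) observation noise.

A bead attached to a rotary enzyme such as F1-ATPase carries momentum, so
the recorded angle shows AR(1)-correlated noise. Plain smoothing then
mistakes slow noise excursions for steps. This example diagnoses the
autocorrelation, estimates the feedback coefficient, and refits with the
AR(1)-whitened total-variation functional before reading off the
periodicity.
"""

import numpy as np

from steptrace import (LangevinParams, ar_tv_denoise, autocorrelation,
                       dominant_periodicity, ecf, estimate_ar1,
                       gen_ou_trace, gen_rotational_stepper, shrink,
                       tv_denoise, wrap_angles)

step = 2 * np.pi / 6
a_true = 0.9
sig_eps = 0.3 * step * np.sqrt(1 - a_true ** 2)

clean, _ = gen_rotational_stepper(6, dwell_mean=50.0, n_revolutions=50,
                                  seed=3)
noisy = gen_ou_trace(clean, LangevinParams(a=a_true, noise_sd=sig_eps),
                     seed=4)

diag = autocorrelation(noisy.values - clean.values, max_lag=5)
print(f"noise ACF at lags 1..5: {np.round(diag.acf[1:], 3)} "
      f"(white-noise band +/-{diag.conf_band:.4f})")

first = tv_denoise(noisy, 2 * 0.3 * step)
a_hat = estimate_ar1(noisy, first.per_sample)
resid = noisy.values - first.per_sample
eps_hat = np.std(resid[1:] - a_hat * resid[:-1])
print(f"estimated feedback a = {a_hat:.3f}, innovation sd = {eps_hat:.3f}")

refit = ar_tv_denoise(noisy, a_hat, gamma=2 * eps_hat * (1 - a_hat))
result = shrink(ecf(wrap_angles(refit.per_sample), F_max=100), mode="mad")
print(f"dominant periodicity: {dominant_periodicity(result)} states/rev")
print("-> the AR-whitened fit recovers the enzyme's sixfold state "
      "arrangement despite strongly correlated noise.")
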