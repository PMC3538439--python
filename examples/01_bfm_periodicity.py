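"""Recover the step count of a rotary motor from a noisy time-angle trace.

Simulates a bacterial-flagellar-motor-style assay: 26 stable angles per
revolution, geometric dwells, Gaussian angular noise. The analysis chain is
total-variation step smoothing, wrapping to the circle, the empirical
characteristic function (ECF) at integer frequencies, and MAD-calibrated
hard shrinkage. The frequency of the largest surviving coefficient is the
number of steps per revolution.
"""

import numpy as np

from steptrace import (dominant_periodicity, ecf, gen_rotational_stepper,
                       shrink, tv_denoise, wrap_angles)

step = 2 * np.pi / 26
noise_sd = 0.3 * step

trace, states = gen_rotational_stepper(
    steps_per_rev=26, dwell_mean=20.0, n_revolutions=50, seed=1,
    angle_noise_sd=noise_sd)
print(f"simulated {len(trace)} samples over 50 revolutions "
      f"(noise sd = {noise_sd:.3f} rad = 0.3 steps)")

idealized = tv_denoise(trace, gamma=2 * noise_sd)   # gamma = 2 sigma
print(f"TV idealization: {idealized.n_levels} constant segments")

spectrum = ecf(wrap_angles(idealized.per_sample), F_max=100)
result = shrink(spectrum, mode="mad")
print(f"shrinkage threshold lambda = {result.lam:.4f}; "
      f"surviving frequencies: {[int(f) for f in result.kept_freqs]}")
print(f"dominant periodicity: {dominant_periodicity(result)} steps/rev")
print("-> the largest surviving ECF coefficient sits at the motor's true "
      "26-fold step structure; higher survivors are its harmonics.")
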