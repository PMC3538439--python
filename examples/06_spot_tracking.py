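"""Sub-pixel bead tracking: PSF fitting, circle fit, time-angle trace.

Renders camera frames of a bead moving around a circle in 26 discrete
angular positions (Poisson photon noise), fits an isotropic 2-D Gaussian
point-spread function to every frame, and converts the positions to a
rotation angle about the fitted circle centre.
"""

import numpy as np

from steptrace import (SpotFit, angles_from_positions, fit_spot,
                       frames_to_trace, gen_spot_frame)

K, radius, centre = 26, 4.0, 10.0
angles_true = 2 * np.pi * np.arange(K) / K
frames = []
for rev in range(2):
    for th in angles_true:
        truth = SpotFit(x=centre + radius * np.cos(th),
                        y=centre + radius * np.sin(th),
                        sigma=1.5, amplitude=500.0, background=5.0)
        frames.append(gen_spot_frame(truth, (21, 21), noise="poisson",
                                     seed=rev * K + int(th * 100)))

single = fit_spot(frames[0])
print(f"frame 0 fit: centre = ({single.x:.3f}, {single.y:.3f}) px, "
      f"sigma = {single.sigma:.3f} px (truth: (14.000, 10.000), 1.500)")

x, y, intensity = frames_to_trace(frames)
theta = angles_from_positions(x, y)
wrapped = np.mod(theta.values, 2 * np.pi)
diff = np.abs(wrapped[:, None] - angles_true[None, :])
err = np.minimum(diff, 2 * np.pi - diff).min(axis=1)
print(f"median angular error: {np.median(err) * 1e3:.2f} mrad over "
      f"{len(frames)} frames")
print(f"mean integrated intensity: {intensity.values.mean():.0f} counts "
      f"(truth {500 * 2 * np.pi * 1.5 ** 2:.0f})")
print("-> localization is an order of magnitude finer than one pixel, so "
      "the 26 angular positions are cleanly resolved.")
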