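# steptrace

Step detection, state idealization and periodic density estimation for
noisy single-molecule time series.

## The problem

Molecular machines — rotary motors like the bacterial flagellar motor
(BFM) or F1-ATPase, kinesins, ion channels, FRET-labelled complexes —
switch between a small set of stable conformations on time scales faster
than the camera or detector that watches them. The recorded trace is
therefore a **piecewise-constant (PWC) signal**: constant levels with
instantaneous jumps, obscured by thermal Gaussian noise, Poisson photon
noise, or autocorrelated noise from the inertia of a reporter bead.
Classical linear smoothing cannot separate such signals from noise (both
have infinite bandwidth), so this package implements the nonlinear tools
the field uses instead, end to end, together with seeded synthetic
generators so every method can be validated against ground truth.

## What is inside

| module | what it does |
| --- | --- |
| `steptrace.synthetic` | Markov step trains, AR(1)/Ornstein–Uhlenbeck traces, Poisson photon counts, rotational steppers, all seeded |
| `steptrace.filters` | running mean / median / amplitude-weighted mean, running two-sample t-test change detector |
| `steptrace.denoise` | exact total-variation (TV) denoising, robust (L1) TV by linear programming, mean-shift level-set clustering, segmentation into (knots, levels) |
| `steptrace.ar` | autocorrelation diagnostics, AR(1) feedback estimation, AR-whitened TV denoising |
| `steptrace.hmm` | Gaussian hidden Markov models: Baum–Welch EM with restarts, Viterbi, AIC state-count selection |
| `steptrace.density` | histograms, FFT kernel density estimates, the empirical characteristic function (ECF) with MAD-calibrated hard shrinkage and Fourier inversion for periodic state densities |
| `steptrace.dwell` | dwell-time extraction, exponential vs power-law maximum likelihood, BIC comparison, Q–Q points |
| `steptrace.spots` | isotropic 2-D Gaussian PSF fitting of camera frames, sub-pixel bead tracking, circle fit and time–angle extraction |
| `steptrace.io`, `steptrace.pipeline`, `steptrace.cli` | CSV trace/spectrum formats, deterministic multi-stage pipelines, a thin `steptrace` command-line interface |

## The core methods

**TV denoising.** The idealization m of a trace x minimizes

    E(m) = 1/2 Σᵢ (xᵢ − mᵢ)² + γ Σᵢ |mᵢ₊₁ − mᵢ|,

whose minimizer is always piecewise constant. A constant region of width
w samples between transitions of height h is merged away exactly when
γ > w·h/2, and γ = 2σ removes about 95% of Gaussian noise of scale σ.
The solver is an exact O(L) dynamic program (cross-checked in the test
suite against an independent convex-programming oracle).

**AR(1)-whitened TV.** With bead-inertia noise the observation model is
xᵢ = a·xᵢ₋₁ + (1−a)·μᵢ + εᵢ; substituting it into the TV functional
gives a whitened quadratic data term, still solved exactly, with `a`
estimated from the lag-1 autocorrelation of the residuals of a first
pass.

**ECF shrinkage.** For a rotary motor the state density on the circle is
periodic and sparse in Fourier space: P(f) = (1/N) Σ exp(i f θⱼ) at
integer f. Coefficients below the universal threshold λ = ζ·√(2 ln F)
are set to zero, with ζ = 1.482·MAD(|P(f)|) robust to the large signal
coefficients; the surviving frequency of largest magnitude is the motor's
step count per revolution.

**State counting and dwell statistics.** A Gaussian HMM fitted by EM with
AIC = 2·NLL + 2(K² + 2K − 1) selects the number of states; dwell times of
the idealized levels are compared between exponential (Poisson stepping)
and power-law models by BIC.

## A worked example

`examples/01_bfm_periodicity.py` simulates a BFM-style assay (26 steps per
revolution, 50 revolutions, geometric dwells of mean 20 samples, angular
noise 0.3 steps) and runs the full chain:

```
simulated 26344 samples over 50 revolutions (noise sd = 0.072 rad = 0.3 steps)
TV idealization: 5050 constant segments
shrinkage threshold lambda = 0.0472; surviving frequencies: [3, 7, 26, 33, 52, 59, 78]
dominant periodicity: 26 steps/rev
```

The dominant surviving ECF coefficient lands on the true 26-fold step
structure; 52 and 78 are its harmonics, and the remaining survivors sit at
the noise floor far below the signal peaks. The other scripts in
`examples/` walk through AR(1) noise and F1-ATPase sixfold recovery, HMM
state counting, running filters, dwell-model comparison and sub-pixel
spot tracking, each printing the numbers it computes.

There is also a small CLI:

```sh
steptrace simulate stepper --config cfg.json --seed 1 --out trace.csv
steptrace denoise tv --gamma 0.15 --in trace.csv --out steps.csv
steptrace density ecf --in steps.csv --out density.csv
```

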