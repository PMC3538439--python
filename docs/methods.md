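# Methods

This note records the models, parameter conventions, numerical choices
and known limitations of `steptrace`, in the package's own words.

## Signal model

All analysis operates on uniformly sampled scalar traces. The underlying
object of interest is a piecewise-constant (PWC) forcing μ: each constant
level is one stable conformational state of a molecular system, and
transitions are effectively instantaneous at experimental sampling rates.
Three noise regimes are modelled:

* **White Gaussian** — thermal noise; variance independent of state.
* **Poisson photon counts** — counts n ~ Poisson(f(r)) with a state-
  dependent mean f(r), so the variance tracks the molecular
  configuration; at high counts this approaches a Gaussian.
* **AR(1) / discretized Langevin** — x_i = a·x_{i−1} + (1−a)·μ_i + ε_i,
  the first-order discretization of overdamped Langevin dynamics in a
  harmonic potential. `a` (0 ≤ a < 1) lumps the physical constants
  (stiffness, drag, temperature, sampling interval) together with the
  innovation scale σ_ε; only (a, σ_ε) are ever exposed or fitted, since
  that pair is what the data identify. The stationary noise variance is
  σ_ε²/(1−a²) and the lag-k autocorrelation a^k.

The (1−a) factor on the forcing makes μ the equilibrium level of the
recursion; this convention is isolated in `synthetic.gen_ou_trace` and
`ar.ar_tv_denoise` so it can be swapped in one place.

## Total-variation denoising

`tv_denoise` minimizes E(m) = ½Σ(x_i−m_i)² + γΣ|m_{i+1}−m_i| exactly.
The ½ scaling of the data term pins the γ conventions:

* two equal blocks of width w and height difference h merge exactly when
  γ > w·h/2 (verified by a sweep test at the printed bound);
* for Gaussian noise of scale σ, γ = 2σ removes ≈95% of the noise
  (the ±2σ mass of a Gaussian is 95.45%);
* the solution mean equals the data mean, and the number of distinct
  levels is non-increasing in γ.

The solver is a dynamic program over the derivative of the Bellman
message — a continuous, non-decreasing, piecewise-linear function held as
a deque of knots — equivalent in exactness to taut-string algorithms and
amortized O(L). It accepts per-sample weights, which is what makes the
AR(1) extension below exact. An independent oracle (the box-constrained
dual quadratic program solved by `scipy.optimize.lsq_linear`) verifies
the solver in the test suite over exhaustive small signal grids and
random instances; the oracle never stands in for the solver.

Degenerate inputs: γ = 0 or length-1 signals return the data; equal
neighbouring levels are merged at a tolerance of 1e-9 × data range.

**Reading off states.** A TV minimizer may split one jump into a short
staircase of intermediate segments (the penalty is the same either way),
and long dwells may carry shallow sub-plateaus. `to_levels` therefore
supports, besides the amplitude `merge_tol`, a `min_segment` dwell: runs
shorter than it are absorbed into the neighbour with the closer level,
shortest first. State-count analyses use a minimum dwell a few noise
correlation times long and well below the true dwell.

## Robust TV and mean shift

`robust_tv_denoise` replaces the squared data error with the absolute
error and solves the resulting linear program with HiGHS
(`scipy.optimize.linprog`). An isolated outlier of any size is removed
iff 2γ > 1 (subgradient condition), which the tests assert on both sides
of the bound. L1 minimizers need not be unique; the objective value, not
the argmin, is the tested quantity.

`mean_shift_denoise` performs level-set clustering: starting from m = x,
every sample is simultaneously replaced by the mean of all samples within
amplitude distance W (flat kernel; a Gaussian kernel of scale W is an
option). The audited objective is the pairwise truncated quadratic
½Σ_ij min((m_i−m_j)², W²), which the iteration does not increase on the
seeded fixtures in the tests. The neighbourhood is the full signal (no
temporal windowing): level-set membership is an amplitude notion. W
controls the minimum separation of recovered levels; closely spaced
levels below W merge.

## AR(1)-aware step recovery

With AR(1) noise the exact Gaussian negative log likelihood of the
forcing μ contributes ½(1−a²)(x_1−μ_1)² for the first sample (its
stationary law) and ½(x_i − a·x_{i−1} − (1−a)·μ_i)² for i ≥ 2. Adding
γΣ|Δμ| and rewriting per sample gives a *weighted* TV problem with
targets y_1 = x_1, y_i = (x_i − a·x_{i−1})/(1−a) and weights 1−a²,
(1−a)², solved by the same dynamic program. Including the stationary
first-sample term (rather than dropping the first sample) makes the
functional reduce *exactly* to plain TV at a = 0 — an identity the tests
assert at solver-path precision.

`a` is estimated by a two-pass procedure: a plain TV fit supplies μ̂, the
lag-1 autocorrelation of x − μ̂ (clipped to [0, 0.999]) supplies â, and
the AR-whitened functional is refit. The estimate is biased low when the
first-pass fit absorbs part of the correlated noise, but the refit is
robust to that bias in the recovery tests. Since γ acts on the whitened
functional, a practical scale is γ ≈ 2·σ̂_ε·(1−â), with σ̂_ε the standard
deviation of the whitened residuals.

## Gaussian HMM

States form a Markov chain on {1..K}; observations are Gaussian per
state. Baum–Welch EM runs from randomized, data-anchored starts
(quantile means with jitter of 0.25 pooled-sd/K, pooled sd, sticky 0.95
transitions), keeping the best of `n_restarts` converged fits because
the likelihood surface is non-convex. Convergence: relative NLL change
< 1e-8 (default) or 500 iterations; a variance floor of 1e-6 × data
variance blocks the single-sample collapse degeneracy and is flagged
when hit. The scaled forward–backward and Viterbi recursions are
numba-compiled; the likelihood is verified against brute-force path
enumeration for L ≤ 8, K ≤ 3 and against an independent reference HMM
implementation evaluating the same parameters.

Model size is chosen by AIC = 2·NLL + 2p with p = K(K−1) + (K−1) + 2K =
K² + 2K − 1 free parameters, the count for a K-state Gaussian HMM with
free initial law; the penalty lives in one function (`hmm.aic`) so an
alternative criterion is a one-line substitution. Drifting levels and
nonparametric state counts are out of scope.

## Periodic densities and ECF shrinkage

Histograms are normalized to unit mass; the FFT KDE convolves the
nearest-grid-binned delta train with a Gaussian kernel (grid extended 4
bandwidths past the data), and is tested to 1e-8 against direct
summation over the binned positions.

For angles, the ECF P(f) = (1/N)Σ exp(i f θ_j) at integer f (cycles per
revolution, default F = 100 — comfortably above the 26 steps and first
harmonics of the motors of interest) is the natural sparse
representation. Hard shrinkage zeroes coefficients with |P(f)| ≤ λ,
λ = ζ·√(2 ln F), with ζ either the standard deviation of the magnitudes
or the robust 1.482·MAD (the Gaussian-consistency factor 1/Φ⁻¹(0.75));
MAD is the default because the signal coefficients themselves are the
outliers the plain standard deviation would absorb. When the data are
exactly periodic the noise floor is zero; a 1e-9 absolute floor on λ
keeps numerical dust out of the survivor set.

A calibration fact worth stating plainly: under pure noise the
magnitudes are Rayleigh with component scale 1/√(2N), both ζ estimates
land near 0.65 of that scale, so λ ≈ 2 component scales and roughly
10–15% of null coefficients survive at the noise floor (the tests assert
this rate against the analytic Rayleigh tail). The method is therefore a
peak-finder, not a false-discovery-controlled detector: dominant and
clearly separated secondary periodicities are robust, but a lone
marginal survivor should not be over-interpreted.

Inversion uses p(θ) = (1/2π)(1 + 2Σ_f Re[P̃(f)e^{−ifθ}]); hard
thresholding can leave small negative excursions, which are clipped and
the density renormalized. Multiple traces of the same motor can be
pooled by averaging |P(f)|² across traces before thresholding
(`average_power`); the pooled coefficients are phaseless.

## Dwell-time analysis

Dwells are run lengths of the idealization times the sample interval.
The first and last dwells are censored (their true extent is
unobserved) and excluded from fits by default. Exponential fits use
λ̂ = 1/mean; power-law fits use the continuous Pareto ML
α̂ = 1 + n/Σln(t/x_min) with x_min user-supplied or the minimum fitted
dwell (automatic x_min selection is out of scope). BIC = −2·loglik +
p·ln n with p = 1 for both models, *lower preferred*; report conventions
that phrase BIC as an evidence score to be maximized flip the sign, so
"a larger BIC for the power law" there is a smaller value here. Q–Q
points place sorted dwells at plotting positions (k−½)/n against the
model inverse CDF.

## Spot localization

Frames are modelled as an isotropic 2-D Gaussian PSF on a uniform
background (5 parameters: centre x, y, width σ, amplitude, background);
pixel centres sit at integer coordinates, origin at the top-left pixel
centre. The default objective is Gaussian least squares
(`scipy.optimize.least_squares`, bounded); Poisson maximum likelihood is
available for photon-limited frames. Initialization: median background,
background-subtracted intensity centroid, σ = 1.5 px. Movie fits are
chained (each fit initializes the next); a failed frame keeps the
previous parameters and is flagged rather than aborting. Angles for a
bead on a rotary motor come from an algebraic (Kasa) circle fit over the
whole track followed by atan2 about the centre and unwrapping.
Multi-spot association, astigmatic 3-D PSFs and EMCCD excess-noise
modelling are out of scope.

## Synthetic generators and what they do not emulate

The generators provide the study conditions for every test: rotational
steppers default to equispaced stable angles (a jitter option exists),
geometric dwells (discrete-time Markov; a rounded-exponential
continuous-time option exists for dwell tests), monotone unwrapped
angles, and seeded reproducibility down to the bit. The rotary-motor
test assays use 26 steps/revolution with dwell mean 20 samples and
angular noise 0.3 steps (50 revolutions), and 6 steps/revolution with
AR(1) a = 0.9 bead noise at 0.3 steps stationary scale — sizes chosen so
every recovery experiment runs in seconds on one core while the
stochastic pass criteria have comfortable margins. Not emulated: bead–
motor hydrodynamic coupling beyond AR(1), EMCCD gain/readout noise,
photobleaching, level drift, back-stepping of real motors. Passing tests
therefore demonstrate correctness of the algorithms under their stated
noise models, not robustness to every artifact of real recordings.

## Pipelines and determinism

`run_pipeline` executes a JSON-declared stage list (simulate / denoise /
wrap / ecf / shrink / density / dwell), writing every intermediate
artifact and a report with parameters and per-stage summaries. A single
global seed is expanded into per-stage substreams keyed by (stage name,
occurrence index) via `numpy` SeedSequence, so inserting a stage does not
perturb later stages' draws. Floats in reports are serialized with
repr-roundtrip precision; identical config + seed reproduces outputs
byte for byte.
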