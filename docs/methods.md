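# Methods

This note documents the models, defaults and numerical choices in
`motordcm`, and what the synthetic cohort does and does not emulate.

## Forward model

**Neural dynamics.** One scalar state per region, `ż = A_full z + C u`.
`A[i, j]` is the influence of source *i* on target *j* (Hz); because
rows index sources — the reverse of the common ODE convention — the
derivative is computed as `A_fullᵀ z`. The diagonal of the stored `A`
is ignored: effective self-connections are `−0.5 Hz · exp(λᴬⱼ)`,
strictly negative for any finite log-scaler, which guarantees that the
uncoupled system is stable. Inputs `u` are binary condition indicators
on a microtime grid (default 16 bins per 2 s scan, bin width 0.125 s);
a trial occupies the single bin containing its onset (half-open bins,
floor mapping), so driving strengths are interpreted per-event.

**Haemodynamics (balloon model).** Per region: vasoactive signal
`ṡ = z − κs − γ(f−1)` with `κ = 0.64 Hz · exp(λᵏ)` pooled over regions
and flow feedback `γ = 0.32 Hz`; inflow `ḟ = s`; venous volume
`τⱼ v̇ = f − v^{1/α}` and deoxyhaemoglobin
`τⱼ q̇ = f·(1−(1−E₀)^{1/f})/E₀ − v^{1/α} q/v` with per-region transit
time `τⱼ = 2 s · exp(λᵗⱼ)`, Grubb exponent `α = 0.32` and resting
oxygen extraction `E₀ = 0.4`. The rest point `z = s = 0, f = v = q = 1`
is an exact fixed point of the implementation (verified by test), so
zero input produces an identically zero prediction.

**Observation.** `y = V₀(k₁(1−q) + k₂(1−q/v) + k₃(1−v))` in fractional
signal change, with `k₁ = 4.3 ν₀ E₀ TE`, `k₂ = ε r₀ E₀ TE`,
`k₃ = 1 − ε`. Defaults target 3 T: `TE = 0.03 s`, `V₀ = 0.04`,
`r₀ = 110 Hz`, `ν₀ = 28.265·B₀ = 84.8 Hz`, and the intravascular/
extravascular ratio `ε` **fixed** at 0.46 (not estimated), for
stability. `epsilon_prior_fit` reproduces the derivation of the ε
density from relaxation-time ranges (T₂ᵢ* 15–25 ms, T₂ₑ* 30–45 ms,
0.5 ms steps, TE 30 ms): a lognormal fitted to
`ε = exp(TE/T₂ₑ* − TE/T₂ᵢ*)` on the grid. Maximum likelihood on logs
gives location `exp(μ) ≈ 0.48` and scale² ≈ 0.06; the fitting criterion
(MLE vs moment matching) is exposed as an option because the location
is mildly criterion-dependent at the second decimal.

**Integration.** Fixed-step RK4 at the microtime bin width, inputs held
constant within a bin, JIT-compiled with numba (a pure-Python reference
path is kept and cross-validated in tests). RK4 was chosen over a
first-order update because step-halving then changes predictions by
≈1e−6 relative (first-order: ≈4e−2), comfortably inside the 1e−4
robustness budget, at negligible cost. Predictions are sampled
mid-scan (configurable offset). Divergence (state norm above 1e6 or
loss of positivity in f, v, q) raises an `InstabilityError` naming the
offending parameter magnitudes.

**Volterra kernels.** The first-order kernel is the response to a
single unit event from rest, 32 s window by default — long enough for
the response to settle back to baseline. The "sign of the rM1
response" used throughout is the sign of the kernel's
largest-magnitude sample; |extremum| < 1e−6 fractional signal counts as
indeterminate.

## Synthetic cohort

The generator emulates the study conditions the analysis assumes:

* **Design**: 120 audio-visual trials (40 per tone), 4 audio-only,
  4 visual-only; SOAs jittered in [2, 26] s. Uniform jitter is the
  default (least informative); a truncated-exponential option
  (scale 1.6 s) is used for full-scale designs because 128 trials only
  fit a 261-scan × 2 s session when the SOA distribution is skewed
  short, as null-trial interleaving produces. The scan period is not
  part of the emulated specification; 2 s is the package default.
  Stimulus durations (300 ms tone, 34 ms checkerboard) are recorded in
  event tables but inputs are event (single-bin) indicators.
* **Responder groups**: "negative" (46 %) and "positive" (54 %)
  responders. Covariates (age, rM1 amplitude) are drawn from the
  corresponding component of a two-component 2D Gaussian mixture with
  means [44.77, −3.53] / [62.07, 4.51], variances [289.71, 5.20] /
  [238.31, 8.12] and covariances −11.16 / −12.43.
* **Parameters**: the positive-responder template drives lSMA/lPMd,
  spreads activity within the left hemisphere and crosses to the right
  with net excitatory drive into rM1; negative responders differ by
  −0.65 Hz (lSMA→rM1), −0.60 Hz (lPMd→rM1) and +0.30 Hz (lM1→rM1) —
  differences concentrated on the three inter-hemispheric connections,
  with the first two largest and the third about half their size and
  opposite in sign. These templates were chosen once so that the two
  groups' rM1 kernels have opposite signs (verified by test); they are
  constructed, not estimates of any real cohort. Between-subject SDs
  default to 0.1 Hz on connections and inputs and 0.05 on log-scalers.
* **Noise**: AR(1) with coefficient 0.2 at snr 1 by default (fMRI noise
  is autocorrelated; white noise is available since real pipelines
  pre-whiten). `snr` is signal SD over noise SD per region.

What it does **not** emulate: voxel-level data, motion or physiological
artefacts, behavioural responses, scanner drift, and spatial
correlation between regions' noise. Passing tests therefore demonstrate
internal consistency of the method chain (can the inversion recover
what the forward model generated at realistic noise?), not performance
on real fMRI.

## Subject-level inversion (variational Laplace)

Observation model `y = g(θ) + e`, with one Gaussian noise precision per
region, parameterised as log-precision `h_r` and optimised by
Fisher-scoring alongside the parameters. The approximate posterior is
Gaussian; the mean ascends the free energy by Gauss–Newton steps with
Levenberg–Marquardt damping, and proposals that decrease F are rejected
(damping ×8, up to 6 retries per iteration), so F is non-decreasing
over accepted steps by construction. Convergence: |ΔF| < 0.01 on four
consecutive accepted iterations, or 128 iterations. When no acceptable
ascent step remains the fit is returned as converged (flagged
`stalled`), because at an optimum every proposal is numerically
F-decreasing; an error is raised only when F cannot be computed at the
starting point. Jacobians are central finite differences (step 1e−4)
— robustness over speed at this problem size.

Priors (all zero-mean): between-region A ~ N(0, 1/16); self-connection
log-scalers ~ N(0, 1/16); driving inputs C ~ N(0, 1) where switched on;
decay and transit log-scalers ~ N(0, 1/256); per-region constant
offsets ~ N(0, 1). Model variants are expressed by prior variance
alone: `m1` switches on C rows for lSMA/lPMd, `m2` for rSMA/rPMd;
parameters with exactly zero prior variance are excluded from the
optimisation and returned bit-identical to the prior. Noise
hyperpriors are Gaussian in log-precision, centred on the data's
empirical log-precision with variance 16 (mildly informative,
scale-aware). With a linear forward model and fixed noise the scheme
reproduces the conjugate Bayesian linear-regression posterior and the
exact log evidence to numerical precision (tested).

Re-estimation from a supplied start value (e.g., group-average
connectivity) leaves priors untouched and keeps whichever of the two
fits has higher free energy; with the default start this is a no-op.

Model evidence comparisons use free energies directly: pairwise log
Bayes factors and softmax probabilities under uniform model priors.
The pipeline compares architectures by fixed-effects sums of
subject-level free energies.

## Group level (parametric empirical Bayes)

Design: recursive Gram–Schmidt with mean-centring — constant (kept
all-ones so its coefficients read as group averages), centred group
indicator (1 = negative responder before centring), age residualised on
the preceding columns, rM1 amplitude residualised on all three. The
rM1-amplitude covariate in the pipeline is the fitted peak amplitude of
each subject's rM1 timeseries regressed on a canonical impulse response
placed at every trial onset (the voxelwise stage that produced the
original amplitudes is out of scope).

Each subject's posterior enters as a pseudo-likelihood: precision
`P̃ᵢ = Σᵢ⁻¹ − Σ₀⁻¹` (posterior minus prior precision, so the
first-level prior is not double-counted), with non-informative
directions (eigenvalues ≤ 1e−8) floored and their pseudo-data means
zeroed. The second level is then exactly linear-Gaussian:
`m̃ᵢ = (xᵢᵀ ⊗ I_M) β + εᵢ`, `cov(εᵢ) = Γ(γ) + P̃ᵢ⁻¹`, with
`Γ(γ) = Σ_f exp(−γ_f) D_f` and `D_f` the diagonal of first-level prior
variances within field f (A incl. self-connections, C, decay, transit).
β is integrated out analytically (prior: zero-mean, variance equal to
the corresponding first-level prior variance per covariate), and the
log-precisions γ are optimised by bounded L-BFGS-B with N(0, 4)
hyperpriors. The reported group free energy conditions on the
first-level fits and omits constants common to all second-level models,
which cancel in every comparison the package makes; the hyperparameter
entropy term is likewise omitted.

**Bayesian model reduction** re-evaluates evidence and posterior under
a shrunk coefficient prior analytically (switched-off coefficients get
prior variance 1e−8); it matches a direct refit on conjugate toys to
1e−4 (tested). It powers: the 8×8 field-set grid (average-set ×
difference-set over {all; A,C; A,τ,κ; C,τ,κ; A; C; τ,κ; none} = 64
models, residual covariates always on); per-coefficient presence
probabilities (softmax of on-vs-off free energies); and the greedy
search. The search scores every single removal per iteration, prunes
all non-F-reducing removals as a batch (falling back to the best single
removal when the batch jointly reduces F, ties to the first index), and
stops when nothing can be removed; it is capped at 2¹⁶ evaluated
models, and the final Bayesian model average is weighted by softmax
evidence over the last sweep's candidates.

## Clustering

K-component full-covariance 2D Gaussian mixture by hand-written EM
(tolerance 1e−8 on the log-likelihood, ≤500 iterations, best of seeded
restarts). Initialisation splits at the BOLD-amplitude median — one
cluster above, one below — mirroring initialisation with positive- and
negative-response clusters; k-means and random inits are options.
Component covariances are floored at eigenvalue 1e−6 to prevent
collapse. `AIC = 2k − 2logL`, `BIC = k ln N − 2logL` with
`k = (K−1) + 2K + 3K`; deltas are reported as criterion(K=1) −
criterion(K), so positive favours the mixture. The "negative
responder" label always attaches to the component with the lower
amplitude mean, making assignments invariant to component order. The
scikit-learn EM serves as an independent cross-check in tests (our
optimum must be a fixed point of its update), never as the
implementation.

## Virtual experiments

Sweeps cover ±1 Hz in 21 steps for connections and driving inputs and
±1 log-unit for log-scaling parameters (Hz offsets are meaningless for
unitless log-scalers); a parameter is in the sign-flip set iff its
sweep produces rM1 kernel extrema of both signs, and the flip point is
refined by bisection to 0.01. Offsets whose integration diverges are
recorded per-offset, not fatal. A base model whose kernel extremum is
below the 1e−6 floor has no defined sign and is rejected — this also
covers the degenerate all-zero model, where no sweep outcome would be
interpretable. Peak metrics report the signed extremum (ties to the
earlier time) and its latency rounded half-up to 0.5 s. The
connection-vs-amplitude regressions are ordinary least squares
(statsmodels), with single-predictor R equal to the Pearson
correlation.

## Pipeline, seeds, problem sizes

Stage seeds are derived by SHA-256 hashing of (top seed, stage name),
truncated below 2³¹, so stages have independent reproducible streams.
The full-scale defaults (128 trials, 261 scans, 16 bins/scan) match the
emulated study; the test suite runs the inversion-heavy stages on
shortened sessions (≈50–60 scans, 11–14 trials) and 8–20 subjects so
the whole suite completes in a few minutes on one CPU — these sizes are
the package's chosen desk-scale study conditions, and the group-level
recovery tests use synthetic subject posteriors (group-structured means
with posterior covariance at 5 % of the prior) where full inversion of
hundreds of subjects would add nothing to the property under test.

## Known limitations

* One neural state per region: no excitatory/inhibitory separation, no
  bilinear (condition-modulated) connectivity, no stochastic dynamics.
* The free-energy objective omits across-model constants (documented
  above); absolute F values are not comparable across different data.
* Finite-difference gradients make a single subject inversion O(p)
  forward integrations per iteration (~seconds at desk scale; minutes
  at full scale).
* The greedy search explores a tiny corner of the 2^(4M) model space;
  like any greedy procedure it can keep a locally-supported coefficient
  (type-I survivor) under between-subject noise.
* The synthetic cohort's group structure is constructed, not estimated;
  conclusions about real ageing cohorts require the original data.
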