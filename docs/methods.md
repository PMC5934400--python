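# Methods

This note records the statistical model behind `trajfit`, the conventions
and defaults the package commits to, and what its synthetic-data tests do
and do not demonstrate about real tracking data.

## Model and estimators

The data are M independent, identically distributed trajectories of a
scalar observable sampled on a common strictly increasing grid of N times.
All inference is about the ensemble mean ȳ_i = (1/M) Σ_m y_i^(m) and its
fluctuations.  The unbiased sample covariance across trajectories,

    Q̄_ij = (1/(M−1)) Σ_m (y_i^(m) − ȳ_i)(y_j^(m) − ȳ_j),

and the covariance of the mean C̄ = Q̄/M are the only statistics consumed
by the estimators.  Because ȳ is an average of M iid draws, its
distribution is asymptotically Gaussian with covariance C̄; every error
formula in the package is a leading-order-in-1/M statement under that
asymptotic.

Point estimation minimises χ² = Λᵀ R Λ (Λ_i = f(t_i;θ) − ȳ_i).  Weight
choices:

* `wls_diagonal` — R = diag(1/C̄_ii).  No inversion of a noisy matrix; the
  package default.
* `ccm_full_inverse` — R = C̄⁻¹.  Requires M − 1 ≥ N and a condition
  number below 1/ε_machine (≈ 4.5·10¹⁵); otherwise an `IllConditionedError`
  is raised, and the validation harness counts the event.  Even when
  invertible, the plugin inverse of a noisy covariance biases θ̂ for
  observables that are nonlinear in the underlying noise (squared
  displacements), with the Brownian-motion bias growing like N/ln N — see
  the bias laws below.
* `bmals` — R = K⁻¹ with K_ij = min(t_i,t_j)², the shape of the exact
  covariance of Brownian squared displacements.  This is generalised least
  squares with the true (up to scale) covariance; the overall scale of R is
  immaterial for both θ̂ and Δ̂, which the suite asserts exactly.

The parameter covariance is Δ̂ = φ̂/M with
φ̂ = 4 ĥ⁻¹ Gᵀ (Rᵀ Q̄ R) G ĥ⁻¹ and
ĥ_ab = 2 Σ_ij ∂²f_i/∂θ_a∂θ_b R_ij Λ_j + 2 (Gᵀ R G)_ab.  Notes:

* The residual × Hessian term of ĥ is always included by default.  Many
  standard treatments drop it (Gauss–Newton curvature); a keyword
  (`include_hessian_term=False`) reproduces that behaviour for comparison.
* Replacing Q̄ by its diagonal yields the classical uncorrelated-error WLS
  covariance (ECE); with R = C̄⁻¹ and Q̄ = MC̄ the inner matrix Rᵀ Q̄ R
  collapses to M C̄⁻¹, and the implementation evaluates both the generic
  and the collapsed route, cross-checking them to 1e−8.
* For a constant fit function the estimator reduces exactly to the
  familiar variance-of-a-correlated-mean result Σ_ij Q̄_ij/(MN²); for a
  linear fit with diagonal weights it reduces to the standard linear
  error-propagation expression.  Both reductions are asserted in the suite
  against independently derived closed forms.
* Only ĥ (K×K, with K ≤ 2 for all built-in models) is ever inverted.  A
  singular ĥ (flat cost surface) raises an error carrying its condition
  number.

Fit functions carry analytic gradients and Hessians because ĥ needs ∂²f.
A finite-difference wrapper exists for user-defined models and logs a
warning, since derivative error propagates into Δ̂.  All built-in
derivatives are verified symbolically (the damped-oscillator second
derivative, for instance, is x₀t²(θ₁t − 1)e^(−θ₁t)), and a shared
finite-difference consistency test (relative tolerance 1e−5) guards every
model.

Optimisation is BFGS (L-BFGS-B when a model declares box bounds) with the
analytic χ² gradient, gradient tolerance 1e−10, and a deterministic
5-point multistart around the model's heuristic initial guess; the lowest
χ² wins, first-found on ties.  The power-law initial guess is a log–log
regression over the last half of the time points, which is robust to the
slow transient of heavy-tailed walks.  Time points with zero sample
variance (the t = 0 point of displacement data) are rejected with an
instructive error rather than silently dropped; `TrajectoryEnsemble.drop_t0`
and the CLI flag `--drop-t0` make the exclusion explicit.

## Bias laws and resampling

For Brownian motion the leading bias of the fitted MSD prefactor obeys
M·(⟨θ̂₁⟩ − θ₁*)/D = G(N) with G(N) = −4(1 − 1/N) for the diagonal-weight
WLS fit (tiny and essentially N-independent) and
G(N) ≈ −8N/(ln N + γ + 2 ln 2) for CCM (growing with N).  The acceptance
suite measures both by simulation; the CCM comparison allows 20% for the
subleading terms of the large-N form on top of Monte Carlo error, a band
fixed from the O(1/ln N) convergence of the asymptotics before the
measurements were made.

The grouped jackknife removes the O(1/M) bias: trajectories are shuffled
once (seeded) and split into g near-equal contiguous blocks;
θ_J = gθ̂ − (g−1)·mean of the delete-one-group refits.  The second order
additionally refits all g(g−1)/2 delete-two-group subsets and eliminates
the 1/M² term by Richardson elimination over estimates built on g, g−1 and
g−2 groups' worth of data (an exact 3×3 solve).  Second order is
implemented but not recommended: in practice the next-order term it
exposes tends to be larger than the one it removes.  The closed-form
covariance remains valid at the jackknifed point and is evaluated there on
the full-sample statistics.

The bootstrap resamples whole trajectories (rows) with replacement — never
time points, which would destroy the within-trajectory correlation — and
takes the sample covariance of the B refitted parameter vectors (default
B = 100).  Replicates whose resample leaves a zero-variance time point are
dropped and counted.

## Simulators

All simulators take a seed (NumPy `SeedSequence`-compatible) and are
bit-reproducible.  Ground-truth parameters θ*:

| process | observable | mean law | θ* |
|---|---|---|---|
| `bm` | squared displacement | 2dD·t | (2dD) |
| `fbm` | squared displacement | 2dK_f·t^{2H} | (2dK_f, 2H) |
| `ctrw` | squared displacement | ≈ θ₁*·t^α (asymptotic) | (dσ_j²·sin(πα)/(πα τ₀^α), α) |
| `dho` | position | x₀(1 + θ₁t)e^{−θ₁t} | (θ₁) |

* Brownian motion draws exact Gaussian increments between sampling times
  (variance 2DΔt per component) — no finer grid is needed.
* Fractional Brownian motion factorises the exact position kernel
  K_f(t^{2H} + s^{2H} − |t−s|^{2H}) by Cholesky at the N sampling times:
  O(N³) but exact for arbitrary (not necessarily equispaced) grids, which
  is the right trade at the N ≤ a few hundred used here.
* The CTRW uses Pareto waiting times ψ(τ) = ατ₀^α/τ^{1+α} (τ ≥ τ₀) and iid
  Gaussian jumps; waits are drawn in vectorised blocks until every
  renewal clock passes the last sampling time.  Any waiting law with tail
  exponent α gives the same MSD exponent; the prefactor is a convention of
  this choice, its quoted θ₁* follows from the renewal theorem and is
  approached slowly — validation therefore judges the exponent strictly
  and exempts the prefactor where the transient matters.
* The damped oscillator integrates the critically damped linear Langevin
  system with the exact Gaussian one-step update (van Loan block-matrix
  exponential for the propagator and per-step noise covariance), stepping
  directly between sampling times with zero discretisation bias; an
  Euler–Maruyama integrator is kept purely as a cross-check.

Package default geometry mirrors the validation protocol: N = 75
equispaced times, M = 1000 trajectories, S = 500 replicate ensembles.
Default process parameters (D = 1, d = 1, K_f = 1, H = 0.75, α = 0.7,
τ₀ = 10⁻³, σ_j = 1, θ₁ = 1, x₀ = 1, oscillator noise amplitude 0.5) are
package conventions chosen to give clearly resolved signal over the
default time window; none of the estimators' properties depend on them.

## Validation harness and problem sizes

`run_validation` spawns S child seed streams from one master seed (so
reports are reproducible bit-for-bit), simulates S independent ensembles,
fits each with each requested method, and reports per method: mean and
replicate spread of θ̂ (the spread is the ground truth that σ̂ must
match), mean σ̂, 1σ/2σ coverage of θ*, relative bias, R², and the
fraction of replicates whose covariance was ill-conditioned.  Per-replicate
failures are counted, never fatal.  `phase_map` repeats this over an
(N, M) grid, calling a cell acceptable when every parameter's mean bias is
within 10% of θ*, and flagging cells where more than half the replicates
were ill-conditioned.  `error_vs_n_curve` thins a single set of full-grid
replicates with `subsample_times` to chart spread and σ̂ versus N — the
spread does not decay to zero with N at fixed M, because correlations cap
the information content of denser sampling; only more trajectories help.

The shipped statistical checks run at S = 200, M = 500, N = 50 per process
(S = 500, M = 1000, N = 75 for the headline coverage number, S = 2000 at
M = 100 for the small WLS bias, S = 50 per phase-map cell), sizes chosen
so the whole suite completes in a few minutes on one CPU while keeping the
Monte Carlo bands decisive; all pass/fail bands are binomial or
standard-error intervals computed from the runs themselves.

## What the synthetic tests do not show

The generators produce ideal, complete, common-grid data with known
ground truth.  They do not emulate localisation noise, motional blur,
pixelation, missed detections or broken tracks, trajectory-length
heterogeneity, or drift — all present in real particle-tracking data.
Passing tests therefore demonstrate the correctness and calibration of the
estimators under the stated model (iid trajectories, finite fourth
moments, M large enough for the Gaussian asymptotic), not robustness to
experimental artefacts.  Known soft spots: for heavy-tailed CTRW at small
M the Gaussian asymptotic for ȳ converges slowly and σ̂ for the prefactor
degrades; jackknife and bootstrap inherit multistart cost multiplied by
their refit counts; R² is reported as a heuristic only — its distribution
under correlated residuals is not characterised, and a CCM fit can have
R² ≪ 1 at large N while WLS on the same data fits well.
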