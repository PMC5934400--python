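# trajfit

Function fitting for time-dependent **ensemble-averaged trajectory data**,
with parameter errors that respect temporal correlations.

## The problem

In single-particle tracking and many other fields one records M independent
trajectories of an observable y (e.g. the squared displacement of a tracked
particle) at N common sampling times, averages them into a mean curve
ȳ_i, and fits a parametric law f(t; θ) — say the MSD of free diffusion
f = θ₁t, or the anomalous-diffusion power law f = θ₁t^θ₂ — by minimising
the weighted least-squares cost

    χ²(θ) = Λᵀ R Λ,    Λ_i = f(t_i; θ) − ȳ_i,

with a symmetric positive-definite weight matrix R.  The point estimate θ̂
is easy; its **uncertainty** is where standard practice fails.  The
fluctuations of ȳ around its true mean are strongly correlated across
sampling times (a trajectory that is above the mean at t_i tends to stay
above it at t_j), so the textbook WLS error formula — which assumes
independent errors per point — can understate σ(θ̂) by a large factor.

`trajfit` implements the correlation-aware covariance estimator
(**WLS-ICE**, "including correlations in the error estimate").  With
G_ia = ∂f(t_i)/∂θ_a, the sample covariance Q̄ across trajectories, and the
residuals Λ at the minimum:

    Δ̂    = φ̂ / M                                  (K×K parameter covariance)
    φ̂    = 4 ĥ⁻¹ Gᵀ (Rᵀ Q̄ R) G ĥ⁻¹
    ĥ_ab = 2 Σ_ij [∂²f_i/∂θ_a∂θ_b] R_ij Λ_j + 2 Σ_ij [∂f_i/∂θ_a] R_ij [∂f_j/∂θ_b]

valid for any R to leading order in 1/M.  Only the small K×K matrix ĥ is
inverted — never the noisy N×N covariance — so the estimator is immune to
the ill-conditioning that plagues the correlated-χ² method (CCM, R = C̄⁻¹).
Setting Q̄ → diag(Q̄) recovers the classical uncorrelated formula (WLS-ECE),
useful mainly to demonstrate how badly it undershoots.

The package also provides: CCM and a Brownian-motion-adapted GLS weighting
(BMALS), grouped jackknife bias correction (orders 1 and 2), trajectory
bootstrap, seeded simulators for four prototype processes (Brownian motion,
fractional Brownian motion, continuous-time random walks with heavy-tailed
waits, a critically damped Langevin oscillator), and a replicate-based
validation harness (ground-truth spreads, interval coverage, R², bias /
ill-conditioning phase maps over (N, M)).

## Worked example

Simulate fractional Brownian motion (Hurst exponent H = 0.75, so the MSD is
2K_f·t^{2H} = 2·t^{1.5}), then fit the power law and compare error
estimates:

```sh
trajfit simulate --process fbm --H 0.75 --K_f 1.0 --d 1 \
    --n-times 50 --t-max 50 --n-traj 500 --seed 42 --out msd.csv
trajfit fit --input msd.csv --model power_law --method wls --errors wls-ice
```

The fit report (abridged) reads:

```
"theta_hat":  [1.9418252530118196, 1.5022614570255497],
"sigma_hat":  [0.16964262025618018, 0.027495744930551954],
"chi2":       4.007399262464393,
"r_squared":  0.9996471136146509,
"converged":  true
```

The estimates straddle the true values (θ₁*, θ₂*) = (2, 1.5) well within
one estimated σ.  Re-running with `--errors wls-ece` gives
`sigma_hat = [0.0641, 0.0104]` — about 2.7× smaller than the
correlation-aware values, the typical overconfidence of the classical
formula on correlated data.

The same machinery is available as a library:

```python
import numpy as np, trajfit as tf

spec = tf.ProcessSpec("bm", {"D": 1.0, "d": 1}, times=np.arange(1.0, 76.0), M=1000)
ens = tf.simulate(spec, seed=1)                    # squared displacements
stats, fit = tf.fit_ensemble(ens, tf.model_linear())
cov = tf.wlsice_covariance(stats, fit.model, fit.weights, fit, ens.times)
print(fit.theta_hat, cov.sigma_hat)                # theta1 ~ 2dD = 2
```

`trajfit validate` and `trajfit phasemap` run the replicate experiments
(S independent ensembles, coverage, bias maps) from the command line; see
`trajfit --help`.

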