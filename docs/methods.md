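# Methods

## Model

`jrnmm` simulates a stochastic Jansen–Rit neural mass model. Three neural
populations (pyramidal cells, excitatory and inhibitory interneurons) are
described by their mean postsynaptic potentials `Q = (x0, x1, x2)` (mV) and
the corresponding derivatives `P = (x3, x4, x5)` (mV/s). Each population is a
critically damped second-order filter driven through a logistic firing-rate
gain

    Sigm(x) = nu_max / (1 + exp(r (v0 - x))),

and the system is written as a damped stochastic Hamiltonian (Langevin-type)
system with additive noise on the momenta:

    dQ = P dt
    dP = (-Gamma^2 Q - 2 Gamma P + G(t, Q)) dt + Sigma dW,

with `Gamma = diag[a, a, b]`, `Sigma = diag[sigma3, sigma4, sigma5]`, three
independent Wiener processes, and displacement

    G(t, Q) = G^I(t) + G^II(Q)
    G^I  = (A a mu3, A a mu4, B b mu5)
    G^II = (A a Sigm(x1 - x2), A a C2 Sigm(C1 x0), B b C4 Sigm(C3 x0)).

The output signal `Y = x1 - x2` is the EEG-like net membrane potential of the
pyramidal population. Because the noise is additive, the Itô and Stratonovich
readings coincide.

**Units.** Everything is on the seconds scale: the classical time constants
of 10 ms and 20 ms become rate constants `a = 100 1/s` and `b = 50 1/s`. The
standard constants are `A = 3.25 mV`, `B = 22 mV`, `nu_max = 5 1/s`,
`v0 = 6 mV`, `r = 0.56 1/mV`, and the connectivities scale with a single
parameter `C` as `C1 = C`, `C2 = 0.8 C`, `C3 = C4 = 0.25 C` (default
`C = 135`). The customary noisy alpha-rhythm configuration is `mu = (0, 220,
0)` and `sigma = (10, 1000, 10)`; `mu4` and `sigma4` enter the `x4` equation
exactly as written above, on the seconds scale. Inputs and noise scales may
also be smooth functions of time, in which case they must declare an explicit
upper bound (the moment bounds need `mu_i <= mu_i,max`).

## Exact sub-flows and splitting integrators

The linear part has block drift matrix `M = [[0, I], [-Gamma^2, -2 Gamma]]`
with diagonal sub-blocks, so the matrix exponential is available in closed
form,

    e^{Mt} = [[theta(t), kappa(t)], [theta'(t), kappa'(t)]],
    theta  = e^{-Gamma t}(I + Gamma t),   kappa  = e^{-Gamma t} t,
    theta' = -Gamma^2 e^{-Gamma t} t,     kappa' = e^{-Gamma t}(I - Gamma t),

valid verbatim for any diagonal `Gamma` including `a = b`, and for negative
`t` (inverse flow). Two Lie–Trotter splittings use this flow exactly:

* **OU splitting** (`ou`): the noise joins the linear sub-system, which is a
  six-dimensional Ornstein–Uhlenbeck process sampled exactly: `X <- e^{M dt}
  X + xi`, `xi ~ N(0, Cov(dt))`. For constant `Sigma` the transition
  covariance has the closed form implemented in `ou_step_covariance`; for
  time-dependent `Sigma` the matrix-valued covariance ODE is integrated once
  per step-size with fixed-step classical Runge–Kutta (100 substeps) and
  cached. `xi` is coloured through a symmetric eigendecomposition square
  root; eigenvalues in `[-1e-12 ||Cov||, 0)` are clipped to zero because the
  `Q`-block is singular as `dt -> 0`.
* **Wiener splitting** (`wiener`): the noise joins the nonlinear kick, which
  becomes a Wiener process with drift: `P <- P + dt G^II(Q) + int G^I +
  Sigma dW`.

The composition applies the nonlinear/stochastic kick first and the linear
flow second; a `commute` flag swaps the order (the analytic properties hold
either way). The **Strang** scheme (`strang`) symmetrises the Wiener
splitting (half linear flow, full kick, half linear flow) and is second order
for the noiseless system while remaining mean-square order one with noise.
**Euler–Maruyama** (`em`) is included as the standard baseline. The integral
`int G^I` over a step is exact for constant inputs and uses 5-point
Gauss–Legendre quadrature for time-dependent ones.

**Randomness.** A single seed spawns four child streams: one per Wiener
component, plus one for the OU scheme's correlated six-dimensional
increments. Runs with equal seeds are bit-identical.

## Moment envelopes, escape bounds and calibration

The variation-of-constants (convolution) representation

    Q(t) = theta(t) Q0 + kappa(t) P0 + int_0^t kappa(t-s) G(s, Q(s)) ds
         + int_0^t kappa(t-s) Sigma dW(s)

combined with `0 <= G <= C_G`, `C_G = (A a (mu3max + nu_max), A a (mu4max +
C2 nu_max), B b (mu5max + C4 nu_max))`, yields:

* a first-moment envelope `u(t) <= E[Q(t)] <= u(t) + Gamma^-2 (I - theta)
  C_G` with `u = theta Q0 + kappa P0` (the envelope contracts exponentially
  to `[0, Gamma^-2 C_G]`);
* a second-moment upper envelope with the elementwise indicator `1+(u)`
  applied per component and per time point, limit `(Gamma^-2 C_G +
  Gamma^-3/2 Sigma / 2)^2`;
* a dominating Gaussian process with mean `u + Gamma^-2 (I - theta) C_G` and
  variance `Gamma^-3 Sigma^2 (I + kappa theta' - theta^2) / 4`, whose
  quantiles bound pointwise escape probabilities: `P(X_i(t) >= x_th) <= 1 -
  F_{Y_i(t)}(x_th)`. Components are treated as pointwise independent bounds;
  no joint (simultaneous-in-time or cross-component) statement is made.

`calibrate_sigma` inverts the bound: it solves `F_{Y(t)}(x_th) = alpha` for
the noise scale by bracketing and Brent root finding (1e-10 relative
tolerance). The threshold must lie above the envelope mean; `alpha <= 0.5`
then admits no root and is rejected with a diagnostic, and the degenerate
pair (threshold at the mean, `alpha = 0.5`) returns 0 by convention.

`convolution_reconstruct` discretises the convolution representation with a
left-endpoint rectangle rule on the trajectory's own grid (first-order
accurate). For the Wiener splitting this reproduces the stepped trajectory
*exactly* — unrolling `X_{i+1} = e^{M dt}(X_i + (0, kick_i))` gives
`Q_n = theta(t_n) Q0 + kappa(t_n) P0 + sum_k kappa(t_n - t_k) kick_k` with
`t_k` the left endpoints — so it serves as an independent oracle for the
steppers.

## Ergodicity diagnostics

With all `sigma_i > 0` constant the model has a unique invariant measure and
is geometrically ergodic, and the splitting chains satisfy a discrete
Lyapunov drift condition for `dt < 1/(2 max(a, b))` (0.005 s at the standard
constants). The package checks the consequences numerically:

* `long_run` simulates a single long path and returns post-burn-in, strided
  samples (defaults: burn-in 10 s, stride 10 steps — the correlation time of
  the alpha regime is ~0.1 s, so strided samples at 10 ms are weakly
  dependent). It warns when ellipticity fails.
* `kde_density` is a Gaussian-kernel estimator with an *absolute* bandwidth;
  the default is Silverman's rule `0.9 min(sd, IQR/1.34) n^{-1/5}`.
* `time_average` reports batch-means standard errors (20 contiguous batches
  by default).
* `drift_check` estimates `E[V_1(X_{i+1}) | V_1(X_i)]` for the Lyapunov
  functional `V_1 = 1 + |P|^2/2 + 3 |Gamma Q|^2/2 + <P, Gamma Q>` by binning
  transitions into 20 equal-count bins and fitting a least-squares line
  through the bin means; slope < 1 confirms the contraction. Above the
  step-size restriction the report flags the hypothesis violation instead of
  asserting.

**Modality experiments.** Density modality is classified by counting local
maxima above 5% of the global maximum. Silverman's bandwidth is kept as the
general default but is *not* used for the modality experiments: at small
sample sizes the rare-excursion shoulder of the C=135 density fluctuates
around the 5% threshold, and at large sample sizes the rule resolves the two
turning-point humps of a single alpha cycle (0.7 mV apart, nearly equal
height) into separate modes. The modality studies therefore fix the
bandwidth at 0.5 mV — above the intra-cycle hump separation and far below
the multi-mV separation of distinct dynamical states — and use T = 200 s,
burn-in 20 s, stride 5 at `dt = 2e-3` with the Strang scheme. With these
settings the unimodal (C=135) vs multimodal (C=270) classification is stable
across seeds.

## Convergence-order measurement

`estimate_ms_order` measures mean-square orders with coupled Brownian paths:
increments are generated on the finest grid (`dt_min / 4`) and aggregated by
summation to each coarser dyadic grid, so every run sees the same noise. The
reference solution is the Strang splitting on the finest grid (no exact
solution exists); errors are RMS endpoint errors over the path ensemble, and
the reported order is the least-squares slope of `log(error)` vs `log(dt)`
with a standard error over 10 disjoint path groups. For the OU scheme the
exact Gaussian increment is not a function of the coarse Brownian increment
alone; in coupled mode it is reconstructed from the fine increments as the
right-endpoint Riemann sum `xi = sum_j e^{M (m-1-j) delta} S dW_j`, whose
covariance converges to the exact transition covariance as the fine step
`delta -> 0` (verified in the tests), so the coupling error vanishes faster
than the first-order scheme error being measured.

**Problem sizes.** The stochastic order studies use T = 1 s, 500 paths and
`dt in {4e-3, 2e-3, 1e-3, 5e-4}` on the noisy alpha regime; slopes are 0.93
± 0.01 for both splittings. The deterministic Strang study uses `dt in
{2e-3, 1e-3, 5e-4, 2.5e-4}`: at 4e-3 this oscillatory system is outside the
asymptotic regime for a second-order fit, so the step list sits one dyadic
level finer (slope ≈ 2.1).

**Euler–Maruyama at coarse steps.** On the C=135 limit-cycle regime the EM
endpoint error is saturated at the signal scale for `dt >= 5e-4` (the phase
of the oscillation decoheres from the reference), so a log-log fit over the
coarse window yields a slope near 0.44 rather than the asymptotic order one.
This is the same step-size fragility visible in the EM phase portraits and
invariant densities: EM only enters its asymptotic first-order regime below
roughly 1e-4 s here, where its fitted slope rises towards one (0.79 at `dt
in {1.25e-4 .. 3.1e-5}`; 1.12 on the linearised system). The test suite
records this as is: the EM case of the coarse-step order check fails, while
both splitting schemes pass — the practical argument for the splittings.

## Synthetic data

All experiments run on internally generated trajectories; there is no
external data. The presets bundle the study conditions: the noisy
alpha-rhythm regime (`alpha_C135`, also `C135`), the weak-noise
phase-portrait regime (`phase_C135_smallnoise`, `sigma = (1, 200, 1)`), and
the connectivity sweep `C in {68, 135, 270, 675}` spanning the transition
from unimodal to multimodal stationary output densities.
What passing tests show is internal consistency of the model, bounds and
integrators under these idealised conditions (constant inputs, additive
Gaussian white noise, exactly known parameters); they do not validate the
model against physiological EEG recordings, parameter uncertainty, or
non-white input noise.

## Known limitations

* Envelopes are provided for `Q` only; the analogous `P` results are not
  implemented.
* The escape bounds are pointwise in time and component; no uniform or joint
  bounds.
* The Strang scheme stays mean-square order one with noise; raising it would
  require higher-order stochastic integrals, which are out of scope, as are
  adaptive step-size control, Fokker–Planck solves, Malliavin density
  estimation and multi-population extensions.
* For time-dependent diffusion the OU transition covariance is integrated on
  `[0, dt]` once per step-size (the per-step time dependence within a run is
  not re-integrated); slowly varying `Sigma` is the intended use case.
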