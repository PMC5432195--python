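# Methods

## Model

`balnet` simulates two coupled balanced subnetworks of binary neurons.
Each subnetwork holds one excitatory (E) and one inhibitory (I) population
of N neurons.  Within a subnetwork, synapses are random (probability K/N,
1 ≪ K ≪ N) with strengths J_ab/√K; the within-couplings are fixed at
J_EE = J_IE = 1, J_EI = −J_E, J_II = −J_I.  The two subnetworks inhibit each
other: each inhibitory population projects to the opposing excitatory
population, either all-to-all with weak synapses −J̃√K/N (default) or
sparsely (probability K/N) with strong synapses −J̃/√K.  Excitatory
populations receive a constant feedforward drive √K·E0.

Neurons are binary, σ ∈ {0, 1}, updated asynchronously at Poisson times
(mean interval τ_E = 10 ms for E neurons, τ_I = 8 ms for I neurons).  At an
update, σ ← Θ(u) with u the total weighted input minus the threshold T
(default 1 for all populations).  The dynamics are fully deterministic given
the connectivity and the update schedule; all apparent stochasticity is
chaotic network noise.

Default couplings throughout: J_E = 4, J_I = 2.5, E0 = 0.3.

## Mean-field theory

For N → ∞ the population activities m = (m1, m2, m3, m4) (order E1, I1, E2,
I2) obey τ_i dm_i/dt = −m_i + H(−u_i/√α_i), with H the Gaussian tail
function, u_i = √K(C m + E0)_i − T_i the population-mean input (C the
coupling matrix) and α_i the across-neuron input variance (α1 = m1 + J_E²m2
etc.; in sparse cross mode the cross synapses add J̃²·m_opp to the
excitatory rows).  Steady states solve m_i = H(−u_i/√α_i).

As K → ∞ the steady-state conditions become the linear system C m + E0 = 0,
which is singular exactly at J̃ = J_E − J_I.  At that tuning the solutions
form a line, parametrized by m1 = x, m2 = x/J_I, m3 = −x + J_I E0/(J_E−J_I),
m4 = −x/J_I + E0/(J_E−J_I), valid for 0 < x < J_I·E0/(J_E−J_I); its
direction is the null vector (1, 1/J_I, −1, −1/J_I).

At finite K the line is only approximate.  The symmetric fixed point
(m1 = m3, m2 = m4) always exists and is found by damped Newton iteration on
the reduced two-variable system (residual tolerance 10⁻¹³, iterates kept
strictly inside (0,1); an independent nested-bisection solve cross-checks it
in the tests).  The Jacobian is assembled from the analytic partials
f_ij = ∂H(−u_i/√α_i)/∂m_j with time in units of τ_E (inhibitory rows divided
by τ = τ_I/τ_E = 0.8).  At the symmetric point a closed form gives all four
eigenvalues; tuning J̃ to the root of the eigenvalue closest to zero
(Brent's method on the bracket [J_E−J_I, J_E−J_I+1]) yields J̃* ≈ 1.70 at
K = 1000 — and J̃* → J_E − J_I = 1.5 as K grows.  Equivalent formulations
(nullcline slope ∂m3/∂m1 = −1, the closed-form f14 identity) agree to
machine precision and are tested against each other.

The scalar attractor coordinate is X(t) = v0·(m(t) − m0), where m0 is the
symmetric point and v0 the slow left eigenvector, normalized so that
v0·r0 = 1 with the right eigenvector r0 scaled to first component 1.  With
this normalization X equals the line-parameter offset x − x_sym along the
exact K → ∞ line.

Sign conventions: the steady-state form m = H(−u/√α) fixes both the sign of
the H argument and the √α normalization; integrator and fixed-point code use
it consistently.

## Simulation algorithm

A single global exponential clock with total rate 2N/τ_E + 2N/τ_I drives
events (Gillespie-style); each event picks a population proportionally to
its rate and a neuron uniformly.  This is statistically identical to
per-neuron Poisson clocks.  Per-neuron inputs are cached and updated
additively when a presynaptic neuron flips; the all-to-all cross-inhibition
is never materialized — it is exact given the opposing population count and
added at evaluation time (−J̃√K·m_opp).  A full brute-force recomputation
of the cache every 10⁶ events caps floating-point drift (verified ≤
10⁻⁹·√K against direct summation).  Θ(0) = 0 by convention: a neuron with
input exactly at threshold stays (or becomes) inactive.  The inner loop is
compiled with numba; a pure-Python reference step with identical mechanics
backs the mechanistic tests.

Mirrored mode copies subnetwork 1's synapses to subnetwork 2; with a
mirrored schedule (each event applied to the same index in both
subnetworks) and a mirrored initial state the subnetwork symmetry
m1(t) = m3(t), m2(t) = m4(t) is exact to the bit, which the tests assert.

Optional input noise: an Ornstein–Uhlenbeck process
τ_noise ξ' = −ξ + σ_noise η(t) (default τ_noise = 30 ms when enabled),
propagated *exactly* between consecutive event times and added to E0 of the
excitatory populations; shared between subnetworks or independent per
subnetwork.

Three independent seed streams (connectivity, schedule, initial state) make
the perturbed-replica protocol expressible: replicas share the connectivity
and schedule and differ only by flipped neurons.

## Tuning finite networks

The N → ∞ mean field locates the singular coupling, but finite simulated
networks realize a slow rate λ_emp offset from the mean-field value (at
K = 100, N = 4000–16000 we measure λ_emp ≈ λ_mf + 0.007/ms).  Tuning the
simulation to the mean-field singular point therefore overshoots and the
state drifts to an end of the line.  `experiments.tune_empirical` follows
the empirical protocol instead: λ is estimated from the drift moment
F(X, Δt) ≈ −λXΔt of short pilot runs at two safely stable detunings, and J̃
is set by solving the resulting linear λ_emp(J̃) for the target.

The stochastic test suites use a fixed *weakly tuned* coupling — the
mean-field J̃ for λ = −1/50 ms — which realizes λ_emp ≈ −1/80 ms.  This
keeps the memory-decay time an order of magnitude above the neuron time
scale (the regime of interest) while keeping trajectories inside the
central attractor range and the Ornstein–Uhlenbeck regime measurable within
minutes of simulated time.

## Diffusion statistics

The conditional moments F(X, Δt) (drift) and G(X, Δt) (diffusion) are
estimated exactly as defined: all sample times with |X(t) − X| < δ
(δ = 10⁻³ by default) contribute displacements over each lag; cells with
fewer than 50 samples are reported missing.  Standard errors are
trial-level when at least three independent trials populate a cell,
otherwise pooled per-sample errors (optimistic, since successive samples
are correlated — noted wherever used).

OU convention: dX = −λX dt + √(2D) dW, so the stationary variance is D/λ
and the small-lag diffusion slope is G/Δt → 2D.  Because G(0, Δt)
conditions on the starting value, its exact OU form is
G(0, Δt) = Var(Δt|X=0) = (D/λ)(1 − e^(−2λΔt)), saturating at D/λ; fits use
this self-consistent form (validated on exactly sampled OU paths).  Fits
exclude lags below τ — where single-neuron statistics, not the collective
OU regime, govern G — and iterate the upper window once to 4/λ̂.

Short lags: G(X, Δt)/Δt = (2/N) Σ_j (v0_j)² (−dq_j/dt|₀), with q_j the
population-averaged single-neuron autocorrelation.  The initial slope is
estimated by fitting a + b e^(−t/τ_q) over the slope window and
differentiating at zero; a plain linear fit over the same window
underestimates |dq/dt(0)| by ~25% (secant bias on a convex decay) and is
kept only as an option.  The prediction is parameter-free and is compared
with measured G at Δt ≤ τ/20, where the collective contribution (relative
size O(Δt·rate)) is negligible at desk scale.

Cross-covariances implement the printed estimators verbatim: the
single-pair unbiased estimate (lagged product normalized by M − |lag|,
full-record means subtracted) averaged over distinct pairs, and the
population-level version from mean activities (which includes the
auto-covariance terms, a relative O(1/N) contribution).  The default
sampling interval for covariance measurements is 66 ms.

## Semi-analytic diffusion prediction

Near its fixed point a single balanced subnetwork is modeled as
δṁ = B1 δm + B2 δE + ξ with B1, B2 from the analytic linearization and ξ
the effective chaotic noise.  Its covariance is inferred from the measured
activity covariance C_m of a single network (simulated at the drive each
subnetwork receives at the coupled symmetric point, E_in = E0 − J̃·m_I) via

    C_ξ(t) = −C_m″ − C_m′ B1ᵀ + B1 C_m′ + B1 C_m B1ᵀ,

with Gaussian smoothing (width τ_E/5) before the central differences
because second derivatives of empirical covariances are otherwise dominated
by sampling noise.  The middle-term signs follow from the covariance
convention C_m(Δt) = ⟨δm(t+Δt) δm(t)ᵀ⟩; an exact spectral forward model
(linear system driven by known colored noise) pins them down in the tests —
the inverse recovers the known C_ξ to better than 2%, while the
opposite-sign variant errs by ~4%.

The coupled system's slow coordinate then obeys Ẋ = λX + v0·ξ̃ with ξ̃ the
block-diagonal two-subnetwork noise, giving

    C_X(t) = −(1/2λ) ∫ e^(λ|t′|) v0ᵀ C̃_ξ(t−t′) v0 dt′,
    G(Δt)  = 2 (C_X(0) − C_X(Δt)),

evaluated by trapezoidal quadrature on the measured lag support (C_ξ decays
within ~τ; contributions beyond the window are negligible).  λ is the
*realized* slow rate measured from the coupled simulation — the reduction
Ẋ = λX + v0·ξ̃ describes the realized, not the idealized, slow mode.  The
pipeline has no fitting parameters and is linear in C_m, which is the
mechanism behind the 1/N scaling of the diffusion coefficient.

## Problem sizes

Analytic/mean-field computations run in seconds at any K.  The stochastic
suites use N ∈ {4000, 8000, 16000} at K = 100 with 6 trials × 8 s per size,
30 s single-network runs at N ∈ {4000, 8000}, one finely sampled run
(Δt_rec = 0.25 ms) for single-neuron statistics, and a 16 s spike record of
400 neurons per population for inter-spike-interval statistics (shorter
records select high-rate neurons and bias the CV down) — all chosen so the
full suite completes in minutes on one core while leaving the tested
properties (D·N constancy, covariance collapse, the zero-parameter G
prediction) statistically resolvable.  At these sizes the N → ∞ mean field
carries visible finite-size error (activities biased by up to ~2% at low
drive; the realized slow rate offset from the mean-field value), which
bounds how sharply theory–simulation comparisons can resolve at desk scale.  The experiment drivers accept full-scale settings (N up to 1.5×10⁵,
K = 500–1000, up to 1500 trials) behind an explicit acknowledgment; those
runs take hours and their quantitative outcomes (e.g. diffusion
coefficients of order 10⁻⁶ per 10 ms at N ~ 10⁵) are not re-verified at
desk scale.

## What the synthetic data does and does not emulate

Validation inputs are generated, never measured: seeded random
connectivity, simulated binary-state trajectories, exactly sampled OU paths
(estimator ground truth), a Bernoulli-refresh surrogate with closed-form
autocorrelation, and spectrally constructed linear-system covariances
(noise-inversion ground truth).  Passing tests therefore demonstrate
internal consistency of model, theory and estimators — they do not speak to
biological realism: real circuits have conductance-based neurons, synaptic
delays and filtering, structured connectivity and nonstationary drive, none
of which the binary model represents.

## Known limitations

* The finite-N offset of λ is measured, not derived; `tune_empirical`
  calibrates it per configuration but extrapolates when the target |λ| is
  much smaller than the pilot rates.
* Conditional-moment standard errors from a single trace ignore temporal
  correlation; trial-level errors are used wherever trials exist.
* Nullcline continuation can fail near the saturated corners of activity
  space; failed grid points are flagged NaN rather than interpolated.
* The sparse-cross and input-noise scenarios are exercised by experiment
  drivers and invariants, at lighter statistical depth than the all-to-all
  mirrored default.
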