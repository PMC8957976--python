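# Methods

This note documents the generative model, the inversion scheme, the group
statistics, the synthetic-cohort design, and the numerical decisions behind
`cmcdcm`, in enough detail to re-derive or challenge any of them.

## Network specification

Five regions in fixed index order — MC (1), PFC (2), BG (3), MTL (4),
SENS (5) — with "row = target, column = source" orientation for every
matrix (so `A[r, c]` is the connection c→r, matching the `A·y` convention
of the state equation).  Both CMC variants share eight directed fixed
connections (SENS↔MC, MTL↔PFC, SENS↔PFC bidirectionally, plus PFC→MC and
PFC→BG; MC→PFC is deliberately absent — the architecture is asymmetric)
and five always-present self-connections.  The **direct** variant adds the
fixed edge BG→PFC; the **modulatory** variant instead estimates two
second-order gains, BG gating MTL→PFC and BG gating SENS→PFC.  Counting
off-diagonal A entries plus D entries, the variants differ by exactly one
free parameter (10 vs 9); input (C) and self parameters are identical.

## Drivers

Resting-state runs have no events, so deterministic low-frequency boxcars
stand in for the drivers: for each f ∈ {0.01, 0.02, 0.04, 0.08} Hz the
columns 1[sin(2πft) > 0] and 1[sin(2πft + π/2) > 0] (cycles of 100, 50, 25
and 12.5 s, duty 1/2, quarter-period lag).  Columns are built on a
micro-time grid of dt = TR/16 and evaluated at **bin centers**: switch
times for the default frequencies lie exactly on bin edges, so center
evaluation never hits a zero crossing, gives exactly 0.5 duty over integer
periods, and makes the quarter-period shift identity exact.  Boxcars take
values {0, 1} and are not mean-centered (the sign convention of C would
otherwise be unidentifiable).  The same columns, down-sampled to scan
times, form the GLM design of the regressor-quality check.

## Forward model

Neural dynamics follow the bilinear state equation (see README).  Each
region's activity drives the classical balloon–Windkessel cascade

    ds/dt = y − κs − γ(f − 1),   df/dt = s,
    τ dv/dt = f − v^{1/α},       τ dq/dt = f·E(f)/ρ − v^{1/α} q/v,
    E(f) = 1 − (1−ρ)^{1/f},

with constants κ = 0.64 s⁻¹, γ = 0.32 s⁻¹, τ = 2.0 s, α = 0.32, ρ = 0.4,
V₀ = 0.04, and output nonlinearity (percent signal change)

    BOLD = 100·V₀·(k₁(1−q) + k₂(1−q/v) + k₃(1−v)),  k₁ = 7ρ, k₂ = 2, k₃ = 2ρ−0.2.

These are the standard constants of the balloon observation model;
hemodynamic parameters are fixed and shared across regions (the analysis
estimates connectivity, not hemodynamics).

**Integration.**  Classical fixed-step RK4 at dt = TR/16 for both the
neural and hemodynamic systems.  The step grid is aligned with the boxcar
switch times, so each step sees a constant input and RK4 keeps full order
despite the discontinuous drive; the hemodynamic stage interpolates neural
activity linearly to step midpoints.  A first-order (Euler) scheme at this
step size has relative error of order dt/(2τ) ≈ 4% and cannot meet the
package's own 1e−3 agreement bound against an adaptive reference, which is
why RK4 was chosen; with RK4 the fixed-step endpoint agrees with a
piecewise adaptive RK45 reference to better than 1e−3 (tested), and
halving dt moves endpoints by far less than 1e−3.  BOLD is read out at the
micro-sample nearest each scan time k·TR.

**Domain of validity.**  A neural trajectory with |y| > 1e3 aborts with a
structured divergence error.  The balloon equations are *genuinely
singular* when inflow reaches zero (E(f) → 1−(1−ρ)^{1/f} blows up), which
sustained strongly negative neural activity can cause; an adaptive solver
fails at the same point, so this is a property of the model, not of the
integrator.  Trajectories with f, v or q outside (0, 100] therefore also
raise divergence (the states are ratios to rest and physiologically O(1)).

## Synthetic cohorts

Each group's ground-truth distribution is a `GroupParameterProfile`:
per-entry means and between-subject jitter SDs.  Defaults:

* **Fixed connections (A)** — the published modulatory-model group means
  and dispersions per group (e.g. PD SENS→MC −0.16 ± 0.002, HC 0.11 ±
  0.006, and so on for the eight connections).
* **Gating gains (D)** — PD: 0.24 ± 0.11 (BG|MTL→PFC) and −1.59 ± 0.31
  (BG|SENS→PFC); HC: −3.84 ± 0.02 and −2.39 ± 0.56.
* **Self-decays** — −0.5 ± 0.1 Hz, redrawn (bounded retries) if a draw is
  non-negative.
* **Driver weights (C)** — no published values exist.  The default truth
  profile is heterogeneous weights 0.04 + 0.015·N(0,1) drawn once from a
  fixed seed (1905) and shared by every cohort, so regions couple to the
  low-frequency drivers with distinct patterns; between-subject jitter is
  0.01 (a quarter of the weight scale — jitter at the generic 0.1 level
  would routinely flip drive signs and destabilize the bilinear dynamics).
  The **HC profile uses half the PD drive amplitude**: the HC gating gains
  (−3.84 and −2.39 acting jointly on PFC) are only dynamically admissible
  at weaker neural excursions — at PD-level drive virtually every HC draw
  crosses the inflow singularity.  Group differences in low-frequency
  fluctuation amplitude are themselves a documented feature of PD cohorts,
  so per-group drive scales are within the generator's remit.
* **Direct-variant BG→PFC** — printed nowhere; defaults 0.15 (PD) and 0.10
  (HC), PD > HC matching the reported direction of the cross-model
  contrast.  Arbitrary but fixed and documented.
* **Observation noise** — i.i.d. Gaussian per sample with SD set per
  subject to (mean per-region signal SD)/SNR, SNR = 3 by default
  (mid-range of conventional DCM simulation practice); an explicit
  `noise_sd` overrides this.

Cohorts default to 70 PD + 41 HC (111 subjects).  Per-subject seeds derive
deterministically from the master seed; parameter draws and noise draws use
separate seed streams, so cohorts are byte-reproducible.  A subject whose
drawn parameters produce dynamics outside the model's domain is **redrawn**
from a deterministic sub-stream (≤ 8 attempts) — the synthetic population
is the profile distribution truncated to dynamically valid systems, the
analogue of the fact that real recordings are bounded by construction.

What the generator does *not* emulate: scanner drift, motion,
physiological noise, spatial structure, hemodynamic variability across
subjects or regions.  Passing tests therefore demonstrate correctness of
the estimation machinery under the stated statistical assumptions, not
robustness to real-world artifacts.

## Inversion (variational Laplace)

Per subject and variant, the masked parameters are fitted by maximizing a
free-energy objective F = accuracy − complexity under a Gaussian
observation model with one noise precision exp(h) shared across regions:

* **Parameterization** — off-diagonal A, C and D entries on their natural
  scale; self-decays as log-latents a_ii = −0.5·exp(λ) (negativity
  preserved; reported back-transformed, delta-method covariance).
* **Priors** — zero-mean shrinkage: off-diagonal A variance 1/16 (fixed
  connections are fractions of the 0.5 Hz self-decay), C variance 1,
  self-latents N(0, 1/64), noise log-precision N(4, 1) (matching
  percent-signal-change units at SNR ≈ 3).  **D variance 4**: gating gains
  are unitless ratios with published magnitudes up to ~4, and — because the
  quasi-constant part of a gating signal y_BG·y_src is collinear with the
  gated fixed connection — the A:D prior ratio decides how that shared
  component is attributed.  A D prior much tighter than the gains it must
  represent provably understates them (recovery simulations show the
  planted 0.24 gain shrinking to ~0.10 at variance 1 and recovering
  near-unbiased at variance 4, assessed on a held-out seed set before
  freezing).
* **Optimization** — iterated Gauss–Newton with Levenberg–Marquardt
  damping on the penalized objective; forward sensitivities by forward
  finite differences (step 1e−4, latent scale) evaluated with a batched
  compiled (numba) RK4 integrator, one sweep for the whole Jacobian.  The
  noise log-precision is updated each outer iteration by a closed-form
  (1-D Newton) step including its hyperprior.  A **free-energy guard**
  tracks the best state and reverts with increased damping whenever an
  iteration lowers F — without it, a blown-up residual collapses the noise
  precision and the optimizer can drift into absurd regions at essentially
  flat penalized objective.  Convergence when the F improvement falls
  below 0.01 nats; cap 64 iterations; initialization at the prior means,
  optional seeded multi-start for hard cases (off by default).  Candidate
  steps whose forward sweep diverges are rejected (damping increases);
  parameter directions whose perturbed sweep diverges get zero sensitivity
  for that iteration.
* **Posterior** — Laplace: covariance = inverse of (exp(h)·JᵀJ + prior
  precision) at the optimum, symmetrized, eigenvalue floor −1e−8 enforced.
  F (accuracy − parameter complexity − hyperparameter complexity) is the
  log-evidence plug-in for model comparison.

The compiled batched integrator and the plain reference implementation in
`generative` share the identical update rule and are held to 1e−10
agreement by a dedicated test, so the fast path cannot drift from the
documented model.

## Model comparison and group statistics

* **BMS** — fixed-effects log group Bayes factor: sum over subjects of
  per-subject free-energy differences (modulatory − direct).  Verdicts use
  strict thresholds: > 10 strong, > 3 moderate, otherwise the direct
  (null) model is retained; exactly 3 is *not* moderate.
* **BPA** — fixed-effects combination of per-subject Gaussian posteriors:
  Λ_g = ΣΛᵢ − (n−1)Λ₀ and μ_g = Λ_g⁻¹(ΣΛᵢμᵢ − (n−1)Λ₀μ₀), full-matrix,
  on the generative scale (the prior enters through its delta-method
  moments there).  A non-positive-definite combined precision (possible if
  per-subject posteriors are wider than the prior) raises with
  diagnostics.
* **Directional tests** — per parameter, z = (μ_PD − μ_HC)/√(σ²_PD +
  σ²_HC); p_less = Φ(z), p_greater = 1 − Φ(z).  This equals the posterior
  probability of the sign of the difference under independent Gaussian
  group posteriors; both readings are documented, one implementation.  σ
  columns of group summaries are treated as standard deviations, the
  reading under which the published direct-connection table reproduces in
  full.  Reported tables round means to two decimals, floor p at
  "<0.001", and print an em-dash for the direction not tested (p_greater
  is only tested where the 'less' direction failed to reject at 0.05).
  One published row (the second gating connection) prints a p that does
  not follow from its own (μ, σ) summaries (z ≈ 1.25 → p_greater ≈ 0.11);
  the recomputation reports the computed value rather than matching the
  printed one.
* **Cross-model contrast** — for the fixed connections estimated under
  both variants, the PD−HC mean difference per variant with a
  sign-disagreement flag.

## GLM regressor check

Per region, an omnibus F over the eight boxcars (intercept + 8 columns at
scan resolution, unconvolved by default so the GLM design equals the DCM
drive; at ≤ 0.08 Hz hemodynamic convolution mainly phase-shifts).  df1 = 8,
df2 = scans − 9; rank-deficient designs (e.g. an all-zero column) are
rejected, never silently repaired.  The group-level one-sample t of log F
is centered on the analytic null mean E[log F] = ψ(df1/2) − log(df1/2) −
ψ(df2/2) + log(df2/2) (ψ the digamma function) — not on zero, and not on
log E[F] = log(df2/(df2−2)), which differs from E[log F] by ~0.13 at these
dfs.  The fast linear-algebra path is cross-checked against statsmodels
OLS F-tests in the suite.  With 111 subjects the group test has df = 110,
matching the study's t(110) > 3.166 reporting threshold; null calibration
at that threshold is part of the suite.

## Problem sizes used in the shipped experiments

The recovery experiment uses 10 subjects (jitter 0, SNR 3, TR 2.5 s, 240
scans) and the model-selection experiment 8 subjects (default jitter) —
the study's own desk-scale calibration sizes; module-level tests use 80–120
scans where only mechanics are exercised.  One subject-level inversion
takes a few seconds on one CPU.

## Known limitations

* Deterministic-input DCM only: no stochastic, spectral or time-varying
  variants; a single static fit per 10-minute run.
* Hemodynamics fixed and homogeneous; no per-region or per-subject
  estimation of κ, τ.
* Fixed-effects group machinery only (the analysis under replication uses
  fixed-effects BMS/BPA); no random-effects BMS, covariates, or
  multiple-comparison correction across connections.
* The bilinear model's validity region excludes parameter regimes that
  drive inflow to zero; profile distributions are truncated accordingly.
* Finite-difference sensitivities: P+1 forward sweeps per iteration;
  adequate at 5 regions, not designed for much larger networks.
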