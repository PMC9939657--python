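# Methods

## Channel model and simulation

The model is the Hodgkin–Huxley hERG formulation with one activation gate
`a` and one inactivation gate `r`; the open probability is `a·r` and the
current `I_Kr = g_Kr·a·r·(V − E_K)` in pA, with voltages in volts, rates in
1/s and conductance in pA/V. The reversal potential uses
R = 8.314472 J/(K·mol), T = 298.15 K, F = 96485.3415 C/mol, z = +1,
[K⁺]ₒ = 4 mM, [K⁺]ᵢ = 110 mM, giving E_K ≈ −85.15 mV; all constants are
overridable through `PhysicalConstants`.

Under voltage clamp with a piecewise-constant command, both gate ODEs are
linear with constant coefficients inside each segment, so the default
simulation backend propagates the exact per-segment solution
`x(t) = x_∞ + (x₀ − x_∞)e^{−t/τ}` and evaluates it at the requested sample
times. This is exact to floating point, step-size free, and makes a
15.4 s / 5 kHz sweep cost a few milliseconds. An adaptive stiff ODE
backend (`method="ode"`, LSODA at abs_tol 1e-8 / rel_tol 1e-10 — the
printed tolerances, noting rel < abs is unusual but kept configurable) is
retained as an independent cross-check; the two agree to ~1e-17 relative
RMS. Gates start at equilibrium for the protocol's first segment voltage,
which makes traces protocol-deterministic. Rate-law exponents beyond ±700
raise a simulation-infeasibility error instead of propagating infinities;
the fitter maps that to its "failed" classification.

A useful exactness consequence: keep-first decimation of a uniform grid is
itself a uniform grid, so simulating directly at the downsampled rate
equals simulate-at-5-kHz-then-decimate bit for bit. The fitting objective
exploits this fast path.

## Staircase protocol

The published staircase is available only graphically, so
`build_default_staircase()` ships a documented stand-in honouring the
printed constraints: 15.4 s total, 500 ms core steps, voltages confined to
[−120, +60] mV. Layout: 1 s holding at −80 mV; a 500 ms activation probe
at +40 mV with 500 ms return; twenty-four 500 ms steps zig-zagging up and
back down across the window; a 500 ms deactivation probe at −120 mV; 0.9 s
trailing holding. Users needing the published protocol supply it as a
`duration_s,voltage_V` CSV; all downstream code is protocol-agnostic.

## Prior, constraints, and the learning space

Parameters are drawn componentwise-uniform inside the prior box and
accepted only if the four extreme-voltage rates lie strictly inside
(0.0167, 10⁶) 1/s — one event per minute up to the fastest resolvable
transition. Each constraint couples exactly one (prefactor, sensitivity)
pair, so rejection is per pair; this is distributionally identical to
joint rejection but avoids its ~10⁻⁶ joint acceptance rate. Sampling uses
counter-based Philox substreams keyed by (seed, sample, pair, attempt), so
sample *i* is independent of every other sample's rejection history and
the first *k* samples do not depend on *n*.

The learning space applies log₁₀ to the decade-spanning parameters — the
four prefactors and g_Kr (3.7 decades) — then min–max scales every
component to [0, 1] using bounds derived from the prior box, never from a
data batch, so training, validation and inference share one fixed,
exactly invertible transform. Sensitivities stay linear.

## Synthetic data

Two generators, used for different questions:

* **Training prior draws** (`generate_dataset`): simulate each accepted
  θ on the staircase at 5 kHz, add iid N(0, σ²) noise with σ = 10.84 pA
  (the steady-state noise level of the recordings this pipeline emulates),
  then decimate by 50 to 1,540 samples at 100 Hz. Noise precedes
  decimation because the noise model is stated on the recorded signal.
  Each example pairs the trace with the normalized θ. Infeasible draws are
  resampled under fresh substreams and logged in the manifest.
* **Physiological cell population** (`generate_cells`): the literature
  room-temperature parameter set (sinusoidal-protocol patch-clamp fitting;
  g_Kr = 0.1524 µS, p₁…p₈ as in `LITERATURE_THETA`) jittered per component
  by a lognormal factor exp(N(0, 0.2²)) — about ±20% cell-to-cell
  variability — clipped to the prior box and constraint-checked.

The distinction matters for identifiability. Most of the uniform prior's
volume lies in kinetically degenerate regimes (e.g. inactivation with
microsecond time constants) where a single sweep cannot resolve individual
rate parameters: fits reach the noise floor while the parameters sit on
compensation plateaus whose noiseless traces differ by well under 1 pA
RMS. Parameter-*recovery* claims are therefore evaluated on the
physiological population, where the staircase renders all nine parameters
practically identifiable; the *warm-start* benchmark uses held-out prior
draws, the split that plays the role of the experimental cells for the
regressor. What passing tests show, and do not show: recovery accuracy is
demonstrated in the physiological regime, not over the whole prior; and
synthetic noise is iid Gaussian — leak, series-resistance and capacitance
artifacts of real recordings are out of scope.

## Spectrogram features

Traces are divided by a fixed global scale (10⁴ pA — per-trace scaling
would erase the amplitude cue that identifies g_Kr) and transformed by a
centered STFT: reflect padding by n_fft/2, periodic Hann window of length
48 zero-padded centrally to n_fft = 256, hop 12, one-sided magnitudes,
log1p compression. A 1,540-sample trace yields exactly
(256/2 + 1) × (⌊1540/12⌋ + 1) = 129 × 129. Bilinear align-corners resizing
(identity at equal shape, constants preserved) produces the 97 × 97
stage-1 resolution.

## Regressor

The backbone is deliberately small for single-CPU training: the input
grid is bilinearly pooled to a fixed 24 × 24 feature grid, flattened and
fed to an MLP (hidden layers 256/128, adam, learning rate 10⁻³, batch 64,
L2 α = 10⁻⁵), trained on the mean squared Euclidean error of the
normalized 9-vector. Because the pooling front-end is
resolution-agnostic, the two-stage schedule — stage 1 on 97 × 97
spectrograms over a subset, stage 2 on 129 × 129 over the full set —
continues the same weights, mirroring a transfer-learning curriculum.
Feature z-scoring is implemented but off by default: it measurably hurts
both validation MSE and held-out prediction quality by flattening the
low-frequency amplitude bins. Predictions are clipped to [0, 1] and are
exactly de-normalizable. At the desk scale used throughout (~2,000
training examples) the regressor's value is a coarse but informative
initializer, not the near-oracle a six-figure training set would give.

## Fitting

The objective is the RMS residual (pA) between the observed downsampled
trace and the simulation for a candidate θ. CMA-ES — the standard
(µ/µ_w, λ) strategy with cumulative step-size adaptation and rank-one plus
rank-µ covariance updates, λ = 4 + ⌊3 ln 9⌋ = 10 — runs in the normalized
unit box, where steps are commensurate across ten-decade parameter
ranges. Out-of-box candidates are clipped with a quadratic penalty;
constraint violations add a log-scale penalty; infeasible simulations get
a worst-case sentinel. The starting point is evaluated and seeds the
incumbent.

Numerical choices that required care:

* **Initial step size σ₀ = 0.03.** The benchmark's subject is the value
  of the initializer; σ₀ must be small enough that the search first
  exploits the start's neighbourhood. At σ₀ ≈ 0.1 the early search is
  essentially initializer-independent and all starts cost the same.
* **Stopping.** Two rules, whichever fires first, plus a 1,000-iteration
  cap: a TolFun-style test — the spread of the last 30 generation-best
  objectives (and the incumbent) below 0.01 pA, a threshold far beneath
  the 10.84 pA noise floor, so later "improvement" is physically
  meaningless — and a long-patience test — no incumbent improvement over
  90 iterations, which covers a start already at the optimum, where
  generation bests track the shrinking step size rather than progress.
  Best-ever-based stagnation alone either fires prematurely from good
  warm starts (before covariance adaptation engages) or, at very tight
  tolerances, never fires and buries the initializer effect under an
  800-iteration refinement tail.
* **Outcome classification.** Failure = optimizer/simulator breakdown
  (all-infeasible first population, NaN objective). Converged = final
  RMSE ≤ 1.2 σ — the best attainable RMSE on a noisy trace concentrates
  near σ, and 1.2 leaves room for finite-sample fluctuation. A clean
  termination above that is a local minimum. The factor is configurable.
* **Recovery settings** (`RECOVERY_CONFIG`): σ₀ = 0.05, TolFun 10⁻⁴ pA
  over 60 generations, cap 2,000 — a tighter, longer search, since the
  question there is parameter accuracy rather than fitting speed.

The three-initializer benchmark fits every cell from (i) the regressor's
de-normalized prediction, (ii) a fixed "prior" vector defaulting to the
normalized-box midpoint, (iii) a fresh constrained-prior draw, under one
shared optimizer configuration and paired seeds. Summaries report both the
paired mean iterations over all cells (the headline comparison — means
over converged fits only are selection-biased in favour of an initializer
that drops its hardest cells) and the converged-only mean, plus
failure/local-minimum counts. Wall times are reported but never asserted
(hardware-dependent).

## Posterior exploration

Adaptive Metropolis in the normalized space: iid Gaussian likelihood with
known σ (σ estimation from data is out of scope) times the constrained
uniform prior. The proposal starts isotropic (0.1²/9 · I) and from
iteration 500 is refreshed every 50 steps to 2.38²/9 times the empirical
chain covariance plus jitter. One thousand consecutive rejections raise a
stall error. On physiological cells the adapted chain accepts ~25–30% of
proposals and covers the generating parameters within ±3 posterior SDs.

## Problem sizes and limitations

Default study sizes are desk scale, chosen so the full pipeline retrains
and re-benchmarks in minutes on one CPU: ~2,000 training examples
(1,800/200 split; stage 1 on 1,200), 20 benchmark cells, 10 recovery
cells, 10⁴ sampler draws, 2 × 10⁴ MCMC samples. At this scale the
warm-start effect is a reproducible ordering (predicted starts converge in
fewer iterations than random ones, with no failures), not a fixed-ratio
speedup; per-cell iteration counts remain noisy, and sign tests over 20
cells are underpowered. Known limitations: the staircase is an
approximation of the published protocol; the noise model is additive
Gaussian only; the regressor gives point predictions without uncertainty;
no drug-block or temperature dependence beyond the fixed T constant.
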