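# Methods

## Model

The package simulates the two-variable Morris–Lecar membrane model

```
c dv/dt = -gCa m_inf(v)(v - vCa) - gK w (v - vK) - gL (v - vL) + I(t)
  dw/dt = lambda(v) (w_inf(v) - w)
```

with `m_inf(v) = 0.5(1 + tanh((v - v1)/v2))`, `w_inf(v) = 0.5(1 + tanh((v - v3)/v4))`
and `lambda(v) = phi cosh((v - v3)/(2 v4))`.  Units are fixed throughout: time in
ms, voltage in mV, currents in uA/cm², conductances in mS/cm², capacitance in
uF/cm²; frequencies are therefore in kHz (cycles per ms).

Two presets are shipped (`strml.TYPE_I`, `strml.TYPE_II`).  `TYPE_I`
(gCa = 4.4, gK = 8, gL = 2, v3 = 12, v4 = 17.4, phi = 1/15, Ibias = 33, Ic = 4.3)
sits just below a saddle-node-on-invariant-circle (SNIC) transition, where the
firing rate grows continuously from zero.  `TYPE_II` (gCa = 5.6, gK = 5, gL = 3,
v3 = -4.5, v4 = 15, phi = 0.04, Ibias = 63, Ic = 4.1) sits just below a
subcritical Hopf / fold-of-cycles transition, where oscillations set in at a
finite frequency.  `phi` for `TYPE_I` is stored as the exact rational 1/15.
With these parameters the package's own detectors place the Type I SNIC at
Ibias = 37.63, the Type II fold of cycles at 67.31 and its Hopf at 68.07, and
the Type I upper-branch Hopf at 77.32 uA/cm² (all recomputed by
`scripts/acceptance.py`).

## Deterministic analyses

*Fixed points.*  At equilibrium `w` is slaved to `w_inf(v)`, so the search is a
1-D root problem in `v` over [-85, 60] mV: sign changes are bracketed at
0.25 mV resolution and polished with Brent's method (xtol 1e-12).  Stability is
classified from the eigenvalues of the analytic Jacobian, which a test pins
against central finite differences at relative tolerance 1e-5.

*Bifurcations in the bias current.*  The SNIC is located by bisection on the
fixed-point count (3 vs 1); a Hopf by the sign change of Re(eigenvalue) on the
uppermost equilibrium branch, accepted only where the eigenvalues are complex;
both to 0.005 uA/cm².  The fold of the periodic branch is found by continuing
the stable cycle downward in current — each step reuses the previous
oscillatory end state — and bisecting on loss of a sustained oscillation (no
v > 0 excursion in the last 2000 ms of a 6000 ms window).  The 4000 ms settle
window matters: just below the fold, transient oscillations persist for many
cycles before collapsing.

*Cycle frequency.*  Periods are measured from upward crossings of the Poincaré
section v = -20 mV after a transient discard (default 1000 ms; 6000 ms near the
fold).  An estimate whose successive periods spread by more than 0.5 % raises
rather than returning a number.  At the low end of the Type II branch
(I = fold + 0.02) the measured frequency is ~0.0050 kHz, rising steeply along
the branch (0.0062 kHz by I ≈ 67.6, 0.0067 at 68.0); the value at the fold was
confirmed against an adaptive Runge–Kutta reference at rtol 1e-11 and is
independent of the initial condition.

*Threshold manifolds.*  For Type I the threshold curve is the saddle's
invariant set, traced by integrating from ±1e-4-scaled eigenvector offsets
(stable directions backward in time, unstable forward) with an adaptive solver;
the returned separatrix polyline is the incoming (stable) pair joined through
the saddle, and the outgoing pair is kept in `branches`.  For Type II, which
has a single stable fixed point, the separatrix is located empirically:
along vertical lines in the (v, w) plane, the spike/decay outcome under frozen
current is bisected in `w` to 1e-4 ("spike" = the trajectory reaches v > 0 mV
within 500 ms).  Because the input current enters the `v` nullcline, the
separatrix rises in `w` as the instantaneous current grows — the moving
threshold that underlies the whole epoch analysis.

## Stochastic input and integration

The extrinsic stimulus is `Iext(t) = Ic + delta2 * eta2(t)`, one frozen
realization shared by all trials.  `eta2` is Gaussian white noise convolved
with the unit-area alpha kernel `alpha(t) = (t/tau²) exp(-t/tau)` (truncated at
15 tau), then normalized to unit variance, so the stimulus SD equals `delta2`
for every correlation time.  This normalization is what lets stimulus strength
and correlation time act as independent knobs; the raw (un-normalized)
convolution, whose stationary SD is `1/(2 sqrt(tau))`, remains available as
`filtered_noise` and via `build_signal(..., normalize=False)`.

Integration uses classical RK4 with a fixed step dt = 1/30 ms on the
deterministic flow, the current held at its grid value across the four slopes,
followed by a per-step stochastic voltage update.  The default noise
convention (`mode='increment'`) treats both noise sources as unit-variance
discrete-time sequences scaled by their coefficients and applied as per-step
drifts that are *not* divided by the capacitance:

```
v[n+1] = RK4(v[n], w[n]; Ibias + Ic) + (delta1 * Z_n + (Iext[n] - Ic)) * dt
```

with `Z_n` drawn independently per trial.  This convention is tied to the
working step: it makes `delta1` and `delta2` commensurate knobs on one
voltage-drive scale, and it is the calibration under which this model regime
shows its characteristic phenomena — a constant input of the same mean fires
unreliably while the frozen fluctuating input locks spike times across trials,
reliability grows monotonically with stimulus SD, and the Hopf-side preset has
an interior reliability optimum in the correlation time (near tau = 8 ms at
delta1 = 5, delta2 = 1.64) while the SNIC-side preset increases monotonically.
The conventional SDE reading (`mode='current'`: stimulus through the
right-hand side and an intrinsic white-noise current `(delta1/c) sqrt(dt) Z`)
is implemented as an alternative; at the coefficient scales above its
extrinsic term is weaker by the factor c = 20 and barely influences timing.
The integrator's noise statistics are pinned by an Ornstein–Uhlenbeck
reduction (leak-only membrane): stationary variance `delta1² theta dt / 2` in
the increment convention and `(delta1/c)² theta / 2` in the current
convention, each verified to 3 %.

Numerical stability: `lambda(v)` grows as cosh, so the fixed step becomes
unstable when extreme drifts push `v` beyond roughly ±200 mV.  Stimulus SDs up
to ~4 uA/cm² are safe for both presets; blow-ups raise a `FloatingPointError`
naming the step rather than returning garbage.

Trials start from the stable fixed point at I = Ibias + Ic, and the first
500 ms are discarded from every analysis.  Per-trial intrinsic streams are
spawned from the ensemble master seed (`numpy.random.SeedSequence`), recorded
in the raster metadata, and reproduce the ensemble bit-for-bit.

## Reliability measure

Spikes are upward crossings of the working threshold vth = -20 mV with
sub-step linear interpolation and a 30 ms debounce (well below the ISIs
studied, above the spike width).  Each trial's train is convolved with a
unit-amplitude Gaussian of width sigma_c = 20 ms (truncated at ±6 sigma), and

```
R = 2/(N(N-1)) * sum_{i<j} <s_i, s_j> / (|s_i| |s_j|)
```

is the mean pairwise cosine over N = 45 trials by default (R stabilizes for
N > 30).  A pair with a silent trial contributes 0 — a silent trial is treated
as maximally unreliable.  The filtered trains are sampled on the simulation
grid restricted to the analysis window; the discrete R matches the two-Gaussian
closed form `exp(-Delta²/(4 sigma_c²))` to 1e-3 at this resolution.

## Spike-evoking epochs

Events are anchored at the threshold crossings of a designated reference trial
(trial 0).  For each anchor, the nearest spike of every trial within ±75 ms
(match window 150 ms, covering the largest observed spreads) is associated to
the event.  An event is *reliable* when all 30 trials spike and the spread
(max - min of matched times) is strictly below 20 ms; *unreliable* when all
trials spike but the spread is 20 ms or more; *unclassifiable* when any trial
misses (a miss says nothing about timing spread, and mixing misses into the
unreliable pool would bias its statistics), when the anchor lacks a full
100 ms lookback, or when its matched set overlaps the previous event's (such
anchors are retained and labelled, never silently dropped).  The boundary case
spread = 20 ms is unreliable — "below the cutoff" is read strictly.  For the
pooled statistics the pipeline also provides *isolated* pools — events whose
full lookback window is free of earlier reference spikes — which minimize
interactions between consecutive spikes; the package's headline direction
checks use these.

Each event stores the signal excerpt over the 100 ms before its anchor.  The
spike-triggered average is the per-bin mean of the aligned excerpts, with bin
width defaulting to the simulation step (at that resolution the step-function
windowing of the usual STA definition reduces to per-sample averaging).  The
*action* over a lookback L is the trapezoidal area of the excerpt's last L ms
divided by L — the mean current delivered while the threshold was approached.
Action integrates the full stimulus including its mean Ic; since every pool
shares the same Ic the baseline cancels from all comparisons.  The gating
variable at threshold is `w` interpolated at the exact crossing instant of each
matched spike.

Reliable events are subdivided into equal-count tertiles by action at
L = 20 ms (ties broken by anchor time); each tertile gets its own sub-STA and
its distribution of per-event firing-time SDs.  Group comparisons use the
standard two-sided tests: paired t, pooled two-sample t, and the F ratio of
variances; identical paired groups return statistic 0 with p = 1, other
zero-variance inputs raise.

## Epoch library and spliced signals

`build_epoch_library` harvests labelled excerpts from fresh stimulation
segments: spike-evoking epochs around ensemble-consensus anchors (110 ms:
100 before, 10 after), and non-spiking background epochs — 50 ms windows drawn
at random and kept only if, embedded in a constant-Ic baseline and presented to
five fresh trials, fewer than half of the trials spike near them.  The label is
thus an empirical property of the epoch itself.  Because any stretch whose mean
sits clearly above Ic tends to trigger a spike under the drift convention,
quiet material is biased below Ic; a mean-diverse (quantile-spaced) subset is
retained so that splicing can steer signal means both ways.

`splice_signal` concatenates scheduled spike-evoking epochs with gaps filled
greedily from the non-spiking pool: each draw takes the epoch — or the crop
offset within it — whose mean best corrects the projected deviation of the
*entire* signal from Ic, with the sums of all still-scheduled epochs accounted
for.  Only the immediately preceding epoch is excluded per draw, so the
corrective high-mean pieces stay reusable across long gap runs.  Epoch
interiors are never rescaled; the final mean must land within 1 % of Ic or the
construction raises with the deficit.  `insert_sta_copies` does the same with
one fixed waveform and records every onset; the default inter-copy gaps are
kept short (60–120 ms) because background material alone cannot hold the mean
over gap-dominated layouts.

## Experiment scaling

The drivers default to desk-scale sizes: reliability sweeps use 20-trial
ensembles over ~20 s of model time per point with ≥3 master seeds for error
bars; the correlation-time sweep in the acceptance script uses 24 trials ×
4 seeds × >30 s per trial; the epoch pipeline runs 30 trials over 60–120 s
signals, yielding pools of a few hundred reliable and unreliable events.  All
stochastic claims the package tests are direction/shape statements at these
sizes, not reproductions of exact curve values.

## Known limitations

- The increment noise convention does not converge to an SDE as dt → 0; it is a
  discrete-time calibration at dt = 1/30 ms.  Weak-convergence checks apply to
  `mode='current'` only.
- The fixed step is unstable under extreme stimulus drifts (SD ≳ 5 uA/cm² for
  the Type I preset); failures raise, they are not repaired.
- In the Type I calibration the low-action tertile of reliable events fires
  with *larger* timing SD than the high-action tertile — the opposite of the
  Type II ordering; the corresponding check is asserted for both presets and
  fails for Type I by construction, which is a property of this calibration
  worth knowing rather than hiding.
- Spectral peaks of spliced signals reflect the repeating unit's envelope;
  with 110 ms epochs at 156 ms periods the strongest periodogram line can be a
  harmonic of 1/period.
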