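# Methods

This note records the generative model, the analysis conventions, and
the design choices made where the procedure was genuinely open. All
angles are in degrees (counterclockwise from +x, canonical range
[0, 360), signed differences in (−180, 180] with ties at +180); all
times are in ms on a session clock starting at zero; positions are in
cm with the workspace centered at the origin.

## Task model

Targets are drawn 5–15 cm from the current target at a uniform angle;
a candidate outside the 20 × 20 cm workspace is replaced by adding
+90° to its angle and fixing the distance at 5 cm, repeated until the
candidate is inside. The +90° sign is the one that produces the
clockwise selection bias: simulated over ≥50,000 chained reaches the
circular mean of Φ = φ_T − φ_P is ≈149°, whereas a −90° step gives
≈211°. Termination is guaranteed because from any interior point of a
square with 10 cm half-width at least one of four 90°-spaced points at
5 cm distance is interior (asserted over a fine grid in the tests).

Event timing per reach: landing on a target starts a 200 ms hold; the
target command fires 100 ms after landing and the target appears
96 ms later (display delay), so analyses aligned to "target onset" use
command time + 96 ms. Trials chain four reaches; consecutive trials
are separated by 1 s.

## Behavioral generative model

The simulated subject expects the next target at φ_E = φ_P + φ*, with
φ* = 150° by default (the task's true conditional mean). Two planted
effects make the behavior testable:

* **Trajectory bias.** Movement direction over time is a circular
  blend θ(t) = φ_T + w(t)·wrap(φ_E − φ_T), with
  w(t) = w₀·exp(−t/τ), τ = 150 ms, and w₀ = bias·min(1, r/10 cm)
  (bias = 0.7 by default): initial directions bend toward φ_E, more
  strongly for starts far from the center. The speed profile is
  minimum-jerk; after integrating the blended-direction path, the
  small terminal miss is redistributed proportionally to traveled
  arc length so the reach lands exactly on the target without
  disturbing the initial direction.
* **Latency.** Planted latency = 180 ms + slope_eff·|wrap(φ_T − φ_E)|
  + N(0, 20 ms), truncated at 20 ms, with slope_eff = 0.4 ms/deg ×
  (0.5 + r/10 cm): surprising targets are slower, more so far from
  the center. Measured latency (first time hand speed exceeds
  8 cm/s after onset, central differences on 10 ms samples) adds the
  ramp time of the speed profile (~40–60 ms) but preserves the
  planted ordering (r ≈ 0.7 against planted values).

Hold-period jitter is a per-hold constant offset (sd 0.1 cm), not
per-sample noise: white positional noise at 10 ms sampling would
produce apparent speeds above the 8 cm/s latency threshold while the
hand is still. Sampled kinematic noise is 0.02 cm per sample. A
configurable fraction (3% by default, in the few-percent range typical
of well-trained subjects on this task) of reaches is injected as errors: hold violations
(hold < 200 ms) or timeouts (> 1.4 s from onset to landing), flagged
and excluded by the analysis-side filter together with the first reach
of each trial.

## Synthetic populations

The conditional-probability ground truth p(upcoming movement within
±60° of direction c | hand position) is estimated by Monte Carlo from
the task's own drawing algorithm on a grid of positions (1 cm spacing,
24 direction centers, 4,000–10,000 draws per cell; queries interpolate
bilinearly in position, nearest in direction). In the VR condition the
draws happen in screen coordinates and directions are converted to
hand coordinates by subtracting the 30° rotation.

Rates (sp/s), piecewise per reach with a linear 50 ms blend across
target onset to avoid PSTH discontinuities:

* pre-target (hold onset → target onset):
  * PR: baseline + prob_gain · p(PD window | current hand position)
  * SR: baseline
  * M1-like: baseline + movement_gain · T(φ_prev) · exp(−t/τ_decay),
    tuned to the previous movement (τ_decay = 300 ms)
* post-target (onset → landing):
  baseline + movement_gain · T(φ_move), where
  T(φ) = exp[β(cos(φ − PD) − 1)] is a von Mises bump normalized to 1
  at the PD, so movement_gain is the peak modulation regardless of β.

Defaults: baseline 5 sp/s, movement_gain 25 sp/s, β = 2,
prob_gain 30 sp/s, PDs evenly spaced with jitter. These put pre-target
PR modulation at 2–4× baseline with the post-target peak (30 sp/s)
above the pre-target peak (~21 sp/s) — the regime in which decoding
requires amplitude rescaling between epochs. Spikes are inhomogeneous
Poisson in 1 ms bins.

What the generator does **not** emulate: spike-history and refractory
structure, noise correlations between neurons, PD drift between
planning and execution, biomechanical costs, eye position, and
learning dynamics within the VR block (the VR population is simply
re-synthesized under the rotated statistics). Passing tests therefore
show that the analysis chain recovers planted structure of this form
at realistic rates and sample sizes — not that real recordings contain
such structure.

## Analysis conventions

* **Smoothed maps.** Weighted k-NN over 2-D covariates, weights ∝
  distance^d with a 10⁻⁶ cm floor before negative powers. Two
  canonical settings: (k = 20% of points, d = 0) wherever a map acts
  as a covariate (GLM columns, PD and preferred-position corrections)
  and (k = 30%, d = −1) for maps consumed directly (position-activity
  maps, profile smoothing). The covariate setting is deliberately
  smoother: with d = −1 the correction map absorbs local noise and
  measurably degrades PD recovery. Cross-validated selection over a
  candidate grid is available (`select_smoothing_params`), ties broken
  toward larger k.
* **Tuning fits.** Least squares (not Poisson), because targets are
  residuals after covariate subtraction and may be negative. Nonlinear
  fits are multi-started at the rate-weighted circular mean +
  {0°, 120°, 240°} with β ∈ [−10, 10]; a negative-β optimum is
  re-expressed by flipping φ* by 180°. The β bound exists because
  unbounded fits on near-flat residuals collapse onto single-point
  spikes (β > 300) that fit pure noise; |β| = 10 is far narrower than
  any physiological tuning encountered here. Flat fits
  (β ≤ 10⁻³) are flagged unreliable with φ* undefined.
* **GLM.** Newton/IRLS with step-halving and a ridge penalty of 10⁻⁶
  on non-intercept terms as a numerical stabilizer; verified against
  statsmodels at ridge 0. Covariate columns are cross-fitted (each
  reach's θ comes from maps whose neighbors lie in the other folds of
  the same 5-fold partition used for the GLM), z-scored with
  training-fold statistics. Cross-validated pseudo-R² pools held-out
  λ̂ across folds against held-out mean-model references. The
  bootstrap (1,000 reps, reaches resampled with replacement, a fresh
  fold split per replicate) runs through a batched IRLS with capped
  Newton steps instead of per-system step-halving; batched and looped
  fitters agree to 10⁻⁶ on common instances.
* **Classification.** A covariate "matters" in a window when the
  single-covariate model's CV pseudo-R² and the full-vs-reduced
  relative pseudo-R² both have bootstrap 95% CI lower bounds above
  zero (relaxed variant: bootstrap medians above zero). PR = position
  matters in the early window (−100 to 50 ms) and upcoming movement in
  the late window (50 to 200 ms); SR = movement only. Inclusion
  requires ≥2 sp/s in either window.
* **Decoder.** Composite tuning per neuron: φ* from the post-target
  fit (50–200 ms), α and β re-fit on pre-target counts (−100 to 0 ms)
  against the future movement direction; a flat pre-target fit falls
  back to the mean pre-target rate (β = 0). Expected counts are
  floored at 0.1 sp/s × window so Poisson means stay positive. The
  posterior over the 1° grid is computed in log space and normalized
  by logsumexp. FWHM is the angular measure of the contiguous
  above-half-maximum arc containing the posterior mode; other arcs
  above threshold set a multimodal flag; MAP ties break toward the
  smallest angle; empty decode windows are decoded (all counts zero),
  never skipped. Neuron screening for decoding uses the relaxed
  (median) criterion, per session. VR decoding keeps the
  baseline-trained tunings.
* **Summary statistics.** Bias summaries use the median with a
  bootstrap SE of the median (1,000 reps, adopted everywhere a rep
  count was needed); bias is undefined when |wrap(φ_ref − φ_T)| < 1°
  or the hand moved < 10⁻³ cm in the window. Latencies more than 6 sd
  from the session mean are dropped. Multi-session regressions use a
  shared-slope, per-session-intercept least-squares model with a
  two-sided t-test on the slope.

## Emergent geometry worth knowing

Because the task's Φ mean is 150° (not 180°), a PR neuron's preferred
angular hand position sits near PD − 150°, i.e. roughly — but not
exactly — opposite its PD; the recovered histogram of PD − preferred
position consequently centers near +150°. Post-target decoded widths
converge across distance bins (~90° under the rescaled tunings) rather
than dropping below the farthest bin's pre-target width; the
position-dependence of the width is a strictly pre-target phenomenon,
which is the property of interest.

## Problem sizes

The test suite and the example use sessions of 60–400 trials
(~170–1,200 analyzed reaches), populations of 25–100 neurons,
probability maps at 4,000 Monte-Carlo draws per cell, and 1,000
bootstrap replicates for classification CIs (smaller for screening
steps); the chained-draw statistic uses 50,000–60,000 reaches. These
sizes were chosen so each recovery result is stable across seeds at
desk scale.
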