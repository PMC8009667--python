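# Methods

`pursuitlearn` re-implements, as a tested simulation-plus-analysis pipeline,
the behavioural analysis chain of smooth-pursuit direction-change adaptation
experiments in which learning can be acquired *passively* — by watching a
covert target change direction during fixation, without tracking it.  No
primate data accompany the original experiments, so the package pairs the
analysis chain with a synthetic eye-trace generator whose ground truth is an
explicit learning law; the acceptance surface is parameter recovery of that
law through the full chain.

## Task model

A trial presents a target that, after 1 s of fixation, moves at 20 °/s in a
*base* direction; on learning trials an orthogonal 20 °/s component in the
*learned* direction is added 250 ms after motion onset.  Motion ends at
650 ms and the target holds still for 500 ms.  Blocks contain 100 trials:

* **motor** — 100 eye-movement learning trials;
* **washout** — 50 eye-movement + 50 fixation trials, randomly interleaved,
  all step-ramp (4° eccentric step, 20 °/s ramp back through the centre,
  crossing it at 200 ms) with no direction change;
* **fixation-style blocks** (congruent/incongruent, motion/position,
  reward-cued, fixation-only) — 90 fixation + 10 eye-movement probe trials,
  exactly one probe at a uniformly random position in each consecutive group
  of ten; reward-cued blocks split the 90 fixation trials 45/45 between
  congruent and incongruent flavours;
* **small-angle / no-angle** — all eye-movement blocks whose 90 main trials
  carry a 0.5 °/s (or zero) learned component, probed by 10 full-change
  trials.

Sessions interleave learning blocks with washout blocks (the washout
*precedes* its learning block by default; this pairing defines each block's
"corresponding washout").  The alternating-direction paradigm (two
fixation-only block types with learned directions 180° apart) has no
washouts; the multi-direction paradigm draws (base, learned) combinations
pseudorandomly so that all eight are used once before any repeats, with each
washout sharing its successor's geometry.

Coordinates are screen-centred degrees, angles counter-clockwise from
rightward = 0°; time is sampled at 1 ms with sample 0 at motion onset and the
pre-motion second carried as negative time.  Failed-trial repetition and the
reward-delivery hardware are not modelled: they shape animal training, not
the analysis chain.

## Generative model

The predictive learned velocity expressed on a trial is

g(T) = A1·(1 − e^(−T/τ1)) + A2·(1 − e^(−T/τ2)) + c,

with T an *effective exposure* count threaded through the session:

| event | update |
|---|---|
| eye-movement trial with the full 20 °/s change | T ← T + 1 |
| congruent fixation trial | T ← T + w_passive |
| … with unrewarded cue | × w_reward_unrewarded |
| … with vanish window (position blocks) | × w_position |
| no-change or 0.5 °/s small-angle trial | no change |
| any washout-block trial | T ← T · washout_decay |

Exposure is kept per (base, learned) direction context, so the
alternating-direction and multi-direction paradigms accumulate independent
counts per geometry; cross-direction interference is not modelled.
Small-angle trials are deliberately non-instructive: empirically the
small-angle/no-angle contrast is null, so the generator treats only the full
orthogonal change as the instructive signal.

Defaults (all configurable in `SimConfig`): A1 = 2 °/s, A2 = 1 °/s,
τ2 = 30 trials, c = 0; τ1 = 0.04 trials in the single-direction
(`HOMOGENEOUS_PRESET`) and 1.2 trials in the multi-direction
(`RICH_PRESET`) preset — the two fast constants are the quantities the
recovery studies target.  w_passive = 0.33 sits at the midpoint of the
empirical 18–48 % passive/motor bound; w_reward_unrewarded = 0.5 and
w_position = 0.4 are free parameters that only order the reward and
motion/position contrasts correctly.

`washout_decay` defaults to 0.8 per trial.  The value is dictated by an
interaction between the fast learning component and the baseline
convention: the washout baseline averages the *last 25 eye-movement trials*
of the block (roughly its second half), and with τ1 a small fraction of a
trial any residual exposure above ~0.1 saturates the fast component.  A
slower decay (e.g. 0.9/trial) leaves T ≈ 0.2 at mid-block, so baselines
would inherit a 1–2 °/s learned residue from the preceding block and the
motor/fixation ordering would depend on block order.  0.8 drives T below
0.01 before the baseline window opens, matching the requirement that eye
velocity in the learned direction be close to zero at washout end.

## Trace synthesis

Eye-movement trials: eye velocity is the target velocity passed through a
first-order lag (time constant 40 ms, gain 0.95) delayed by the 100 ms
pursuit reaction time.  The predictive component rises linearly from 100 ms
before the change, holds through motion end, and is scaled so that its mean
over the closed 200–300 ms window equals g exactly — downstream response
metrics are therefore exact by construction in the noise-free limit.
Catch-up saccades are raised-cosine velocity pulses (30 ms) whose
displacement cancels the current position error; a saccade is programmed
when the position error predicted one reaction time ahead exceeds 1.5°,
using the error state one reaction time in the past (sensory delay), and is
cancelled if the prediction no longer holds at execution time.  The
cancellation is what keeps step-ramp trials saccade-free: the initial 4°
step error resolves itself before the saccade would land.  Any injected
pulse correcting ≥ 1.5° peaks above 100 °/s and 10 000 °/s², comfortably
above the detection thresholds.

Fixation trials: the eye stays at the fixation point apart from residual
Gaussian velocity bumps (SD 50 ms) centred one reaction time after the
change — a base-direction bump on every fixation trial and a smaller
learned-direction bump only when the change is actually visible (congruent,
non-vanishing trials).  Bump amplitudes are gamma-distributed
(mean 1, SD 0.5) so base velocity varies across trials; no coupling from
residual velocity to learning is generated, which is what the
regression/tercile null analyses test.  White position noise (SD 0.03°,
1 kHz) on both channels yields, after differentiation and filtering, a
per-trial learned-response noise of ≈ 0.3 °/s — the response-noise level
used in the recovery studies.

Traces are position-only; each trial's random stream derives from
(seed, block index, trial index), so traces are bit-identical whether or not
other trials are materialised.  Blinks, microsaccades, and an ocular plant
are out of scope.

## Analysis chain

Positions are smoothed with a unit-sum Gaussian kernel (σ = 5 ms, truncated
at ±4σ, edge-renormalised) and centrally differentiated for velocity and
acceleration.  A sample is saccadic when the acceleration magnitude exceeds
1000 °/s², or speed exceeds 15 °/s during fixation phases, or 50 °/s while
the target moves ([0, 650] ms — the rule keys on target motion, not trial
kind, so it applies on fixation trials too).  Contiguous saccadic samples
merge; gaps under 10 ms merge; intervals are padded by ±5 ms (padding and
merge gap are configuration knobs; the originals were verified by eye).
Saccadic samples become missing data — no interpolation.  Aligned trials are
averaged over valid samples only (SEM where ≥ 2 valid), and averaged traces
are smoothed with a 21 ms centred moving average that shrinks at edges and
skips missing samples.

The *washout baseline* is the missing-aware average of the learned-direction
velocity of the last 25 eye-movement trials of the corresponding washout
block, computed *without* the display moving average so that subtracting the
baseline from its own trials cancels exactly.  *Learned velocity* projects
the two-channel velocity onto the learned-direction unit vector (positive =
toward the learned direction, which is the sign adjustment) and subtracts
the baseline sample-wise; the alternating-direction paradigm uses a zero
baseline, since learning there is assessed by the left/right contrast.  The
*learned response* is the mean over valid samples in the closed
[200, 300] ms window (101 samples; the window is the 100 ms around the
change), NaN when fully saccadic.

Block-type ratios divide each mean learned response by the motor-block mean
(trials pooled by default; per-subject averaging first is available).  The
passive-learning bound pair is the fixation-congruent ratio (upper) and the
fixation-only ratio (lower).  Comparisons: Friedman across matched
motor/fixation/washout triples with Bonferroni-corrected signed-rank
post-hocs; paired signed-rank for adjacent-block designs; rank-sum for
unpaired contrasts; OLS of learned response on subject (categorical) and
mean fixation base velocity; and terciles of fixation base velocity at the
33.3/66.7 empirical percentiles.  All p-values two-sided.

## Learning-curve fitting

The double-exponential model is fitted by nonlinear least squares with
A1, A2 ≥ 0 and τ ∈ [10⁻³, 10³] trials: every ordered pair from an 8-point
log-spaced τ grid is scored with (A1, A2, c) solved by bounded linear least
squares, the best three starts are polished by trust-region least squares,
and components are relabelled so τ1 ≤ τ2.  When one amplitude vanishes the
active component is reported in the first slot with A2 at its zero bound.

A fast constant well below one trial is only *set-identified* at integer
trial spacing: every τ1 small enough to saturate within the first trial fits
identically.  After optimisation the SSE is profiled over τ1 (amplitudes
re-solved, τ2 fixed); when the Δχ² ≤ 1 flat set spans more than two decades
the reported τ1 is the geometric midpoint of that set (accepted only if its
SSE is no worse than the best grid start), and the set is returned as
`tau1_interval`.  This makes the reported value a deterministic, centred
representative of the equivalence class instead of an arbitrary point of a
flat valley; for identifiable constants the flat set is narrow and the rule
never engages.

`fraction_fast` is the ratio of the summed fast-component learning over
T = 0..n−1 to the summed total learning (baseline excluded); a `final` mode
ratios the component values at T = n−1 instead.

## Recovery studies and problem sizes

The recovery studies generate responses at the response level (learning law
plus Gaussian response noise, SD 0.3 °/s — the level the full trace chain
produces), average 50 (homogeneous) or 32 (rich, four per direction
combination) motor blocks by trial index, and fit.  The slow constant and
asymptote are recovered per seed (±30 % and ±10 %); the sub-trial fast
constant is set-identified, so factor-of-3 recovery is assessed on the
profile-centred estimate.  Full-chain checks use scaled-down sessions —
three learning blocks (one per type) per replicate for the ordering
property, three congruent/incongruent block pairs per replicate for the
passive ablation — sizes at which the contrasts are already decisively
powered.

## Known limitations

* The exposure law is descriptive, not mechanistic; washout is passive decay
  rather than error-driven extinction, and opposite-direction learning does
  not interfere.
* The trace generator produces no blinks, drift, tremor, or microsaccades,
  and pursuit gain is stationary within a session; passing tests therefore
  certify the analysis chain, not robustness to every artefact of real
  recordings.
* The predictive-component ramp shape is a convention; only its
  analysis-window mean is a contract.
* Sub-trial fast time constants remain unidentifiable from trial-indexed
  data; the profile interval should always be consulted alongside the point
  estimate.
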