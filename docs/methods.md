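# Methods

## The task being emulated

Four groups of simulated participants (default 15 per group) make
simultaneous 10 cm bimanual reaches to targets directly forward (90°) or
backward (270°) of two home positions, with both hands always moving in the
same direction. The block schedule is: visual baseline **VBL** (30 trials,
cursors for both hands), kinesthetic baseline **KBL** (30 trials, left cursor
removed), exposure **EXP** (250 trials, right hand perturbed by group), and
washout **POST** (50 trials, perturbations off). Perturbations: a 45°
clockwise rotation of the right cursor about home (visuomotor group), a curl
force field F = g·S·v with g = 20 N·s/m and S the 90° clockwise map
(dynamic group), both (combined), or none (control). The left hand receives a
force channel on 20% of its trials in every block: spring walls of
2000 N/m (20 N/cm) beginning 0.125 mm either side of the home→target line,
with 5 N·s/m lateral viscous damping acting between and beyond the walls. The
channel gains ramp up over 1.5 s while the hand rests at home, so the ramp
factor is 1 throughout the movement proper. Movement durations are drawn from
a clipped normal (375 ± 40 ms, clipped to 250–550 ms) so most trials fall in
the rewarded 300–450 ms window; each trial is classified short/ideal/long
against that window.

All internal units are SI; angles and lateral displacements are
counterclockwise-positive everywhere, which makes deviations into the first
and third quadrants negative for the 90°/270° targets. (In the rotation's own
clockwise-positive convention, the fully compensating right-hand aim offset
is −45°; in the package's convention it is +45°.)

## Hand model

Each hand is a 1 kg point mass driven by a PD controller
(kp = 800 N/m, kd = 40 N·s/m) tracking a minimum-jerk reference
s(τ) = 10τ³ − 15τ⁴ + 6τ⁵ aimed along the target direction plus an aim
deviation. These gains give a well-damped tracking bandwidth (~28 rad/s,
ζ ≈ 0.7) so unperturbed movements are straight, land on target and complete
within the timing window; the controller is deliberately generic — the
simulation constrains timing and geometry, not the control law. Integration
is semi-implicit Euler at 1 kHz with a settle margin of 300 ms after the
reference ends so every trial reaches rest; recorded samples are decimated to
200 Hz by default (configurable). Recorded per-sample forces (fx, fy) are the
*environment* forces on the hand (curl field or channel wall) plus sensor
noise; the participant's own compensation forces act on the dynamics but are
not part of the force-sensor signal.

## Adaptation and interlimb crosstalk

Each perturbation modality has a single-rate state-space learner
x' = a·x + b·(applied − x), updated on every trial (so baselines leave the
state at zero and washout decays it, producing aftereffects that shrink over
POST). Defaults: rotation a = 0.99, b = 0.10; curl a = 0.99, b = 0.08. These
give ~90% asymptotic compensation well before the end of the 250-trial
exposure and visible washout within 30 post-exposure trials. The right hand
aims at target + rotation estimate and applies a feedforward force
−(dyn estimate)·g·S·v opposing the expected field; after the field is
removed, the residual compensation is what produces the curl aftereffect.

Interference is modelled as a counterclockwise left-hand aim bias leaked from
the right hand's adaptation states:

bias = κ_rot · x_rot + κ_dyn · x_dyn · s_dyn

with κ_rot = 0.15, κ_dyn = 0.06 and s_dyn = 45° (the degree-equivalent of a
fully compensated field). At full adaptation these defaults put the group
means near 0° (control), 2.4° (dynamic), 6.75° (visuomotor) and 9.1°
(combined) — interference that grows over exposure, is counterclockwise, and
orders control < dynamic < visuomotor ≤ combined. The gains were fixed once
as part of the generator's definition; they are the quantity a real
experiment estimates, not a free dial.

Noise: per-trial aim noise (SD 1.5° with vision, 2.5° without), endpoint
noise scaling with the reference (SD 2 mm / 4 mm), and white force-sensor
noise (SD 0.05 N). Removing the left cursor from KBL onward is modelled
purely as this noise increase.

## Kinematic measures

Movement onset is the first sample whose tangential speed exceeds 5% of the
trial's peak and stays above it for 50 ms, then backtracked to the preceding
near-rest sample (0.5% of peak); offset is the last supra-threshold sample,
extended forward the same way. The backtracking step places the onset at the
true start of motion rather than at the threshold crossing (about 20 ms
early on a 400 ms minimum-jerk profile) and is the package's deterministic
replacement for interactive event checking. Peak velocity is the argmax of
speed in [onset, offset] (earliest on ties); the ballistic end is the first
post-peak strict local minimum of speed or the first sample at ≤1% of peak
speed (sampled data rarely hits exact zero), falling back to the offset.

IDE is the signed angle between home→position and home→target at peak
velocity — evaluated on the *cursor* (rotated frame) for the right hand while
the rotation is on, on the hand otherwise. IEE is the same angle at the
ballistic end, always in hand coordinates; FEE is the signed lateral
displacement (cm) of the hand from the target line at offset. RMSE is the RMS
perpendicular deviation from the straight target vector over [onset, offset]
divided by the movement length; the denominator is the traversed path length
by default ("the length of the movement actually made"), with a
straight-line-distance option. Baseline correction subtracts each
participant/hand's baseline-block mean (KBL for the left hand, VBL for the
right) from every trial, so corrected baseline means are exactly zero.
Channel trials are flagged and excluded from kinematic analyses, since the
channel suppresses exactly the lateral deviations the measures quantify.

## Kinetic measures

Channel-trial wall forces are projected on the counterclockwise perpendicular
of the target line (sign-flipped so they represent the hand's push against
the wall), resampled to 1000 points of normalized movement time, and read at
three landmarks: the average relative time of peak velocity and of the
ballistic end — estimated from the same hand's non-channel exposure trials,
where those events are well defined — and movement end (fraction 1.0).
Landmark forces are computed per trial and then averaged (a config-free
choice; averaging profiles first and reading once gives the same means for
linear readouts). Kinetic measures are not baseline-corrected.

## Statistics

The mixed (split-plot) ANOVA uses the classical decomposition: between
stratum — group and subjects-within-groups error; within stratum — phase,
group×phase, and phase×subjects-within-groups error. Generalized eta squared
follows the scheme for designs with only manipulated factors:
ges = SS_effect / (SS_effect + ΣSS_error), summing both error strata for
every effect. The Huynh–Feldt epsilon is reported for within effects and is
identically 1 for the two-level phase factor; the general k-level formula is
implemented (Greenhouse–Geisser from the double-centered pooled covariance,
then the HF small-sample correction, clipped at 1). Degenerate inputs are
handled explicitly: zero error mean-squares give F = 0, p = 1 when the effect
is also zero, and an infinite flagged F otherwise.

Unbalanced-but-complete designs are accepted: main-effect sums of squares use
group-size-weighted means (a Type-I-like decomposition) while the
within-subject error is computed from exact residuals; all analyses in the
default pipeline are balanced, where every decomposition coincides.

Simple effects are one-way ANOVAs within each phase, followed by all-pairs
Tukey HSD over the four groups using the one-way error term and the
studentized range distribution (Tukey–Kramer SE for unequal cells). The
first-exposure perturbation-magnitude check is a two-sided pooled-variance
(Student) t-test — pooled rather than Welch so a 15-vs-15 comparison has the
conventional 28 degrees of freedom.

If a participant happens to have no channel trial inside an analysis window
(possible under the 20%-per-block placement), that participant is dropped
from the affected kinetic ANOVA rather than aborting the run; the manifest
records any analysis skipped entirely.

## Analysis plan

Ten mixed ANOVAs: right-hand adaptation (RMSE, IDE; early vs. late exposure),
right-hand aftereffects (RMSE; late exposure vs. first post-exposure window),
left-hand interference (RMSE, IDE, IEE, FEE; early vs. late), and left-hand
channel forces at the three landmarks (early vs. late). Windows default to 30
trials, trial bins to 10. All of it is configurable through
`AnalysisConfig`.

## Calibration and recovery checks

*Type-I error*: with both crosstalk gains set to zero the four groups are
exchangeable for the left hand, so the group effect in the left-hand RMSE
mixed ANOVA is a true null. The calibration design uses 4 groups × 5
participants, blocks 5/5/30/5, 10-trial early/late windows and the left hand
only — the F-test is exact under the null at any size, so the scaled-down
design estimates the same rejection rate at far lower cost. Over 1000
replicates the rate sits at the nominal 5% (test tolerance ±2%).

*Learning-rate recovery*: under the generator, exposure errors follow
e_{n+1} = R(1−a) + (a−b)·e_n, so regressing the participant-averaged error
curve on its lag recovers retention and rate; with default noise and 15
participants the rate comes back within 10% relative. A flat curve (rate 0)
is flagged non-identifiable instead of fitted.

*Channel stiffness*: quasi-static presses at three penetration depths regress
to the programmed 20 N/cm slope exactly (the wall law is linear by
construction); a ramp factor of 0.5 halves the slope.

## What the generator does and does not emulate

It reproduces the design's structure: block schedule, balanced pseudorandom
targets shared by the hands, exact per-block channel-trial counts, timing
feedback classification, adaptation curves with aftereffects, and
interference that grows with adaptation in the expected group order. It does
**not** model biomechanics (muscles, joint geometry), reaction times, online
feedback corrections within a trial (so left-hand IDE and IEE coincide when
reaches are straight), explicit strategies, or trial-to-trial state noise in
the learner. Passing tests therefore certify the analysis code and the
qualitative structure of the phenomenon, not quantitative agreement with any
particular human dataset — group-level F statistics from human data depend on
effect and noise magnitudes the generator fixes by assumption.

## Numerical choices and degenerate inputs

- Curl sense defaults to clockwise (S = [[0, 1], [−1, 0]]); the sense only
  flips signs and is configurable.
- The channel's "5 N" lateral viscous term is treated as a viscous
  coefficient (5 N·s/m): a damping term must scale with velocity to damp
  wall-to-wall oscillation.
- The integration horizon depends only on the configuration (maximum allowed
  duration + settle margin), never on batch composition, so trial records are
  byte-identical however trials are chunked for vectorised integration.
- Resampling uses linear interpolation on normalized time (exact on linear
  signals, endpoints preserved); landmark readout indexes round(f·999) on the
  1000-point grid.
- All-zero speed series, zero-length paths, points at the home position,
  missing baselines, incomplete designs and single-depth stiffness fits raise
  typed errors rather than returning silent NaNs.

## Problem sizes used by the checks

The bundled checks run at desk scale: geometry targets use single noise-free
trials; the schedule and ordering checks use the full default experiment (60
participants × 360 trials × 2 hands), the ordering over 10 seeds; the null
calibration uses 1000 scaled-down replicates; learning-rate recovery uses the
default 15 participants (right hand only). These sizes are the package's own
choices for the bundled verification suite and are configurable.
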