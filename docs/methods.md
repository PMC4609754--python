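# Methods

This note documents the estimators, models, conventions and design choices
implemented in `erpentropy`, and what the synthetic-data generator does and
does not emulate.

## Sample entropy

For a series x₁…x_N, template length m and tolerance multiplier r, we form
the N − m templates of length m and of length m + 1 (the shared-count
convention of the original estimator, which guarantees U_{m+1} ≤ U_m and
hence sampEn ≥ 0) and count ordered pairs i ≠ j whose distance is ≤
r · SD(x). SD uses the population convention (ddof = 0) and is recomputed
per analysis frame, so the estimator is amplitude-scale free. The distance
is Chebyshev (max-norm) by default; Euclidean is available
(`SampEnParams(distance="euclidean")`) but changes the effective tolerance
geometry, so results under the two are not directly comparable. Matching is
inclusive (distance ≤ r), and ties at exactly r are therefore counted —
relevant only for discrete-valued inputs.

Degenerate frames follow two conventions chosen so that batch pipelines
never abort:

* SD = 0 (flat or clipped frame): all templates match exactly; the value is
  defined as 0 with a `degenerate` flag.
* U_m = 0 or U_{m+1} = 0: the estimate is undefined; the value is NaN with
  the flag set, and NaN values are excluded (and counted) wherever epochs
  are averaged. They are never imputed and never become ±infinity.

Series shorter than m + 2 samples are rejected. The vectorized
implementation (and its batch form used by the pipeline) is tested for
exact count-level agreement against an independent O(N²) brute-force
template-comparison oracle.

## Window schedule

A 500 ms rectangular window slides in 100 ms steps over the stimulus-locked
epoch; centers run from +250 ms to +1250 ms (11 windows), so the last
window spans +1000…+1500 ms. Conversions use `round(ms · fs / 1000)`; the
window is the half-open sample interval `[round((c − 250) · fs/1000),
start + 125)` so that at 250 Hz every window holds exactly 125 samples.
The tolerance is recomputed from each window's own SD. No per-epoch
normalization is applied before windowing — the tolerance already adapts to
the window's amplitude, and normalizing would change nothing for a
scale-free estimator.

## Epoch pipeline

Epochs span 0…+1500 ms post-stimulus (375 samples at 250 Hz); no baseline
interval is required downstream. Epochs from incorrect trials or trials
flagged as artifact-contaminated are excluded; artifact detection itself is
out of scope — flags are taken from the trial log as given. Participants
with fewer than 10 usable epochs for any condition type are removed, where
a condition type is a session × trialtype cell (the minimal set the
analyses require; congruency sub-cells are not separately screened). The
threshold is strict: exactly 10 keeps the participant.

Windowed entropy is averaged in this order: over the epochs of a stimulus
type (missing values dropped from the mean with counts logged), then over
the electrodes of each regional group — left frontal (Fp1, F3, F7), right
frontal (Fp2, F4, F8), left temporal (T7, TP7, FT7), right temporal (T8,
TP8, FT8), left parietal (P3, P7), right parietal (P4, P8) — then over
window centers within three half-open bins (0, 500], (500, 1000],
(1000, 1500] ms, which contain 3, 5 and 3 of the 11 window centers. Because
all three reductions are unweighted means, their order is immaterial
(verified to 1e-12). The 11-window-to-3-bin reduction is a package
decision: averaging all windows by center uses every computed window and
keeps bins non-overlapping; `bin_mode="center_window_only"` instead takes
the single span-matching window (centers 250 / 750 / 1250 ms).

## Behavioral task and ANOVA

The task crosses Go/No-Go with flanker congruency over eight five-letter
strings; B and U targets demand a response, D and V demand withholding.
Schedules balance the eight strings within each block (120 / 8 = 15 per
block; configurable to unconstrained sampling), giving exactly 300 Go and
300 No-Go trials over five blocks. Scoring is symmetric: +5 points per
correct trial, −5 per error (the stake is configurable). Misses on Go
trials count as errors; no RT floor is applied. Mean RT is computed over
hits (correct Go responses) only; error rate is percent incorrect per
participant × session × trialtype × congruency cell.

The mixed (split-plot) ANOVA exploits the fact that every factor has two
levels: with ±1 contrast codes, each effect's sum of squares is
N · mean(c·y)², each within effect (and its group interaction) is tested
against the subject-within-group stratum of its own per-subject contrast
score, and the group effect against the between-subject stratum. This is a
classical expected-mean-squares computation, not a likelihood fit, so an
independent direct sums-of-squares oracle can verify it exactly; sphericity
corrections are unnecessary with 2-level factors. Group-mean forms of the
formulas are used so that mildly unequal group sizes (e.g. the 14/16 split
a 19-boy/11-girl gender-wise median split produces) remain valid; under
balance they coincide with the contrast forms. For RT the design drops
Trialtype (RT exists only for Go trials).

Follow-up analyses: `simple_effects` re-runs the within-subject ANOVA on
one group, either against the pooled full-sample stratum (default,
df = n_subjects − n_groups) or the slice's own stratum
(`error="slice"`, df = n_slice − 1); `posthoc_contrast` tests a paired
two-level contrast inside a slice against either the pooled within-group
variance of that same paired difference (default) or the slice-only
variance. Pooled is the default because whole-sample contrasts then reduce
exactly to the omnibus within-effects.

## Fitness

The graded test starts at 25 W, adds 25 W every 120 s at 60 rpm, to
voluntary exhaustion; "maximal watt performance" is the load of the last
stage begun (floor convention at stage boundaries — no partial-stage
credit). Fitness = max watt / BMI (BMI = kg/m², with a [10, 60] plausibility
guard that warns on unit mistakes). Groups come from a gender-wise median
split; scores strictly above the gender median are "higher" fit, scores at
or below it "lower" (a deterministic, conservative tie rule). Exercise
bouts target 60% of individual maximal heart rate. The simulated stage
heart rates (linear in load, participant noise, capped at max HR, made
monotone) are a simulation convenience only, not an empirical HR model.

## Trajectory model

Per region, entropy is modelled with a linear mixed model: random intercept
plus random linear and quadratic time per participant (full covariance;
on a singular fit the model is refitted with a diagonal covariance and a
logged warning), and fixed effects of linear time, quadratic time, the
design factors and all factor × time products. Time over the three bins is
coded with orthonormal polynomial contrasts, linear (−1, 0, 1)/√2 and
quadratic (1, −2, 1)/√6; two-level factors are effect-coded ±0.5 so each
coefficient is the average difference between its levels, with signs fixed
as: left hemisphere +0.5 (a negative Hemisphere coefficient means lower
entropy on the left), higher fit +0.5, exercise session +0.5, No-Go +0.5,
incongruent +0.5.

Inference on the t statistics uses the standard normal by default; a t
distribution with residual df is available (`df_method="residual"`) as a
coarse finite-sample alternative. Backward elimination removes one term per
refit: among currently removable terms (no retained higher-order term
contains them; the intercept is never removable; linear and quadratic time
are distinct components, so e.g. Hemisphere × TimeSq protects Hemisphere
but not Hemisphere × Time), p values are Hochberg-adjusted — per
elimination step by default, per model optionally — and the highest-order
term with the largest adjusted p above α = 0.05 is dropped. The Hochberg
step-up adjustment itself is `adj(i) = min_{j ≥ i} (m − j + 1) p_(j)`,
capped at 1, and is verified against an exhaustive evaluation of the
sequential rejection rule.

Post-hoc contrasts: adjacent bins are compared with paired t tests on
participant means (df = n − 1); fitness groups are compared per bin with
the rank-sum (Wilcoxon/Mann–Whitney) normal-approximation Z, chosen for
robustness at ~15 per group, with Welch's t as an option.

## Synthetic data generator

Defaults are the study conditions: 30 participants (19 boys, 11 girls),
two sessions, five 120-trial blocks, 250 Hz, 39 extended 10–20 channels,
and ~150 usable epochs per trialtype × congruency cell.

**EEG.** Each channel stream mixes a band-limited 8–12 Hz oscillation
(random frequency and phase per epoch × channel) with low-passed white
noise; the profile value w is the noise *variance* fraction, i.e.
s(t) = √(1 − w(t))·osc + √w(t)·noise. The noise is white Gaussian passed
through a 2nd-order 50 Hz low-pass: the gentle rolloff deliberately keeps
some fast structure so that expected sampEn is strictly increasing in w
over the whole [0, 1] range — with amplitude-share mixing or steeper
filters the w → sampEn curve saturates above w ≈ 0.6 and the mapping stops
being invertible, which would make entropy-scale effect sizes ambiguous.
w(t) is interpolated across the epoch from per-bin values (bin centers
250 / 750 / 1250 ms) per group × region × hemisphere. The default profile
was read off the Monte-Carlo calibration curve
(`sampen_vs_noise_fraction`, cached per configuration) so binned pipeline
entropy lands in the 0.42–0.56 nat range with the three regional shapes:
linear decrease in temporal regions, sharp drop then plateau frontally,
drop then right-side rebound parietally. The higher-fit group's left
frontal w is lowered by 0.008, ≈ 0.03 nats at the curve's local slope —
the programmed group effect the end-to-end tests recover. A small
participant-level w offset (SD 0.004) supplies between-participant
variance; the generator does not program random time-slope variance, so
fitted random-slope variances are near zero and the diagonal-covariance
fallback is exercised on generated data.

**Behavior.** RTs are lognormal (median 420 ms, σ = 0.22) with a +40 ms
incongruent shift and fitness × exercise shifts (−25 ms for higher-fit
after exercise, +15 ms for lower-fit); errors are Bernoulli per
group × session × trialtype cell (±0.03 congruency shift), with the
lower-fit rest No-Go rate elevated (0.21 vs ≈ 0.10–0.12 elsewhere) to
produce the fitness × exercise × trialtype error interaction; Go errors
are misses, No-Go errors are false alarms; artifacts are independent
Bernoulli flags at 5%.

**What passing tests do and do not show.** The generator emulates the
statistical structure the analysis assumes — stationary-in-window mixtures,
independent channels, exchangeable epochs, no ERP waveform, no volume
conduction, no biophysical dynamics, no artifacts beyond random flags.
Recovery of programmed effects therefore validates the pipeline's
statistics and plumbing, not claims about real EEG.

## Problem sizes and numerical choices

Simulation-based tests and the acceptance script choose reduced problem
sizes as their own design: end-to-end group-effect runs use the rest
session, one stimulus category, 10 usable epochs per participant and the
regional electrodes only (the frontal six where only the frontal contrast
is at issue); mixed-model calibration simulates directly at the
binned-entropy level (30 participants × 2 hemispheres × 3 bins). Batch
entropy computation processes windows in chunks of 192 series to bound
pairwise-distance temporaries at ~30 MB. All stochastic operations take an
explicit seed; identical seeds give bit-identical output.

## Known limitations

* Mixed-model p values use the normal approximation; no Satterthwaite or
  Kenward–Roger df.
* The split-plot ANOVA requires a complete within-design (no imputation);
  unequal group sizes are handled, unequal within-cells are not.
* EDF export is not provided (epoched container + JSON sidecar instead);
  EDF reading requires the optional mne dependency.
* The elimination path of the trajectory model depends on the adjustment
  family (per-step default) and is not guaranteed to find the globally
  best sub-model — it is a faithful stepwise procedure, not a model search.
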