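# Methods

`pericalc` implements the analysis stage of a one-photon calcium-imaging
experiment in which mice perform self-initiated operant tasks: aligning
deconvolved calcium event traces to behavioral events, classifying each
neuron as excited, inhibited or nonresponsive in each trial epoch, and
comparing classified populations between groups (e.g. genotypes).  This
note documents the statistical model, the choices made where the design
was genuinely open, and what the synthetic-data studies do and do not
establish.

## Data model and clocks

The pipeline consumes *deconvolved* event-amplitude traces (cells ×
frames at 20 Hz, non-negative), produced upstream by a sparse
deconvolution of denoised fluorescence.  Working on deconvolved events
rather than raw fluorescence avoids spillover between adjacent trial
epochs caused by slow indicator kinetics.  Raw-movie processing (motion
correction, source extraction, deconvolution) is out of scope.

Behavioral events are logged on the task controller's clock; frames on
the acquisition clock.  Both record a shared 5 s on/off sync pulse
train.  `fit_clock_map` fits the affine map
`imaging = offset + drift · behavior` to rank-matched pulse edges by
least squares.  The affine (rather than pure-offset) model is a strict
generalization: clocks drift measurably over a 40 min session, and a
pure offset is the `drift = 1` special case.  Because a periodic pulse
train fits equally well at any whole-period lag, candidate alignments
with near-minimal residual are disambiguated by choosing the smallest
|offset| — physical clock offsets are far below the 5 s half-period.
The fit refuses to proceed (desynchronization error) when the residual
RMS exceeds 0.025 s, half a frame.  With 5 ms edge jitter over 40 min
(480 edges), the recovered map deviates from the generating one by well
under a millisecond (`clock_alignment_check`).

Frame indexing is 0-based; all time windows are half-open `[start, end)`
in seconds; frame index = `floor((t − t₀) · 20)`.

## Trials and epochs

A trial is *correct* when the cued port is poked within the response
window (1.5 s by default; reward delivered at the poke), *incorrect* on
a poke to the non-cued port, *omitted* when no response occurs.  In the
delay task, side pokes during the 3 s delay increment a premature-
response counter and never change the outcome.

Epoch windows, anchored per trial:

| epoch | window | anchor |
|---|---|---|
| T | −2 → 0 s | trial initiation |
| C | initiation (cue task) / cue onset (delay task) → response | cue response |
| D | 0 → 3 s | initiation (delay task) |
| R | 0 → 3 s | reward delivery |
| P | 3 → 6 s | reward delivery |
| baseline | last 6 s of the preceding ITI | trial availability |

The C epoch has variable length (the response latency), so all
comparisons use per-second rates; latency differences therefore do not
bias event counts.  The delay task uses five epochs (T, C, D, R, P); a
four-epoch variant without C is available (`delay_include_cue_epoch`),
since conventions differ on whether the short post-delay cue period is
scored separately.

*Event rate* is operationally the number of frames whose deconvolved
amplitude strictly exceeds a threshold (default 0) per second of
window.  An amplitude-weighted variant is provided.  Note that counting
occupied frames slightly compresses high rates (a frame with two events
counts once): at a true rate r the expected reading is
`20·(1 − exp(−r/20))`, a 2.4% shrinkage at 1 event/s.  The synthetic
checks account for this.

Classification uses correct trials only, each paired with the baseline
rate from its own preceding ITI (`pairing="per_trial"`); pairing every
trial against the cell's session-averaged baseline is available
(`pairing="session_mean"`) since either reading of "averaged baseline
activity" is defensible.  Per-trial pairing is the default because it
yields a genuinely paired test robust to slow drifts in excitability.
Trials whose preceding ITI is shorter than 6 s (typically the first) are
excluded and counted.  The T window can in principle overlap the
baseline window if the animal initiates within 2 s of availability; the
windows are anchored to different events and overlap is permitted.

## The permutation test

For each cell × epoch, the statistic is the mean paired difference
(epoch rate − baseline rate, events/s).  The null distribution is
generated by independent random sign flips of the per-trial differences,
10,000 rounds, two-tailed, with the add-one correction
`p = (1 + #{|s*| ≥ |s|}) / (1 + n_perm)` — strictly positive and valid
at any round count; ties count toward the tail (conservative).  When
`2ⁿ ≤ n_perm` the exact enumeration over all 2ⁿ sign assignments is used
automatically, removing Monte-Carlo noise on small trial counts.  Sign
flips and within-pair label swaps are equivalent for a mean-difference
statistic, which motivates that choice of statistic; a studentized
variant would change nothing under sign flips at fixed n (the p-value is
invariant to positive rescaling of the differences, a property the suite
asserts).

Family-wise error is controlled by Bonferroni across epochs *and*
directions: the per-test threshold is `α / (2 · n_epochs)` — 0.05/8 for
the four-epoch cue task, 0.05/10 for the five-epoch delay task.  The
divisor follows the count of epoch×direction comparisons rather than
being pinned at 8 for both tasks; it is configurable.  A cell
significant in ≥ 1 epoch is *responsive*; its category string lists
significant epochs with directions in canonical T→C→D→R→P order
(`"C+R+P+"`, `"R-P-"`, …; `""` = nonresponsive).  Within a cell one set
of permutation rounds is shared across epochs — each marginal p-value is
unaffected and Bonferroni is valid under arbitrary dependence — turning
the test into a single matrix product per cell.

## Population statistics

Peri-event traces are z-normalized per cell against its own baseline:
each bin's trial-averaged rate is centered on the mean and scaled by the
SD of the per-trial baseline rates, then averaged over cells (± SEM)
within group.  Cells with zero baseline SD are excluded and counted.
Group comparisons: Pearson chi-square (no continuity correction; a
correction flag exists) on per-epoch excited/inhibited/nonresponsive
counts — cell types absent from both groups are dropped from the table
so margins stay positive; a two-way mixed-design ANOVA (group × time,
cells as the repeated-measures unit, via `pingouin.mixed_anova`) on the
normalized traces; category frequency tables among responsive cells with
the minimal category set reaching a coverage target (default 80%); and
Pearson correlations for per-animal metrics.  Both "percent of all
cells" and "percent of responsive cells" denominators are emitted,
explicitly labeled, as figures in this literature use either.

## Locomotion

Motion is the count of pixels changing by strictly more than 10 gray
units between consecutive video frames (30 fps), which removes baseline
pixel flicker; strict inequality is the convention adopted and is
configurable.  Counts are resampled onto the 20 Hz imaging time base by
duration-weighted binning — each frame's count is spread uniformly over
its interval and integrated per bin — which conserves total motion
exactly (asserted to 1e-9 relative).

## The synthetic-session generator

The generator emulates the statistical structure the analysis assumes:

- **Trials** — self-initiated, variable ITI uniform on
  `[max(0.5·mean, 6 s), 1.5·mean]` (mean 45 s under field conditions;
  the lower clamp guarantees a complete 6 s baseline), outcome mixture
  defaulting to 59% correct / 5% incorrect / 36% omitted (the field
  figures are 59 ± 3 / 5 ± 1 / 37 ± 3; the defaults are the nearest
  mixture summing to one), response latency normal(0.93, 0.3) s
  truncated to the response window, premature pokes as a homogeneous
  Poisson process (0.1 pokes/s) during the delay.
- **Events** — per-frame Poisson counts with mean
  `baseline_rate × multiplier(epoch) / 20`; a frame with k events
  carries a Gamma(2k, scale/2) amplitude sum.  The event-count model is
  the minimal assumption consistent with analyzing an event *rate*; the
  gamma amplitude choice is a modeling convenience, not an inference
  about indicator physics.
- **Tuning** — per-cell multiplicative epoch modulation (ground truth
  retained), drawn from a category mixture per cohort; default strong
  effects are ×5 (excited) and ×0.1 (inhibited) on a 1 event/s baseline.
- **Clocks** — affine behavior→imaging model (default offset 0, drift 1)
  with optional per-edge sync jitter.
- **Scheduling** — the ITI timer starts after the 6 s post-reward period
  and initiation follows availability by U(2, 4) s, so tuned epochs
  never leak into baseline windows even at the 10 s fast-test ITI; with
  45 s ITIs such overlap is impossible regardless.

It does **not** simulate raw fluorescence, source-extraction artifacts,
crosstalk between neighboring cells, indicator kinetics, slow drifts in
excitability, or burst/refractory deviations from Poisson.  Passing
tests therefore establish the *statistical correctness of the pipeline*
(test validity, FWER control, unbiased recovery of seeded structure),
not robustness to those real-data pathologies.

## Validation studies and problem sizes

`pericalc.validation` bundles the standard studies; the test suite and
`scripts/acceptance.py` run them identically.  Sizes were chosen so each
study has the statistical resolution it needs while the whole battery
runs in minutes on one core:

- **Null calibration** — 2,000 untuned cells, 30 correct trials, 10,000
  rounds: per-epoch P(p ≤ 0.05) within 3 binomial SEs of 0.05 and
  Bonferroni responsive fraction ≤ 0.05 + 3 SE.
- **Oracle agreement** — 200 ten-trial cells: Monte-Carlo p within
  3·√(p(1−p)/10⁴) of the exhaustive 2¹⁰ enumeration in ≥ 99% of cases.
- **Worked exact case** — differences (+1, +1, +1): p = 2/8 = 0.25.
- **Category recovery** — 500 cells seeded {R+: 0.3, R−P−: 0.1,
  null: 0.6} at strong effects, 40 trials: recovered counts inside the
  binomial 99% CI of the seeded proportions.
- **Contrast detection** — two 300-cell delay-task groups with D+
  prevalence 0.25 vs 0.10: D-epoch chi-square p < 0.05 in ≥ 90% of 50
  replicates.
- **Clock recovery** — offset 1.5 s, drift 1.0005, 5 ms jitter, 40 min:
  max mapping error < 0.025 s.
- **Closed forms** — chi-square [[30,10],[10,30]] = 20 exactly; motion
  resampling conservation ≤ 1e-9 relative; epoch windows exact on a
  hand-constructed trial.

Simulation studies use the fast task profile (10 s mean ITI, sessions
sized to the required trial count); the field profile (45 s ITI, 40 min
sessions) is the `TaskSpec` default.

## Numerical choices and limitations

- Tie detection in the permutation tail uses an absolute tolerance of
  `1e-9 · (1 + max|diff|)` so exact ties are counted regardless of
  floating-point summation order.
- All-zero difference vectors return p = 1, direction "0" (degenerate,
  not an error); fewer than 2 trials is an error.
- Per-cell random streams are spawned from a master seed
  (`numpy.random.SeedSequence`), so population classification is
  reproducible and independent of evaluation order; the pipeline's
  tables are byte-identical across re-runs of the same config.
- Animal-level nesting is deliberately absent from the ANOVA (cells are
  the unit, matching how population traces are averaged); conclusions
  about animals require mixed models outside this package's scope.
- The chi-square comparison assumes cells are independent; cells
  recorded simultaneously in one animal are not, so on real data its
  p-values are anticonservative to an unknown degree.
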