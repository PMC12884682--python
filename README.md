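# pericalc

Peri-event classification of deconvolved calcium event traces from
operant-task imaging sessions.

`pericalc` is for systems neuroscientists who record one-photon calcium
imaging (e.g. miniscope recordings of striatal medium spiny neurons)
while mice perform self-initiated operant tasks, and who want to answer:
*which neurons change their event rate in which part of the trial, in
which direction, and do two groups (genotypes, treatments) differ in
those proportions?*

## What it computes

For each cell and each named trial epoch — T (2 s before trial
initiation), C (cue onset → response), D (3 s delay, waiting task),
R (0–3 s after reward), P (3–6 s after reward) — the per-trial event
rate on correct trials is compared with a paired baseline rate from the
last 6 s of the preceding intertrial interval using a **two-tailed
paired sign-flip permutation test** (10,000 rounds; exhaustive
enumeration automatically when 2ⁿ ≤ 10,000):

- statistic: mean paired difference  s = mean(rate_epoch − rate_baseline)
- null: independent random sign flips of the per-trial differences
- p = (1 + #{|s*| ≥ |s|}) / (1 + n_perm), two-tailed

Significance is Bonferroni-controlled across epochs × directions
(α / (2·n_epochs), i.e. p < 0.05/8 for the four-epoch cue task).  Each
responsive cell receives a mixed-selectivity **category string** such as
`"C+R+P+"` or `"R-P-"`; populations are then compared between groups by
per-epoch chi-square on excited/inhibited/nonresponsive counts, category
frequency tables, z-normalized peri-event population traces and a
group × time mixed-design ANOVA.

The package also handles the plumbing around the statistics —
behavioral↔imaging clock synchronization from shared 5 s on/off sync
pulses (affine least-squares fit), trial parsing from the operant event
log (correct / incorrect / omitted, premature-response counting), a
pixel-change locomotion index from overhead video — and includes a
**synthetic-session generator** with known ground-truth tuning so every
stage is verifiable without animal data.

## Worked example

Simulate two 200-cell cohorts that differ in reward tuning (25% of
control cells excited in R and P and 5% reward-inhibited, versus 10%
and 15% in the knockout group), classify every cell, and compare the
populations:

```python
from pericalc import (TaskSpec, CohortSpec, generate_cohort, build_trials,
                      build_rate_table, classify_population)
from pericalc.population import proportion_table, category_frequencies
from pericalc.session_io import ClockMap

task = TaskSpec(task_kind="cue_guided", iti_mean=10.0, session_length=900.0)
cohorts = [
    CohortSpec(group_label="control", cells_per_mouse=200,
               category_mixture={"R+P+": 0.25, "R-": 0.05, "": 0.70},
               trial_outcome_mixture=(1.0, 0.0, 0.0), rng_seed=1),
    CohortSpec(group_label="knockout", cells_per_mouse=200,
               category_mixture={"R+P+": 0.10, "R-": 0.15, "": 0.75},
               trial_outcome_mixture=(1.0, 0.0, 0.0), rng_seed=2),
]
classes = {}
for b in generate_cohort(cohorts, task):
    trials = build_trials(b.log, task, ClockMap.identity())
    table = build_rate_table(b.recording, trials, task)
    classes[b.group_label] = classify_population(table, master_seed=0)

print(proportion_table(classes, task.epoch_labels).to_string(index=False))
freq, cover = category_frequencies(classes["control"]["category"])
print(freq.to_string(index=False))
print("categories covering 80% of responsive cells:", cover)
```

Output:

```
epoch  excited_control  inhibited_control  nonresponsive_control  excited_knockout  inhibited_knockout  nonresponsive_knockout      chi2  df        p
    T                0                  1                    199                 0                   3                     197  1.010101   1 0.314879
    C                0                  1                    199                 0                   2                     198  0.335852   1 0.562233
    R               46                 10                    144                18                  36                     146 26.959445   2 0.000001
    P               46                  0                    154                18                   0                     182 14.583333   1 0.000134

category  count    share  cumulative_share
    R+P+     45 0.789474          0.789474
      R-     10 0.175439          0.964912
  C-R+P+      1 0.017544          0.982456
      T-      1 0.017544          1.000000
categories covering 80% of responsive cells: ['R+P+', 'R-']
```

Reading it: in the T and C epochs (where no tuning was seeded) almost
every cell is nonresponsive and the groups do not differ; in the reward
and post-reward epochs the classifier recovers the seeded contrast —
more excited cells in control, more inhibited cells in knockout — and
the per-epoch chi-square flags both (p ≪ 0.05).  The category table
recovers the two seeded categories (45/200 ≈ the seeded 25% of R+P+
cells, at the classifier's per-epoch power) plus two isolated
false-positive labels, consistent with the Bonferroni family-wise error
budget.

The same pipeline is available from the shell:

```sh
pericalc run --config demo.yaml --out runs/demo    # simulate → classify → summarize
pericalc simulate / epochs / classify / population / locomotion ...
```

Re-running with the same config reproduces all output tables
byte-for-byte.

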