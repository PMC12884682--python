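"""Simulation-based validation studies for the classification pipeline.

Each function runs one self-contained study on synthetic sessions —
null calibration of the permutation test, Monte-Carlo vs exhaustive
enumeration agreement, seeded-category recovery, between-group contrast
detection, sync-pulse clock recovery and closed-form spot checks — and
returns a dict of scalar results.  The test suite and the
``scripts/acceptance.py`` entry point both call these, so the numbers
they report are always recomputed from scratch.

Study sizes are the package's standard validation conditions (documented
in the methods note); every study takes an explicit seed and is fully
deterministic given it.
"""

from __future__ import annotations

import numpy as np

from pericalc import classify as pc
from pericalc import population as pop
from pericalc.epochs import (EpochRateTable, Trial, build_rate_table,
                             build_trials, epoch_windows)
from pericalc.locomotion import motion_index, resample_motion
from pericalc.session_io import ClockMap, fit_clock_map
from pericalc.synth import CohortSpec, generate_session, make_profiles
from pericalc.task import TaskSpec


def _fast_task(kind: str) -> TaskSpec:
    """The CI profile: 10 s mean ITI instead of the field's 45 s."""
    return TaskSpec(task_kind=kind, iti_mean=10.0, session_length=600.0)


def _simulate_rate_table(kind: str, cohort: CohortSpec, n_trials: int,
                         seed) -> tuple[EpochRateTable, list]:
    """Generate a session with >= n_trials correct trials, parse its log
    and return the rate table truncated to exactly n_trials trials."""
    # Upper-bound the trial cycle length to size the session.
    task_probe = _fast_task(kind)
    cycle = (task_probe.iti_bounds[1] + task_probe.max_trial_span + 1.0)
    need = n_trials / max(cohort.trial_outcome_mixture[0], 1e-9)
    task = TaskSpec(task_kind=kind, iti_mean=10.0,
                    session_length=float(np.ceil(need * cycle + 60.0)))
    rng = np.random.default_rng(seed)
    profiles = make_profiles(cohort, rng)
    rec, log, _, profs = generate_session(task, profiles, cohort, seed=rng)
    trials = build_trials(log, task, ClockMap.identity())
    table = build_rate_table(rec, trials, task)
    if table.n_trials < n_trials:
        raise RuntimeError(
            f"session yielded only {table.n_trials} usable trials")
    table = EpochRateTable(
        rates=table.rates[:, :n_trials], baseline_rates=table.baseline_rates[:, :n_trials],
        epoch_labels=table.epoch_labels, trial_indices=table.trial_indices[:n_trials],
        cell_ids=table.cell_ids, n_trials_excluded=table.n_trials_excluded)
    return table, profs


def null_calibration(seed: int, n_cells: int = 2000, n_trials: int = 30,
                     n_perm: int = 10_000, alpha: float = 0.05) -> dict:
    """Size of the test on untuned cells (all-correct fast sessions).

    Returns the per-epoch fractions of cells with p <= alpha, their mean,
    and the fraction classified responsive under the Bonferroni
    threshold alpha / (2 * n_epochs).
    """
    cohort = CohortSpec(group_label="null", cells_per_mouse=n_cells,
                        trial_outcome_mixture=(1.0, 0.0, 0.0),
                        rng_seed=seed)
    table, _ = _simulate_rate_table("cue_guided", cohort, n_trials, seed)
    classes = pc.classify_population(table, alpha=alpha, n_perm=n_perm,
                                     master_seed=seed)
    per_epoch = {lab: float((classes[f"p_{lab}"] <= alpha).mean())
                 for lab in table.epoch_labels}
    return {
        "n_cells": n_cells,
        "n_trials": n_trials,
        "per_epoch_fraction_p_le_alpha": per_epoch,
        "mean_fraction_p_le_alpha": float(np.mean(list(per_epoch.values()))),
        "responsive_fraction": float(classes["responsive"].mean()),
        "binomial_se": float(np.sqrt(alpha * (1 - alpha) / n_cells)),
    }


def oracle_agreement(seed: int, n_cells: int = 200, n_trials: int = 10,
                     n_perm: int = 10_000) -> dict:
    """Monte-Carlo p vs exhaustive 2**n enumeration on small trial counts.

    Cells are random Poisson epoch/baseline rate pairs.  A case agrees
    when |p_mc - p_exact| <= 3 * sqrt(p_exact (1 - p_exact) / n_perm).
    """
    rng = np.random.default_rng(seed)
    agree = 0
    devs = []
    for i in range(n_cells):
        base = rng.poisson(6.0, size=n_trials) / 6.0
        epoch = rng.poisson(3.0, size=n_trials) / 3.0
        exact = pc.paired_permutation_test(epoch, base, method="exact").p_two_tailed
        mc = pc.paired_permutation_test(epoch, base, n_perm=n_perm,
                                        seed=rng, method="mc").p_two_tailed
        tol = 3 * np.sqrt(exact * (1 - exact) / n_perm)
        dev = abs(mc - exact)
        devs.append(dev)
        # add-one correction shifts the MC estimate by < 1/n_perm
        agree += dev <= tol + 1.0 / n_perm
    return {"n_cells": n_cells, "agreement_fraction": agree / n_cells,
            "max_abs_deviation": float(np.max(devs))}


def exact_small_case() -> dict:
    """Worked exact case: paired differences (+1, +1, +1)."""
    res = pc.paired_permutation_test([1.0, 1.0, 1.0], [0.0, 0.0, 0.0],
                                     method="exact")
    return {"p_two_tailed": res.p_two_tailed, "n_trials": res.n_trials,
            "n_enumerated": res.n_permutations}


def category_recovery(seed: int, n_cells: int = 500, n_trials: int = 40,
                      n_perm: int = 10_000) -> dict:
    """Recovery of a seeded category mixture {R+: 0.3, R-P-: 0.1, null: 0.6}.

    Strong effects (multipliers 5.0 / 0.1 on a 1 event/s baseline); the
    recovered proportion of each seeded category should sit inside the
    binomial 99% CI around its seeded value.
    """
    mixture = {"R+": 0.3, "R-P-": 0.1, "": 0.6}
    cohort = CohortSpec(group_label="mix", cells_per_mouse=n_cells,
                        category_mixture=mixture,
                        trial_outcome_mixture=(1.0, 0.0, 0.0),
                        baseline_rate=1.0, excited_multiplier=5.0,
                        inhibited_multiplier=0.1, rng_seed=seed)
    table, _ = _simulate_rate_table("cue_guided", cohort, n_trials, seed)
    classes = pc.classify_population(table, n_perm=n_perm, master_seed=seed)
    out = {"n_cells": n_cells, "n_trials": n_trials}
    for cat in ("R+", "R-P-"):
        p = mixture[cat]
        half = 2.5758 * np.sqrt(n_cells * p * (1 - p))
        out[cat] = {
            "seeded_proportion": p,
            "recovered_count": int((classes["category"] == cat).sum()),
            "recovered_proportion": float((classes["category"] == cat).mean()),
            "ci99_count": (p * n_cells - half, p * n_cells + half),
        }
    return out


def contrast_detection(seed: int, n_seeds: int = 50, n_cells: int = 300,
                       n_trials: int = 40, n_perm: int = 10_000) -> dict:
    """Detection of a group difference in D+ prevalence (0.25 vs 0.10).

    Two delay-task groups per replicate; the per-epoch chi-square on
    excited/inhibited/nonresponsive counts in the delay (D) epoch should
    reject at p < 0.05 in the large majority of replicates.
    """
    detected = 0
    root = np.random.SeedSequence(seed)
    for rep_ss in root.spawn(n_seeds):
        rep_seed = int(rep_ss.generate_state(1)[0] % (2 ** 31))
        classes = {}
        for g, prop in (("A", 0.25), ("B", 0.10)):
            cohort = CohortSpec(
                group_label=g, cells_per_mouse=n_cells,
                category_mixture={"D+": prop, "": 1.0 - prop},
                trial_outcome_mixture=(1.0, 0.0, 0.0),
                rng_seed=rep_seed + (0 if g == "A" else 1))
            table, _ = _simulate_rate_table("delay", cohort, n_trials,
                                            rep_seed + (0 if g == "A" else 1))
            classes[g] = pc.classify_population(table, n_perm=n_perm,
                                                master_seed=rep_seed)
        prop_tab = pop.proportion_table(classes, ["D"])
        detected += float(prop_tab.loc[0, "p"]) < 0.05
    return {"n_seeds": n_seeds, "n_cells_per_group": n_cells,
            "detection_rate": detected / n_seeds}


def clock_alignment_check(seed: int, offset: float = 1.5,
                          drift: float = 1.0005, jitter_sd: float = 0.005,
                          session_length: float = 2400.0) -> dict:
    """Affine clock recovery from jittered 5 s on/off sync pulses.

    A 40 min pulse train with the given offset/drift/jitter is fitted
    and the worst-case mapping error over the session is reported.
    """
    rng = np.random.default_rng(seed)
    beh = np.arange(0.0, session_length, 5.0)
    img = offset + drift * beh + rng.normal(0.0, jitter_sd, size=beh.size)
    cm = fit_clock_map(beh, img, check=False)
    t = np.linspace(0.0, session_length, 4001)
    err = np.abs(cm.to_imaging(t) - (offset + drift * t))
    return {"n_edges": int(beh.size),
            "max_mapping_error_s": float(err.max()),
            "fitted_offset": cm.offset, "fitted_drift": cm.drift,
            "residual_rms": cm.residual_rms}


def closed_form_checks(seed: int = 0) -> dict:
    """Closed-form spot checks: chi-square, motion conservation, windows."""
    chi2, df, _ = pop.chi_square_2xk([[30, 10], [10, 30]])

    rng = np.random.default_rng(seed)
    frames = rng.integers(0, 255, size=(301, 24, 24)).astype(np.int32)
    counts = motion_index(frames, threshold=10)
    trace = resample_motion(counts, source_fps=30.0)
    conservation = abs(trace.motion_index.sum() - counts.sum()) / counts.sum()

    task = TaskSpec(task_kind="cue_guided")
    trial = Trial(index=0, availability_time=95.0, initiation_time=100.0,
                  cue_on_time=100.0, response_time=100.9, response_port="left",
                  cued_port="left", reward_time=100.9, outcome="correct",
                  premature_count=0, preceding_iti=(50.0, 95.0))
    expected = {"T": (98.0, 100.0), "C": (100.0, 100.9),
                "R": (100.9, 103.9), "P": (103.9, 106.9),
                "baseline": (89.0, 95.0)}
    windows = dict(epoch_windows(trial, task))
    max_dev = max(abs(windows[k][i] - expected[k][i])
                  for k in expected for i in (0, 1))
    return {"chi_square_2x2": float(chi2), "chi_square_df": int(df),
            "motion_conservation_rel_error": float(conservation),
            "epoch_window_max_deviation_s": float(max_dev)}
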