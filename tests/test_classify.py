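"""Permutation-test correctness, Bonferroni control and categorization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pericalc.classify import (bonferroni_threshold, classify_cell,
                               classify_population,
                               paired_permutation_test,
                               summarize_epoch_counts)
from pericalc.epochs import build_rate_table, build_trials
from pericalc.session_io import ClockMap
from pericalc.synth import CohortSpec, TuningProfile, generate_session
from pericalc.task import TaskSpec


def test_exact_enumeration_three_positives():
    """(+1,+1,+1): only the all-plus and all-minus of the 8 sign patterns
    reach |mean| = 1, so the two-tailed exact p is 2/8."""
    res = paired_permutation_test([1.0, 1, 1], [0.0, 0, 0], method="exact")
    assert res.p_two_tailed == pytest.approx(0.25)
    assert res.exact and res.n_permutations == 8
    assert res.direction == "+"


def test_degenerate_all_zero_differences():
    res = paired_permutation_test([1.0, 2, 3], [1.0, 2, 3])
    assert res.p_two_tailed == 1.0
    assert res.direction == "0"


def test_input_validation():
    with pytest.raises(ValueError):
        paired_permutation_test([1.0], [0.0])
    with pytest.raises(ValueError):
        paired_permutation_test([1.0, 2], [0.0])
    with pytest.raises(ValueError):
        bonferroni_threshold(1.5, 4)
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)


def test_monte_carlo_matches_exact_enumeration():
    """At n = 10 trials the 10,000-round Monte-Carlo p sits within 3
    binomial SEs of the exhaustive 2^10 enumeration."""
    rng = np.random.default_rng(8)
    for _ in range(20):
        base = rng.poisson(6.0, size=10) / 6.0
        epoch = rng.poisson(3.0, size=10) / 3.0
        exact = paired_permutation_test(epoch, base,
                                        method="exact").p_two_tailed
        mc = paired_permutation_test(epoch, base, n_perm=10_000, seed=rng,
                                     method="mc").p_two_tailed
        tol = 3 * np.sqrt(exact * (1 - exact) / 10_000) + 1e-4
        assert abs(mc - exact) <= tol


def test_auto_selects_exact_for_small_n():
    res = paired_permutation_test(np.arange(1.0, 9), np.zeros(8),
                                  n_perm=10_000)
    assert res.exact and res.n_permutations == 256


@settings(derandomize=True, max_examples=30)
@given(diffs=st.lists(st.floats(-5, 5, allow_nan=False, width=32),
                      min_size=3, max_size=8),
       scale=st.floats(0.01, 100.0))
def test_positive_scaling_leaves_p_unchanged(diffs, scale):
    """The sign-flip null depends only on signs and relative magnitudes,
    so scaling all paired differences by c > 0 cannot move p."""
    d = np.asarray(diffs, dtype=float)
    p1 = paired_permutation_test(d, np.zeros_like(d),
                                 method="exact").p_two_tailed
    p2 = paired_permutation_test(d * scale, np.zeros_like(d),
                                 method="exact").p_two_tailed
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_p_floor_and_tie_handling():
    # p can never fall below 1/(n_perm+1) (MC) or 2/2^n (exact, stat != 0)
    d = np.full(12, 3.0)
    res = paired_permutation_test(d, np.zeros(12), method="exact")
    assert res.p_two_tailed == pytest.approx(2 / 4096)
    res = paired_permutation_test(np.full(30, 3.0), np.zeros(30),
                                  n_perm=1000, seed=0, method="mc")
    assert res.p_two_tailed >= 1 / 1001


@pytest.mark.parametrize("n_epochs,expected",
                         [(4, 0.00625), (5, 0.005), (1, 0.025)])
def test_bonferroni_divisor(n_epochs, expected):
    assert bonferroni_threshold(0.05, n_epochs) == pytest.approx(expected)


def _session_table(mult, n_cells=1, seed=21, session_length=1100.0):
    task = TaskSpec(task_kind="cue_guided", iti_mean=10.0,
                    session_length=session_length)
    cohort = CohortSpec(group_label="g", trial_outcome_mixture=(1.0, 0, 0))
    profiles = [TuningProfile(cell_id=f"c{i}", baseline_rate=1.0,
                              epoch_multipliers=dict(mult))
                for i in range(n_cells)]
    rec, log, _, _ = generate_session(task, profiles, cohort, seed=seed)
    trials = build_trials(log, task, ClockMap.identity())
    return build_rate_table(rec, trials, task)


def test_strong_excitation_classified_r_plus():
    table = _session_table({"R": 5.0})
    assert table.n_trials >= 40
    cc = classify_cell(table.rates[0], table.baseline_rates[0],
                       table.epoch_labels, seed=1, cell_id="c0")
    assert cc.category == "R+"


def test_strong_suppression_classified_r_minus_p_minus():
    table = _session_table({"R": 0.1, "P": 0.1}, seed=22)
    cc = classify_cell(table.rates[0], table.baseline_rates[0],
                       table.epoch_labels, seed=1)
    assert cc.category == "R-P-"


def test_category_soundness_and_canonical_order():
    """Every epoch named in a category is significant at the adjusted
    threshold, every significant epoch is named, in canonical order."""
    table = _session_table({"T": 5.0, "P": 0.1}, seed=23)
    cc = classify_cell(table.rates[0], table.baseline_rates[0],
                       table.epoch_labels, seed=2)
    thr = bonferroni_threshold(0.05, len(table.epoch_labels))
    named = {r.epoch_label for r in cc.results.values()
             if r.epoch_label + r.direction in
             [cc.category[i:i + 2] for i in range(0, len(cc.category), 2)]}
    sig = {lab for lab, r in cc.results.items() if r.p_two_tailed < thr}
    assert named == sig
    letters = cc.category[::2]
    assert letters == "".join(l for l in "TCDRP" if l in letters)


def test_population_determinism_and_null_fwer():
    table = _session_table({}, n_cells=100, seed=24, session_length=700.0)
    c1 = classify_population(table, master_seed=5)
    c2 = classify_population(table, master_seed=5)
    assert c1.equals(c2)
    # Bonferroni guarantee: responsive fraction below alpha + 3 SE
    frac = c1["responsive"].mean()
    assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 100)
    counts = summarize_epoch_counts(c1, table.epoch_labels)
    assert (counts[["excited", "inhibited", "nonresponsive"]].sum(axis=1)
            == 100).all()


def test_session_mean_pairing_mode():
    table = _session_table({"R": 5.0}, seed=25)
    cc = classify_population(table, master_seed=1, pairing="session_mean")
    assert cc.loc[0, "category"] == "R+"
    with pytest.raises(ValueError):
        table.baselines("bogus")
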