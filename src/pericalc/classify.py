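"""Paired sign-flip permutation classification of task-responsive cells.

For each cell and trial epoch, the per-trial epoch event rate is compared
with the paired baseline rate by a two-tailed permutation test: the
statistic is the mean paired difference, and the null distribution is
generated by independent random sign flips of the per-trial differences
(10,000 rounds by default).  This makes no distributional assumption —
calcium event rates are decidedly non-normal — beyond sign symmetry of
the paired differences under the null.

The Monte-Carlo p-value uses the add-one correction
``p = (1 + #{|s*| >= |s|}) / (1 + n_perm)``, which is strictly positive
and valid at any number of rounds; ties count toward the tail.  When the
trial count ``n`` is small enough that all ``2**n`` sign assignments fit
within the permutation budget, the exact enumeration is used instead
(``p = #{|s*| >= |s|} / 2**n``), eliminating Monte-Carlo noise.

Significance is controlled family-wise by Bonferroni across epochs *and*
directions (excitation/inhibition): the per-test threshold is
``alpha / (2 * n_epochs)`` — 0.05/8 for the four-epoch cue-guided task.
A cell significant in at least one epoch is *responsive* and receives a
mixed-selectivity category string listing its significant epochs and
directions in canonical order, e.g. ``"C+R+P+"`` or ``"R-P-"``; the empty
string marks a nonresponsive cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pericalc.epochs import EpochRateTable
from pericalc.task import CANONICAL_EPOCHS, canonical_category

#: Numerical slack when comparing |permuted stat| with |observed stat|:
#: exact ties must count toward the tail regardless of float summation order.
_TIE_ATOL_SCALE = 1e-9


@dataclass
class PermResult:
    """Outcome of one paired permutation test (one cell, one epoch)."""

    cell_id: str
    epoch_label: str
    observed_stat: float      # mean paired difference, events/s
    p_two_tailed: float
    direction: str            # "+", "-", or "0"
    n_trials: int
    n_permutations: int
    exact: bool = False


@dataclass
class CellClass:
    """Per-cell classification: per-epoch results and the category string."""

    cell_id: str
    results: dict[str, PermResult]
    category: str

    @property
    def responsive(self) -> bool:
        return self.category != ""


def bonferroni_threshold(alpha: float, n_epochs: int) -> float:
    """Per-test threshold controlling FWER across epochs × direction.

    ``alpha / (2 * n_epochs)``: the divisor counts every epoch twice,
    once per direction of change (0.05/8 for four epochs).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    return alpha / (2 * n_epochs)


def _signflip_pvalues(diffs: np.ndarray, n_perm: int,
                      rng: np.random.Generator | None,
                      method: str = "auto") -> tuple[np.ndarray, np.ndarray, bool]:
    """Two-tailed sign-flip p-values for an (n_trials, n_epochs) matrix.

    One sign assignment per permutation round is shared across the
    epochs of the matrix (each column's marginal p is unaffected).
    Returns ``(stats, pvalues, exact)``.
    """
    n, k = diffs.shape
    if n < 2:
        raise ValueError("paired permutation test requires >= 2 trials")
    stats = diffs.mean(axis=0)
    atol = _TIE_ATOL_SCALE * (1.0 + float(np.abs(diffs).max(initial=0.0)))

    use_exact = (method == "exact"
                 or (method == "auto" and 2 ** n <= n_perm))
    if method not in ("auto", "exact", "mc"):
        raise ValueError(f"unknown method: {method!r}")

    if use_exact:
        codes = np.arange(2 ** n, dtype=np.int64)
        signs = (((codes[:, None] >> np.arange(n)) & 1) * 2 - 1).astype(float)
        null = signs @ diffs / n                       # (2**n, k)
        exceed = np.abs(null) >= np.abs(stats)[None, :] - atol
        p = exceed.mean(axis=0)
        return stats, p, True

    if rng is None:
        raise ValueError("Monte-Carlo permutation requires a seed or Generator")
    signs = rng.integers(0, 2, size=(n_perm, n)).astype(float) * 2 - 1
    null = signs @ diffs / n
    exceed = np.abs(null) >= np.abs(stats)[None, :] - atol
    p = (1 + exceed.sum(axis=0)) / (1 + n_perm)
    return stats, p, False


def paired_permutation_test(epoch_rates, baseline_rates, n_perm: int = 10_000,
                            seed=None, method: str = "auto",
                            adjusted_alpha: float | None = None,
                            cell_id: str = "", epoch_label: str = "") -> PermResult:
    """Two-tailed paired sign-flip permutation test on one rate vector pair.

    ``epoch_rates`` and ``baseline_rates`` are per-trial vectors of equal
    length n >= 2.  ``method`` is ``"auto"`` (exact enumeration when
    ``2**n <= n_perm``), ``"exact"`` or ``"mc"``.

    ``direction`` is the sign of the observed statistic; when
    ``adjusted_alpha`` is given, it is forced to ``"0"`` for
    non-significant results (``p >= adjusted_alpha``).
    """
    e = np.asarray(epoch_rates, dtype=float)
    b = np.asarray(baseline_rates, dtype=float)
    if e.shape != b.shape or e.ndim != 1:
        raise ValueError("epoch and baseline rate vectors must be equal-length 1-D")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    diffs = (e - b)[:, None]
    rng = None if seed is None else np.random.default_rng(seed)
    stats, p, exact = _signflip_pvalues(diffs, n_perm, rng, method)
    stat, pval = float(stats[0]), float(p[0])
    if stat == 0.0:
        direction = "0"
    else:
        direction = "+" if stat > 0 else "-"
    if adjusted_alpha is not None and pval >= adjusted_alpha:
        direction = "0"
    return PermResult(cell_id=cell_id, epoch_label=epoch_label,
                      observed_stat=stat, p_two_tailed=pval,
                      direction=direction, n_trials=e.size,
                      n_permutations=(2 ** e.size if exact else n_perm),
                      exact=exact)


def classify_cell(epoch_rates, baseline_rates, epoch_labels,
                  alpha: float = 0.05, n_perm: int = 10_000, seed=None,
                  method: str = "auto", cell_id: str = "") -> CellClass:
    """Classify one cell across all epochs and compose its category.

    ``epoch_rates`` is (n_trials, n_epochs); ``baseline_rates`` is the
    paired per-trial baseline vector.  All epochs share one set of
    permutation rounds (marginally exact; Bonferroni is valid under any
    dependence), which reduces the test to a single matrix product.
    """
    e = np.asarray(epoch_rates, dtype=float)
    b = np.asarray(baseline_rates, dtype=float)
    if e.ndim != 2 or e.shape[1] != len(epoch_labels):
        raise ValueError("epoch_rates must be (n_trials, n_epochs)")
    if b.shape != (e.shape[0],):
        raise ValueError("baseline_rates must be a per-trial vector")
    diffs = e - b[:, None]
    rng = None if seed is None else np.random.default_rng(seed)
    stats, pvals, exact = _signflip_pvalues(diffs, n_perm, rng, method)

    thr = bonferroni_threshold(alpha, len(epoch_labels))
    results: dict[str, PermResult] = {}
    pairs: list[tuple[str, str]] = []
    for k, lab in enumerate(epoch_labels):
        stat, p = float(stats[k]), float(pvals[k])
        if p < thr and stat != 0.0:
            direction = "+" if stat > 0 else "-"
            pairs.append((lab, direction))
        else:
            direction = "0"
        results[lab] = PermResult(
            cell_id=cell_id, epoch_label=lab, observed_stat=stat,
            p_two_tailed=p, direction=direction, n_trials=e.shape[0],
            n_permutations=(2 ** e.shape[0] if exact else n_perm),
            exact=exact)
    return CellClass(cell_id=cell_id, results=results,
                     category=canonical_category(pairs))


def classify_population(table: EpochRateTable, alpha: float = 0.05,
                        n_perm: int = 10_000, master_seed: int = 0,
                        pairing: str = "per_trial",
                        method: str = "auto") -> pd.DataFrame:
    """Classify every cell of an :class:`EpochRateTable`.

    Per-cell random streams are spawned deterministically from
    ``master_seed``, so the classification table is reproducible and
    independent of evaluation order.  Returns one row per cell with
    per-epoch p-values/directions and the composed category string.
    """
    base = table.baselines(pairing)
    children = np.random.SeedSequence(master_seed).spawn(table.n_cells)
    rows = []
    for i, cid in enumerate(table.cell_ids):
        cc = classify_cell(table.rates[i], base[i], table.epoch_labels,
                           alpha=alpha, n_perm=n_perm,
                           seed=np.random.default_rng(children[i]),
                           method=method, cell_id=cid)
        row: dict = {"cell_id": cid, "category": cc.category,
                     "responsive": cc.responsive}
        for lab in table.epoch_labels:
            r = cc.results[lab]
            row[f"p_{lab}"] = r.p_two_tailed
            row[f"dir_{lab}"] = r.direction
            row[f"stat_{lab}"] = r.observed_stat
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_epoch_counts(classes: pd.DataFrame,
                           epoch_labels) -> pd.DataFrame:
    """Counts of excited / inhibited / nonresponsive cells per epoch."""
    rows = []
    for lab in epoch_labels:
        d = classes[f"dir_{lab}"]
        rows.append({
            "epoch": lab,
            "excited": int((d == "+").sum()),
            "inhibited": int((d == "-").sum()),
            "nonresponsive": int((d == "0").sum()),
        })
    return pd.DataFrame(rows)
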