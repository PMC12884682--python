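"""Group-level population summaries and between-group comparisons.

Covers the statistics applied after per-cell classification: z-normalized
peri-event population traces, per-epoch excited/inhibited/nonresponsive
proportions compared between groups by chi-square, mixed-selectivity
category frequency tables, a two-way mixed-design (group × time) ANOVA on
the normalized traces, and per-animal Pearson correlations.

Z-normalization is per cell against its own ITI baseline: each peri-event
bin's trial-averaged event rate is centered on the cell's mean per-trial
baseline rate and scaled by the SD of the per-trial baseline rates, so a
bin sitting 2 baseline-SDs above baseline reads z ≈ 2.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from pericalc.session_io import SessionRecording
from pericalc.task import TaskSpec

logger = logging.getLogger(__name__)

_ALIGNMENT_COLUMN = {
    "response": "response_time",
    "initiation": "initiation_time",
    "reward": "reward_time",
}


def perievent_z_traces(recording: SessionRecording, trials: pd.DataFrame,
                       task: TaskSpec, alignment_event: str = "response",
                       window: tuple[float, float] = (-5.0, 10.0),
                       threshold: float = 0.0):
    """Per-cell z-normalized peri-event rate traces over correct trials.

    Returns ``(time_bins, z, kept)`` where ``z`` is cells × bins (rows of
    excluded cells dropped), ``time_bins`` are bin centers relative to the
    alignment event, and ``kept`` is the boolean mask of cells with
    positive baseline SD (zero-SD cells are excluded and logged).
    """
    col = _ALIGNMENT_COLUMN[alignment_event]
    fr = recording.frame_rate
    t0 = float(recording.frame_times[0])
    pre = int(round(-window[0] * fr))
    post = int(round(window[1] * fr))
    n_bins = pre + post
    base_len = int(round(task.baseline_duration * fr))

    events = (recording.traces > threshold).astype(float) * fr  # rate/frame

    sums = np.zeros((recording.n_cells, n_bins))
    n_used = 0
    base_rates = []  # per usable trial: per-cell baseline rate
    for row in trials.itertuples(index=False):
        if row.outcome != "correct" or not row.baseline_complete:
            continue
        t_ev = getattr(row, col)
        if not np.isfinite(t_ev):
            continue
        c = int(np.floor((t_ev - t0) * fr + 1e-9))
        if c - pre < 0 or c + post > recording.n_frames:
            continue
        b_end = int(np.floor((row.iti_end - t0) * fr + 1e-9))
        b_start = b_end - base_len
        if b_start < 0:
            continue
        sums += events[:, c - pre:c + post]
        base_rates.append(events[:, b_start:b_end].mean(axis=1))
        n_used += 1
    if n_used == 0:
        raise ValueError("no correct trial windows fall inside the recording")

    mean_trace = sums / n_used
    base = np.stack(base_rates, axis=1)          # cells × trials
    mu = base.mean(axis=1)
    sd = base.std(axis=1, ddof=1)
    kept = sd > 0
    if not np.all(kept):
        logger.info("perievent_z_traces: excluded %d cell(s) with zero "
                    "baseline SD", int((~kept).sum()))
    z = (mean_trace[kept] - mu[kept, None]) / sd[kept, None]
    time_bins = (np.arange(n_bins) - pre + 0.5) / fr
    return time_bins, z, kept


def normalized_population_trace(recording: SessionRecording,
                                trials: pd.DataFrame, task: TaskSpec,
                                alignment_event: str = "response",
                                window: tuple[float, float] = (-5.0, 10.0),
                                threshold: float = 0.0) -> pd.DataFrame:
    """Mean ± SEM z-normalized peri-event trace across a group's cells."""
    time_bins, z, _ = perievent_z_traces(recording, trials, task,
                                         alignment_event, window, threshold)
    n = z.shape[0]
    sem = z.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(z.shape[1])
    return pd.DataFrame({"time_s": time_bins, "mean_z": z.mean(axis=0),
                         "sem_z": sem, "n_cells": n})


def chi_square_2xk(counts) -> tuple[float, int, float]:
    """Pearson chi-square test of homogeneity on a 2 × k count table.

    No continuity correction (matching the uncorrected Pearson statistic);
    returns ``(statistic, df, p)``.  Zero row/column margins are an error.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2 x k contingency table")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    stat, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)


def proportion_table(classes_by_group: dict[str, pd.DataFrame],
                     epoch_labels) -> pd.DataFrame:
    """Per-epoch excited/inhibited/nonresponsive counts per group, with
    the chi-square comparison across groups for each epoch."""
    groups = list(classes_by_group)
    rows = []
    for lab in epoch_labels:
        counts = []
        for g in groups:
            d = classes_by_group[g][f"dir_{lab}"]
            counts.append([int((d == "+").sum()), int((d == "-").sum()),
                           int((d == "0").sum())])
        entry: dict = {"epoch": lab}
        for g, (exc, inh, non) in zip(groups, counts):
            entry[f"excited_{g}"] = exc
            entry[f"inhibited_{g}"] = inh
            entry[f"nonresponsive_{g}"] = non
        if len(groups) == 2:
            # Cell types absent from both groups carry no information;
            # drop them so the chi-square table has positive margins.
            arr = np.asarray(counts)
            arr = arr[:, arr.sum(axis=0) > 0]
            if arr.shape[1] >= 2:
                stat, dof, p = chi_square_2xk(arr)
            else:
                stat, dof, p = 0.0, 0, float("nan")
            entry.update(chi2=stat, df=dof, p=p)
        rows.append(entry)
    return pd.DataFrame(rows)


def category_frequencies(categories, coverage_target: float = 0.80,
                         ) -> tuple[pd.DataFrame, list[str]]:
    """Frequency table of mixed-selectivity categories among responsive cells.

    ``categories`` is an iterable of category strings (``""`` =
    nonresponsive; excluded from the denominator).  Returns the table
    sorted by descending frequency (ties broken alphabetically for
    determinism) with cumulative shares, and the minimal leading set of
    categories whose cumulative share reaches ``coverage_target``.
    """
    cats = [c for c in categories if c]
    if not cats:
        warnings.warn("no responsive cells; category table is empty")
        return (pd.DataFrame(columns=["category", "count", "share",
                                      "cumulative_share"]), [])
    vc = pd.Series(cats).value_counts()
    df = (vc.rename_axis("category").reset_index(name="count")
          .sort_values(["count", "category"], ascending=[False, True],
                       kind="stable").reset_index(drop=True))
    df["share"] = df["count"] / df["count"].sum()
    df["cumulative_share"] = df["share"].cumsum()
    n_cover = int(np.searchsorted(df["cumulative_share"].to_numpy(),
                                  coverage_target - 1e-12) + 1)
    return df, df["category"].head(n_cover).tolist()


def mixed_anova_genotype_time(z_traces: dict[str, np.ndarray]) -> pd.DataFrame:
    """Two-way mixed-design ANOVA (group × time) on per-cell traces.

    ``z_traces`` maps group label → cells × bins matrix (bins must match
    across groups; cells are the repeated-measures unit).  Returns a
    table with F and p for the between factor (group), the within factor
    (time) and their interaction.
    """
    import pingouin as pg

    groups = list(z_traces)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    n_bins = {g: z_traces[g].shape[1] for g in groups}
    if len(set(n_bins.values())) != 1:
        raise ValueError("time bins must be balanced across groups")
    frames = []
    offset = 0
    for g in groups:
        z = np.asarray(z_traces[g], dtype=float)
        if z.shape[0] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 cells")
        n_cells, nb = z.shape
        frames.append(pd.DataFrame({
            "z": z.ravel(),
            "time": np.tile(np.arange(nb), n_cells),
            "cell": np.repeat(np.arange(n_cells) + offset, nb),
            "group": g,
        }))
        offset += n_cells
    long = pd.concat(frames, ignore_index=True)
    aov = pg.mixed_anova(data=long, dv="z", within="time", subject="cell",
                         between="group")
    out = aov.rename(columns={"Source": "source", "p-unc": "p",
                              "p_unc": "p"})
    out["source"] = out["source"].replace({"group": "group",
                                           "time": "time",
                                           "Interaction": "interaction"})
    return out[["source", "DF1", "DF2", "F", "p"]]


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with two-tailed t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
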