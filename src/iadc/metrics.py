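"""Descriptive and coordination measures for contest sessions.

All operations work on tidy per-member-round tables (see :mod:`iadc.io` for
the schema) or on small arrays extracted from them. The coordination
measures follow the conventions of small-group contest experiments:

* within-group variance of the three members' contributions in a round
  (sample variance, n-1 denominator; lower = better coordinated),
* the count of non-contributing member-rounds in a 15-round block (0..45),
* the one-way random-effects intraclass correlation ICC(1), treating groups
  as classes and member-round contributions as observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DECISION_TIME_CUTOFF_S = 180.0


def within_group_variance(contributions) -> float:
    """Sample variance (denominator n-1) of one group's three contributions."""
    c = np.asarray(contributions, dtype=float)
    if c.shape != (3,):
        raise ValueError("expected exactly three member contributions")
    return float(np.var(c, ddof=1))


def count_noncontributors(block: pd.DataFrame) -> dict:
    """Count zero-contribution member-rounds in one group's block.

    Parameters
    ----------
    block : DataFrame with columns ``round`` and ``contribution`` holding one
        group's complete block (3 members x all rounds).

    Returns
    -------
    dict with ``total`` (0..45 for a 15-round block) and ``per_round``
    (Series indexed by round, values 0..3).
    """
    zero = block["contribution"] == 0
    per_round = zero.groupby(block["round"]).sum()
    return {"total": int(zero.sum()), "per_round": per_round}


def icc_group_cohesion(values: np.ndarray) -> float:
    """One-way random-effects ICC(1) over a groups x observations table.

    ``ICC(1) = (MSB - MSW) / (MSB + (k - 1) MSW)`` with k observations per
    group; groups are the classes. Requires at least two groups and equal
    group sizes. A value of 1 means members of each group are identical
    while groups differ; 0 means no within-group resemblance.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D groups x observations array")
    n_groups, k = x.shape
    if n_groups < 2:
        raise ValueError("ICC is undefined for a single group")
    if k < 2:
        raise ValueError("need at least two observations per group")
    grand = x.mean()
    group_means = x.mean(axis=1)
    msb = k * np.sum((group_means - grand) ** 2) / (n_groups - 1)
    msw = np.sum((x - group_means[:, None]) ** 2) / (n_groups * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0.0:
        return 0.0  # all observations identical: no variance to apportion
    return float((msb - msw) / denom)


def preprocess_decision_times(
    records: pd.DataFrame, cutoff_s: float = DECISION_TIME_CUTOFF_S
) -> pd.DataFrame:
    """Apply the decision-time exclusion and log10 transform.

    Rows with decision time above `cutoff_s` (or nonpositive, where the
    log is undefined) are dropped; the survivors gain ``log10_time`` and a
    ``contributed`` flag. The exclusion fraction is attached as
    ``result.attrs["excluded_fraction"]``.
    """
    t = records["decision_time_s"]
    keep = t.notna() & (t > 0) & (t <= cutoff_s)
    out = records.loc[keep].copy()
    out["log10_time"] = np.log10(out["decision_time_s"])
    out["contributed"] = out["contribution"] > 0
    n_timed = int(t.notna().sum())
    out.attrs["excluded_fraction"] = (
        float((n_timed - keep.sum()) / n_timed) if n_timed else 0.0
    )
    return out


@dataclass(frozen=True)
class ContestOutcomes:
    success_rate: float
    mean_spoils_win: float      # NaN if the group never won
    mean_leftover_loss: float   # NaN if the group never lost
    n_rounds: int


def contest_outcomes(
    g_attacker: np.ndarray, g_defender: np.ndarray, attacker_contribs: np.ndarray
) -> ContestOutcomes:
    """Attacker-side outcome summary for one group's block.

    Spoils are averaged over winning rounds only (per-member share,
    ``(60 - G_defender) / 3``); leftovers over losing rounds only (mean of
    the three members' ``20 - contribution``). Groups that never win
    propagate spoils as missing rather than zero.
    """
    ga = np.asarray(g_attacker)
    gd = np.asarray(g_defender)
    a = np.asarray(attacker_contribs, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3 or len(ga) != len(gd) != 0:
        if a.shape[0] != len(ga) or len(ga) != len(gd):
            raise ValueError("misaligned outcome arrays")
    win = ga > gd
    success = float(win.mean()) if len(win) else 0.0
    spoils = (
        float(((60 - gd[win]) / 3).mean()) if win.any() else float("nan")
    )
    lost = ~win
    leftover = (
        float((20 - a[lost]).mean()) if lost.any() else float("nan")
    )
    return ContestOutcomes(success, spoils, leftover, len(win))


def moving_average(series, window: int = 3) -> np.ndarray:
    """Centered moving average, window shrinking at the edges.

    Length-preserving; with window 3 the first and last points average two
    values. Used to smooth per-round trajectories.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot smooth an empty series")
    if window < 1:
        raise ValueError("window must be >= 1")
    half = (window - 1) // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        lo = max(0, i - half)
        hi = min(len(x), i + window - half)
        out[i] = x[lo:hi].mean()
    return out


def bootstrap_bivariate_means(
    contribution: np.ndarray,
    payment: np.ndarray,
    condition: np.ndarray,
    n_boot: int = 1000,
    resample_n: int = 40,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Bootstrap cloud of (contribution, payment) means per condition.

    For each condition label, groups are resampled with replacement at
    sample size `resample_n`, `n_boot` times; each resample contributes one
    mean pair. Mirrors the resampling illustration of bivariate treatment
    separation.
    """
    contribution = np.asarray(contribution, dtype=float)
    payment = np.asarray(payment, dtype=float)
    condition = np.asarray(condition)
    rng = np.random.default_rng(seed)
    rows = []
    for cond in pd.unique(condition):
        mask = condition == cond
        if not mask.any():
            raise ValueError(f"condition {cond!r} has no groups")
        c = contribution[mask]
        p = payment[mask]
        idx = rng.integers(0, len(c), size=(n_boot, resample_n))
        rows.append(
            pd.DataFrame(
                {
                    "condition": cond,
                    "mean_contribution": c[idx].mean(axis=1),
                    "mean_payment": p[idx].mean(axis=1),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
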