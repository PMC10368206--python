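"""Behavioral metrics: outcome labeling, d', lick thresholds and lick profiles.

The discriminability index is d' = Phi^-1(hit fraction) - Phi^-1(FA fraction),
with fractions of exactly 1 (0) clipped to 0.99 (0.01) before the inverse
normal so that perfect sessions stay finite.  Session performance is the
maximum d' over a sliding 150-trial window; hit and correct-rejection rates
are reported on that same best window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

log = logging.getLogger(__name__)

__all__ = [
    "BehaviorMetrics",
    "clip_rate",
    "dprime",
    "lick_threshold",
    "label_outcomes",
    "best_window_dprime",
    "lick_probability_profile",
    "average_profiles",
]

#: d' learning threshold used to call a session "learned".
LEARNING_THRESHOLD = 2.0


@dataclass(frozen=True)
class BehaviorMetrics:
    """Best-window performance summary of one session."""

    dprime: float
    hit_rate: float
    cr_rate: float
    window_start: int
    threshold: float | None = None


def clip_rate(p: float) -> float:
    """Clip a response fraction away from 0/1 exactly at the corners."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"fraction {p} outside [0, 1]")
    if p == 1.0:
        return 0.99
    if p == 0.0:
        return 0.01
    return p


def dprime(hit_frac: float, fa_frac: float) -> float:
    """Discriminability index from hit and false-alarm fractions."""
    return float(norm.ppf(clip_rate(hit_frac)) - norm.ppf(clip_rate(fa_frac)))


def lick_threshold(pretrial_rates) -> float:
    """Individualized lick-rate threshold: last-pretrial mean minus 1 SD.

    ``pretrial_rates`` are per-trial lick rates (licks/s) from the final
    pretrial session.  Sample SD (n-1); floored at zero.
    """
    rates = np.asarray(pretrial_rates, dtype=float)
    if rates.size < 2:
        raise ValueError("need >=2 pretrial rate observations to estimate a SD")
    return float(max(rates.mean() - rates.std(ddof=1), 0.0))


def _window_rates(licks: pd.DataFrame, trial_ids, window: tuple[float, float]):
    """Mean lick rate (licks/s) inside the response window, per trial."""
    start, end = window
    in_win = licks[(licks["time"] >= start) & (licks["time"] < end)]
    counts = in_win.groupby("trial_id").size()
    return np.array([counts.get(t, 0) / (end - start) for t in trial_ids])


def label_outcomes(
    schedule: pd.DataFrame,
    licks: pd.DataFrame,
    threshold: float,
    response_window: tuple[float, float],
) -> pd.DataFrame:
    """Label each trial Hit/Miss (preferred) or FA/CR (nonpreferred).

    A trial counts as a response when its mean lick rate over the response
    window reaches ``threshold`` (licks/s).
    """
    if not schedule["stimulus"].isin(["P", "NP"]).all():
        raise ValueError("schedule contains unlabeled stimulus entries")
    rates = _window_rates(licks, schedule["trial_id"].to_numpy(), response_window)
    responded = rates >= threshold
    is_p = (schedule["stimulus"] == "P").to_numpy()
    outcome = np.where(
        is_p,
        np.where(responded, "Hit", "Miss"),
        np.where(responded, "FA", "CR"),
    )
    out = schedule.copy()
    out["outcome"] = outcome
    out.attrs.update(schedule.attrs)
    out.attrs["threshold"] = float(threshold)
    return out


def _rates_from_counts(n_hit, n_miss, n_fa, n_cr):
    n_p, n_np = n_hit + n_miss, n_fa + n_cr
    if n_p == 0 or n_np == 0:
        return None
    return n_hit / n_p, n_fa / n_np


def best_window_dprime(outcomes: pd.DataFrame, window: int = 150) -> BehaviorMetrics:
    """Maximum d' over all contiguous trial windows of the given length.

    Hit and CR rates are computed on the same best window.  Ties resolve to
    the earliest window; windows missing one stimulus class entirely are
    skipped.
    """
    n = len(outcomes)
    if n < window:
        raise ValueError(f"session has {n} trials; need at least {window}")
    oc = outcomes["outcome"].to_numpy()
    ind = {k: np.concatenate([[0], np.cumsum(oc == k)]) for k in ("Hit", "Miss", "FA", "CR")}
    best = None
    for s in range(n - window + 1):
        e = s + window
        counts = {k: ind[k][e] - ind[k][s] for k in ind}
        rates = _rates_from_counts(
            counts["Hit"], counts["Miss"], counts["FA"], counts["CR"]
        )
        if rates is None:
            continue
        hit_frac, fa_frac = rates
        d = dprime(hit_frac, fa_frac)
        if best is None or d > best.dprime:
            best = BehaviorMetrics(
                dprime=d,
                hit_rate=float(hit_frac),
                cr_rate=float(1.0 - fa_frac),
                window_start=s,
            )
    if best is None:
        raise ValueError("no window contains both stimulus classes")
    return best


def lick_probability_profile(
    licks: pd.DataFrame,
    outcomes: pd.DataFrame,
    group_by: list[str],
    horizon: float = 2.0,
    bin_width: float = 0.1,
) -> pd.DataFrame:
    """Per-bin lick probability for one mouse, per trial group.

    Probability in a bin is the fraction of the group's trials with at least
    one lick in that 0.1 s bin.  Groups with no trials are dropped with a
    warning (e.g. Miss trials, which are rare in trained animals).
    Returns a long table (group columns, bin_left, probability).
    """
    n_bins = int(np.floor(horizon / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    rows = []
    for keys, grp in outcomes.groupby(group_by, observed=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        ids = grp["trial_id"].to_numpy()
        if ids.size == 0:
            log.warning("empty trial group %s dropped", dict(zip(group_by, keys)))
            continue
        sub = licks[licks["trial_id"].isin(ids)]
        # trials x bins lick-present matrix
        hit_any = np.zeros((ids.size, n_bins), dtype=bool)
        pos = {t: i for i, t in enumerate(ids)}
        b = np.floor(sub["time"].to_numpy() / bin_width).astype(int)
        ok = (b >= 0) & (b < n_bins)
        for t, bb in zip(sub["trial_id"].to_numpy()[ok], b[ok]):
            hit_any[pos[t], bb] = True
        prob = hit_any.mean(axis=0)
        for bl, p in zip(edges[:-1], prob):
            rows.append(dict(zip(group_by, keys)) | {"bin_left": bl, "probability": p})
    return pd.DataFrame(rows)


def average_profiles(profiles: list[pd.DataFrame], group_by: list[str]) -> pd.DataFrame:
    """Average per-mouse probability curves across mice (never pooled trials)."""
    stacked = pd.concat(profiles, ignore_index=True)
    return (
        stacked.groupby(group_by + ["bin_left"], observed=True)["probability"]
        .mean()
        .reset_index()
    )
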