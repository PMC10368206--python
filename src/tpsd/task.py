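"""Task structure for the temporal-pattern go/no-go discrimination paradigm.

Two audiovisual rhythms are presented that differ only in temporality: a
preferred (rewarded, "go") pattern and a nonpreferred (unrewarded, "no-go")
pattern, each a train of identical audiovisual pulses separated by fixed
silent/gray gaps.  Time is trial-relative: t = 0 at the onset of the first
intra-trial stimulus.  This module builds stimulus timelines, binary
stimulus-on indicators, randomized session schedules and exposure totals for
the main paradigm, its duration-matched variant, and the stimulus-off control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TaskVariant",
    "StimulusTimeline",
    "TPSD",
    "TPSD_MOD",
    "CONTROL",
    "VARIANTS",
    "build_timeline",
    "stimulus_indicator",
    "build_session_schedule",
    "total_stimulus_exposure",
]

STIMULI = ("P", "NP")
STAGES = ("naive", "learned", "pretrial")
OUTCOMES = ("Hit", "Miss", "CR", "FA", "unlabeled")


@dataclass(frozen=True)
class TaskVariant:
    """Parameters of one task paradigm.

    ``n_intra`` and ``stim_dur`` are per-pattern: the preferred and
    nonpreferred rhythms may differ in both pulse count and pulse duration.
    All times are seconds, trial-relative.
    """

    name: str
    n_intra: dict[str, int]
    stim_dur: dict[str, float]
    gap_dur: float
    reward_time: float
    response_window: tuple[float, float]
    timeout_range: tuple[float, float] = (6.5, 8.0)
    iti: float = 4.0
    stimulus_on: bool = True  # False for the monitor/speaker-off control

    def __post_init__(self) -> None:
        for stim in STIMULI:
            if stim not in self.n_intra or stim not in self.stim_dur:
                raise ValueError(f"variant {self.name!r} missing pattern {stim!r}")
            if self.n_intra[stim] < 1 or self.stim_dur[stim] <= 0:
                raise ValueError("pulse count must be >=1 and duration positive")
        if self.gap_dur < 0:
            raise ValueError("gap duration must be non-negative")

    def pattern_duration(self, stimulus: str) -> float:
        """Total pattern duration: n pulses plus the n-1 interleaved gaps."""
        _check_stimulus(stimulus)
        n = self.n_intra[stimulus]
        return n * self.stim_dur[stimulus] + (n - 1) * self.gap_dur


# Main paradigm: four 0.2 s pulses (go) vs four 0.9 s pulses (no-go),
# 0.2 s gaps, reward at 1.2 s, response window 1-2 s.
TPSD = TaskVariant(
    name="TPSD",
    n_intra={"P": 4, "NP": 4},
    stim_dur={"P": 0.2, "NP": 0.9},
    gap_dur=0.2,
    reward_time=1.2,
    response_window=(1.0, 2.0),
)

# Duration-matched variant with inverted preference: three 733 ms pulses (go)
# vs seven 200 ms pulses (no-go); both patterns total 2.6 s. Reward at 2.3 s,
# response window 2-3.2 s.
TPSD_MOD = TaskVariant(
    name="TPSD_mod",
    n_intra={"P": 3, "NP": 7},
    stim_dur={"P": 0.733, "NP": 0.2},
    gap_dur=0.2,
    reward_time=2.3,
    response_window=(2.0, 3.2),
)

# Control: identical schedule/timing but monitor and speaker off.
CONTROL = TaskVariant(
    name="control",
    n_intra={"P": 4, "NP": 4},
    stim_dur={"P": 0.2, "NP": 0.9},
    gap_dur=0.2,
    reward_time=1.2,
    response_window=(1.0, 2.0),
    stimulus_on=False,
)

VARIANTS: dict[str, TaskVariant] = {v.name: v for v in (TPSD, TPSD_MOD, CONTROL)}


@dataclass(frozen=True)
class StimulusTimeline:
    """On/off epochs of one pattern presentation, trial-relative seconds."""

    epochs: tuple[tuple[float, float], ...]  # (onset, offset) of on-epochs
    total_duration: float
    active: bool = True  # False => indicator is all-off (control)

    def __post_init__(self) -> None:
        prev_off = -math.inf
        for on, off in self.epochs:
            if off <= on:
                raise ValueError("epoch offset must exceed onset")
            if on < prev_off:
                raise ValueError("epochs must be sorted and non-overlapping")
            prev_off = off


def _check_stimulus(stimulus: str) -> None:
    if stimulus not in STIMULI:
        raise ValueError(f"unknown stimulus {stimulus!r}; expected one of {STIMULI}")


def _resolve_variant(variant: TaskVariant | str) -> TaskVariant:
    if isinstance(variant, str):
        try:
            return VARIANTS[variant]
        except KeyError:
            raise ValueError(f"unknown variant {variant!r}") from None
    return variant


def build_timeline(variant: TaskVariant | str, stimulus: str) -> StimulusTimeline:
    """Construct the on/off epoch sequence of one pattern.

    Epochs alternate on/gap starting and ending with an on-pulse; there is no
    leading gap, so the total duration is ``n*dur + (n-1)*gap``.
    """
    variant = _resolve_variant(variant)
    _check_stimulus(stimulus)
    n, dur, gap = variant.n_intra[stimulus], variant.stim_dur[stimulus], variant.gap_dur
    epochs = []
    t = 0.0
    for i in range(n):
        epochs.append((t, t + dur))
        t += dur + (gap if i < n - 1 else 0.0)
    return StimulusTimeline(
        epochs=tuple(epochs), total_duration=t, active=variant.stimulus_on
    )


def stimulus_indicator(
    timeline: StimulusTimeline, bin_width: float, horizon: float
) -> np.ndarray:
    """Binary per-bin stimulus indicator: 1 where the stimulus is on, 0 off.

    Bins are half-open ``[t, t+bin_width)``; a bin counts as "on" when its
    midpoint falls inside an on-epoch.  The control timeline yields all zeros.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if horizon < timeline.total_duration - 1e-9:
        raise ValueError("horizon must cover the full pattern duration")
    n_bins = math.ceil(horizon / bin_width)
    out = np.zeros(n_bins, dtype=np.int8)
    if not timeline.active:
        return out
    mids = (np.arange(n_bins) + 0.5) * bin_width
    for on, off in timeline.epochs:
        out[(mids >= on) & (mids < off)] = 1
    return out


def build_session_schedule(
    variant: TaskVariant | str,
    n_trials: int,
    ratio: float,
    seed: int | np.random.Generator,
    stage: str = "naive",
) -> pd.DataFrame:
    """Randomized trial schedule with an exact preferred-trial count.

    ``ratio`` is the preferred fraction (0.7 in the main task, 0.6 in the
    ratio-control sessions); the preferred count is round-half-up of
    ``n_trials * ratio`` and the order is a seeded permutation.
    """
    variant = _resolve_variant(variant)
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    rng = np.random.default_rng(seed)
    n_p = int(math.floor(n_trials * ratio + 0.5))
    stim = np.array(["P"] * n_p + ["NP"] * (n_trials - n_p), dtype=object)
    rng.shuffle(stim)
    table = pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "stimulus": stim,
            "stage": stage,
            "outcome": "unlabeled",
        }
    )
    table.attrs["variant"] = variant.name
    table.attrs["ratio"] = float(ratio)
    return table


def total_stimulus_exposure(
    schedule: pd.DataFrame, variant: TaskVariant | str
) -> dict[str, float]:
    """Seconds of total pattern exposure per stimulus type over a session."""
    variant = _resolve_variant(variant)
    counts = schedule["stimulus"].value_counts() if len(schedule) else {}
    return {
        stim: float(counts.get(stim, 0)) * variant.pattern_duration(stim)
        for stim in STIMULI
    }
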