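"""Synthetic session generator: lick trains and deconvolved spike rasters.

No recordings from the study are deposited, so every downstream stage is
exercised on surrogate data with the statistical structure the analysis
assumes:

* licking is an inhomogeneous Bernoulli point process on the 250 Hz lickport
  clock, with naive profiles that lick indiscriminately (plus reward
  consumption) and learned profiles that ramp toward the reward on preferred
  trials and suppress licking on nonpreferred trials from ~0.7 s;
* spiking is Bernoulli per 1/15 s frame with a rate combining a baseline,
  a stimulus-locked drive during preferred-pattern on-epochs (learned stage),
  a decaying suppression factor on learned nonpreferred trials, and a lick
  coupling for planted lick-modulated cells.

Suppression onset on a nonpreferred trial follows that trial's behavior:
trials where licking is withheld suppress from 0.7 s, impulsive (false-alarm
style) trials suppress late (1.4 s), emulating the report that correct
rejections suppress early while false alarms predictively code the preferred
stimulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .raster import FRAME_RATE, SpikeRaster
from .task import VARIANTS, build_timeline, build_session_schedule, stimulus_indicator

__all__ = [
    "LICK_CLOCK_HZ",
    "BehaviorProfile",
    "PopulationSpec",
    "FixtureConfig",
    "SessionBundle",
    "simulate_licking",
    "simulate_population",
    "make_fixture",
]

LICK_CLOCK_HZ = 250.0


class BehaviorProfile(BaseModel):
    """Licking-rate model for one training stage.

    Rates are licks/s on the 250 Hz grid.  ``stim_gain_P`` scales the ramp
    toward the reward on engaged preferred trials; ``stim_gain_NP`` is the
    residual rate multiplier after lick suppression on learned nonpreferred
    trials.  The study reports no quantitative lick rates; defaults are free
    parameters of the generator, not claims about the animals.
    """

    model_config = ConfigDict(extra="forbid")

    stage: str = "learned"
    base_rate: float = 4.0
    stim_gain_P: float = 2.5
    stim_gain_NP: float = 0.1
    suppression_onset: float = 0.7
    ramp_start: float = 0.3
    reward_time: float = 1.2
    reward_gain: float = 1.5  # naive consumption licking after the reward
    lapse_prob: float = 0.05  # learned preferred trials with no engagement
    impulsive_prob: float = 0.15  # learned nonpreferred trials without suppression
    lapse_gain: float = 0.2
    refractory: float = 0.07  # s; licking is rhythmic at <= ~14 Hz

    @model_validator(mode="after")
    def _check(self) -> "BehaviorProfile":
        if self.stage not in ("naive", "learned"):
            raise ValueError("stage must be 'naive' or 'learned'")
        for name in ("base_rate", "stim_gain_P", "stim_gain_NP", "reward_gain", "lapse_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.stage == "learned" and not self.stim_gain_NP < self.stim_gain_P:
            raise ValueError("learned profile requires stim_gain_NP < stim_gain_P")
        return self


class PopulationSpec(BaseModel):
    """Generator parameters for one imaged population.

    ``n_cells=None`` draws the population size from the across-animal
    distribution N(108, 39.2), truncated below at 10 cells.  The frame rate
    is fixed at 15 Hz (deconvolved two-photon frames).
    """

    model_config = ConfigDict(extra="forbid")

    stage: str = "learned"
    n_cells: int | None = None
    fraction_stim_locked: float = 0.35
    fraction_lick_cells: float = 0.1
    lick_coupling: float = 0.8
    suppression_onset: float = 0.7
    delayed_onset: float = 1.4
    suppression_tau: float = 0.25
    baseline_p: float = 0.06  # spike probability per 1/15 s frame
    stim_drive: float = 2.0  # multiplicative drive during on-epochs (learned)
    max_p: float = 0.95

    frame_rate: float = Field(default=FRAME_RATE, frozen=True)

    @model_validator(mode="after")
    def _check(self) -> "PopulationSpec":
        if self.stage not in ("naive", "learned"):
            raise ValueError("stage must be 'naive' or 'learned'")
        for name in ("fraction_stim_locked", "fraction_lick_cells", "lick_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.baseline_p <= self.max_p <= 1.0:
            raise ValueError("need 0 <= baseline_p <= max_p <= 1")
        if self.frame_rate != FRAME_RATE:
            raise ValueError("frame rate is fixed at 15 Hz")
        return self

    def draw_n_cells(self, rng: np.random.Generator) -> int:
        if self.n_cells is not None:
            if self.n_cells < 1:
                raise ValueError("n_cells must be positive")
            return self.n_cells
        while True:  # truncated N(108, 39.2)
            n = int(round(rng.normal(108.0, 39.2)))
            if n >= 10:
                return n


def _lick_rate_curve(t: np.ndarray, stimulus: str, kind: str, prof: BehaviorProfile) -> np.ndarray:
    """Instantaneous lick rate (licks/s) on the time grid for one trial."""
    base = prof.base_rate
    if prof.stage == "naive":
        rate = np.full_like(t, base)
        if stimulus == "P":  # consumption licking at the chance-encountered reward
            rate[t >= prof.reward_time] = base * prof.reward_gain
        return rate
    # learned stage
    ramp = np.clip(
        (t - prof.ramp_start) / max(prof.suppression_onset - prof.ramp_start, 1e-9),
        0.0,
        1.0,
    )
    engaged = base * (1.0 + (prof.stim_gain_P - 1.0) * ramp)
    if kind == "lapse":
        return np.full_like(t, base * prof.lapse_gain)
    if stimulus == "P" or kind == "impulsive":
        return engaged
    # withheld nonpreferred trial: engaged approach, then suppression
    rate = engaged.copy()
    rate[t >= prof.suppression_onset] = base * prof.stim_gain_NP
    return rate


def simulate_licking(
    schedule: pd.DataFrame,
    profile: BehaviorProfile,
    seed: int | np.random.Generator,
    horizon: float = 2.0,
) -> pd.DataFrame:
    """Draw lick trains for every trial on the 250 Hz lickport clock.

    Returns a long table (trial_id, time) with timestamps in trial-relative
    seconds, sorted and unique at clock resolution.

    Licking is a renewal process with a refractory dead time: the tick-wise
    hazard is inflated to ``r / (1 - r * refractory)`` so the requested rate
    is the mean rate, and no two licks fall within the refractory period.
    This reproduces the quasi-rhythmic structure of real licking.
    """
    rng = np.random.default_rng(seed)
    n_ticks = int(math.floor(horizon * LICK_CLOCK_HZ))
    t = np.arange(n_ticks) / LICK_CLOCK_HZ
    t_ref = profile.refractory
    rows_id, rows_t = [], []
    for tid, stim in zip(schedule["trial_id"], schedule["stimulus"]):
        kind = "engaged"
        if profile.stage == "learned":
            u = rng.random()
            if stim == "P" and u < profile.lapse_prob:
                kind = "lapse"
            elif stim == "NP" and u < profile.impulsive_prob:
                kind = "impulsive"
        rate = _lick_rate_curve(t, stim, kind, profile)
        hazard = rate / np.clip(1.0 - rate * t_ref, 1.0 / 20.0, None)
        p = np.clip(hazard / LICK_CLOCK_HZ, 0.0, 1.0)
        cand = t[rng.random(n_ticks) < p]
        events = []
        last = -np.inf
        for tc in cand:  # enforce the dead time
            if tc - last >= t_ref:
                events.append(tc)
                last = tc
        events = np.asarray(events)
        rows_id.append(np.full(events.size, tid))
        rows_t.append(events)
    return pd.DataFrame(
        {
            "trial_id": np.concatenate(rows_id) if rows_id else np.array([], dtype=int),
            "time": np.concatenate(rows_t) if rows_t else np.array([]),
        }
    )


def _bin_lick_presence(
    licks: pd.DataFrame, trial_ids: np.ndarray, n_bins: int, bin_width: float
) -> np.ndarray:
    """bins x trials boolean matrix: any lick in the frame bin."""
    out = np.zeros((n_bins, trial_ids.size), dtype=bool)
    pos = {t: i for i, t in enumerate(trial_ids)}
    b = np.floor(licks["time"].to_numpy() / bin_width).astype(int)
    ok = (b >= 0) & (b < n_bins) & licks["trial_id"].isin(trial_ids).to_numpy()
    for tid, bb in zip(licks["trial_id"].to_numpy()[ok], b[ok]):
        out[bb, pos[tid]] = True
    return out


def simulate_population(
    schedule: pd.DataFrame,
    spec: PopulationSpec,
    licks: pd.DataFrame | None,
    seed: int | np.random.Generator,
    horizon: float = 2.0,
    response_window: tuple[float, float] = (1.0, 2.0),
) -> SpikeRaster:
    """Draw a binary spike raster (cells x frames x trials) at 15 Hz."""
    rng = np.random.default_rng(seed)
    if spec.fraction_lick_cells > 0 and licks is None:
        raise ValueError("lick trains required when fraction_lick_cells > 0")
    bin_width = 1.0 / FRAME_RATE
    n_bins = int(math.floor(horizon * FRAME_RATE))
    n_trials = len(schedule)
    trial_ids = schedule["trial_id"].to_numpy()
    n_cells = spec.draw_n_cells(rng)

    # cell roles: planted lick-coupled cells, then stimulus-locked cells
    order = rng.permutation(n_cells)
    n_lick = int(round(spec.fraction_lick_cells * n_cells))
    n_stim = int(round(spec.fraction_stim_locked * n_cells))
    lick_mask = np.zeros(n_cells, dtype=bool)
    lick_mask[order[:n_lick]] = True
    stim_mask = np.zeros(n_cells, dtype=bool)
    stim_mask[order[n_lick : n_lick + n_stim]] = True

    variant = VARIANTS.get(schedule.attrs.get("variant", "TPSD"), VARIANTS["TPSD"])
    ind = stimulus_indicator(
        build_timeline(variant, "P"), bin_width, max(horizon, variant.pattern_duration("P"))
    )[:n_bins].astype(float)

    if licks is not None and len(licks):
        unknown = np.setdiff1d(licks["trial_id"].unique(), trial_ids)
        if unknown.size:
            raise ValueError("lick trains reference trials absent from the schedule")
    lick_present = (
        _bin_lick_presence(licks, trial_ids, n_bins, bin_width)
        if licks is not None
        else np.zeros((n_bins, n_trials), dtype=bool)
    )

    t = np.arange(n_bins) * bin_width
    is_np = (schedule["stimulus"] == "NP").to_numpy()

    # per-trial suppression factor (bins x trials), learned stage only
    suppression = np.ones((n_bins, n_trials))
    if spec.stage == "learned":
        lo, hi = response_window
        win = (t >= lo) & (t < hi)
        window_licks = lick_present[win].sum(axis=0)
        for j in np.flatnonzero(is_np):
            onset = spec.delayed_onset if window_licks[j] >= 2 else spec.suppression_onset
            late = t >= onset
            suppression[late, j] = np.exp(-(t[late] - onset) / spec.suppression_tau)

    drive = np.ones(n_bins)
    if spec.stage == "learned":
        drive = 1.0 + spec.stim_drive * ind

    p = np.empty((n_cells, n_bins, n_trials))
    base = np.full((n_bins, n_trials), spec.baseline_p)
    for c in range(n_cells):
        if lick_mask[c]:
            p[c] = spec.baseline_p + spec.lick_coupling * (
                spec.max_p - spec.baseline_p
            ) * lick_present
        else:
            rate = base * (drive[:, None] if stim_mask[c] else 1.0)
            p[c] = rate * suppression
    np.clip(p, 0.0, spec.max_p, out=p)
    activity = (rng.random(p.shape) < p).astype(np.uint8)
    return SpikeRaster(
        activity=activity,
        bin_width=bin_width,
        lick_flags=lick_mask,
        stim_locked=stim_mask,
        trial_ids=trial_ids,
    )


class FixtureConfig(BaseModel):
    """Full parameter set of one synthetic session."""

    model_config = ConfigDict(extra="forbid")

    variant: str = "TPSD"
    stage: str = "learned"
    n_trials: int = 250
    ratio: float = 0.7
    horizon: float = 2.0
    threshold: float = 3.0  # licks/s in the response window
    profile: BehaviorProfile | None = None
    population: PopulationSpec | None = None

    @model_validator(mode="after")
    def _fill(self) -> "FixtureConfig":
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.profile is None:
            self.profile = BehaviorProfile(stage=self.stage)
        if self.population is None:
            self.population = PopulationSpec(stage=self.stage)
        if self.profile.stage != self.stage or self.population.stage != self.stage:
            raise ValueError("profile/population stage must match fixture stage")
        return self


@dataclass
class SessionBundle:
    """Self-consistent synthetic session: schedule, licks, raster, truth."""

    schedule: pd.DataFrame  # outcomes left "unlabeled"; labeling is behavior's job
    licks: pd.DataFrame
    raster: SpikeRaster
    config: FixtureConfig
    seed: int

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.schedule.to_csv(out / "trials.csv", index=False)
        self.licks.to_csv(out / "licks.csv", index=False)
        self.raster.to_hdf5(out / "raster.h5")
        echo = self.config.model_dump()
        echo["seed"] = self.seed
        (out / "config.yaml").write_text(yaml.safe_dump(echo, sort_keys=False))

    @classmethod
    def load(cls, in_dir) -> "SessionBundle":
        p = Path(in_dir)
        echo = yaml.safe_load((p / "config.yaml").read_text())
        seed = echo.pop("seed")
        return cls(
            schedule=pd.read_csv(p / "trials.csv"),
            licks=pd.read_csv(p / "licks.csv"),
            raster=SpikeRaster.from_hdf5(p / "raster.h5"),
            config=FixtureConfig.model_validate(echo),
            seed=seed,
        )


def make_fixture(config: FixtureConfig | dict, seed: int) -> SessionBundle:
    """Generate one synthetic session from a validated config.

    One master seed spawns independent child streams for the schedule, the
    lick trains and the population, so stages are individually reproducible.
    """
    if isinstance(config, dict):
        config = FixtureConfig.model_validate(config)
    ss = np.random.SeedSequence(seed)
    s_sched, s_lick, s_pop = ss.spawn(3)
    schedule = build_session_schedule(
        config.variant, config.n_trials, config.ratio, np.random.default_rng(s_sched),
        stage=config.stage,
    )
    licks = simulate_licking(
        schedule, config.profile, np.random.default_rng(s_lick), horizon=config.horizon
    )
    variant = VARIANTS[config.variant]
    raster = simulate_population(
        schedule,
        config.population,
        licks,
        np.random.default_rng(s_pop),
        horizon=config.horizon,
        response_window=variant.response_window,
    )
    return SessionBundle(
        schedule=schedule, licks=licks, raster=raster, config=config, seed=seed
    )
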