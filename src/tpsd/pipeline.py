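"""End-to-end orchestration: simulate -> label -> behavior -> lick-cell
removal -> decoding -> dynamics, with seeded provenance and a hashed output
manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import behavior, decoding, dynamics, lick_cells, synth, task

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run", "DEMO", "PAPER_SCALE"]


class DecodeParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_machines_licking: int = 10_000
    n_machines_imaging: int = 1_000
    n_control: int = 200
    score_machines: int = 2  # selection machines per response-window bin
    n_select: int = 20
    bootstrap_iters: int = 1000


class StageToggles(BaseModel):
    model_config = ConfigDict(extra="forbid")

    behavior: bool = True
    lickcells: bool = True
    decode: bool = True
    dynamics: bool = True


class RunConfig(BaseModel):
    """Fully serializable run description; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    fixture: synth.FixtureConfig = synth.FixtureConfig()
    decode: DecodeParams = DecodeParams()
    stages: StageToggles = StageToggles()
    out_dir: str = "results/run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


#: Desk-scale preset: small population, few machines, minutes not hours.
DEMO = RunConfig(
    fixture=synth.FixtureConfig(
        n_trials=160,
        population=synth.PopulationSpec(stage="learned", n_cells=30),
    ),
    decode=DecodeParams(
        n_machines_licking=100, n_machines_imaging=50, n_control=100,
        score_machines=1, bootstrap_iters=200,
    ),
)

#: Defaults at the scale of the original analyses.
PAPER_SCALE = RunConfig()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig | dict, seed: int = 0, out_dir=None) -> dict:
    """Execute the configured stages and write tables, manifest and summary.

    Idempotent under identical config + seed; each output is listed in the
    manifest with its content hash.  Returns the machine-readable summary.
    """
    if isinstance(config, dict):
        config = RunConfig.model_validate(config)
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": seed}
    timings: dict[str, float] = {}
    variant = task.VARIANTS[config.fixture.variant]
    ss = np.random.SeedSequence(seed)
    seeds = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("fixture", "lickcells", "decode", "dynamics"), ss.spawn(4)
        )
    }

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s started", name)

            def __exit__(self, et, ev, tb):
                timings[name] = time.perf_counter() - self.t0
                if ev is not None and not isinstance(ev, PipelineError):
                    raise PipelineError(name, ev) from ev
                log.info("stage %s done in %.1f s", name, timings[name])

        return _Ctx()

    with stage("simulate"):
        bundle = synth.make_fixture(config.fixture, seed)
        bundle.save(out / "fixture")

    with stage("label"):
        outcomes = behavior.label_outcomes(
            bundle.schedule, bundle.licks, config.fixture.threshold,
            variant.response_window,
        )
        outcomes.to_csv(out / "outcomes.csv", index=False)

    if config.stages.behavior:
        with stage("behavior"):
            window = min(150, len(outcomes))
            metrics = behavior.best_window_dprime(outcomes, window=window)
            summary["behavior"] = {
                "dprime": metrics.dprime,
                "hit_rate": metrics.hit_rate,
                "cr_rate": metrics.cr_rate,
                "window_start": metrics.window_start,
                "threshold": config.fixture.threshold,
            }
            pd.DataFrame([summary["behavior"]]).to_csv(
                out / "behavior_metrics.csv", index=False
            )
            profile = behavior.lick_probability_profile(
                bundle.licks, outcomes, ["stimulus", "outcome"],
                horizon=config.fixture.horizon,
            )
            profile.to_csv(out / "lick_probability.csv", index=False)

    raster = bundle.raster
    if config.stages.lickcells:
        with stage("lickcells"):
            scores = lick_cells.score_cells(
                raster, outcomes, variant.response_window,
                n_select=min(config.decode.n_select, raster.n_cells),
                n_machines=config.decode.score_machines,
                seed=seeds["lickcells"],
            )
            admission = lick_cells.admit_session(scores)
            flagged = lick_cells.flag_lick_cells(scores, admission)
            scores.table.assign(flagged=scores.table["cell"].isin(flagged)).to_csv(
                out / "lick_cell_scores.csv", index=False
            )
            summary["lick_cells"] = {
                "admitted": admission.admitted,
                "r": admission.r,
                "p": admission.p,
                "flagged": sorted(flagged),
            }
            raster = lick_cells.remove_cells(raster, flagged)

    if config.stages.decode:
        with stage("decode"):
            y = (outcomes["stimulus"] == "P").astype(int).to_numpy()
            lick_feats = decoding.bin_licks(
                bundle.licks, outcomes["trial_id"], config.fixture.horizon
            )
            lick_curve = decoding.bootstrap_svm_curve(
                lick_feats, y, n_machines=config.decode.n_machines_licking,
                seed=seeds["decode"], with_control=True,
                control_machines=config.decode.n_control,
            )
            lick_curve.to_frame().to_csv(out / "decoding_licks.csv", index=False)
            neural_feats = decoding.raster_features(raster)
            neural_curve = decoding.bootstrap_svm_curve(
                neural_feats, y, n_machines=config.decode.n_machines_imaging,
                seed=seeds["decode"], with_control=True,
                control_machines=config.decode.n_control,
            )
            neural_curve.to_frame().to_csv(out / "decoding_neural.csv", index=False)
            _, hi = lick_curve.control.band()
            above = np.flatnonzero(lick_curve.mean > hi)
            summary["decoding"] = {
                "lick_peak_accuracy": float(lick_curve.mean.max()),
                "lick_onset_s": (
                    float(lick_curve.bin_times[above[0]]) if above.size else None
                ),
                "neural_peak_accuracy": float(neural_curve.mean.max()),
            }

    if config.stages.dynamics:
        with stage("dynamics"):
            rng = seeds["dynamics"]
            oc = outcomes["outcome"].to_numpy()
            frames = []
            for label in ("Hit", "Miss", "CR", "FA"):
                mask = oc == label
                if not mask.any():
                    continue
                s = dynamics.bootstrap_mean_activity(
                    raster, mask, n_iter=config.decode.bootstrap_iters,
                    seed=rng, condition=label,
                )
                frames.append(s.to_frame())
            pd.concat(frames, ignore_index=True).to_csv(
                out / "network_activity.csv", index=False
            )
            ind = task.stimulus_indicator(
                task.build_timeline(variant, "P"), raster.bin_width,
                config.fixture.horizon,
            )[: raster.n_bins]
            full = dynamics.bootstrap_mean_activity(
                raster, None, n_iter=config.decode.bootstrap_iters, seed=rng
            )
            r, p = dynamics.stimulus_correlation(full, ind)
            period = (0.0, min(variant.pattern_duration("P"), config.fixture.horizon))
            dists = {
                label: dynamics.peak_times(raster, oc == label, period, label)
                for label in ("Hit", "CR", "FA")
                if (oc == label).any()
            }
            names = sorted(dists)
            pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
            ks = dynamics.compare_peak_distributions(dists, pairs)
            ks.to_csv(out / "peak_time_ks.csv", index=False)
            order = dynamics.sort_by_peak_time(raster.activity.mean(axis=2))
            np.savetxt(out / "heatmap_order.csv", order, fmt="%d")
            traj = dynamics.outcome_trajectories(raster, outcomes)
            summary["dynamics"] = {
                "stimulus_correlation_r": r,
                "stimulus_correlation_p": p,
                "variance_explained_pct": traj.variance_explained.tolist(),
                "divergence": {
                    f"{a}-{b}": traj.divergence(a, b)
                    for a, b in (("Hit", "CR"), ("Hit", "FA"))
                    if a in traj.trajectories and b in traj.trajectories
                },
            }

    # timings go to the log only: the summary must be bit-identical on rerun
    log.info("stage timings (s): %s", {k: round(v, 3) for k, v in timings.items()})
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    manifest = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary
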