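"""Population-dynamics summaries: bootstrap network activity, stimulus
correlation, peak-time distributions, time-sorted orderings and PCA
trajectories.

Mean network activity per condition is estimated by a trial bootstrap
(resample trials with replacement, average over cells and trials per bin);
per-mouse iteration sets pool into one grand distribution, from which the
mean curve and a 95% percentile band are read.  Peak-time (maximum spiking)
distributions per cell are compared across conditions with two-sample KS
tests under a Bonferroni-adjusted family alpha.  Trajectories are the first
three principal components of trial-averaged outcome activity, fitted on the
concatenated (outcome x bin) observations over the cell dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp, pearsonr
from sklearn.decomposition import PCA

from .raster import SpikeRaster

__all__ = [
    "NetworkSummary",
    "PeakTimeDist",
    "TrajectorySet",
    "bootstrap_mean_activity",
    "pool_summaries",
    "stimulus_correlation",
    "peak_times",
    "compare_peak_distributions",
    "sort_by_peak_time",
    "outcome_trajectories",
]


@dataclass
class NetworkSummary:
    """Bootstrap distribution of mean network activity per time bin."""

    bin_times: np.ndarray
    iterations: np.ndarray  # (n_iter, n_bins)
    condition: str = ""

    @property
    def n_iterations(self) -> int:
        return self.iterations.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.iterations.mean(axis=0)

    def ci(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        lo = (1.0 - level) / 2.0
        return (
            np.quantile(self.iterations, lo, axis=0),
            np.quantile(self.iterations, 1.0 - lo, axis=0),
        )

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.ci()
        return pd.DataFrame(
            {
                "bin_time": self.bin_times,
                "mean_activity": self.mean,
                "ci_lo": lo,
                "ci_hi": hi,
                "condition": self.condition,
            }
        )


@dataclass
class PeakTimeDist:
    """Per-cell time of maximum trial-averaged activity within a period."""

    times: np.ndarray  # seconds, one per cell
    period: tuple[float, float]
    condition: str = ""


@dataclass
class TrajectorySet:
    """Outcome trajectories in principal-component space."""

    trajectories: dict[str, np.ndarray]  # outcome -> (n_bins, n_components)
    variance_explained: np.ndarray  # percent per component
    bin_times: np.ndarray

    def divergence(self, a: str, b: str) -> float:
        """Mean Euclidean distance between two outcome trajectories."""
        ta, tb = self.trajectories[a], self.trajectories[b]
        return float(np.linalg.norm(ta - tb, axis=1).mean())


def bootstrap_mean_activity(
    raster: SpikeRaster,
    trial_mask=None,
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
    condition: str = "",
) -> NetworkSummary:
    """Trial-bootstrap distribution of per-bin mean network activity.

    Cells are never resampled; each iteration redraws trials (within mouse)
    with replacement and averages the binary activity over cells and trials.
    """
    act = raster.activity
    if trial_mask is not None:
        act = act[:, :, np.asarray(trial_mask)]
    n_trials = act.shape[2]
    if n_trials == 0:
        raise ValueError("condition contains no trials")
    rng = np.random.default_rng(seed)
    trial_means = act.mean(axis=0)  # (n_bins, n_trials)
    idx = rng.integers(0, n_trials, size=(n_iter, n_trials))
    iters = trial_means[:, idx].mean(axis=2).T  # (n_iter, n_bins)
    return NetworkSummary(
        bin_times=raster.bin_times, iterations=iters, condition=condition
    )


def pool_summaries(summaries: list[NetworkSummary]) -> NetworkSummary:
    """Pool per-mouse iteration sets into one grand distribution."""
    if not summaries:
        raise ValueError("nothing to pool")
    t0 = summaries[0].bin_times
    for s in summaries[1:]:
        if not np.array_equal(s.bin_times, t0):
            raise ValueError("summaries are on different bin grids")
    return NetworkSummary(
        bin_times=t0,
        iterations=np.vstack([s.iterations for s in summaries]),
        condition=summaries[0].condition,
    )


def stimulus_correlation(summary: NetworkSummary, indicator) -> tuple[float, float]:
    """Pearson r between bootstrapped activity and the 0/1 stimulus indicator.

    Pairs are pooled over (iteration x bin): each iteration's activity trace
    is paired with the same indicator vector.
    """
    ind = np.asarray(indicator, dtype=float)
    if ind.size != summary.bin_times.size:
        raise ValueError("indicator and activity are on different bin grids")
    act = summary.iterations.ravel()
    ind_t = np.tile(ind, summary.n_iterations)
    if act.std() == 0.0 or ind_t.std() == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = pearsonr(act, ind_t)
    return float(r), float(p)


def peak_times(
    raster: SpikeRaster,
    trial_mask=None,
    period: tuple[float, float] = (0.0, 1.4),
    condition: str = "",
) -> PeakTimeDist:
    """Per-cell argmax time of trial-averaged activity within a period.

    Ties resolve to the earliest bin; times are bin left edges.
    """
    lo, hi = period
    mids = raster.bin_times + raster.bin_width / 2.0
    bins = np.flatnonzero((mids >= lo) & (mids < hi))
    if bins.size == 0:
        raise ValueError("period contains no time bins")
    act = raster.activity
    if trial_mask is not None:
        act = act[:, :, np.asarray(trial_mask)]
    if act.shape[2] == 0:
        raise ValueError("condition contains no trials")
    traces = act.mean(axis=2)[:, bins]  # cells x period-bins
    peak_bins = bins[np.argmax(traces, axis=1)]  # argmax: earliest on ties
    return PeakTimeDist(
        times=raster.bin_times[peak_bins], period=period, condition=condition
    )


def compare_peak_distributions(
    dists: dict[str, PeakTimeDist],
    pairs: list[tuple[str, str]],
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sample KS tests per pair under a Bonferroni-adjusted alpha.

    ``alpha_adj = family_alpha / n_pairs`` (0.0083 for six pairs, 0.0167 for
    three).  Exact p-values for small samples, asymptotic otherwise.
    """
    alpha_adj = family_alpha / len(pairs)
    rows = []
    for a, b in pairs:
        xa, xb = dists[a].times, dists[b].times
        if xa.size == 0 or xb.size == 0:
            continue
        method = "exact" if min(xa.size, xb.size) < 30 else "asymp"
        res = ks_2samp(xa, xb, method=method)
        rows.append(
            {
                "pair": f"{a} vs {b}",
                "D": float(res.statistic),
                "p": float(res.pvalue),
                "alpha_adj": alpha_adj,
                "significant": bool(res.pvalue < alpha_adj),
            }
        )
    return pd.DataFrame(rows)


def sort_by_peak_time(traces: np.ndarray) -> np.ndarray:
    """Heatmap row order: cells grouped by peak bin, ascending peak time.

    Within a peak-time group the original cell order is preserved (stable
    sort), so successive groups stack below earlier ones.
    """
    return np.argsort(np.argmax(traces, axis=1), kind="stable")


def outcome_trajectories(
    raster: SpikeRaster,
    outcomes: pd.DataFrame,
    n_components: int = 3,
) -> TrajectorySet:
    """PCA state-space trajectories of trial-averaged outcome activity.

    Per outcome the cell x bin trial-averaged matrix is computed; components
    are fitted on the concatenated (outcome x bin) observations over the cell
    dimensions, and each outcome's trajectory is the projection of its bins
    onto the first ``n_components`` components.
    """
    if raster.n_cells < 2 or raster.n_bins < 2:
        raise ValueError("need >=2 cells and >=2 time bins")
    oc = outcomes["outcome"].to_numpy()
    present = [o for o in ("Hit", "Miss", "CR", "FA") if (oc == o).any()]
    if not present:
        raise ValueError("no labeled outcomes")
    mats = {o: raster.activity[:, :, oc == o].mean(axis=2) for o in present}
    X = np.hstack([mats[o] for o in present]).T  # (outcomes*bins) x cells
    k = min(n_components, min(X.shape) - 1) or 1
    pca = PCA(n_components=k)
    Z = pca.fit_transform(X)
    n_bins = raster.n_bins
    trajs = {
        o: Z[i * n_bins : (i + 1) * n_bins] for i, o in enumerate(present)
    }
    return TrajectorySet(
        trajectories=trajs,
        variance_explained=pca.explained_variance_ratio_ * 100.0,
        bin_times=raster.bin_times,
    )
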