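"""Identification and removal of lick-modulated cells.

Motor/decision activity is separated from sensory activity by decoding
"licked" (Hit + FA) versus "did not lick" (CR + Miss) trial groups from the
population inside the response window — the only systematic difference
between these groups there is licking.  Per response-window bin and machine,
forward sequential selection picks the most predictive cells; each selected
cell accrues the machine's accuracy z-scored against that bin's
shuffled-label control distribution (below-chance machines score negative).
Sessions where total score correlates positively and significantly with
selection count are admitted, and cells whose total score exceeds the mean
by more than one SD are flagged as lick modulated and removed before the
sensory analyses.  A session may legitimately yield no flagged cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .decoding import forward_select
from .raster import SpikeRaster

log = logging.getLogger(__name__)

__all__ = [
    "CellScoreTable",
    "score_cells",
    "admit_session",
    "flag_lick_cells",
    "remove_cells",
]

LICK_GROUP = ("Hit", "FA")
NOLICK_GROUP = ("CR", "Miss")


@dataclass
class CellScoreTable:
    """Per-cell selection counts and summed z-scored accuracies."""

    table: pd.DataFrame  # columns: cell, selection_count, total_score
    n_machines: int
    n_bins: int

    @property
    def selection_count(self) -> np.ndarray:
        return self.table["selection_count"].to_numpy()

    @property
    def total_score(self) -> np.ndarray:
        return self.table["total_score"].to_numpy()


@dataclass
class SessionAdmission:
    admitted: bool
    r: float
    p: float

    def __bool__(self) -> bool:
        return self.admitted


def _window_bins(raster: SpikeRaster, response_window: tuple[float, float]) -> np.ndarray:
    lo, hi = response_window
    mids = raster.bin_times + raster.bin_width / 2.0
    bins = np.flatnonzero((mids >= lo) & (mids < hi))
    if bins.size == 0:
        raise ValueError("no raster bins fall inside the response window")
    return bins


def score_cells(
    raster: SpikeRaster,
    outcomes: pd.DataFrame,
    response_window: tuple[float, float],
    n_select: int = 20,
    n_machines: int = 1000,
    seed: int | np.random.Generator = 0,
    n_control: int = 10,
) -> CellScoreTable:
    """Selection-and-scoring pass over the response-window bins.

    Per bin: a shuffled-label control distribution (``n_control`` machines
    run through the same forward-selection procedure, so selection bias
    cancels) fixes the chance reference; then per machine, ``n_select``
    cells are chosen by forward selection and each receives the machine
    accuracy z-scored against that reference.
    """
    rng = np.random.default_rng(seed)
    oc = outcomes["outcome"].to_numpy()
    lick = np.isin(oc, LICK_GROUP)
    nolick = np.isin(oc, NOLICK_GROUP)
    if not lick.any() or not nolick.any():
        raise ValueError("both lick (Hit/FA) and no-lick (CR/Miss) groups required")
    mask = lick | nolick
    y = lick[mask].astype(int)
    if n_select > raster.n_cells:
        log.warning(
            "n_select=%d clamped to the %d-cell population", n_select, raster.n_cells
        )
        n_select = raster.n_cells
    bins = _window_bins(raster, response_window)
    feats = raster.activity.transpose(1, 2, 0)[:, mask, :].astype(float)

    # chance reference per bin: the same selection procedure on permuted
    # labels, so the optimism of picking cells by held-out accuracy cancels
    ctrl = np.empty((bins.size, n_control))
    for i, b in enumerate(bins):
        for m in range(n_control):
            _, ctrl[i, m] = forward_select(
                feats[b], rng.permutation(y), n_select, rng
            )
    mu = ctrl.mean(axis=1)
    # floor the control spread at the binomial SD of a chance classifier on
    # the test set, so a degenerate (constant) control cannot inflate z
    n_test = max(int(round(0.2 * y.size)), 1)
    sd = np.maximum(ctrl.std(axis=1, ddof=1), 0.5 / np.sqrt(n_test))

    counts = np.zeros(raster.n_cells)
    scores = np.zeros(raster.n_cells)
    for i, b in enumerate(bins):
        X = feats[b]
        for _ in range(n_machines):
            sel, acc = forward_select(X, y, n_select, rng)
            z = (acc - mu[i]) / sd[i]
            counts[sel] += 1.0
            scores[sel] += z
    table = pd.DataFrame(
        {
            "cell": raster.cell_ids,
            "selection_count": counts,
            "total_score": scores,
        }
    )
    return CellScoreTable(table=table, n_machines=n_machines, n_bins=bins.size)


def admit_session(scores: CellScoreTable, alpha: float = 0.05) -> SessionAdmission:
    """Admit a session when score and selection count correlate reliably.

    Pearson r between per-cell total score and selection count; admitted iff
    r > 0 and p < alpha.  Constant vectors cannot be admitted.
    """
    s, c = scores.total_score, scores.selection_count
    if s.size < 3:
        raise ValueError("need >=3 cells to assess the score/count correlation")
    if np.std(s) == 0.0 or np.std(c) == 0.0:
        log.warning("constant score or count vector; session not admitted")
        return SessionAdmission(False, float("nan"), float("nan"))
    r, p = pearsonr(s, c)
    return SessionAdmission(bool(r > 0 and p < alpha), float(r), float(p))


def flag_lick_cells(
    scores: CellScoreTable, admission: SessionAdmission | None = None
) -> set:
    """Cells whose total score exceeds the mean by more than 1 SD.

    A non-admitted session yields no flags; so does a session with identical
    scores (SD = 0, nothing strictly greater).
    """
    if admission is None:
        admission = admit_session(scores)
    if not admission:
        log.info("session not admitted; no lick-modulated cells flagged")
        return set()
    s = scores.total_score
    cut = s.mean() + s.std(ddof=1)
    return set(scores.table["cell"].to_numpy()[s > cut].tolist())


def remove_cells(raster: SpikeRaster, ids) -> SpikeRaster:
    """Drop the flagged cells; ground-truth flags stay on the survivors."""
    ids = list(ids)
    if not ids:
        return raster
    return raster.drop_cells(ids)
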