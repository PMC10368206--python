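"""Time-resolved bootstrapped SVM decoding of stimulus or outcome.

Per 0.067 s time bin, many support-vector machines (RBF kernel) are trained
on repeated stratified 80/20 train/test splits of the trials, yielding a
per-bin distribution of test accuracies; the curve of mean accuracy with a
percentile band is compared against a paired shuffled-label control run the
same way.  Features are either the binned lick count (one feature) or the
per-cell deconvolved spike value (population decoding); the 15 Hz imaging
frames map one-to-one onto the 0.067 s decoding bins.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.svm import SVC

from .raster import SpikeRaster

try:  # low-level libsvm bindings: same solver as SVC, ~10x less call overhead
    from sklearn.svm import _libsvm as _fast_svm

    _fast_svm.set_verbosity_wrap(0)
except Exception:  # pragma: no cover - depends on sklearn internals
    _fast_svm = None

log = logging.getLogger(__name__)

__all__ = [
    "BIN_WIDTH",
    "DecodingCurve",
    "SelectionMap",
    "bin_licks",
    "raster_features",
    "n_decoding_bins",
    "bootstrap_svm_curve",
    "shuffled_control",
    "tune_hyperparameters",
    "kcell_selection_curve",
    "pairwise_outcome_decoding",
]

#: Decoding bin width (s); equals one 15 Hz imaging frame (printed as 0.067 s).
BIN_WIDTH = 1.0 / 15.0


def n_decoding_bins(horizon: float, bin_width: float = BIN_WIDTH) -> int:
    """Bin-count convention: floor(horizon / bin_width), partial bin dropped."""
    return int(math.floor(horizon / bin_width))


def bin_licks(
    licks: pd.DataFrame,
    trial_ids,
    horizon: float,
    bin_width: float = BIN_WIDTH,
) -> np.ndarray:
    """Lick counts per bin per trial -> (n_bins, n_trials, 1) feature array."""
    trial_ids = np.asarray(trial_ids)
    n_bins = n_decoding_bins(horizon, bin_width)
    X = np.zeros((n_bins, trial_ids.size, 1))
    pos = {t: i for i, t in enumerate(trial_ids)}
    b = np.floor(licks["time"].to_numpy() / bin_width).astype(int)
    ok = (b >= 0) & (b < n_bins) & licks["trial_id"].isin(trial_ids).to_numpy()
    for tid, bb in zip(licks["trial_id"].to_numpy()[ok], b[ok]):
        X[bb, pos[tid], 0] += 1.0
    return X


def raster_features(raster: SpikeRaster) -> np.ndarray:
    """Per-cell spike features -> (n_bins, n_trials, n_cells)."""
    return np.ascontiguousarray(raster.activity.transpose(1, 2, 0)).astype(float)


@dataclass
class DecodingCurve:
    """Per-bin bootstrap accuracy distribution with a percentile band."""

    bin_times: np.ndarray  # left edges, s
    accuracies: np.ndarray  # (n_bins, n_machines)
    control: "DecodingCurve | None" = None

    @property
    def n_machines(self) -> int:
        return self.accuracies.shape[1]

    @property
    def mean(self) -> np.ndarray:
        return self.accuracies.mean(axis=1)

    def band(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        lo = (1.0 - level) / 2.0
        return (
            np.quantile(self.accuracies, lo, axis=1),
            np.quantile(self.accuracies, 1.0 - lo, axis=1),
        )

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.band()
        out = pd.DataFrame(
            {"bin_time": self.bin_times, "mean_acc": self.mean, "lo": lo, "hi": hi}
        )
        if self.control is not None:
            clo, chi = self.control.band()
            out["control_mean"] = self.control.mean
            out["control_lo"] = clo
            out["control_hi"] = chi
        return out


@dataclass
class SelectionMap:
    """Per-bin, per-cell selection counts as fractions of possible selections."""

    bin_times: np.ndarray
    fractions: np.ndarray  # (n_bins, n_cells)
    k: int
    n_machines: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.bin_times):
            for c, f in enumerate(self.fractions[i]):
                rows.append({"bin_time": t, "cell": c, "selection_fraction": f})
        return pd.DataFrame(rows)


def _median_kernel_scale(X: np.ndarray) -> float:
    """Median pairwise Euclidean distance heuristic for the RBF kernel scale."""
    n = X.shape[0]
    if n > 200:
        X = X[:: max(1, n // 200)]
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    med = float(np.median(d[np.triu_indices_from(d, k=1)]))
    return med


def _resolve_gamma(X: np.ndarray, kernel_scale: float | None):
    if kernel_scale is None:
        s = _median_kernel_scale(X)
        return 1.0 / (s * s) if s > 0 else _scale_gamma(X)
    return 1.0 / (kernel_scale * kernel_scale)


def _scale_gamma(X: np.ndarray) -> float:
    v = X.var()
    return 1.0 / (X.shape[1] * v) if v > 0 else 1.0


def _make_svm(X: np.ndarray, C: float, kernel_scale: float | None) -> SVC:
    return SVC(kernel="rbf", C=C, gamma=_resolve_gamma(X, kernel_scale))


def _svm_accuracy(Xtr, ytr, Xte, yte, C: float, gamma: float) -> float:
    """RBF-SVM test accuracy; low-level libsvm when available (hot path)."""
    if _fast_svm is not None:
        model = _fast_svm.fit(
            np.ascontiguousarray(Xtr, dtype=np.float64),
            np.asarray(ytr, dtype=np.float64),
            svm_type=0, kernel="rbf", gamma=gamma, C=C,
        )
        pred = _fast_svm.predict(
            np.ascontiguousarray(Xte, dtype=np.float64), *model[:7],
            svm_type=0, kernel="rbf", gamma=gamma,
        )
    else:  # pragma: no cover
        pred = SVC(kernel="rbf", C=C, gamma=gamma).fit(Xtr, ytr).predict(Xte)
    return float(np.mean(pred == yte))


def _check_labels(labels: np.ndarray) -> None:
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present in the labels")


def _bin_accuracies(
    X: np.ndarray,
    y: np.ndarray,
    n_machines: int,
    test_frac: float,
    rng: np.random.Generator,
    shuffle_labels: bool,
    resample_trials: bool,
    C: float,
    kernel_scale: float | None,
) -> np.ndarray:
    """Accuracy distribution of one time bin (one machine per split)."""
    if X.std() == 0.0:
        log.warning("degenerate (constant) features in a bin; recording chance")
        return np.full(n_machines, 0.5)
    accs = np.empty(n_machines)
    n = y.size
    for m in range(n_machines):
        Xm, ym = X, y
        if resample_trials:
            idx = rng.integers(0, n, n)
            Xm, ym = X[idx], y[idx]
            if np.unique(ym).size < 2:
                accs[m] = 0.5
                continue
        if shuffle_labels:
            ym = rng.permutation(ym)
        sss = StratifiedShuffleSplit(
            n_splits=1, test_size=test_frac, random_state=int(rng.integers(2**31))
        )
        (tr, te), = sss.split(Xm, ym)
        if Xm[tr].std() == 0.0:
            accs[m] = 0.5
            continue
        gamma = _resolve_gamma(Xm[tr], kernel_scale)
        accs[m] = _svm_accuracy(Xm[tr], ym[tr], Xm[te], ym[te], C, gamma)
    return accs


def bootstrap_svm_curve(
    features: np.ndarray,
    labels,
    n_machines: int = 1000,
    test_frac: float = 0.2,
    seed: int | np.random.Generator = 0,
    C: float = 1.0,
    kernel_scale: float | None = None,
    bin_width: float = BIN_WIDTH,
    resample_trials: bool = False,
    with_control: bool = False,
    control_machines: int | None = None,
) -> DecodingCurve:
    """Bootstrapped per-bin SVM decoding curve.

    ``features`` is (n_bins, n_trials, n_features); each machine resamples a
    stratified 80/20 split (optionally the trials themselves, with
    replacement) and records its test accuracy.  With ``with_control`` a
    paired shuffled-label curve is attached.
    """
    y = np.asarray(labels)
    _check_labels(y)
    if features.ndim != 3 or features.shape[1] != y.size:
        raise ValueError("features must be (n_bins, n_trials, n_features)")
    if n_machines < 1:
        raise ValueError("n_machines must be >= 1")
    rng = np.random.default_rng(seed)
    n_bins = features.shape[0]
    accs = np.empty((n_bins, n_machines))
    for b in range(n_bins):
        accs[b] = _bin_accuracies(
            features[b], y, n_machines, test_frac, rng, False, resample_trials,
            C, kernel_scale,
        )
    curve = DecodingCurve(
        bin_times=np.arange(n_bins) * bin_width, accuracies=accs
    )
    if with_control:
        curve.control = shuffled_control(
            features, y, control_machines or n_machines, test_frac=test_frac,
            seed=rng, C=C, kernel_scale=kernel_scale, bin_width=bin_width,
        )
    return curve


def shuffled_control(
    features: np.ndarray,
    labels,
    n_machines: int = 1000,
    test_frac: float = 0.2,
    seed: int | np.random.Generator = 0,
    C: float = 1.0,
    kernel_scale: float | None = None,
    bin_width: float = BIN_WIDTH,
) -> DecodingCurve:
    """Chance reference: labels permuted independently per machine."""
    y = np.asarray(labels)
    _check_labels(y)
    if features.size == 0:
        raise ValueError("empty feature array")
    rng = np.random.default_rng(seed)
    n_bins = features.shape[0]
    accs = np.empty((n_bins, n_machines))
    for b in range(n_bins):
        accs[b] = _bin_accuracies(
            features[b], y, n_machines, test_frac, rng, True, False, C, kernel_scale
        )
    return DecodingCurve(bin_times=np.arange(n_bins) * bin_width, accuracies=accs)


def tune_hyperparameters(
    X: np.ndarray,
    y,
    folds: int = 5,
    budget: int = 20,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Tune the RBF box constraint and kernel scale by cross-validation.

    Seeded random search over a log-scaled space around the median-distance
    heuristic, scored by ``folds``-fold stratified CV accuracy; candidate 0
    is the default setting, so ``budget=1`` returns the defaults.  Falls back
    to the defaults with a warning when the data cannot support the folds.
    Applied to full-network neural decoding only; lick decoding uses no
    pretraining optimization.
    """
    y = np.asarray(y)
    _check_labels(y)
    rng = np.random.default_rng(seed)
    s0 = _median_kernel_scale(X)
    if s0 <= 0:
        s0 = 1.0
    defaults = {"C": 1.0, "kernel_scale": s0}
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        warnings.warn("insufficient data for CV folds; returning default parameters")
        return defaults
    candidates = [defaults]
    for _ in range(max(budget - 1, 0)):
        candidates.append(
            {
                "C": float(10 ** rng.uniform(-2, 3)),
                "kernel_scale": float(s0 * 10 ** rng.uniform(-2, 2)),
            }
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=int(rng.integers(2**31)))
    splits = list(skf.split(X, y))
    best, best_acc = defaults, -np.inf
    for cand in candidates[:budget]:
        accs = []
        for tr, te in splits:
            clf = _make_svm(X[tr], cand["C"], cand["kernel_scale"])
            clf.fit(X[tr], y[tr])
            accs.append(clf.score(X[te], y[te]))
        acc = float(np.mean(accs))
        if acc > best_acc:
            best, best_acc = cand, acc
    return dict(best, cv_accuracy=best_acc)


def forward_select(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    rng: np.random.Generator,
    test_frac: float = 0.2,
    C: float = 1.0,
) -> tuple[list[int], float]:
    """Greedy forward selection of k feature columns by held-out accuracy.

    One stratified 80/20 split is drawn; candidates are scored by test
    accuracy of an RBF SVM on the already-selected columns plus the
    candidate.  Ties among equally accurate candidates break by a seeded
    random draw, and once no candidate strictly improves the held-out
    accuracy the remaining slots are filled by a random draw from the unused
    candidates (the greedy objective is flat there, so any order is as
    good).  Columns constant in the training split are never selectable.
    Returns the selected indices and the selected model's held-out accuracy.
    """
    n_feat = X.shape[1]
    if k > n_feat:
        raise ValueError(f"cannot select {k} of {n_feat} features")
    sss = StratifiedShuffleSplit(
        n_splits=1, test_size=test_frac, random_state=int(rng.integers(2**31))
    )
    (tr, te), = sss.split(X, y)
    Xtr, Xte, ytr, yte = X[tr], X[te], y[tr], y[te]

    def _acc(cols: list[int]) -> float:
        # variance-scaled gamma here: the median heuristic would be
        # recomputed for every candidate subset and dominate the scan
        Xc = Xtr[:, cols]
        return _svm_accuracy(Xc, ytr, Xte[:, cols], yte, C, _scale_gamma(Xc))

    usable = [j for j in range(n_feat) if Xtr[:, j].std() > 0]
    selected: list[int] = []
    current = -np.inf
    k_eff = min(k, len(usable))
    while len(selected) < k_eff:
        best_js: list[int] = []
        best_acc = -np.inf
        for j in usable:
            if j in selected:
                continue
            acc = _acc(selected + [j])
            if acc > best_acc:
                best_js, best_acc = [j], acc
            elif acc == best_acc:
                best_js.append(j)
        if best_acc <= current:
            # objective is flat: fill the remaining slots at random
            rest = [j for j in usable if j not in selected]
            fill = rng.choice(len(rest), size=k_eff - len(selected), replace=False)
            selected.extend(rest[i] for i in sorted(fill))
            break
        selected.append(int(best_js[rng.integers(len(best_js))]))
        current = best_acc
    if not selected:
        return [], 0.5
    return selected, _acc(selected)


def kcell_selection_curve(
    features: np.ndarray,
    labels,
    k: int,
    n_machines: int = 1000,
    seed: int | np.random.Generator = 0,
    bin_width: float = BIN_WIDTH,
) -> tuple[DecodingCurve, SelectionMap]:
    """Decoding with forward selection of k cells per bin per machine.

    Selection counts are normalized by the k x n_machines possible selection
    slots per bin, so with k = n_cells every cell accounts for 1/n_cells of
    the slots.
    """
    y = np.asarray(labels)
    _check_labels(y)
    n_bins, _, n_cells = features.shape
    if k > n_cells:
        raise ValueError(f"k={k} exceeds the {n_cells}-cell population")
    rng = np.random.default_rng(seed)
    accs = np.empty((n_bins, n_machines))
    counts = np.zeros((n_bins, n_cells))
    for b in range(n_bins):
        X = features[b]
        if X.std() == 0.0:
            accs[b] = 0.5
            continue
        for m in range(n_machines):
            sel, acc = forward_select(X, y, k, rng)
            accs[b, m] = acc
            counts[b, sel] += 1.0
    times = np.arange(n_bins) * bin_width
    curve = DecodingCurve(bin_times=times, accuracies=accs)
    smap = SelectionMap(
        bin_times=times,
        fractions=counts / (k * n_machines),
        k=k,
        n_machines=n_machines,
    )
    return curve, smap


def pairwise_outcome_decoding(
    features: np.ndarray,
    outcomes: pd.DataFrame,
    pairs: tuple[tuple[str, str], ...] = (("Hit", "CR"), ("Hit", "FA"), ("CR", "FA")),
    n_machines: int = 1000,
    seed: int | np.random.Generator = 0,
    bin_width: float = BIN_WIDTH,
) -> dict[tuple[str, str], DecodingCurve]:
    """One decoding curve + shuffled control per outcome pair.

    Miss trials are not part of the default pairs (too few in trained
    animals); a pair with an empty class is skipped with a log entry.
    """
    rng = np.random.default_rng(seed)
    oc = outcomes["outcome"].to_numpy()
    curves: dict[tuple[str, str], DecodingCurve] = {}
    for a, b in pairs:
        mask = np.isin(oc, (a, b))
        ya = oc[mask]
        if np.unique(ya).size < 2:
            log.info("pair (%s, %s) skipped: a class is empty", a, b)
            continue
        curves[(a, b)] = bootstrap_svm_curve(
            features[:, mask, :],
            (ya == a).astype(int),
            n_machines=n_machines,
            seed=rng,
            bin_width=bin_width,
            with_control=True,
        )
    return curves
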