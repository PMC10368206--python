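"""Binary spike-raster container for deconvolved two-photon activity.

Activity is cells x time-bins x trials at the imaging frame rate (15 Hz);
entries are 0/1 (deconvolved spike present in the frame).  Cell flags carry
the lick-modulated ground truth (synthetic data) or the flags assigned by the
lick-cell identification step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = ["SpikeRaster", "FRAME_RATE"]

FRAME_RATE = 15.0  # Hz


@dataclass
class SpikeRaster:
    activity: np.ndarray  # (n_cells, n_bins, n_trials), uint8 in {0, 1}
    bin_width: float = 1.0 / FRAME_RATE
    cell_ids: np.ndarray | None = None
    lick_flags: np.ndarray | None = None  # bool per cell
    stim_locked: np.ndarray | None = None  # bool per cell (generator truth)
    trial_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity)
        if self.activity.ndim != 3:
            raise ValueError("activity must be cells x bins x trials")
        if not np.isin(self.activity, (0, 1)).all():
            raise ValueError("activity entries must be binary (0/1)")
        self.activity = self.activity.astype(np.uint8)
        n_cells, _, n_trials = self.activity.shape
        if self.cell_ids is None:
            self.cell_ids = np.arange(n_cells)
        if self.trial_ids is None:
            self.trial_ids = np.arange(n_trials)
        if self.lick_flags is None:
            self.lick_flags = np.zeros(n_cells, dtype=bool)
        if self.stim_locked is None:
            self.stim_locked = np.zeros(n_cells, dtype=bool)
        for name in ("cell_ids", "lick_flags", "stim_locked"):
            if len(getattr(self, name)) != n_cells:
                raise ValueError(f"{name} length does not match cell count")
        if len(self.trial_ids) != n_trials:
            raise ValueError("trial_ids length does not match trial count")

    @property
    def n_cells(self) -> int:
        return self.activity.shape[0]

    @property
    def n_bins(self) -> int:
        return self.activity.shape[1]

    @property
    def n_trials(self) -> int:
        return self.activity.shape[2]

    @property
    def bin_times(self) -> np.ndarray:
        """Left edges of the time bins, trial-relative seconds."""
        return np.arange(self.n_bins) * self.bin_width

    def select_trials(self, trial_ids) -> "SpikeRaster":
        idx = np.searchsorted(self.trial_ids, np.asarray(trial_ids))
        if not np.array_equal(self.trial_ids[idx], trial_ids):
            raise KeyError("unknown trial id(s)")
        return replace(
            self, activity=self.activity[:, :, idx], trial_ids=np.asarray(trial_ids)
        )

    def drop_cells(self, cell_ids) -> "SpikeRaster":
        ids = np.asarray(list(cell_ids))
        unknown = np.setdiff1d(ids, self.cell_ids)
        if unknown.size:
            raise KeyError(f"unknown cell id(s): {unknown.tolist()}")
        keep = ~np.isin(self.cell_ids, ids)
        if not keep.any():
            raise ValueError("removing all cells would leave an empty raster")
        return replace(
            self,
            activity=self.activity[keep],
            cell_ids=self.cell_ids[keep],
            lick_flags=self.lick_flags[keep],
            stim_locked=self.stim_locked[keep],
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("activity", data=self.activity, compression="gzip")
            d.attrs["dims"] = "cell x time_bin x trial"
            f.attrs["bin_width"] = self.bin_width
            f.create_dataset("cell_ids", data=self.cell_ids)
            f.create_dataset("lick_flags", data=self.lick_flags.astype(np.uint8))
            f.create_dataset("stim_locked", data=self.stim_locked.astype(np.uint8))
            f.create_dataset("trial_ids", data=self.trial_ids)

    @classmethod
    def from_hdf5(cls, path) -> "SpikeRaster":
        with h5py.File(path, "r") as f:
            return cls(
                activity=f["activity"][()],
                bin_width=float(f.attrs["bin_width"]),
                cell_ids=f["cell_ids"][()],
                lick_flags=f["lick_flags"][()].astype(bool),
                stim_locked=f["stim_locked"][()].astype(bool),
                trial_ids=f["trial_ids"][()],
            )
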