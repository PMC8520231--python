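"""Bead-calibrated size gating and fluorescence quantification of flow events.

Synaptosome-sized particles are identified on the scatter axes by
calibrating forward scatter against fluorescent latex beads of known
diameter (1, 2, 3, 6 µm), interpolating log-scatter vs log-size
monotonically, and gating mapped sizes to the closed interval
[1 µm, 3 µm].  Protein levels on the gated events are summarised as mean
fluorescence intensity (MFI); engulfment assays are summarised as the
percentage of cells above a label-positivity threshold, by default the
99.9th percentile of a negative-control population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SizeCalibration",
    "SizeGate",
    "fit_size_calibration",
    "gate_by_size",
    "mean_fluorescence",
    "engulfment_fraction",
    "positivity_threshold",
]


def _is_bead(events: pd.DataFrame) -> np.ndarray:
    bc = events["bead_class"].fillna("").astype(str)
    return (bc != "").to_numpy()


@dataclass
class SizeCalibration:
    """Monotone piecewise-linear map from log forward scatter to log size."""

    bead_sizes_um: np.ndarray
    bead_scatter_medians: np.ndarray

    def __post_init__(self):
        self.bead_sizes_um = np.asarray(self.bead_sizes_um, dtype=float)
        self.bead_scatter_medians = np.asarray(self.bead_scatter_medians, dtype=float)
        if np.any(np.diff(self.bead_scatter_medians) <= 0):
            order = np.argsort(self.bead_sizes_um)
            bad = [
                f"{self.bead_sizes_um[order][i]:g}um<=x<={self.bead_sizes_um[order][i + 1]:g}um"
                for i in range(len(order) - 1)
                if self.bead_scatter_medians[order][i + 1] <= self.bead_scatter_medians[order][i]
            ]
            raise ValueError(f"bead scatter medians not strictly increasing with size: {bad}")

    def map_size(self, scatter) -> np.ndarray:
        """Mapped particle size in µm; linear extrapolation beyond the bead range."""
        s = np.asarray(scatter, dtype=float)
        out_of_range = (s < self.bead_scatter_medians[0]) | (s > self.bead_scatter_medians[-1])
        if out_of_range.any():
            warnings.warn(
                f"{int(out_of_range.sum())} event(s) outside the bead calibration range; "
                "sizes extrapolated"
            )
        log_x = np.log(self.bead_scatter_medians)
        log_y = np.log(self.bead_sizes_um)
        slope_lo = (log_y[1] - log_y[0]) / (log_x[1] - log_x[0])
        slope_hi = (log_y[-1] - log_y[-2]) / (log_x[-1] - log_x[-2])
        ls = np.log(np.clip(s, np.finfo(float).tiny, None))
        interp = np.interp(ls, log_x, log_y)
        interp = np.where(ls < log_x[0], log_y[0] + slope_lo * (ls - log_x[0]), interp)
        interp = np.where(ls > log_x[-1], log_y[-1] + slope_hi * (ls - log_x[-1]), interp)
        return np.exp(interp)


@dataclass
class SizeGate:
    """Closed size interval retained as synaptosomes (default 1-3 µm)."""

    lower_um: float = 1.0
    upper_um: float = 3.0

    def __post_init__(self):
        if not 0 < self.lower_um < self.upper_um:
            raise ValueError("need 0 < lower < upper")


def fit_size_calibration(events: pd.DataFrame, scatter_channel: str = "FSC_A") -> SizeCalibration:
    """Fit the scatter -> size map from the bead populations in an event table.

    The representative scatter of each bead class is its median; the map
    interpolates log-scatter vs log-size piecewise-linearly through those
    knots, so beads at their own median scatter map back to their nominal
    size exactly.
    """
    beads = events[_is_bead(events)]
    if beads.empty:
        raise ValueError("no bead events present")
    sizes = beads["bead_class"].astype(float)
    classes = np.sort(sizes.unique())
    if classes.size < 2:
        raise ValueError("need >= 2 distinct bead classes to calibrate")
    medians = np.array([beads.loc[sizes == c, scatter_channel].median() for c in classes])
    return SizeCalibration(classes, medians)


def gate_by_size(
    events: pd.DataFrame,
    calibration: SizeCalibration,
    gate: SizeGate | None = None,
    scatter_channel: str = "FSC_A",
) -> pd.DataFrame:
    """Non-bead events whose calibrated size falls inside the closed gate."""
    gate = gate or SizeGate()
    non_bead = events[~_is_bead(events)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mapped = calibration.map_size(non_bead[scatter_channel].to_numpy())
    keep = (mapped >= gate.lower_um) & (mapped <= gate.upper_um)
    gated = non_bead[keep]
    if gated.empty:
        warnings.warn("size gate retained no events")
    return gated


def mean_fluorescence(events: pd.DataFrame, channel: str) -> float:
    """Arithmetic mean fluorescence intensity of a channel over events."""
    if channel not in events.columns:
        raise KeyError(f"channel {channel!r} not in event table")
    if events.empty:
        raise ValueError("MFI undefined on an empty event table")
    return float(events[channel].mean())


def positivity_threshold(negative_control: pd.DataFrame, channel: str, quantile: float = 0.999) -> float:
    """Label-positivity cutoff from a negative-control population quantile."""
    if negative_control.empty:
        raise ValueError("empty negative-control table")
    return float(negative_control[channel].quantile(quantile))


def engulfment_fraction(cell_events: pd.DataFrame, label_channel: str, threshold: float) -> float:
    """Percentage of cells whose label channel exceeds the threshold."""
    if cell_events.empty:
        raise ValueError("engulfment fraction undefined on an empty table")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    positive = (cell_events[label_channel] > threshold).sum()
    return 100.0 * float(positive) / len(cell_events)
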