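"""Novel-object-recognition scoring and small study-design arithmetic.

Recognition memory is summarised per mouse by the discrimination index
DI = (T_novel - T_familiar) / (T_novel + T_familiar), in [-1, 1], with
0 meaning no preference.  Mice with insufficient total exploration are
excluded before group statistics; the threshold defaults to 3 s total,
a conventional choice since published exclusion rules of this kind
rarely quote a number.  A small utility converts inhibitor-chow
concentration to daily drug intake.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = ["DoseSpec", "discrimination_index", "score_trials", "apply_exclusions", "daily_dose"]


@dataclass
class DoseSpec:
    """Drug-in-chow dosing: concentration (ppm) and daily chow intake (g)."""

    chow_concentration_ppm: float = 1200.0
    daily_chow_g: float = 4.0

    def __post_init__(self):
        if self.chow_concentration_ppm < 0 or self.daily_chow_g <= 0:
            raise ValueError("concentration must be >= 0 and daily chow > 0")


def discrimination_index(t_novel: float, t_familiar: float) -> float:
    """DI = (T_novel - T_familiar) / (T_novel + T_familiar)."""
    if t_novel < 0 or t_familiar < 0:
        raise ValueError("exploration times must be non-negative")
    total = t_novel + t_familiar
    if total == 0:
        raise ValueError("zero total exploration time; exclude the trial instead")
    return (t_novel - t_familiar) / total


def score_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Add a DI column to a trial table (columns mouse_id, T_novel, T_familiar)."""
    out = trials.copy()
    out["DI"] = [
        discrimination_index(n, f) for n, f in zip(out["T_novel"], out["T_familiar"])
    ]
    return out


def apply_exclusions(
    trials: pd.DataFrame, min_total_time: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop trials with total exploration below the threshold.

    Returns ``(kept, exclusion_log)``; the log records mouse id, total
    time and the reason for every removal.
    """
    if min_total_time < 0:
        raise ValueError("min_total_time must be >= 0")
    total = trials["T_novel"] + trials["T_familiar"]
    drop = total < min_total_time
    log = pd.DataFrame(
        {
            "mouse_id": trials.loc[drop, "mouse_id"],
            "total_time_s": total[drop],
            "reason": f"total exploration < {min_total_time} s",
        }
    )
    kept = trials.loc[~drop].copy()
    if kept.empty:
        warnings.warn("all trials excluded for insufficient exploration")
    return kept, log


def daily_dose(spec: DoseSpec) -> float:
    """Daily drug intake in mg: ppm x 1e-6 x chow g/day x 1000 mg/g."""
    return spec.chow_concentration_ppm * 1e-6 * spec.daily_chow_g * 1000.0
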