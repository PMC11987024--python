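"""Plate-level ThT preprocessing and half-time-based activity calling.

A plate holds raw fluorescence traces plus a layout assigning each well a
role (sample / blank / control) and a condition label.  Preprocessing is:
(1) subtract the time-pointwise mean of the blank wells, then (2) per
condition, divide every replicate by the maximum over time of the
replicate-mean trace, so the mean trace plateaus at 1.

A compound is called active when the fold-change in mean half-time relative
to the no-compound control crosses 1.25× (inhibitor) or 0.8× (accelerator)
and a two-sided Mann–Whitney U test on the per-well half-times is
significant (default p < 1e-4; exact U distribution for group sizes ≤ 8).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .kinetic_models import KineticCurve, half_time

__all__ = [
    "Plate",
    "ActivityCall",
    "EndpointSummary",
    "blank_subtract",
    "normalize",
    "well_half_times",
    "call_activity",
    "endpoint_intensity",
    "FOLD_THRESHOLDS",
    "P_THRESHOLD",
]

log = logging.getLogger(__name__)

FOLD_THRESHOLDS = (0.8, 1.25)
P_THRESHOLD = 1e-4
ROLES = ("sample", "blank", "control_no_compound", "control_positive")


@dataclass
class Plate:
    """Fluorescence traces (rows: time, columns: wells) plus a layout."""

    times: np.ndarray
    data: pd.DataFrame
    layout: pd.DataFrame  # index: well; columns: role, condition, ...
    blanked: bool = False
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        missing = set(self.data.columns) - set(self.layout.index)
        if missing:
            raise ValueError(f"wells missing from layout: {sorted(missing)}")
        bad = set(self.layout["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown well roles: {sorted(bad)}")

    def wells_with_role(self, role: str) -> List[str]:
        return [w for w in self.data.columns if self.layout.loc[w, "role"] == role]

    def wells_in_condition(self, condition: str) -> List[str]:
        return [
            w
            for w in self.data.columns
            if self.layout.loc[w, "condition"] == condition
            and self.layout.loc[w, "role"] != "blank"
        ]


@dataclass
class ActivityCall:
    compound: str
    fold_change: float
    fold_change_sem: float
    p_value: float
    active: bool
    direction: str  # 'inhibitor' | 'accelerator' | 'none'
    n_compound: int
    n_control: int
    excluded_wells: List[str] = field(default_factory=list)


@dataclass
class EndpointSummary:
    condition: str
    mean: float
    sem: float
    plateau_reached: bool


def blank_subtract(plate: Plate) -> Plate:
    """Subtract the time-pointwise mean of blank wells from every other well."""
    blanks = plate.wells_with_role("blank")
    if not blanks:
        raise ValueError("plate has no blank wells")
    blank_mean = plate.data[blanks].mean(axis=1)
    data = plate.data.copy()
    for w in data.columns:
        if w not in blanks:
            data[w] = data[w] - blank_mean
    return replace(plate, data=data, blanked=True)


def normalize(plate: Plate) -> Plate:
    """Divide each condition's replicates by the max of their mean trace."""
    if not plate.blanked:
        raise ValueError("normalize requires a blank-subtracted plate")
    data = plate.data.copy()
    conditions = {
        plate.layout.loc[w, "condition"]
        for w in data.columns
        if plate.layout.loc[w, "role"] != "blank"
    }
    for cond in conditions:
        wells = plate.wells_in_condition(cond)
        divisor = float(data[wells].mean(axis=1).max())
        if divisor <= 0:
            raise ValueError(
                f"condition {cond!r}: maximum mean blank-subtracted intensity is "
                f"nonpositive ({divisor:g}); flat or failed wells"
            )
        data[wells] = data[wells] / divisor
    return replace(plate, data=data, normalized=True)


def well_half_times(
    plate: Plate, condition: str, **half_time_kwargs
) -> Tuple[Dict[str, float], List[str]]:
    """Per-well half-times for one condition; wells with no crossing are
    excluded and returned separately."""
    t50s: Dict[str, float] = {}
    excluded: List[str] = []
    for w in plate.wells_in_condition(condition):
        t50 = half_time(
            KineticCurve(plate.times, plate.data[w].to_numpy()), **half_time_kwargs
        )
        if t50 is None:
            excluded.append(w)
            log.warning("well %s (%s): no half-time; excluded", w, condition)
        else:
            t50s[w] = t50
    return t50s, excluded


def _mannwhitney_p(a: np.ndarray, b: np.ndarray) -> float:
    method = "exact" if max(a.size, b.size) <= 8 else "asymptotic"
    return float(mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def call_activity(
    plate: Plate,
    compound: str,
    control: str,
    fold_thresholds: Tuple[float, float] = FOLD_THRESHOLDS,
    p_threshold: float = P_THRESHOLD,
) -> ActivityCall:
    """Half-time fold-change + rank-test activity call for one compound."""
    comp_t50, comp_excl = well_half_times(plate, compound)
    ctrl_t50, ctrl_excl = well_half_times(plate, control)
    excluded = comp_excl + ctrl_excl
    if len(comp_t50) < 1 or len(ctrl_t50) < 1:
        return ActivityCall(
            compound=compound, fold_change=float("nan"), fold_change_sem=float("nan"),
            p_value=float("nan"), active=False, direction="none",
            n_compound=len(comp_t50), n_control=len(ctrl_t50),
            excluded_wells=excluded,
        )
    a = np.array(list(comp_t50.values()))
    b = np.array(list(ctrl_t50.values()))
    fold = float(a.mean() / b.mean())
    sem_a = a.std(ddof=1) / math.sqrt(a.size) if a.size > 1 else 0.0
    sem_b = b.std(ddof=1) / math.sqrt(b.size) if b.size > 1 else 0.0
    fold_sem = fold * math.sqrt(
        (sem_a / a.mean()) ** 2 + (sem_b / b.mean()) ** 2
    )
    p = _mannwhitney_p(a, b)
    lo, hi = fold_thresholds
    if fold >= hi:
        direction = "inhibitor"
    elif fold <= lo:
        direction = "accelerator"
    else:
        direction = "none"
    return ActivityCall(
        compound=compound, fold_change=fold, fold_change_sem=fold_sem,
        p_value=p, active=direction != "none" and p < p_threshold,
        direction=direction,
        n_compound=a.size, n_control=b.size, excluded_wells=excluded,
    )


def endpoint_intensity(
    plate: Plate,
    window_frac: float = 0.1,
    slope_tol: float = 0.05,
) -> List[EndpointSummary]:
    """Mean ± SEM of the final-window normalized intensity per condition.

    The plateau is considered reached when the mean trace changes by less
    than ``slope_tol`` (absolute, on the normalized scale) across the final
    window; otherwise the value is reported with a warning flag.
    """
    n_tail = max(2, int(round(window_frac * plate.times.size)))
    out: List[EndpointSummary] = []
    conditions = sorted(
        {
            plate.layout.loc[w, "condition"]
            for w in plate.data.columns
            if plate.layout.loc[w, "role"] != "blank"
        }
    )
    for cond in conditions:
        wells = plate.wells_in_condition(cond)
        tail = plate.data[wells].iloc[-n_tail:]
        per_well = tail.mean(axis=0).to_numpy()
        mean = float(per_well.mean())
        sem = (
            float(per_well.std(ddof=1) / math.sqrt(per_well.size))
            if per_well.size > 1
            else 0.0
        )
        mean_trace = tail.mean(axis=1).to_numpy()
        drift = float(abs(mean_trace[-1] - mean_trace[0]))
        reached = drift <= slope_tol
        if not reached:
            log.warning("condition %s: endpoint window still drifting (%.3g)", cond, drift)
        out.append(EndpointSummary(condition=cond, mean=mean, sem=sem,
                                   plateau_reached=reached))
    return out
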