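"""Microfluidic elugram analysis: normalization, plateau quantification and
running-median spike detection.

In a continuous-flow fluorescence assay the solution-phase signal settles to
a plateau proportional to the free-compound concentration, while large
particles (fibrils or fibril clusters) passing the detector produce brief
spikes.  Spikes are called where the signal exceeds the running median
(window 15 samples) by more than 0.01 normalized fluorescence units;
contiguous supra-threshold samples merge into a single spike.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "Elugram",
    "SpikeCall",
    "DEFAULT_THRESHOLD",
    "DEFAULT_WINDOW",
    "BASELINE_WINDOW_S",
    "PLATEAU_WINDOW_S",
    "running_median",
    "normalize_elugram",
    "detect_spikes",
    "plateau_level",
    "plateau_concentration",
]

DEFAULT_THRESHOLD = 0.01  # normalized fluorescence units above the running median
DEFAULT_WINDOW = 15  # samples
BASELINE_WINDOW_S = (0.0, 15.0)
PLATEAU_WINDOW_S = (30.0, 80.0)


@dataclass
class Elugram:
    """A time-stamped fluorescence trace from a continuous-flow run."""

    times: np.ndarray  # s
    fluorescence: np.ndarray
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.shape != self.fluorescence.shape:
            raise ValueError("times and fluorescence must have equal length")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class SpikeCall:
    indices: List[int]
    times: List[float]
    heights: List[float]  # above the running median
    count: int
    baseline: Optional[float] = None
    plateau: Optional[float] = None


def running_median(y: np.ndarray, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Centered running median with shrink-to-fit windows at both ends.

    An even ``window`` uses the lower median, so the filter output is always
    an observed sample value.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        raise ValueError(f"window ({window}) exceeds series length ({n})")
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1) if window % 2 else min(n, i + half)
        seg = np.sort(y[lo:hi])
        out[i] = seg[(seg.size - 1) // 2] if seg.size % 2 == 0 else np.median(seg)
    return out


def normalize_elugram(raw: Elugram, control_plateau: float) -> Elugram:
    """Divide the trace by the plateau fluorescence of the 100 μM control."""
    if control_plateau <= 0:
        raise ValueError("control plateau must be > 0")
    return replace(raw, fluorescence=raw.fluorescence / control_plateau)


def detect_spikes(
    e: Elugram,
    threshold: float = DEFAULT_THRESHOLD,
    window: int = DEFAULT_WINDOW,
) -> SpikeCall:
    """Flag samples more than ``threshold`` above the running median.

    Contiguous flagged runs are merged into single spikes; each spike is
    located at the sample of maximal excess, with that excess as its height.
    """
    y = e.fluorescence
    med = running_median(y, window)
    excess = y - med
    flagged = excess > threshold
    indices: List[int] = []
    heights: List[float] = []
    i = 0
    n = y.size
    while i < n:
        if flagged[i]:
            j = i
            while j + 1 < n and flagged[j + 1]:
                j += 1
            k = i + int(np.argmax(excess[i : j + 1]))
            indices.append(k)
            heights.append(float(excess[k]))
            i = j + 1
        else:
            i += 1
    return SpikeCall(
        indices=indices,
        times=[float(e.times[k]) for k in indices],
        heights=heights,
        count=len(indices),
    )


def _window_mask(times: np.ndarray, window: Tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (times >= lo) & (times <= hi)


def plateau_level(
    e: Elugram,
    window: Tuple[float, float] = PLATEAU_WINDOW_S,
    threshold: float = DEFAULT_THRESHOLD,
    median_window: int = DEFAULT_WINDOW,
) -> float:
    """Spike-masked median fluorescence over the plateau window."""
    mask = _window_mask(e.times, window)
    if not mask.any():
        raise ValueError(f"no samples in plateau window {window}")
    spikes = detect_spikes(e, threshold=threshold, window=median_window)
    keep = mask.copy()
    keep[spikes.indices] = False
    if not keep.any():
        raise ValueError("plateau window is empty after spike masking")
    return float(np.median(e.fluorescence[keep]))


def plateau_concentration(
    e: Elugram,
    control_plateau: float = 1.0,
    window: Tuple[float, float] = PLATEAU_WINDOW_S,
    threshold: float = DEFAULT_THRESHOLD,
    median_window: int = DEFAULT_WINDOW,
) -> float:
    """Free-compound fraction: plateau level relative to the control's.

    On an already-normalized elugram the control plateau is 1.0, so the
    returned value is the spike-masked plateau median itself.
    """
    if control_plateau <= 0:
        raise ValueError("control plateau must be > 0")
    return plateau_level(e, window, threshold, median_window) / control_plateau
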