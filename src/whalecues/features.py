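"""Per-call acoustic descriptors and longest-call selection.

Each detected call is summarized by 13 descriptors of its frequency contour:
min/max/median/mean frequency, duration, and min/max/median/mean of the
contour's velocity (first derivative, Hz/s) and acceleration (second
derivative, Hz/s^2).  Derivatives are finite differences of a median-smoothed
contour, so descriptors depend only on the contour — never on amplitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from whalecues.detection import CallSegment

__all__ = ["CallDescriptors", "DESCRIPTOR_COLUMNS", "compute_descriptors", "select_longest", "descriptor_table"]

logger = logging.getLogger(__name__)

DESCRIPTOR_COLUMNS = [
    "freq_min_hz", "freq_max_hz", "freq_median_hz", "freq_mean_hz",
    "duration_s",
    "vel_min_hz_s", "vel_max_hz_s", "vel_median_hz_s", "vel_mean_hz_s",
    "acc_min_hz_s2", "acc_max_hz_s2", "acc_median_hz_s2", "acc_mean_hz_s2",
]


@dataclass(frozen=True)
class CallDescriptors:
    """The 13-element acoustic descriptor vector of one call."""

    call_id: int
    onset_s: float
    freq_min_hz: float
    freq_max_hz: float
    freq_median_hz: float
    freq_mean_hz: float
    duration_s: float
    vel_min_hz_s: float
    vel_max_hz_s: float
    vel_median_hz_s: float
    vel_mean_hz_s: float
    acc_min_hz_s2: float
    acc_max_hz_s2: float
    acc_median_hz_s2: float
    acc_mean_hz_s2: float

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in DESCRIPTOR_COLUMNS])


def _stats(x: np.ndarray) -> tuple[float, float, float, float]:
    return float(np.min(x)), float(np.max(x)), float(np.median(x)), float(np.mean(x))


def compute_descriptors(
    segment: CallSegment,
    call_id: int = 0,
    smooth_frames: int = 3,
) -> CallDescriptors:
    """Descriptor vector of one call contour.

    The contour is median-smoothed (``smooth_frames`` kernel, default 3) before
    differencing to keep noise from inflating the acceleration statistics.
    Requires at least 3 contour frames (the second difference needs them);
    shorter segments raise :class:`ValueError` and should be dropped upstream.
    """
    f = np.asarray(segment.contour_hz, dtype=np.float64)
    t = np.asarray(segment.times, dtype=np.float64)
    if f.size < 3:
        raise ValueError(f"contour has {f.size} frames; >= 3 required")
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite contour")
    if smooth_frames > 1:
        f = median_filter(f, size=min(smooth_frames, f.size), mode="nearest")
    hop = float(np.mean(np.diff(t)))
    vel = np.diff(f) / hop
    acc = np.diff(vel) / hop

    fmin, fmax, fmed, fmean = _stats(f)
    vmin, vmax, vmed, vmean = _stats(vel)
    amin, amax, amed, amean = _stats(acc)
    return CallDescriptors(
        call_id=call_id,
        onset_s=segment.onset_s,
        freq_min_hz=fmin, freq_max_hz=fmax, freq_median_hz=fmed, freq_mean_hz=fmean,
        duration_s=float(segment.duration_s),
        vel_min_hz_s=vmin, vel_max_hz_s=vmax, vel_median_hz_s=vmed, vel_mean_hz_s=vmean,
        acc_min_hz_s2=amin, acc_max_hz_s2=amax, acc_median_hz_s2=amed, acc_mean_hz_s2=amean,
    )


def select_longest(calls: list[CallDescriptors], n: int) -> list[CallDescriptors]:
    """The ``n`` longest calls (the most complete ones, from nearby animals).

    If fewer than ``n`` calls exist, all are returned.  Ties in duration are
    broken by earlier onset; selection is deterministic and stable.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    ranked = sorted(calls, key=lambda c: (-c.duration_s, c.onset_s, c.call_id))
    return ranked[: min(n, len(ranked))]


def descriptor_table(calls: list[CallDescriptors], source: str = "") -> pd.DataFrame:
    """One row per call: call_id, source file, the 13 descriptors."""
    rows = [
        {"call_id": c.call_id, "source": source, "onset_s": c.onset_s,
         **{col: getattr(c, col) for col in DESCRIPTOR_COLUMNS}}
        for c in calls
    ]
    return pd.DataFrame(rows, columns=["call_id", "source", "onset_s", *DESCRIPTOR_COLUMNS])
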