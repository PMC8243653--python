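"""Per-beat RR/dRR heart-rate-variability features.

For beat *i* the local block carries the RR and dRR values of the beat
itself and its two neighbours; the windowed block carries summary
statistics (mean/SD of RR, SD of dRR, pNN10..pNN50, RMSSD) over four
time windows: 1 and 5 minutes preceding the beat, 2 and 10 minutes
centered on it.

Conventions: ``RR_i`` is the interval *ending* at beat i's R peak;
``dRR_n = RR_{n+1} - RR_n``.  All values are in milliseconds; pNNx are
percentages in [0, 100].  Windows resolving to fewer than 3 RR entries
yield NaN (imputed downstream with training-fold means).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

from .io import BeatAnnotation

__all__ = [
    "RRSeries",
    "HRVWindowSpec",
    "WINDOW_SPECS",
    "HRV_FEATURE_NAMES",
    "compute_rr_series",
    "beat_local_features",
    "window_stats",
    "beat_hrv_vector",
]

PNN_THRESHOLDS_MS = (10, 20, 30, 40, 50)


@dataclass(frozen=True)
class RRSeries:
    """R-peak times plus first and second differences, in milliseconds."""

    t_ms: np.ndarray  # R-peak times
    rr: np.ndarray  # rr[j] = t_ms[j+1] - t_ms[j]
    drr: np.ndarray  # drr[j] = rr[j+1] - rr[j]

    @property
    def n_beats(self) -> int:
        return self.t_ms.size


@dataclass(frozen=True)
class HRVWindowSpec:
    tag: str
    kind: str  # "preceding" | "centered"
    minutes: float

    @property
    def duration_ms(self) -> float:
        return self.minutes * 60_000.0


WINDOW_SPECS: Tuple[HRVWindowSpec, ...] = (
    HRVWindowSpec("1p", "preceding", 1.0),
    HRVWindowSpec("5p", "preceding", 5.0),
    HRVWindowSpec("2c", "centered", 2.0),
    HRVWindowSpec("10c", "centered", 10.0),
)

_LOCAL_NAMES = (
    "hrv_rr_i",
    "hrv_rr_im1",
    "hrv_rr_ip1",
    "hrv_drr_i",
    "hrv_drr_im1",
    "hrv_drr_ip1",
)
_STAT_NAMES = (
    "meanrr",
    "sdrr",
    "sddrr",
    "pnn10",
    "pnn20",
    "pnn30",
    "pnn40",
    "pnn50",
    "rmssd",
)

#: Canonical ordering of the HRV block (6 local + 4 windows x 9 stats = 42).
HRV_FEATURE_NAMES: Tuple[str, ...] = _LOCAL_NAMES + tuple(
    f"hrv_win{spec.tag}_{stat}" for spec in WINDOW_SPECS for stat in _STAT_NAMES
)


def compute_rr_series(annotations: Sequence[BeatAnnotation], fs: float) -> RRSeries:
    """RR/dRR series from beat annotations (all labels contribute R peaks)."""
    samples = np.asarray([a.sample for a in annotations], dtype=float)
    t_ms = samples * 1000.0 / fs
    if t_ms.size < 2:
        return RRSeries(t_ms, np.empty(0), np.empty(0))
    rr = np.diff(t_ms)
    if np.any(rr <= 0):
        raise ValueError("annotations must be strictly increasing in sample")
    drr = np.diff(rr) if rr.size >= 2 else np.empty(0)
    return RRSeries(t_ms, rr, drr)


def beat_local_features(series: RRSeries, i: int) -> Tuple[float, ...]:
    """``(RR_i, RR_{i-1}, RR_{i+1}, dRR_i, dRR_{i-1}, dRR_{i+1})`` in ms.

    Requires both neighbours: valid for ``2 <= i <= n_beats - 3``
    (guaranteed once the 40-beat record trim is applied).
    """
    n = series.n_beats
    if not 2 <= i <= n - 3:
        raise IndexError(f"beat {i} lacks full RR/dRR context in a {n}-beat series")
    rr, drr = series.rr, series.drr
    return (
        float(rr[i - 1]),  # RR_i ends at beat i
        float(rr[i - 2]),
        float(rr[i]),
        float(drr[i - 1]),  # dRR_i = RR_{i+1} - RR_i
        float(drr[i - 2]),
        float(drr[i]),
    )


def window_stats(series: RRSeries, i: int, spec: HRVWindowSpec) -> Tuple[float, ...]:
    """Nine summary statistics of the RR entries inside one time window.

    An RR entry belongs to the window when its *ending* R-peak time lies
    in ``[t_i - d, t_i)`` (preceding) or ``[t_i - d/2, t_i + d/2]``
    (centered).  Fewer than 3 entries -> all NaN.
    """
    t_i = series.t_ms[i]
    end_times = series.t_ms[1:]  # rr[j] ends at t_ms[j+1]
    if spec.kind == "preceding":
        mask = (end_times >= t_i - spec.duration_ms) & (end_times < t_i)
    elif spec.kind == "centered":
        half = spec.duration_ms / 2.0
        mask = (end_times >= t_i - half) & (end_times <= t_i + half)
    else:
        raise ValueError(f"unknown window kind {spec.kind!r}")
    rr_win = series.rr[mask]
    if rr_win.size < 3:
        return (float("nan"),) * 9
    diffs = np.diff(rr_win)
    abs_diffs = np.abs(diffs)
    pnn = tuple(100.0 * float(np.mean(abs_diffs > x)) for x in PNN_THRESHOLDS_MS)
    return (
        float(np.mean(rr_win)),
        float(np.std(rr_win, ddof=1)),
        float(np.std(diffs, ddof=1)),
        *pnn,
        float(np.sqrt(np.mean(diffs**2))),
    )


def beat_hrv_vector(
    series: RRSeries, i: int, drop: Sequence[str] = ()
) -> Dict[str, float]:
    """Full HRV block for beat ``i`` keyed by canonical feature name.

    ``drop`` removes named features (config switch ``hrv_drop``); the
    default emits all 42.
    """
    values = dict(zip(_LOCAL_NAMES, beat_local_features(series, i)))
    for spec in WINDOW_SPECS:
        stats = window_stats(series, i, spec)
        for stat_name, value in zip(_STAT_NAMES, stats):
            values[f"hrv_win{spec.tag}_{stat_name}"] = value
    for name in drop:
        values.pop(name, None)
    return values
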