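"""Featurization of single-cell calcium recordings.

Turns a uniformly sampled trace (simulated µM concentration or synthetic
fluorescence) into the four oscillation metrics used to compare substrate
conditions: mean transient amplitude, basal threshold level, event frequency
(per minute), and 10–90% rise / 90–10% decay times.

The recordings the metrics were designed for have no operational definition
in the source imaging protocol, so the estimators here are declared
defaults, all exposed as :class:`FeaturizerSettings`:

* baseline ("threshold") — a low quantile (default 10th percentile) of the
  signal, robust to transients occupying a minority of the record;
* noise — MAD of first differences scaled to a Gaussian SD (÷ √2 for the
  differencing);
* events — maximal excursions of the detection-smoothed trace above
  baseline + κ·noise (default κ = 3), merged when peaks are closer than a
  minimum separation (default 2 s);
* rise/decay — linear-interpolated 10%→90% (and 90%→10%) crossing times of
  the amplitude around each peak.

Amplitude is peak minus baseline, not absolute peak.  Events truncated by a
recording boundary count toward frequency but are excluded from rise/decay
means so kinetics stay unbiased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "Trace",
    "TransientEvent",
    "OscillationFeatures",
    "FeaturizerSettings",
    "estimate_baseline",
    "detect_events",
    "featurize",
    "featurize_cohort",
    "FEATURE_COLUMNS",
]

#: Numeric feature columns produced by :func:`featurize_cohort`.
FEATURE_COLUMNS = ("amplitude", "threshold", "frequency_per_min", "rise_time_s", "decay_time_s")

_UNIFORM_RTOL = 1e-6


@dataclass(frozen=True)
class Trace:
    """One cell's uniformly sampled recording.

    ``values`` carry whatever units the recording uses (µM for simulated
    concentration, arbitrary fluorescence units otherwise); units are
    metadata and are never converted.
    """

    times: np.ndarray
    values: np.ndarray
    cell_id: str = "cell"
    condition: Optional[str] = None
    units: str = "a.u."

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValidationError("times and values must be 1-D arrays of equal length")
        if len(t) < 2:
            raise ValidationError("a trace needs at least 2 samples")
        if not (np.isfinite(t).all() and np.isfinite(v).all()):
            raise ValidationError("trace contains non-finite values")
        dts = np.diff(t)
        if dts.min() <= 0:
            raise FormatError("times must be strictly increasing")
        if not np.allclose(dts, dts[0], rtol=_UNIFORM_RTOL, atol=_UNIFORM_RTOL * abs(dts[0])):
            raise FormatError("trace is not uniformly sampled")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class TransientEvent:
    """One detected calcium transient.

    ``rise_time``/``decay_time`` are NaN when the corresponding flank is
    truncated by a recording boundary (or an unresolved neighbor).
    """

    onset_time: float
    peak_time: float
    peak_value: float
    offset_time: float
    amplitude: float
    rise_time: float
    decay_time: float

    @property
    def truncated(self) -> bool:
        return math.isnan(self.rise_time) or math.isnan(self.decay_time)


@dataclass(frozen=True)
class OscillationFeatures:
    """Per-cell summary of a recording.

    ``amplitude``, ``rise_time`` and ``decay_time`` are means over detected
    events and are None when no event was detected (absent, not zero).
    ``frequency`` is events per minute of recording.
    """

    amplitude: Optional[float]
    threshold: float
    frequency: float
    rise_time: Optional[float]
    decay_time: Optional[float]
    n_events: int
    degenerate: bool = False
    short_record: bool = False


@dataclass(frozen=True)
class FeaturizerSettings:
    baseline_quantile: float = 0.10
    kappa: float = 3.0
    min_separation: float = 2.0
    smoothing_window: float = 0.25  # s; detection-only moving average
    hysteresis: float = 0.5  # events end where the signal falls below baseline + hysteresis*kappa*noise

    def __post_init__(self) -> None:
        if not 0 < self.baseline_quantile < 0.5:
            raise ValidationError("baseline_quantile must lie in (0, 0.5)")
        if self.kappa < 0 or self.min_separation < 0 or self.smoothing_window < 0:
            raise ValidationError("kappa, min_separation and smoothing_window must be >= 0")
        if not 0 <= self.hysteresis <= 1:
            raise ValidationError("hysteresis must lie in [0, 1]")


def estimate_baseline(
    trace: Trace, quantile: float = 0.10
) -> tuple[float, float, bool]:
    """Estimate (baseline, noise_sd, degenerate_flag) for a trace.

    The baseline is the given lower quantile of the signal.  Noise is
    estimated from first differences — which cancel the slow transient
    component — via the median absolute deviation scaled to a Gaussian SD
    (×1.4826) and divided by √2 because differencing doubles the variance.
    A constant trace returns noise_sd 0 with the degenerate flag set.
    """
    if not 0 < quantile < 0.5:
        raise ValidationError("quantile must lie in (0, 0.5)")
    v = trace.values
    baseline = float(np.quantile(v, quantile))
    d = np.diff(v)
    mad = float(np.median(np.abs(d - np.median(d))))
    noise_sd = 1.4826 * mad / math.sqrt(2.0)
    degenerate = bool(np.all(v == v[0]))
    return baseline, noise_sd, degenerate


def _smooth(values: np.ndarray, window_s: float, dt: float) -> np.ndarray:
    w = int(round(window_s / dt))
    if w < 2:
        return values
    if w % 2 == 0:
        w += 1
    from scipy.ndimage import uniform_filter1d

    return uniform_filter1d(values, size=w, mode="nearest")


def _interp_crossing(t0, t1, v0, v1, level) -> float:
    if v1 == v0:
        return float(t0)
    return float(t0 + (level - v0) * (t1 - t0) / (v1 - v0))


def _flank_time(
    times: np.ndarray,
    values: np.ndarray,
    peak_idx: int,
    lo_level: float,
    hi_level: float,
    bound_idx: int,
    direction: int,
) -> float:
    """10–90% flank duration on one side of a peak; NaN when truncated.

    ``direction`` −1 walks left (rise), +1 walks right (decay); ``bound_idx``
    is the last index that may be inspected (neighbor peak or record end).
    """
    t_hi = t_lo = None
    i = peak_idx
    while i != bound_idx:
        j = i + direction
        if t_hi is None and values[j] <= hi_level:
            t_hi = _interp_crossing(times[i], times[j], values[i], values[j], hi_level)
        if values[j] <= lo_level:
            t_lo = _interp_crossing(times[i], times[j], values[i], values[j], lo_level)
            break
        i = j
    if t_hi is None or t_lo is None:
        return float("nan")
    return abs(t_lo - t_hi)


def detect_events(
    trace: Trace,
    baseline: float,
    noise_sd: float,
    kappa: float = 3.0,
    min_separation: float = 2.0,
    smoothing_window: float = 0.25,
    hysteresis: float = 0.5,
) -> list[TransientEvent]:
    """Detect calcium transients above ``baseline + kappa * noise_sd``.

    Detection runs on a moving-average–smoothed copy of the trace (the raw
    trace when ``smoothing_window`` spans fewer than two samples).  An event
    is a maximal excursion above the detection threshold, extended with
    hysteresis to where the signal falls back below
    ``baseline + hysteresis * kappa * noise_sd`` — without the hysteresis,
    noise hovering around the threshold on a transient's decay flank would
    split one transient into several.  Excursions whose peaks are closer
    than ``min_separation`` seconds are then merged, keeping the higher
    peak.  Peak values are read from the smoothed trace, so amplitudes are
    not inflated by the expected maximum of the noise over the excursion.
    """
    from scipy.signal import find_peaks

    t = trace.times
    smooth = _smooth(trace.values, smoothing_window, trace.dt)
    thr = baseline + kappa * noise_sd
    low_thr = baseline + hysteresis * kappa * noise_sd

    distance = max(1, int(round(min_separation / trace.dt)))
    prominence = kappa * noise_sd if noise_sd > 0 else None
    peaks, _ = find_peaks(smooth, height=thr, distance=distance, prominence=prominence)
    if len(peaks) == 0:
        return []

    events: list[TransientEvent] = []
    for idx, p in enumerate(peaks):
        p = int(p)
        peak_value = float(smooth[p])
        amplitude = peak_value - baseline
        if amplitude <= 0:
            continue
        left_bound = int(peaks[idx - 1]) if idx > 0 else 0
        right_bound = int(peaks[idx + 1]) if idx + 1 < len(peaks) else len(t) - 1
        # event boundaries: where the signal falls back below the hysteresis
        # level, clipped at the valley toward a neighboring event
        seg = smooth[left_bound : p + 1]
        below = np.nonzero(seg <= low_thr)[0]
        onset_idx = left_bound + (int(below[-1]) if len(below) else int(np.argmin(seg)))
        seg = smooth[p : right_bound + 1]
        below = np.nonzero(seg <= low_thr)[0]
        offset_idx = p + (int(below[0]) if len(below) else int(np.argmin(seg)))
        lo = baseline + 0.1 * amplitude
        hi = baseline + 0.9 * amplitude
        rise = _flank_time(t, smooth, p, lo, hi, left_bound, -1)
        decay = _flank_time(t, smooth, p, lo, hi, right_bound, +1)
        events.append(
            TransientEvent(
                onset_time=float(t[onset_idx]),
                peak_time=float(t[p]),
                peak_value=peak_value,
                offset_time=float(t[offset_idx]),
                amplitude=float(amplitude),
                rise_time=rise,
                decay_time=decay,
            )
        )
    return events


#: Below this duration (s) the per-minute frequency is flagged unreliable.
MIN_RELIABLE_DURATION = 10.0


def featurize(trace: Trace, settings: FeaturizerSettings = FeaturizerSettings()) -> OscillationFeatures:
    """Extract :class:`OscillationFeatures` from one trace."""
    baseline, noise_sd, degenerate = estimate_baseline(trace, settings.baseline_quantile)
    events = detect_events(
        trace, baseline, noise_sd,
        kappa=settings.kappa,
        min_separation=settings.min_separation,
        smoothing_window=settings.smoothing_window,
        hysteresis=settings.hysteresis,
    )
    duration_min = trace.duration / 60.0
    frequency = len(events) / duration_min if duration_min > 0 else 0.0
    rises = [ev.rise_time for ev in events if not math.isnan(ev.rise_time)]
    decays = [ev.decay_time for ev in events if not math.isnan(ev.decay_time)]
    return OscillationFeatures(
        amplitude=float(np.mean([ev.amplitude for ev in events])) if events else None,
        threshold=baseline,
        frequency=frequency,
        rise_time=float(np.mean(rises)) if rises else None,
        decay_time=float(np.mean(decays)) if decays else None,
        n_events=len(events),
        degenerate=degenerate,
        short_record=trace.duration < MIN_RELIABLE_DURATION,
    )


def featurize_cohort(
    traces: Sequence[Trace], settings: FeaturizerSettings = FeaturizerSettings()
) -> pd.DataFrame:
    """Feature table with one row per cell (columns: cell_id, condition, features).

    Missing per-event features (cells with no detected events) are NaN.
    """
    if len(traces) == 0:
        raise ValidationError("empty cohort")
    ids = [tr.cell_id for tr in traces]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise FormatError(f"duplicate cell_id {dup!r} in cohort")
    rows = []
    for tr in traces:
        f = featurize(tr, settings)
        rows.append(
            {
                "cell_id": tr.cell_id,
                "condition": tr.condition,
                "amplitude": np.nan if f.amplitude is None else f.amplitude,
                "threshold": f.threshold,
                "frequency_per_min": f.frequency,
                "rise_time_s": np.nan if f.rise_time is None else f.rise_time,
                "decay_time_s": np.nan if f.decay_time is None else f.decay_time,
                "n_events": f.n_events,
            }
        )
    return pd.DataFrame(rows)
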