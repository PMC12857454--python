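"""Per-cardiac-cycle averaging of raw hemodynamic waveforms.

Finger-photoplethysmography pressure devices and transcranial Doppler
velocimeters are recorded as uniformly sampled waveforms (typically 1 kHz).
Beat-by-beat analysis works on the mean of each signal over each cardiac
cycle, with cycle onsets taken from an external detector (e.g., ECG R peaks).
The resulting beat series is deliberately left on its irregular cardiac time
grid: nothing here interpolates or resamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

#: Known acquisition delays of pressure monitors relative to the Doppler /
#: ECG channels, in seconds.  Applying the named shift time-aligns the
#: pressure waveform with the rest of the montage.
DEVICE_TIME_SHIFTS: dict[str, float] = {
    "nexfin": -0.250,
    "finometer": -1.000,
}

#: Plausible cardiac inter-beat interval range (s); boundary spacings outside
#: it are flagged but not rejected.
CARDIAC_INTERVAL_RANGE_S = (0.3, 2.5)


@dataclass(frozen=True)
class RawWaveform:
    """Uniformly sampled signal (mmHg or cm/s)."""

    sampling_rate_hz: float
    start_time_s: float
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("waveform values must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(len(self.values)) / self.sampling_rate_hz


@dataclass(frozen=True)
class CycleBoundaries:
    """Strictly increasing cardiac-cycle onset times (e.g., R-peak times)."""

    times_s: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        object.__setattr__(self, "times_s", t)
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("cycle boundary times must be strictly increasing")
        lo, hi = CARDIAC_INTERVAL_RANGE_S
        ivl = np.diff(t)
        bad = np.flatnonzero((ivl < lo) | (ivl > hi))
        if bad.size:
            log.warning(
                "%d cycle intervals outside plausible cardiac range %s s "
                "(first at t=%.3f s)", bad.size, CARDIAC_INTERVAL_RANGE_S,
                t[bad[0]],
            )


@dataclass(frozen=True)
class BeatSeries:
    """Per-cardiac-cycle mean signal on the (irregular) beat time grid.

    ``times_s`` are cycle midpoints; ``values`` the arithmetic mean of the raw
    samples within each cycle.
    """

    times_s: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "values", v)
        if len(t) != len(v):
            raise ValueError("times and values must have equal length")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("beat times must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return len(self.times_s)

    def truncated(self, t_max_s: float) -> "BeatSeries":
        """Beats with time <= ``t_max_s`` (used for duration-truncation runs)."""
        keep = self.times_s <= t_max_s
        return BeatSeries(self.times_s[keep], self.values[keep])


def apply_time_shift(w: RawWaveform, shift_s: float) -> RawWaveform:
    """Translate a waveform in time to undo a device acquisition delay.

    Samples are untouched; only ``start_time_s`` moves.  The applied shift is
    recorded in ``meta['time_shift_s']`` (cumulative over repeated calls).
    """
    if abs(shift_s) >= w.duration_s:
        raise ValueError(
            f"time shift {shift_s} s exceeds waveform duration {w.duration_s} s"
        )
    meta = dict(w.meta)
    meta["time_shift_s"] = meta.get("time_shift_s", 0.0) + shift_s
    return RawWaveform(
        sampling_rate_hz=w.sampling_rate_hz,
        start_time_s=w.start_time_s + shift_s,
        values=w.values,
        meta=meta,
    )


def average_over_cycles(w: RawWaveform, b: CycleBoundaries) -> BeatSeries:
    """Average a waveform over each cardiac cycle.

    Each consecutive boundary pair ``[t_i, t_{i+1})`` contributes one beat:
    value = mean of the samples falling in the half-open interval, timestamp =
    the interval midpoint.  Cycles containing no samples are dropped with a
    warning.
    """
    bt = b.times_s
    inside = (bt >= w.start_time_s) & (bt <= w.start_time_s + w.duration_s)
    if inside.sum() < 2:
        raise ValueError("need at least two cycle boundaries inside the waveform span")
    bt = bt[inside]

    t = w.times_s
    # index of first sample >= each boundary
    edges = np.searchsorted(t, bt, side="left")
    times, values = [], []
    dropped = 0
    for i in range(len(bt) - 1):
        lo, hi = edges[i], edges[i + 1]
        if hi <= lo:
            dropped += 1
            continue
        times.append(0.5 * (bt[i] + bt[i + 1]))
        values.append(float(w.values[lo:hi].mean()))
    if dropped:
        log.warning("dropped %d cardiac cycles containing no samples", dropped)
    return BeatSeries(np.asarray(times), np.asarray(values))
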