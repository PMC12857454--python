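"""Per-transition directional sensitivity metrics for forced MAP oscillations.

Repeated squat-stands (RSS) drive near-square-wave oscillations of mean
arterial pressure (MAP) at a protocol frequency (0.05 Hz: 20 s cycles;
0.10 Hz: 10 s cycles).  Within each cycle MAP rises from a minimum to a
maximum (INC) and falls back (DEC), and middle cerebral artery mean blood
velocity (MCAv) follows with its own extrema.  The directional-sensitivity
metric is the time-adjusted ratio of the MCAv rate of change to the MAP rate
of change over a single transition,

    ratio_abs = (dMCAv / dt_MCAv) / (dMAP / dt_MAP),

in cm/s per mmHg, together with a relative variant where each signal's change
is first normalised by the cycle minimum of that signal ("baseline"),

    ratio_rel = (%MCAv / dt_MCAv) / (%MAP / dt_MAP).

A ratio below one during INC relative to DEC expresses the hysteresis-like
attenuation of cerebral blood velocity responses to pressure rises.

This module detects the alternating extrema on beat series, assembles the
per-transition metrics, applies the artifact filters (a leading-instability
rule and a single-pass >3 SD outlier rule), and averages included transitions
over cumulative analysis windows (0-60 s ... 0-300 s).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .beat_processing import BeatSeries

log = logging.getLogger(__name__)

Direction = Literal["INC", "DEC"]


class NoOscillationError(ValueError):
    """The beat series carries no detectable protocol-driven oscillation."""


class BeatGapError(ValueError):
    """A gap in the beat series exceeds one protocol half-cycle."""


@dataclass(frozen=True)
class Extremum:
    kind: Literal["min", "max"]
    time_s: float
    value: float


@dataclass(frozen=True)
class TransitionMetrics:
    """One MAP transition (INC or DEC) with its matched MCAv response.

    Delta, rate and ratio fields are stored signed; descriptive summaries use
    absolute values (a negative ratio marks MCAv moving against MAP).
    """

    index: int
    direction: Direction
    map_from: Extremum
    map_to: Extremum
    mcav_from: Extremum | None
    mcav_to: Extremum | None
    delta_map: float
    delta_mcav: float
    dt_map: float
    dt_mcav: float
    rate_map: float
    rate_mcav: float
    rel_change_map: float
    rel_change_mcav: float
    ratio_abs: float
    ratio_rel: float
    included: bool = True
    exclusion_reason: Literal["none", "outlier", "initial_unstable", "incomplete"] = "none"


@dataclass(frozen=True)
class WindowSummary:
    """Mean metrics over included transitions in one cumulative window."""

    participant_id: str
    frequency_hz: float
    direction: Direction
    window_s: float
    n_included: int
    mean_ratio_abs: float
    mean_ratio_rel: float
    mean_delta_map: float
    mean_delta_mcav: float
    mean_dt_map: float
    mean_dt_mcav: float
    mean_rate_map: float
    mean_rate_mcav: float


def _moving_average(v: np.ndarray, width: int) -> np.ndarray:
    if width <= 1 or len(v) < width:
        return v
    kernel = np.ones(width) / width
    sm = np.convolve(v, kernel, mode="same")
    # edges of "same" convolution are biased toward zero; patch with partial means
    half = width // 2
    for i in range(half):
        sm[i] = v[: i + half + 1].mean()
        sm[-(i + 1)] = v[-(i + half + 1):].mean()
    return sm


def detect_extrema(
    series: BeatSeries,
    frequency_hz: float,
    *,
    min_amplitude: float = 5.0,
    smooth_beats: int = 3,
) -> list[Extremum]:
    """Detect the alternating min/max sequence driven by the RSS protocol.

    The search is anchored on the protocol half-cycle length ``1/(2f)``: the
    first extremum is located from a lightly smoothed copy of the series
    (whichever of the first cycle's global minimum or maximum occurs first
    fixes the phase), then each subsequent extremum is the global raw-beat
    extremum inside a window of 0.5-1.5 half-cycles after the previous one
    (first occurrence on ties).  Extremum values are read off the raw beats.
    """
    t = series.times_s
    v = series.values
    hc = 0.5 / frequency_hz
    if len(t) < 4 or t[-1] - t[0] < 2 * hc:
        raise NoOscillationError("series shorter than one full oscillation cycle")

    gaps = np.diff(t)
    worst = int(np.argmax(gaps))
    if gaps[worst] > hc:
        raise BeatGapError(
            f"gap of {gaps[worst]:.2f} s between beats at t={t[worst]:.2f} s "
            f"and t={t[worst + 1]:.2f} s exceeds one half-cycle ({hc:.2f} s)"
        )

    sm = _moving_average(v, smooth_beats)
    # detectability: at least one full cycle must show a smoothed peak-trough
    # amplitude above threshold (the lead-in may legitimately be smaller)
    edges = np.arange(t[0], t[-1] + 2 * hc, 2 * hc)
    spans = [
        sm[(t >= lo) & (t < hi)] for lo, hi in zip(edges[:-1], edges[1:])
    ]
    amps = [s.max() - s.min() for s in spans if s.size >= 2]
    if not amps or max(amps) < min_amplitude:
        raise NoOscillationError(
            "no oscillation: best smoothed single-cycle peak-trough amplitude "
            f"{max(amps) if amps else 0.0:.2f} below detectability "
            f"threshold {min_amplitude}"
        )

    # phase: earlier of the first cycle's smoothed global min / max
    idx = np.flatnonzero(t <= t[0] + 2 * hc)
    i_max = idx[int(np.argmax(sm[idx]))]
    i_min = idx[int(np.argmin(sm[idx]))]
    kind: str = "max" if t[i_max] < t[i_min] else "min"
    anchor = i_max if kind == "max" else i_min

    # refine the anchor on raw beats within half a half-cycle
    sel = np.flatnonzero(np.abs(t - t[anchor]) <= 0.5 * hc)
    pick = sel[int(np.argmax(v[sel]))] if kind == "max" else sel[int(np.argmin(v[sel]))]
    extrema = [Extremum(kind, float(t[pick]), float(v[pick]))]

    # walk backward: an opposite extremum may precede the anchor at the very
    # start of the recording (smoothing biases the edge, so the anchor can
    # land on the second extremum).  A candidate is only accepted when its
    # excursion from the anchor is a substantial fraction of the overall
    # oscillation amplitude, so a recording that starts mid-slope does not
    # grow a spurious boundary extremum.
    amp_ref = float(sm.max() - sm.min())
    while True:
        first = extrema[0]
        lo, hi = first.time_s - 1.5 * hc, first.time_s - 0.5 * hc
        if hi < t[0]:
            break
        sel = np.flatnonzero((t >= lo) & (t <= hi))
        if sel.size == 0:
            break
        kind = "min" if first.kind == "max" else "max"
        pick = sel[int(np.argmax(v[sel]))] if kind == "max" else sel[int(np.argmin(v[sel]))]
        if abs(float(v[pick]) - first.value) < 0.6 * amp_ref:
            break
        extrema.insert(0, Extremum(kind, float(t[pick]), float(v[pick])))

    while True:
        last = extrema[-1]
        lo, hi = last.time_s + 0.5 * hc, last.time_s + 1.5 * hc
        if lo > t[-1]:
            break
        sel = np.flatnonzero((t >= lo) & (t <= hi))
        if sel.size == 0:
            break
        kind = "min" if last.kind == "max" else "max"
        pick = sel[int(np.argmax(v[sel]))] if kind == "max" else sel[int(np.argmin(v[sel]))]
        extrema.append(Extremum(kind, float(t[pick]), float(v[pick])))
    return extrema


def _nearest(cands: Sequence[Extremum], time_s: float, tol_s: float) -> Extremum | None:
    best, best_d = None, tol_s
    for e in cands:
        d = abs(e.time_s - time_s)
        if d <= best_d:
            best, best_d = e, d
    return best


def build_transitions(
    map_ext: Sequence[Extremum],
    mcav_ext: Sequence[Extremum],
    frequency_hz: float,
) -> list[TransitionMetrics]:
    """Pair MAP extrema into INC/DEC transitions and match the MCAv response.

    Each consecutive MAP extremum pair defines one transition (min->max: INC,
    max->min: DEC).  The MCAv extrema of matching kind nearest in time to the
    MAP extrema (within a quarter cycle) complete the transition; when either
    side is missing the transition is emitted excluded with reason
    ``incomplete``.  Relative changes use each signal's transition minimum as
    baseline.
    """
    hc = 0.5 / frequency_hz
    tol = 0.5 * hc
    mcav_min = [e for e in mcav_ext if e.kind == "min"]
    mcav_max = [e for e in mcav_ext if e.kind == "max"]

    out: list[TransitionMetrics] = []
    for i in range(len(map_ext) - 1):
        a, b = map_ext[i], map_ext[i + 1]
        direction: Direction = "INC" if b.kind == "max" else "DEC"
        va = _nearest(mcav_min if a.kind == "min" else mcav_max, a.time_s, tol)
        vb = _nearest(mcav_min if b.kind == "min" else mcav_max, b.time_s, tol)

        dt_map = b.time_s - a.time_s
        delta_map = b.value - a.value
        rate_map = delta_map / dt_map
        base_map = min(a.value, b.value)
        rel_map = delta_map / base_map

        if va is None or vb is None or vb.time_s <= va.time_s:
            out.append(
                TransitionMetrics(
                    index=i, direction=direction, map_from=a, map_to=b,
                    mcav_from=va, mcav_to=vb,
                    delta_map=delta_map, delta_mcav=math.nan,
                    dt_map=dt_map, dt_mcav=math.nan,
                    rate_map=rate_map, rate_mcav=math.nan,
                    rel_change_map=rel_map, rel_change_mcav=math.nan,
                    ratio_abs=math.nan, ratio_rel=math.nan,
                    included=False, exclusion_reason="incomplete",
                )
            )
            continue

        dt_mcav = vb.time_s - va.time_s
        delta_mcav = vb.value - va.value
        rate_mcav = delta_mcav / dt_mcav
        base_mcav = min(va.value, vb.value)
        rel_mcav = delta_mcav / base_mcav
        out.append(
            TransitionMetrics(
                index=i, direction=direction, map_from=a, map_to=b,
                mcav_from=va, mcav_to=vb,
                delta_map=delta_map, delta_mcav=delta_mcav,
                dt_map=dt_map, dt_mcav=dt_mcav,
                rate_map=rate_map, rate_mcav=rate_mcav,
                rel_change_map=rel_map, rel_change_mcav=rel_mcav,
                ratio_abs=rate_mcav / rate_map,
                ratio_rel=(rel_mcav / dt_mcav) / (rel_map / dt_map),
            )
        )
    return out


def flag_initial_unstable(
    transitions: Sequence[TransitionMetrics],
    *,
    fraction_of_median: float = 0.5,
) -> list[TransitionMetrics]:
    """Exclude unstable leading transitions.

    Automated stand-in for the visual discarding of atypical oscillations at
    the start of a recording: leading transitions whose |delta MAP| falls
    below ``fraction_of_median`` of the recording's median |delta MAP| are
    excluded (reason ``initial_unstable``) up to the first passing transition;
    later transitions are never touched by this rule.
    """
    deltas = [abs(tr.delta_map) for tr in transitions if np.isfinite(tr.delta_map)]
    if not deltas:
        return list(transitions)
    threshold = fraction_of_median * float(np.median(deltas))
    out = []
    leading = True
    for tr in transitions:
        if leading and abs(tr.delta_map) < threshold:
            out.append(replace(tr, included=False, exclusion_reason="initial_unstable"))
        else:
            leading = False
            out.append(tr)
    return out


def _zscore_outlier_mask(values: np.ndarray, sd_multiplier: float) -> np.ndarray:
    """Single-pass mean/SD outlier mask (sample SD, n-1); no value flagged
    when the SD is zero."""
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        return np.zeros(len(values), dtype=bool)
    return np.abs(values - mean) > sd_multiplier * sd


def flag_outliers(
    transitions: Sequence[TransitionMetrics],
    sd_multiplier: float = 3.0,
) -> list[TransitionMetrics]:
    """Exclude per-transition ratio artifacts (> ``sd_multiplier`` SD).

    Within each direction group, the mean and sample SD of the |ratio| values
    of currently included transitions over the full recording are computed
    once and values outside the band are excluded (reason ``outlier``).  The
    pass is applied independently to the absolute and relative ratios; a
    transition is excluded if either trips.  Groups with fewer than three
    included transitions are left unfiltered with a warning.
    """
    out = list(transitions)
    for direction in ("INC", "DEC"):
        idx = [
            i for i, tr in enumerate(out)
            if tr.direction == direction and tr.included and np.isfinite(tr.ratio_abs)
        ]
        if len(idx) < 3:
            if idx:
                log.warning(
                    "direction %s has only %d included transitions; "
                    "outlier filter skipped", direction, len(idx),
                )
            continue
        flagged = np.zeros(len(idx), dtype=bool)
        for attr in ("ratio_abs", "ratio_rel"):
            vals = np.array([abs(getattr(out[i], attr)) for i in idx])
            flagged |= _zscore_outlier_mask(vals, sd_multiplier)
        for j, i in enumerate(idx):
            if flagged[j]:
                out[i] = replace(out[i], included=False, exclusion_reason="outlier")
    return out


def window_average(
    transitions: Sequence[TransitionMetrics],
    window_lengths_s: Sequence[float],
    *,
    participant_id: str,
    frequency_hz: float,
) -> list[WindowSummary]:
    """Average included transitions over cumulative windows from time zero.

    A transition belongs to window ``W`` iff the time of its terminal MAP
    extremum is <= ``W`` (a transition only counts once complete), so each
    shorter window's transitions are a prefix of every longer one.  Ratio,
    delta and rate summaries are means of absolute values; empty windows yield
    ``n_included=0`` with NaN means.
    """
    out = []
    for direction in ("INC", "DEC"):
        for w in window_lengths_s:
            sel = [
                tr for tr in transitions
                if tr.direction == direction and tr.included
                and tr.map_to.time_s <= w
            ]
            if sel:
                def m(fn):
                    return float(np.mean([fn(tr) for tr in sel]))
                out.append(WindowSummary(
                    participant_id=participant_id,
                    frequency_hz=frequency_hz,
                    direction=direction,
                    window_s=float(w),
                    n_included=len(sel),
                    mean_ratio_abs=m(lambda tr: abs(tr.ratio_abs)),
                    mean_ratio_rel=m(lambda tr: abs(tr.ratio_rel)),
                    mean_delta_map=m(lambda tr: abs(tr.delta_map)),
                    mean_delta_mcav=m(lambda tr: abs(tr.delta_mcav)),
                    mean_dt_map=m(lambda tr: tr.dt_map),
                    mean_dt_mcav=m(lambda tr: tr.dt_mcav),
                    mean_rate_map=m(lambda tr: abs(tr.rate_map)),
                    mean_rate_mcav=m(lambda tr: abs(tr.rate_mcav)),
                ))
            else:
                out.append(WindowSummary(
                    participant_id=participant_id,
                    frequency_hz=frequency_hz,
                    direction=direction,
                    window_s=float(w),
                    n_included=0,
                    mean_ratio_abs=math.nan, mean_ratio_rel=math.nan,
                    mean_delta_map=math.nan, mean_delta_mcav=math.nan,
                    mean_dt_map=math.nan, mean_dt_mcav=math.nan,
                    mean_rate_map=math.nan, mean_rate_mcav=math.nan,
                ))
    return out
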