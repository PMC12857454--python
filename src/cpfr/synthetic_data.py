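"""Simulated repeated squat-stand (RSS) hemodynamics with known ground truth.

MAP is modelled as a periodic piecewise-linear oscillation around a baseline:
each protocol cycle rises from a minimum to a maximum over ``rise_fraction``
of the cycle and falls back over the remainder (squat-stand forcing is
square-wave-like, and a piecewise-linear shape keeps every per-transition
delta, interval and rate analytically exact for oracle tests).  MCAv follows
the same cycles with its own segment durations and a single per-cycle
amplitude; its rise/fall durations are derived from the programmed
directional gains

    gain_inc = (dMCAv/dt_MCAv) / (dMAP/dt_MAP)   on rising segments,
    gain_dec = idem on falling segments,

which is the only closure consistent with a periodic waveform (equal rise and
fall amplitudes within a cycle).  With the default 0.10 Hz parameters (gains
0.91 / 1.01, MAP intervals 4.8 / 5.2 s) the derived MCAv intervals are
5.06 / 4.94 s, matching the interval asymmetry observed in humans.

Both signals are sampled at irregular cardiac beat times, i.i.d. Gaussian
beat noise is added, a small fraction of beats is replaced by artifact
spikes, and the first cycles can be generated at reduced (40%) amplitude to
emulate the unstable lead-in of a real recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .beat_processing import BeatSeries
from .signal_io import Recording


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults emulate a healthy adult at 0.05 Hz RSS."""

    seed: int = 0
    frequency_hz: float = 0.05
    duration_s: float = 310.0
    beat_interval_mean_s: float = 0.82
    beat_interval_sd_s: float = 0.05
    map_baseline_mmhg: float = 90.0
    mcav_baseline_cms: float = 62.0
    map_osc_amplitude_mmhg: float = 40.0
    gain_inc: float = 0.91
    gain_dec: float = 1.01
    rise_fraction: float | None = None  # default 0.46 at 0.05 Hz, 0.48 at 0.10 Hz
    mcav_time_scale_inc: float | None = None  # None: derived from the gains
    mcav_time_scale_dec: float | None = None
    beat_noise_sd_map: float = 1.0
    beat_noise_sd_mcav: float = 0.8
    cycle_amplitude_cv_map: float = 0.05
    cycle_amplitude_cv_mcav: float = 0.04
    drift_mmhg_per_min: float = 0.0
    artifact_rate: float = 0.005
    unstable_lead_cycles: int = 1
    corner_aligned_beats: bool = False
    participant_id: str = "sim01"

    def __post_init__(self) -> None:
        if self.gain_inc <= 0 or self.gain_dec <= 0:
            raise ValueError("directional gains must be positive")
        if self.map_osc_amplitude_mmhg <= 0:
            raise ValueError("oscillation amplitude must be positive")
        rf = self.resolved_rise_fraction
        if not 0.2 < rf < 0.8:
            raise ValueError(f"rise_fraction {rf} outside (0.2, 0.8)")
        if self.duration_s < 2.0 / self.frequency_hz:
            raise ValueError("duration must cover at least two oscillation cycles")

    @property
    def resolved_rise_fraction(self) -> float:
        if self.rise_fraction is not None:
            return self.rise_fraction
        return 0.48 if self.frequency_hz >= 0.075 else 0.46

    @classmethod
    def noiseless(cls, frequency_hz: float, **overrides) -> "SynthConfig":
        """Oracle configuration: zero noise/artifacts/lead-in, a regular beat
        grid, and beats aligned to the protocol corners so that the discrete
        beat series samples every true extremum exactly."""
        base = dict(
            frequency_hz=frequency_hz,
            duration_s=300.0,
            beat_interval_mean_s=0.8,
            beat_interval_sd_s=0.0,
            beat_noise_sd_map=0.0,
            beat_noise_sd_mcav=0.0,
            cycle_amplitude_cv_map=0.0,
            cycle_amplitude_cv_mcav=0.0,
            drift_mmhg_per_min=0.0,
            artifact_rate=0.0,
            unstable_lead_cycles=0,
            corner_aligned_beats=True,
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class TransitionTruth:
    cycle: int
    direction: str
    terminal_time_s: float
    delta_map: float
    delta_mcav: float
    dt_map: float
    dt_mcav: float
    gain: float
    stable: bool


@dataclass(frozen=True)
class SynthTruth:
    """Programmed quantities attached to one simulated recording."""

    config: SynthConfig
    gain_inc: float  # realized time-adjusted INC ratio of the clean waveform
    gain_dec: float
    map_rise_s: float
    map_fall_s: float
    mcav_rise_s: float
    mcav_fall_s: float
    mcav_osc_amplitude_cms: float
    transitions: tuple[TransitionTruth, ...] = field(default_factory=tuple)


def _geometry(c: SynthConfig):
    """MAP/MCAv segment durations and the MCAv amplitude closing the cycle."""
    cycle = 1.0 / c.frequency_hz
    r_map = c.resolved_rise_fraction * cycle
    f_map = cycle - r_map
    a = c.map_osc_amplitude_mmhg
    if c.mcav_time_scale_inc is not None:
        r_v = c.mcav_time_scale_inc * r_map
        f_v = cycle - r_v
        b = c.gain_inc * a * r_v / r_map
    else:
        b = a * cycle / (r_map / c.gain_inc + f_map / c.gain_dec)
        r_v = b * r_map / (a * c.gain_inc)
        f_v = cycle - r_v
    g_inc = (b / r_v) / (a / r_map)
    g_dec = (b / f_v) / (a / f_map)
    return cycle, r_map, f_map, r_v, f_v, b, g_inc, g_dec


def _corners(starts, rise_s, amps, baseline):
    """Piecewise-linear corner times/values for min->max->min cycles."""
    times = [starts[0]]
    vals = [baseline - amps[0] / 2.0]
    for i, s in enumerate(starts):
        nxt = amps[i + 1] if i + 1 < len(amps) else amps[i]
        times.append(s + rise_s)
        vals.append(baseline + amps[i] / 2.0)
        times.append(s + (starts[1] - starts[0]))
        vals.append(baseline - nxt / 2.0)
    return np.asarray(times), np.asarray(vals)


def _beat_times(c: SynthConfig, rng: np.random.Generator, corner_times: np.ndarray):
    t, times = 0.0, [0.0]
    while True:
        step = c.beat_interval_mean_s
        if c.beat_interval_sd_s > 0:
            step = max(0.3, rng.normal(c.beat_interval_mean_s, c.beat_interval_sd_s))
        t += step
        if t > c.duration_s:
            break
        times.append(t)
    beats = np.asarray(times)
    if c.corner_aligned_beats:
        corners = corner_times[corner_times <= c.duration_s]
        # drop beats hugging a corner, then insert the exact corner times
        near = np.min(np.abs(beats[:, None] - corners[None, :]), axis=1)
        beats = np.unique(np.concatenate([
            beats[near > 0.25 * c.beat_interval_mean_s], corners,
        ]))
    return beats


def simulate_recording(c: SynthConfig) -> tuple[Recording, SynthTruth]:
    """Generate one beat-by-beat RSS recording plus its ground truth."""
    rng = np.random.default_rng(c.seed)
    cycle, r_map, f_map, r_v, f_v, b_amp, g_inc, g_dec = _geometry(c)

    n_cycles = int(math.ceil(c.duration_s / cycle)) + 1
    starts = np.arange(n_cycles) * cycle
    lead = np.where(np.arange(n_cycles) < c.unstable_lead_cycles, 0.4, 1.0)
    # per-cycle physiological amplitude variability (squat depth, breathing);
    # the MCAv amplitude tracks the MAP amplitude with its own deviation
    e_map = 1.0 + (rng.normal(0.0, c.cycle_amplitude_cv_map, n_cycles)
                   if c.cycle_amplitude_cv_map > 0 else 0.0)
    e_mcav = 1.0 + (rng.normal(0.0, c.cycle_amplitude_cv_mcav, n_cycles)
                    if c.cycle_amplitude_cv_mcav > 0 else 0.0)
    a_amps = c.map_osc_amplitude_mmhg * lead * np.clip(e_map, 0.5, 1.5)
    v_amps = b_amp * lead * np.clip(e_map * e_mcav, 0.5, 1.5)

    map_t, map_v = _corners(starts, r_map, a_amps, c.map_baseline_mmhg)
    mcav_t, mcav_v = _corners(starts, r_v, v_amps, c.mcav_baseline_cms)

    beats = _beat_times(c, rng, np.union1d(map_t, mcav_t))
    map_beats = np.interp(beats, map_t, map_v)
    mcav_beats = np.interp(beats, mcav_t, mcav_v)
    if c.drift_mmhg_per_min:
        map_beats = map_beats + c.drift_mmhg_per_min * beats / 60.0
    if c.beat_noise_sd_map > 0:
        map_beats = map_beats + rng.normal(0.0, c.beat_noise_sd_map, len(beats))
    if c.beat_noise_sd_mcav > 0:
        mcav_beats = mcav_beats + rng.normal(0.0, c.beat_noise_sd_mcav, len(beats))
    if c.artifact_rate > 0:
        for arr, scale in ((map_beats, c.map_osc_amplitude_mmhg), (mcav_beats, b_amp)):
            hit = rng.random(len(beats)) < c.artifact_rate
            arr[hit] += rng.choice([-1.0, 1.0], hit.sum()) * 0.5 * scale

    truths = []
    for i in range(n_cycles):
        stable = i >= c.unstable_lead_cycles
        fa = a_amps[i]
        fb = v_amps[i]
        if starts[i] + r_map <= c.duration_s:
            truths.append(TransitionTruth(
                cycle=i, direction="INC", terminal_time_s=float(starts[i] + r_map),
                delta_map=float(fa), delta_mcav=float(fb),
                dt_map=float(r_map), dt_mcav=float(r_v),
                gain=float(g_inc), stable=stable,
            ))
        if starts[i] + cycle <= c.duration_s:
            truths.append(TransitionTruth(
                cycle=i, direction="DEC", terminal_time_s=float(starts[i] + cycle),
                delta_map=float(fa), delta_mcav=float(fb),
                dt_map=float(f_map), dt_mcav=float(f_v),
                gain=float(g_dec), stable=stable,
            ))

    rec = Recording(
        participant_id=c.participant_id,
        frequency_hz=c.frequency_hz,
        map_series=BeatSeries(beats, map_beats),
        mcav_series=BeatSeries(beats, mcav_beats),
        meta={"synthetic": True, "seed": c.seed},
    )
    truth = SynthTruth(
        config=c, gain_inc=float(g_inc), gain_dec=float(g_dec),
        map_rise_s=float(r_map), map_fall_s=float(f_map),
        mcav_rise_s=float(r_v), mcav_fall_s=float(f_v),
        mcav_osc_amplitude_cms=float(b_amp),
        transitions=tuple(truths),
    )
    return rec, truth


@dataclass(frozen=True)
class CohortSpread:
    """Between-subject SDs of the generator parameters.

    The directional asymmetry (gain_dec - gain_inc) is a within-subject
    contrast, so its between-subject spread is parameterised separately from
    (and well below) the spread of the overall gain level.
    """

    gain_mean_sd: float = 0.15
    gain_asym_sd: float = 0.05
    map_amplitude_sd: float = 10.0
    map_baseline_sd: float = 12.0
    mcav_baseline_sd: float = 12.0
    beat_interval_sd: float = 0.08


def simulate_cohort(
    n_participants: int,
    base: SynthConfig,
    spread: CohortSpread | None = None,
    seed: int = 0,
) -> tuple[list[Recording], list[SynthTruth]]:
    """Simulate a cohort with per-participant parameters drawn around ``base``.

    Child seeds are derived deterministically from ``seed``; respiratory
    covariates are not modelled (all simulated participants breathe, by
    construction, outside the protocol frequency band).
    """
    if n_participants < 3:
        raise ValueError("a cohort needs at least three participants")
    spread = spread or CohortSpread()
    rng = np.random.default_rng(seed)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_participants) % (2**31)

    gain_mean0 = 0.5 * (base.gain_inc + base.gain_dec)
    asym0 = base.gain_dec - base.gain_inc

    recordings, truths = [], []
    for i in range(n_participants):
        gm = max(0.2, rng.normal(gain_mean0, spread.gain_mean_sd))
        asym = rng.normal(asym0, spread.gain_asym_sd)
        g_inc = max(0.05, gm - asym / 2.0)
        g_dec = max(0.05, gm + asym / 2.0)
        cfg = replace(
            base,
            seed=int(child_seeds[i]),
            participant_id=f"sim{i + 1:03d}",
            gain_inc=g_inc,
            gain_dec=g_dec,
            map_osc_amplitude_mmhg=max(
                10.0, rng.normal(base.map_osc_amplitude_mmhg, spread.map_amplitude_sd)),
            map_baseline_mmhg=max(
                60.0, rng.normal(base.map_baseline_mmhg, spread.map_baseline_sd)),
            mcav_baseline_cms=max(
                30.0, rng.normal(base.mcav_baseline_cms, spread.mcav_baseline_sd)),
            beat_interval_mean_s=float(np.clip(
                rng.normal(base.beat_interval_mean_s, spread.beat_interval_sd),
                0.5, 1.4)),
        )
        rec, truth = simulate_recording(cfg)
        recordings.append(rec)
        truths.append(truth)
    return recordings, truths
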