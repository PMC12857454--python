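"""End-to-end glue: recordings -> transitions -> window summaries -> stats."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import transition_metrics as tm
from .group_stats import RmAnovaResult, rm_anova_2way
from .signal_io import (
    Recording,
    RunConfig,
    summaries_to_frame,
    transitions_to_frame,
)


def process_recording(
    rec: Recording, config: RunConfig
) -> tuple[list[tm.TransitionMetrics], list[tm.WindowSummary]]:
    """Run the full per-recording metric chain with the configured filters."""
    f = rec.frequency_hz
    map_ext = tm.detect_extrema(
        rec.map_series, f, min_amplitude=config.filtering.min_amplitude)
    mcav_ext = tm.detect_extrema(
        rec.mcav_series, f, min_amplitude=config.filtering.min_amplitude)
    transitions = tm.build_transitions(map_ext, mcav_ext, f)
    transitions = tm.flag_initial_unstable(
        transitions,
        fraction_of_median=config.filtering.initial_fraction_of_median)
    transitions = tm.flag_outliers(transitions, config.filtering.sd_multiplier)
    summaries = tm.window_average(
        transitions, config.protocol.window_lengths_s,
        participant_id=rec.participant_id, frequency_hz=f)
    return transitions, summaries


def analyze_cohort(recordings, config: RunConfig) -> dict[str, pd.DataFrame]:
    """Per-recording metrics for a cohort, as tidy frames keyed by table kind."""
    trans_frames, summary_rows = [], []
    for rec in recordings:
        transitions, summaries = process_recording(rec, config)
        trans_frames.append(transitions_to_frame(
            transitions, participant_id=rec.participant_id,
            frequency_hz=rec.frequency_hz))
        summary_rows.extend(summaries)
    return {
        "transitions": pd.concat(trans_frames, ignore_index=True),
        "window_summaries": summaries_to_frame(summary_rows),
    }


def direction_duration_table(
    summaries: pd.DataFrame, metric: str = "ratio_abs"
) -> tuple[np.ndarray, list[str], list[float]]:
    """Pivot window summaries to the n x direction x duration ANOVA array.

    Participants with any missing cell are dropped.  Returns the array plus
    the direction and duration level labels.
    """
    wide = summaries.pivot_table(
        index="participant", columns=["direction", "window_s"],
        values=f"mean_{metric}", aggfunc="first")
    wide = wide.dropna(axis=0)
    directions = sorted({c[0] for c in wide.columns})
    durations = sorted({c[1] for c in wide.columns})
    x = np.empty((len(wide), len(directions), len(durations)))
    for i, d in enumerate(directions):
        for j, w in enumerate(durations):
            x[:, i, j] = wide[(d, w)].to_numpy()
    return x, directions, durations


def direction_effect(
    summaries: pd.DataFrame, metric: str = "ratio_abs", gg_correction: bool = True
) -> list[RmAnovaResult]:
    """Two-way RM-ANOVA (direction x duration) on a cohort's summaries."""
    x, _, _ = direction_duration_table(summaries, metric)
    return rm_anova_2way(x, gg_correction=gg_correction)
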